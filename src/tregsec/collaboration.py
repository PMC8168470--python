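"""Regulator collaboration quadrants for Treg DEGs.

A regulator perturbation contrast (transcription-factor knockout or
antibody blockade versus control) is compared with a Treg-vs-Tconv
contrast.  The polarity convention is fixed: a gene DOWN after removing or
blocking the regulator is a candidate *regulator-induced* gene; a gene UP
is a candidate *regulator-suppressed* gene.  Crossing this with the Treg
DEG direction gives four disjoint classes covering every Treg DEG:

* induced        — Treg-up  ∩ perturbation-down (regulator drives it up)
* suppressed     — Treg-down ∩ perturbation-up  (regulator keeps it down)
* noncollab_up   — remaining Treg-up genes
* noncollab_down — remaining Treg-down genes

Same-direction overlaps (e.g. Treg-up and perturbation-up) and genes that
are not DEG — or not measured — in the perturbation all count as
non-collaboration: with DEG-table inputs they cannot be told apart.  A
strict mode drops unmeasured genes from the denominator instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from .de import ContrastResult
from .decompose import percent
from .screens import GroupComparison, compare_groups


class Regulator(str, enum.Enum):
    FOXP3 = "FOXP3"
    CTLA4 = "CTLA4"
    PD1 = "PD1"
    NOX2 = "NOX2"
    NRF2 = "NRF2"
    CUSTOM = "custom"


class PerturbationKind(str, enum.Enum):
    KNOCKOUT = "knockout"
    BLOCKADE = "blockade"


@dataclass
class RegulatorContrast:
    """A perturbation-vs-control contrast for one regulator.

    Blockade datasets share the knockout polarity convention: blockade-down
    means regulator-induced-candidate.
    """

    regulator: Regulator | str
    perturbation_kind: PerturbationKind | str
    contrast: ContrastResult

    def __post_init__(self) -> None:
        self.regulator = Regulator(self.regulator)
        self.perturbation_kind = PerturbationKind(self.perturbation_kind)


@dataclass
class CollaborationPartition:
    """Disjoint four-way classification of one Treg contrast's DEGs."""

    dataset_id: str
    regulator: str
    induced: frozenset[str]
    suppressed: frozenset[str]
    noncollab_up: frozenset[str]
    noncollab_down: frozenset[str]

    @property
    def total_deg(self) -> int:
        return (
            len(self.induced)
            + len(self.suppressed)
            + len(self.noncollab_up)
            + len(self.noncollab_down)
        )

    @property
    def n_noncollab(self) -> int:
        return len(self.noncollab_up) + len(self.noncollab_down)

    @property
    def n_collab(self) -> int:
        return len(self.induced) + len(self.suppressed)

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "regulator": self.regulator,
            "induced": len(self.induced),
            "suppressed": len(self.suppressed),
            "noncollab_up": len(self.noncollab_up),
            "noncollab_down": len(self.noncollab_down),
            "total_deg": self.total_deg,
            "noncollab_pct": noncollab_fraction(self),
            "noncollab_up_pct_of_up": noncollab_fraction(self, among="up"),
        }


def partition_collaboration(
    treg: ContrastResult,
    reg: RegulatorContrast,
    strict: bool = False,
) -> CollaborationPartition:
    """Classify every Treg DEG by agreement with the perturbation contrast.

    With ``strict=True`` Treg DEGs not measured in the perturbation dataset
    are dropped entirely (removed from the denominator) instead of being
    counted as non-collaboration.
    """
    pert = reg.contrast
    treg_up = treg.up_genes
    treg_down = treg.down_genes
    if strict:
        treg_up = treg_up & pert.genes
        treg_down = treg_down & pert.genes
    induced = treg_up & pert.down_genes
    suppressed = treg_down & pert.up_genes
    return CollaborationPartition(
        dataset_id=treg.dataset_id,
        regulator=reg.regulator.value,
        induced=frozenset(induced),
        suppressed=frozenset(suppressed),
        noncollab_up=frozenset(treg_up - induced),
        noncollab_down=frozenset(treg_down - suppressed),
    )


def noncollab_fraction(
    partition: CollaborationPartition, among: str = "all"
) -> float | None:
    """Percent of non-collaboration genes, two decimals.

    ``among='all'`` uses all Treg DEGs as the denominator; ``among='up'``
    (or ``'down'``) restricts both numerator and denominator to that Treg
    direction — published headline fractions are ambiguous between the two,
    so both are available.  Missing (None) when the denominator is zero.
    """
    if among == "all":
        return percent(partition.n_noncollab, partition.total_deg)
    if among == "up":
        return percent(
            len(partition.noncollab_up),
            len(partition.induced) + len(partition.noncollab_up),
        )
    if among == "down":
        return percent(
            len(partition.noncollab_down),
            len(partition.suppressed) + len(partition.noncollab_down),
        )
    raise ValueError(f"unknown denominator choice {among!r}")


def compare_noncollab_across_groups(
    partitions: Mapping[str, CollaborationPartition],
    groups: Mapping[str, str],
    focal_group: str | None = "tumor_tissue",
    metric: str = "n_noncollab",
) -> GroupComparison:
    """Group comparison of per-dataset non-collaboration counts.

    ``groups`` maps dataset_id -> condition group.  Groups with < 2 datasets
    are excluded from the test (with the exclusion recorded); fewer than two
    testable groups raises.
    """
    values: dict[str, list[float]] = {}
    for dataset_id, part in partitions.items():
        if dataset_id not in groups:
            raise ValueError(f"dataset {dataset_id!r} has no condition group")
        value = getattr(part, metric)
        values.setdefault(str(groups[dataset_id]), []).append(float(value))
    if focal_group is not None and focal_group not in values:
        focal_group = None
    return compare_groups(values, metric=metric, focal_group=focal_group)
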