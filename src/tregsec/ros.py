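"""ROS regulatome: the NOX2-KO x NRF2-KO gene partition and Treg screens.

NOX2 (the phagocyte NADPH oxidase catalytic subunit) generates reactive
oxygen species; NRF2 is the master antioxidant transcription factor.  A
gene differentially expressed in *both* knockout contrasts can therefore be
classified by the sign pattern:

* **ROS-promoted**  — up in NOX2 KO and down in NRF2 KO
  (losing the oxidase de-represses it, losing the antioxidant lowers it);
* **ROS-suppressed** — down in NOX2 KO and up in NRF2 KO;
* **uncertain**      — DEG in both contrasts with the same sign.

Genes DEG in only one contrast are excluded from the partition entirely.
Treg contrasts are then screened against the three classes by plain
intersection with their up/down DEG sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .de import ContrastResult
from .screens import GroupComparison, compare_groups


@dataclass
class ROSPartition:
    """Disjoint promoted/suppressed/uncertain gene sets from the dual KO."""

    promoted: frozenset[str]
    suppressed: frozenset[str]
    uncertain: frozenset[str]

    @property
    def total_classified(self) -> int:
        return len(self.promoted) + len(self.suppressed) + len(self.uncertain)

    def class_of(self, gene: str) -> str | None:
        if gene in self.promoted:
            return "promoted"
        if gene in self.suppressed:
            return "suppressed"
        if gene in self.uncertain:
            return "uncertain"
        return None

    def to_dict(self) -> dict:
        return {
            "promoted": len(self.promoted),
            "suppressed": len(self.suppressed),
            "uncertain": len(self.uncertain),
            "total_classified": self.total_classified,
        }


def classify_ros(nox2: ContrastResult, nrf2: ContrastResult) -> ROSPartition:
    """Partition the genes DEG in both KO contrasts by sign pattern.

    Either contrast with zero DEGs yields an empty partition.  Swapping the
    two inputs swaps promoted and suppressed and leaves uncertain fixed.
    """
    both = nox2.deg_genes & nrf2.deg_genes
    promoted = nox2.up_genes & nrf2.down_genes
    suppressed = nox2.down_genes & nrf2.up_genes
    uncertain = both - promoted - suppressed
    return ROSPartition(
        promoted=frozenset(promoted),
        suppressed=frozenset(suppressed),
        uncertain=frozenset(uncertain),
    )


@dataclass
class ROSScreenRecord:
    """Counts of one Treg contrast's up/down DEGs in each ROS class."""

    dataset_id: str
    n_up_promoted: int
    n_down_promoted: int
    n_up_suppressed: int
    n_down_suppressed: int

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "up_promoted": self.n_up_promoted,
            "down_promoted": self.n_down_promoted,
            "up_suppressed": self.n_up_suppressed,
            "down_suppressed": self.n_down_suppressed,
        }


def screen_contrast(treg: ContrastResult, partition: ROSPartition) -> ROSScreenRecord:
    """Plain intersections of the Treg up/down DEG sets with ROS classes."""
    up = treg.up_genes
    down = treg.down_genes
    return ROSScreenRecord(
        dataset_id=treg.dataset_id,
        n_up_promoted=len(up & partition.promoted),
        n_down_promoted=len(down & partition.promoted),
        n_up_suppressed=len(up & partition.suppressed),
        n_down_suppressed=len(down & partition.suppressed),
    )


def compare_ros_screens(
    records: Mapping[str, ROSScreenRecord],
    groups: Mapping[str, str],
    focal_group: str | None = "tumor_tissue",
    metric: str = "n_down_suppressed",
) -> GroupComparison:
    """Group comparison of a ROS-screen count (default: downregulated
    ROS-suppressed genes, the tumor-tissue headline metric)."""
    values: dict[str, list[float]] = {}
    for dataset_id, rec in records.items():
        if dataset_id not in groups:
            raise ValueError(f"dataset {dataset_id!r} has no condition group")
        values.setdefault(str(groups[dataset_id]), []).append(float(getattr(rec, metric)))
    if focal_group is not None and focal_group not in values:
        focal_group = None
    return compare_groups(values, metric=metric, focal_group=focal_group)
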