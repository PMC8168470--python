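"""Direction-aware pathway activation calls and shared/specific accounting.

This is a generic re-implementation of the pathway-calling layer used with
commercial knowledge bases: the *algorithm* (overlap enrichment + signed
activation score + cutoff rule + cross-dataset Venn accounting) is
reproduced on user- or simulator-supplied signatures.  Proprietary pathway
content and names are intentionally out of scope — pathway identities here
are whatever the supplied signatures are called.

For one contrast and one signed signature:

* enrichment p — upper-tail hypergeometric probability of observing at
  least ``k`` signature members among the contrast's DEGs, in a universe of
  the genes measured in that dataset;
* activation z — over DEG members with a nonzero expected direction, with
  ``c`` sign-consistent and ``d`` sign-inconsistent genes,
  ``z = (c - d) / sqrt(c + d)``;
* status — **activated** when ``p < p_cut`` and ``z >= z_cut``,
  **inhibited** when ``p < p_cut`` and ``z <= -z_cut``, else not called
  (defaults ``p_cut = 0.05``, ``z_cut = 2``; note p strict, z inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .catalogs import PathwaySignature
from .de import STATUS_DOWN, STATUS_UP, ContrastResult

ACTIVATED = "activated"
INHIBITED = "inhibited"
NOT_CALLED = "not_called"


@dataclass(frozen=True)
class EnrichmentCutoffs:
    p_cut: float = 0.05
    z_cut: float = 2.0


@dataclass(frozen=True)
class EnrichmentRecord:
    dataset_id: str
    pathway: str
    k: int  # DEGs ∩ signature members (within universe)
    K: int  # signature size within universe
    n: int  # DEG count within universe
    N: int  # universe size
    p_value: float
    z: float | None
    status: str


def fisher_enrichment(
    deg_genes: set[str], signature: PathwaySignature, universe: set[str]
) -> tuple[int, int, int, int, float]:
    """Hypergeometric upper tail P(X >= k) for the DEG/signature overlap.

    ``deg_genes`` must be a subset of ``universe``; signature members are
    intersected with the universe first.  Returns ``(k, K, n, N, p)``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not deg_genes:
        raise ValueError("empty DEG list")
    if not deg_genes <= universe:
        raise ValueError("DEG genes must be a subset of the universe")
    members = signature.genes & universe
    N = len(universe)
    K = len(members)
    n = len(deg_genes)
    k = len(deg_genes & members)
    # P(X >= k) = sf(k - 1) under Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p, 1.0)


def activation_z(contrast: ContrastResult, signature: PathwaySignature) -> float | None:
    """Sign-agreement activation score over directional DEG members.

    Counts DEG members whose observed direction matches (``c``) or opposes
    (``d``) the signature's expected direction; direction-0 members are
    ignored.  Returns ``(c - d)/sqrt(c + d)``, or ``None`` when no
    directional member is a DEG (status is then forced to not-called).
    """
    status = contrast.table["status"]
    c = d = 0
    for gene, expected in signature.members.items():
        if expected == 0 or gene not in contrast.genes:
            continue
        observed = status.at[gene]
        if observed == STATUS_UP:
            obs_sign = 1
        elif observed == STATUS_DOWN:
            obs_sign = -1
        else:
            continue
        if obs_sign == expected:
            c += 1
        else:
            d += 1
    if c + d == 0:
        return None
    return (c - d) / math.sqrt(c + d)


def classify_pathway(
    p: float, z: float | None, cutoffs: EnrichmentCutoffs = EnrichmentCutoffs()
) -> str:
    """Activation-status rule; a missing z can never be called."""
    if z is None or not p < cutoffs.p_cut:
        return NOT_CALLED
    if z >= cutoffs.z_cut:
        return ACTIVATED
    if z <= -cutoffs.z_cut:
        return INHIBITED
    return NOT_CALLED


def enrich_contrast(
    contrast: ContrastResult,
    signatures: Iterable[PathwaySignature],
    universe: set[str] | None = None,
    cutoffs: EnrichmentCutoffs = EnrichmentCutoffs(),
) -> list[EnrichmentRecord]:
    """Score every signature against one contrast.

    The default universe is the set of genes measured in the dataset — the
    standard enrichment background.
    """
    universe = set(universe) if universe is not None else contrast.genes
    deg = contrast.deg_genes & universe
    records = []
    for sig in signatures:
        k, K, n, N, p = fisher_enrichment(deg, sig, universe)
        z = activation_z(contrast, sig)
        records.append(
            EnrichmentRecord(
                dataset_id=contrast.dataset_id,
                pathway=sig.name,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                z=z,
                status=classify_pathway(p, z, cutoffs),
            )
        )
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "pathway": r.pathway,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "z": float("nan") if r.z is None else r.z,
                "status": r.status,
            }
            for r in records
        ],
        columns=["dataset_id", "pathway", "k", "K", "n", "N", "p_value", "z", "status"],
    )


SHARED = "shared"
SPECIFIC = "specific"
DUAL = "dual"


@dataclass
class GroupPathwaySummary:
    """Group-level accounting of per-dataset pathway calls.

    ``direction`` labels each pathway called at least once in the group as
    activated (called activated >= once, never inhibited), inhibited
    (symmetric) or dual (both observed).  ``sharing`` partitions the same
    pathways into shared (called in >= 2 datasets with a consistent sign),
    specific (called in exactly one dataset) and dual (opposite calls).
    """

    group: str
    calls: dict[str, dict[str, str]]  # pathway -> dataset -> status
    direction: dict[str, str]
    sharing: dict[str, str]

    @property
    def n_activated(self) -> int:
        return sum(1 for v in self.direction.values() if v == ACTIVATED)

    @property
    def n_inhibited(self) -> int:
        return sum(1 for v in self.direction.values() if v == INHIBITED)

    @property
    def n_dual(self) -> int:
        return sum(1 for v in self.direction.values() if v == DUAL)

    @property
    def n_shared(self) -> int:
        return sum(1 for v in self.sharing.values() if v == SHARED)

    @property
    def n_specific(self) -> int:
        return sum(1 for v in self.sharing.values() if v == SPECIFIC)

    def called(self, direction: str) -> set[str]:
        return {p for p, v in self.direction.items() if v == direction}

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "direction": self.direction,
            "sharing": self.sharing,
            "counts": {
                "activated": self.n_activated,
                "inhibited": self.n_inhibited,
                "dual": self.n_dual,
                "shared": self.n_shared,
                "specific": self.n_specific,
            },
        }


def venn_summary(
    group: str,
    group_records: Sequence[EnrichmentRecord],
    min_shared: int = 2,
) -> GroupPathwaySummary:
    """Shared/specific/dual accounting over one group's per-dataset calls.

    Only pathways called (activated or inhibited) in at least one dataset
    enter the summary; ``min_shared`` datasets with a consistent sign define
    a shared pathway.
    """
    if not group_records:
        raise ValueError("no records for group")
    calls: dict[str, dict[str, str]] = {}
    for r in group_records:
        if r.status in (ACTIVATED, INHIBITED):
            calls.setdefault(r.pathway, {})[r.dataset_id] = r.status
    direction: dict[str, str] = {}
    sharing: dict[str, str] = {}
    for pathway, per_ds in calls.items():
        statuses = set(per_ds.values())
        if statuses == {ACTIVATED}:
            direction[pathway] = ACTIVATED
        elif statuses == {INHIBITED}:
            direction[pathway] = INHIBITED
        else:
            direction[pathway] = DUAL
        if direction[pathway] == DUAL:
            sharing[pathway] = DUAL
        elif len(per_ds) >= min_shared:
            sharing[pathway] = SHARED
        else:
            sharing[pathway] = SPECIFIC
    return GroupPathwaySummary(group=group, calls=calls, direction=direction, sharing=sharing)


def cross_group_overlap(
    summaries: Mapping[str, GroupPathwaySummary],
) -> dict[str, dict]:
    """Pairwise and all-group shared-pathway counts, per call direction.

    For each direction (activated / inhibited / dual at the group level) the
    report lists each group's called set size, every pairwise intersection
    size, the all-group intersection, and each group's specific pathways
    (called there and in no other group).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 groups")
    report: dict[str, dict] = {}
    for direction in (ACTIVATED, INHIBITED, DUAL):
        sets = {g: s.called(direction) for g, s in summaries.items()}
        names = sorted(sets)
        pairwise = {
            f"{a}|{b}": sorted(sets[a] & sets[b])
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        }
        common = set.intersection(*sets.values()) if sets else set()
        specific = {
            g: sorted(sets[g] - set().union(*(sets[h] for h in names if h != g)))
            for g in names
        }
        report[direction] = {
            "per_group": {g: sorted(v) for g, v in sets.items()},
            "pairwise_shared": pairwise,
            "all_shared": sorted(common),
            "specific": specific,
        }
    return report
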