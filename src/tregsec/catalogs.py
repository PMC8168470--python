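"""Gene catalogs, panels and signed pathway signatures.

The analysis pipeline intersects differential-expression results with named
gene sets of several kinds:

* **Secretome catalogs** — the canonical (signal-peptide) secretome and three
  non-canonical routes: caspase-1-GSDMD-dependent, caspase-4/11-GSDMD-
  dependent, and exosome-carried proteins.  The four secretome catalogs are
  required to be pairwise disjoint so that their union partitions the
  secretome gene space.
* **Panels** — curated screens (immunometabolism enzymes, trained-immunity
  enzymes, ROS regulatome) that may freely overlap the secretomes.
* **Housekeeping list** — reference genes whose fold changes act as a
  per-contrast quality control.
* **Pathway signatures** — gene sets whose members carry an expected
  regulation direction (+1 / -1 / 0 = unknown), used for direction-aware
  activation calls.

All symbols are matched on a shared canon: uppercased, whitespace-stripped
strings.  Mouse/human symbol pairs such as ``Il6``/``IL6`` therefore collide
on purpose — intersections are plain symbol-list intersections without any
orthology mapping.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class CatalogCategory(str, enum.Enum):
    """Kinds of gene sets the workbench understands."""

    SECRETOME_CANONICAL = "secretome_canonical"
    SECRETOME_CASP1 = "secretome_casp1"
    SECRETOME_CASP4 = "secretome_casp4"
    SECRETOME_EXOSOME = "secretome_exosome"
    PANEL_IMMUNOMETABOLISM = "panel_immunometabolism"
    PANEL_TRAINED_IMMUNITY = "panel_trained_immunity"
    PANEL_ROS_REGULATOME = "panel_ros_regulatome"
    HOUSEKEEPING = "housekeeping"
    CUSTOM = "custom"


#: The four mutually exclusive secretion-route catalogs.
SECRETOME_CATEGORIES = frozenset(
    {
        CatalogCategory.SECRETOME_CANONICAL,
        CatalogCategory.SECRETOME_CASP1,
        CatalogCategory.SECRETOME_CASP4,
        CatalogCategory.SECRETOME_EXOSOME,
    }
)

#: Robust housekeeping reference genes used for contrast-level QC.
HOUSEKEEPING_GENES = (
    "ACTB",
    "GAPDH",
    "PGK1",
    "PPIA",
    "B2M",
    "YWHAZ",
    "SDHA",
    "HMBS",
    "TBP",
)


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol to the shared matching canon.

    Uppercases and removes all whitespace (leading, trailing and internal).
    Idempotent.  Raises :class:`ValueError` on empty / whitespace-only input.
    """
    if not isinstance(raw, str):
        raise ValueError(f"gene symbol must be a string, got {type(raw).__name__}")
    sym = "".join(raw.split()).upper()
    if not sym:
        raise ValueError("empty or whitespace-only gene symbol")
    return sym


@dataclass(frozen=True)
class GeneCatalog:
    """A named, unordered set of normalized gene symbols."""

    name: str
    genes: frozenset[str]
    category: CatalogCategory = CatalogCategory.CUSTOM

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("catalog name must be non-empty")
        if not self.genes:
            raise ValueError(f"catalog {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "category", CatalogCategory(self.category))
        for g in self.genes:
            if normalize_symbol(g) != g:
                raise ValueError(
                    f"catalog {self.name!r} contains non-normalized symbol {g!r}"
                )

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        category: CatalogCategory | str = CatalogCategory.CUSTOM,
    ) -> "GeneCatalog":
        """Build a catalog, normalizing and deduplicating ``symbols``."""
        return cls(name, frozenset(normalize_symbol(s) for s in symbols), CatalogCategory(category))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


@dataclass(frozen=True)
class PathwaySignature:
    """A pathway gene set with per-member expected regulation direction.

    ``members`` maps normalized symbol -> expected direction: ``+1`` for
    genes the pathway's activity pushes up, ``-1`` for genes it pushes down,
    ``0`` when the direction is unknown.  Direction-0 members still count
    toward overlap enrichment but are ignored by the activation z-score.
    """

    name: str
    members: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"signature {self.name!r} needs >= 2 members")
        clean = {}
        for sym, d in self.members.items():
            if d not in (-1, 0, 1):
                raise ValueError(
                    f"signature {self.name!r}: direction for {sym!r} must be -1, 0 or +1"
                )
            clean[normalize_symbol(sym)] = int(d)
        object.__setattr__(self, "members", clean)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.members)

    def flipped(self) -> "PathwaySignature":
        """Signature with every expected direction negated."""
        return PathwaySignature(self.name, {g: -d for g, d in self.members.items()})


class GMTParseError(ValueError):
    """Raised for malformed GMT input; carries the offending line number."""


def load_gmt(
    path: str | Path,
    categories: Mapping[str, CatalogCategory | str] | None = None,
) -> list[GeneCatalog]:
    """Load gene catalogs from a GMT file (``name TAB description TAB genes...``).

    Symbols are normalized; duplicates within a line collapse.  ``categories``
    optionally assigns a :class:`CatalogCategory` per set name (default
    ``custom``).  Lines with fewer than three tab-separated fields raise
    :class:`GMTParseError` naming the line; duplicate set names raise
    :class:`ValueError`.
    """
    categories = categories or {}
    catalogs: list[GeneCatalog] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            if name in seen:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            seen.add(name)
            category = categories.get(name, CatalogCategory.CUSTOM)
            catalogs.append(GeneCatalog.from_symbols(name, fields[2:], category))
    return catalogs


def write_gmt(catalogs: Iterable[GeneCatalog], path: str | Path) -> None:
    """Write catalogs as GMT; genes sorted for byte-stable output."""
    with open(path, "w") as fh:
        for cat in catalogs:
            fh.write("\t".join([cat.name, cat.category.value, *sorted(cat.genes)]) + "\n")


def load_signatures_gmt(path: str | Path) -> list[PathwaySignature]:
    """Load signed signatures from extended GMT.

    Each gene token may carry a direction suffix ``SYMBOL|+1`` or
    ``SYMBOL|-1``; a bare symbol means direction unknown (0).
    """
    signatures: list[PathwaySignature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            if name in seen:
                raise ValueError(f"{path}: duplicate signature name {name!r}")
            seen.add(name)
            members: dict[str, int] = {}
            for token in fields[2:]:
                token = token.strip()
                if not token:
                    continue
                if "|" in token:
                    sym, _, suffix = token.partition("|")
                    try:
                        direction = int(suffix)
                    except ValueError as exc:
                        raise GMTParseError(
                            f"{path}: line {lineno}: bad direction suffix {token!r}"
                        ) from exc
                else:
                    sym, direction = token, 0
                members[normalize_symbol(sym)] = direction
            signatures.append(PathwaySignature(name, members))
    return signatures


def write_signatures_gmt(signatures: Iterable[PathwaySignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            tokens = [
                f"{g}|{d:+d}" if d else g for g, d in sorted(sig.members.items())
            ]
            fh.write("\t".join([sig.name, "signature", *tokens]) + "\n")


@dataclass
class DisjointnessReport:
    """Pairwise overlap counts between catalogs, with a pass/fail verdict.

    ``passed`` is False iff any pair of *secretome-category* catalogs
    overlaps; panels and other categories may overlap freely.
    """

    overlaps: dict[tuple[str, str], int]
    passed: bool
    failing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "overlaps": {f"{a}|{b}": n for (a, b), n in sorted(self.overlaps.items())},
                "failing_pairs": [list(p) for p in self.failing_pairs],
            },
            indent=2,
            sort_keys=True,
        )


def validate_disjoint(catalogs: Sequence[GeneCatalog]) -> DisjointnessReport:
    """Report every pairwise overlap; fail iff secretome catalogs overlap."""
    if len(catalogs) < 2:
        raise ValueError("need >= 2 catalogs for a disjointness report")
    overlaps: dict[tuple[str, str], int] = {}
    failing: list[tuple[str, str]] = []
    for a, b in combinations(catalogs, 2):
        n = len(a.genes & b.genes)
        overlaps[(a.name, b.name)] = n
        if (
            n > 0
            and a.category in SECRETOME_CATEGORIES
            and b.category in SECRETOME_CATEGORIES
        ):
            failing.append((a.name, b.name))
    return DisjointnessReport(overlaps=overlaps, passed=not failing, failing_pairs=failing)


def union_size(catalogs: Iterable[GeneCatalog]) -> int:
    """Number of distinct genes across all catalogs."""
    union: set[str] = set()
    for cat in catalogs:
        union |= cat.genes
    return len(union)


@dataclass
class CatalogSuite:
    """All catalogs and signatures for one analysis run, keyed by name.

    Construction enforces pairwise disjointness of the four secretome-route
    catalogs (when two or more are present).
    """

    catalogs: dict[str, GeneCatalog]
    signatures: dict[str, PathwaySignature] = field(default_factory=dict)

    def __post_init__(self) -> None:
        secretomes = [
            c for c in self.catalogs.values() if c.category in SECRETOME_CATEGORIES
        ]
        if len(secretomes) >= 2:
            report = validate_disjoint(secretomes)
            if not report.passed:
                raise ValueError(
                    f"secretome catalogs overlap: {report.failing_pairs}"
                )

    @classmethod
    def from_catalogs(
        cls,
        catalogs: Iterable[GeneCatalog],
        signatures: Iterable[PathwaySignature] = (),
    ) -> "CatalogSuite":
        return cls(
            catalogs={c.name: c for c in catalogs},
            signatures={s.name: s for s in signatures},
        )

    def by_category(self, category: CatalogCategory | str) -> list[GeneCatalog]:
        category = CatalogCategory(category)
        return [c for c in self.catalogs.values() if c.category == category]

    @property
    def secretomes(self) -> list[GeneCatalog]:
        return [c for c in self.catalogs.values() if c.category in SECRETOME_CATEGORIES]
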