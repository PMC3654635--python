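"""STR marker panels for combined β-thalassemia PGD and HLA matching.

The diagnostic strategy types polymorphic short tandem repeats (STRs) linked
to the β-globin gene (chromosome 11) and spread across the HLA complex
(chromosome 6) in a single multiplex PCR.  This module models the marker
panel — locus metadata, fluorescent dye, primer pair and expected amplicon
size range — together with the coverage rule used to judge whether a marker
combination is fit for clinical use: at least one marker upstream of HLA-A,
one between HLA-A and HLA-B, one between HLA-B and HLA-DRA, one between
HLA-DRA and HLA-DQB1, one downstream of HLA-DQB1, and at least one marker on
each side (5′ and 3′) of the β-globin gene.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Region",
    "HLA_REGIONS",
    "BG_REGIONS",
    "ALL_REGIONS",
    "DYES",
    "StrMarker",
    "Panel",
    "PanelCombination",
    "CoverageReport",
    "PanelError",
    "load_panel",
    "load_combinations",
    "default_panel",
    "default_combinations",
    "validate_combination",
    "export_primers",
    "check_allele_size",
]


class Region(str, enum.Enum):
    """Genomic interval a marker falls in, relative to the target loci."""

    BG_5PRIME = "BG_5PRIME"
    BG_3PRIME = "BG_3PRIME"
    UPSTREAM_HLA_A = "UPSTREAM_HLA_A"
    HLA_A__HLA_B = "HLA_A__HLA_B"
    HLA_B__HLA_DRA = "HLA_B__HLA_DRA"
    HLA_DRA__HLA_DQB1 = "HLA_DRA__HLA_DQB1"
    DOWNSTREAM_HLA_DQB1 = "DOWNSTREAM_HLA_DQB1"


#: The five HLA intervals required by the ESHRE coverage recommendation.
HLA_REGIONS: tuple[Region, ...] = (
    Region.UPSTREAM_HLA_A,
    Region.HLA_A__HLA_B,
    Region.HLA_B__HLA_DRA,
    Region.HLA_DRA__HLA_DQB1,
    Region.DOWNSTREAM_HLA_DQB1,
)

#: The two β-globin flanking regions (5′ and 3′ of the gene).
BG_REGIONS: tuple[Region, ...] = (Region.BG_5PRIME, Region.BG_3PRIME)

ALL_REGIONS: tuple[Region, ...] = BG_REGIONS + HLA_REGIONS

#: Fluorescent dyes used on the capillary sequencer.
DYES = frozenset({"6FAM", "VIC", "NED", "PET"})

_PRIMER_RE = re.compile(r"^[ACGT]+$")


class PanelError(ValueError):
    """Raised for malformed panel or combination files."""


def _norm(name: str) -> str:
    """Normalise a marker name for lookup (strip whitespace, upper-case)."""
    return name.strip().upper()


@dataclass(frozen=True)
class StrMarker:
    """One STR locus of the multiplex panel.

    ``order_index`` ranks markers along their chromosome (left to right on
    the locus map); physical coordinates are not modelled.  ``size_min_bp``
    and ``size_max_bp`` bound the expected amplicon length, inclusive on
    both ends.
    """

    name: str
    chromosome: int
    region: Region
    order_index: int
    primer_fwd: str
    primer_rev: str
    dye: str
    size_min_bp: int
    size_max_bp: int

    def __post_init__(self) -> None:
        if self.chromosome not in (6, 11):
            raise PanelError(f"{self.name}: chromosome must be 6 or 11")
        if self.chromosome == 11 and self.region not in BG_REGIONS:
            raise PanelError(f"{self.name}: chromosome 11 markers must flank β-globin")
        if self.chromosome == 6 and self.region not in HLA_REGIONS:
            raise PanelError(f"{self.name}: chromosome 6 markers must be in an HLA region")
        for primer in (self.primer_fwd, self.primer_rev):
            if not _PRIMER_RE.match(primer):
                raise PanelError(f"{self.name}: malformed primer sequence {primer!r}")
        if self.dye not in DYES:
            raise PanelError(f"{self.name}: unknown dye {self.dye!r} (expected one of {sorted(DYES)})")
        if not self.size_min_bp < self.size_max_bp:
            raise PanelError(f"{self.name}: size range must satisfy min < max")


def check_allele_size(marker: StrMarker, allele_bp: int) -> bool:
    """True iff an allele size lies within the marker's expected range."""
    if allele_bp <= 0:
        raise ValueError("allele size must be positive")
    return marker.size_min_bp <= allele_bp <= marker.size_max_bp


class Panel:
    """An ordered collection of :class:`StrMarker`, unique by name."""

    def __init__(self, markers: Iterable[StrMarker]):
        self._markers: dict[str, StrMarker] = {}
        for m in markers:
            key = _norm(m.name)
            if key in self._markers:
                raise PanelError(f"duplicate marker name {m.name!r}")
            self._markers[key] = m
        if not self._markers:
            raise PanelError("no markers")
        for chrom in (6, 11):
            idx = [m.order_index for m in self.markers_on(chrom)]
            if len(idx) != len(set(idx)):
                raise PanelError(f"duplicate order_index on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self._markers)

    def __iter__(self) -> Iterator[StrMarker]:
        return iter(sorted(self._markers.values(), key=lambda m: (m.chromosome, m.order_index)))

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self._markers

    def __getitem__(self, name: str) -> StrMarker:
        try:
            return self._markers[_norm(name)]
        except KeyError:
            raise KeyError(f"marker {name!r} not in panel") from None

    def markers_on(self, chromosome: int) -> list[StrMarker]:
        """Markers on one chromosome in physical (order_index) order."""
        return sorted(
            (m for m in self._markers.values() if m.chromosome == chromosome),
            key=lambda m: m.order_index,
        )

    def names(self) -> list[str]:
        return [m.name for m in self]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": m.name,
                "chromosome": m.chromosome,
                "region": m.region.value,
                "order_index": m.order_index,
                "primer_fwd": m.primer_fwd,
                "primer_rev": m.primer_rev,
                "dye": m.dye,
                "size_min": m.size_min_bp,
                "size_max": m.size_max_bp,
            }
            for m in self
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        """Write the panel back to its TSV dialect (round-trips exactly)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PanelCombination:
    """A named multiplex mix: an ordered subset of panel marker names."""

    name: str
    marker_names: tuple[str, ...]

    def __post_init__(self) -> None:
        norm = [_norm(n) for n in self.marker_names]
        if len(norm) != len(set(norm)):
            raise PanelError(f"combination {self.name!r} has duplicate markers")

    def resolve(self, panel: Panel) -> list[StrMarker]:
        missing = [n for n in self.marker_names if n not in panel]
        if missing:
            raise PanelError(f"combination {self.name!r}: unknown markers {missing}")
        return [panel[n] for n in self.marker_names]


@dataclass
class CoverageReport:
    """Region-by-region coverage of a combination against the 7-region rule."""

    combination: str
    counts: dict[Region, int] = field(default_factory=dict)
    missing_regions: list[Region] = field(default_factory=list)
    valid: bool = False

    def to_dict(self) -> dict:
        return {
            "combination": self.combination,
            "counts": {r.value: c for r, c in self.counts.items()},
            "missing_regions": [r.value for r in self.missing_regions],
            "valid": self.valid,
        }


def validate_combination(combo: PanelCombination, panel: Panel) -> CoverageReport:
    """Check a marker combination against the seven-region coverage rule.

    A combination is valid when every one of the five HLA intervals and both
    β-globin flanks contains at least one of its markers.  Order-insensitive
    and idempotent.
    """
    markers = combo.resolve(panel)
    counts = {r: 0 for r in ALL_REGIONS}
    for m in markers:
        counts[m.region] += 1
    missing = [r for r in ALL_REGIONS if counts[r] == 0]
    return CoverageReport(
        combination=combo.name,
        counts=counts,
        missing_regions=missing,
        valid=not missing,
    )


def export_primers(markers: Panel | Sequence[StrMarker]) -> str:
    """Render the primer pairs as FASTA text.

    Two records per marker, ``<name>_F`` and ``<name>_R``, ordered by
    chromosome then position; one line per sequence.
    """
    if isinstance(markers, Panel):
        ordered = list(markers)
    else:
        ordered = sorted(markers, key=lambda m: (m.chromosome, m.order_index))
    lines: list[str] = []
    for m in ordered:
        lines.append(f">{m.name}_F")
        lines.append(m.primer_fwd)
        lines.append(f">{m.name}_R")
        lines.append(m.primer_rev)
    return "\n".join(lines) + ("\n" if lines else "")


_PANEL_COLUMNS = [
    "name", "chromosome", "region", "order_index",
    "primer_fwd", "primer_rev", "dye", "size_min", "size_max",
]


def load_panel(path: str | Path) -> Panel:
    """Load a marker panel from its TSV dialect.

    Errors name the offending row (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise PanelError("no markers") from None
    missing_cols = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelError(f"panel file missing columns {missing_cols}")
    if df.empty:
        raise PanelError("no markers")
    markers = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            markers.append(
                StrMarker(
                    name=str(row.name).strip(),
                    chromosome=int(row.chromosome),
                    region=Region(str(row.region).strip()),
                    order_index=int(row.order_index),
                    primer_fwd=str(row.primer_fwd).strip(),
                    primer_rev=str(row.primer_rev).strip(),
                    dye=str(row.dye).strip(),
                    size_min_bp=int(row.size_min),
                    size_max_bp=int(row.size_max),
                )
            )
        except (PanelError, ValueError) as exc:
            raise PanelError(f"row {i} ({row.name}): {exc}") from exc
    return Panel(markers)


def load_combinations(path: str | Path) -> list[PanelCombination]:
    """Load named marker combinations (TSV: name, comma-separated markers)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "markers"):
        if col not in df.columns:
            raise PanelError(f"combination file missing column {col!r}")
    combos = []
    for row in df.itertuples(index=False):
        names = tuple(n.strip() for n in str(row.markers).split(",") if n.strip())
        combos.append(PanelCombination(name=str(row.name).strip(), marker_names=names))
    return combos


def _data_path(filename: str):
    return resources.files("pgdhla.data") / filename


def default_panel() -> Panel:
    """The packaged 26-marker panel (20 HLA + 6 β-globin)."""
    with resources.as_file(_data_path("table1_markers.tsv")) as p:
        return load_panel(p)


def default_combinations() -> list[PanelCombination]:
    """The six packaged multiplex mixes validated on single blastomeres."""
    with resources.as_file(_data_path("table3_combinations.tsv")) as p:
        return load_combinations(p)
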