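"""Family workup: marker informativity and trio-based haplotype phasing.

Before a clinical cycle, the father, mother and affected child are genotyped
on genomic DNA for every panel marker.  Segregation analysis then (i) grades
each marker's informativity — whether an embryo's genotype at that marker
reveals which paternal and/or maternal chromosome it inherited — and
(ii) phases the four founder haplotypes (two per parent), labelling as
founder 1 the haplotype each parent transmitted to the affected child.  By
construction the child's two chromosome-11 founder haplotypes carry the two
disease mutations, and its chromosome-6 pair defines the HLA combination a
tissue-compatible embryo must share.

Phasing assumes no recombination within the proband: each parent's
transmitted allele is read marker by marker from the unique Mendelian
decomposition of the child's genotype.  Markers where that decomposition is
not unique are graded by the side(s) that do resolve, or UNINFORMATIVE.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import (
    HLA_REGIONS,
    CoverageReport,
    Panel,
    PanelCombination,
    Region,
    check_allele_size,
    validate_combination,
)

__all__ = [
    "InformativityClass",
    "Genotype",
    "FamilyReference",
    "MendelianError",
    "PhasingError",
    "assess_informativity",
    "phase_trio",
    "estimate_heterozygosity",
    "select_informative_combination",
    "CombinationRanking",
    "read_genotype_table",
    "write_genotype_table",
]

FATHER = "father"
MOTHER = "mother"
PARENTS = (FATHER, MOTHER)


class InformativityClass(str, enum.Enum):
    FULLY_INFORMATIVE = "FULLY_INFORMATIVE"
    PATERNAL_ONLY = "PATERNAL_ONLY"
    MATERNAL_ONLY = "MATERNAL_ONLY"
    UNINFORMATIVE = "UNINFORMATIVE"


class MendelianError(ValueError):
    """Child allele incompatible with the parental genotypes."""


class PhasingError(ValueError):
    """No informative marker available to phase a chromosome."""


@dataclass(frozen=True)
class Genotype:
    """Observed genomic-DNA genotype at one marker: one or two allele sizes."""

    marker: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError(f"{self.marker}: genomic DNA genotype needs 1-2 alleles")
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"{self.marker}: allele sizes must be positive")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def allele_pair(self) -> tuple[int, int]:
        """The genotype as an ordered pair (homozygotes repeated)."""
        if len(self.alleles) == 1:
            return (self.alleles[0], self.alleles[0])
        return self.alleles  # type: ignore[return-value]

    @property
    def is_heterozygous(self) -> bool:
        return len(set(self.alleles)) == 2


def _decompositions(
    father: tuple[int, int], mother: tuple[int, int], embryo: tuple[int, int]
) -> list[tuple[int, int]]:
    """All (paternal allele, maternal allele) pairs producing the embryo genotype."""
    target = tuple(sorted(embryo))
    seen = set()
    for p in father:
        for m in mother:
            if tuple(sorted((p, m))) == target and (p, m) not in seen:
                seen.add((p, m))
    return sorted(seen)


def assess_informativity(
    father: Genotype, mother: Genotype, child: Genotype | None = None
) -> InformativityClass:
    """Grade a marker's informativity from the parental genotypes.

    A side (paternal or maternal) is informative when that parent is
    heterozygous and *every* genotype an embryo of this couple can show
    pins down that parent's transmitted allele uniquely.  Both sides →
    FULLY_INFORMATIVE; one side → PATERNAL_ONLY / MATERNAL_ONLY; neither →
    UNINFORMATIVE.  If ``child`` is given it is first checked for Mendelian
    consistency.
    """
    fa, ma = father.allele_pair, mother.allele_pair
    if child is not None and not _decompositions(fa, ma, child.allele_pair):
        raise MendelianError(
            f"{child.marker}: child alleles {child.alleles} not derivable "
            f"from parents {father.alleles} x {mother.alleles}"
        )
    paternal_ok = father.is_heterozygous
    maternal_ok = mother.is_heterozygous
    for p in set(fa):
        for m in set(ma):
            decomps = _decompositions(fa, ma, (p, m))
            if len({d[0] for d in decomps}) > 1:
                paternal_ok = False
            if len({d[1] for d in decomps}) > 1:
                maternal_ok = False
    if paternal_ok and maternal_ok:
        return InformativityClass.FULLY_INFORMATIVE
    if paternal_ok:
        return InformativityClass.PATERNAL_ONLY
    if maternal_ok:
        return InformativityClass.MATERNAL_ONLY
    return InformativityClass.UNINFORMATIVE


@dataclass
class FamilyReference:
    """Phased founder haplotypes and the affected child's inheritance.

    ``founder_alleles[parent][index][marker]`` gives the allele size carried
    by that parent's founder haplotype at the marker; index 1 is always the
    haplotype transmitted to the affected child, so on chromosome 11 both
    index-1 haplotypes are the disease haplotypes and the HLA-identical
    embryo must inherit founder pair (1, 1) on chromosome 6.
    """

    founder_alleles: dict[str, dict[int, dict[str, int]]]
    informativity_by_marker: dict[str, InformativityClass]
    markers_chr6: list[str]
    markers_chr11: list[str]
    disease_haplotypes: dict[str, int] = field(default_factory=lambda: {FATHER: 1, MOTHER: 1})
    affected_child_hla_pair: tuple[int, int] = (1, 1)
    linked_mutations: dict[str, str] = field(default_factory=dict)

    def diagnostic_markers(self, chromosome: int) -> list[str]:
        """Markers phased on both sides (usable for embryo origin assignment)."""
        return list(self.markers_chr6 if chromosome == 6 else self.markers_chr11)

    def founder_allele(self, parent: str, index: int, marker: str) -> int:
        return self.founder_alleles[parent][index][marker]

    def to_dict(self) -> dict:
        return {
            "founder_alleles": {
                parent: {str(i): dict(alleles) for i, alleles in per.items()}
                for parent, per in self.founder_alleles.items()
            },
            "informativity_by_marker": {
                m: c.value for m, c in self.informativity_by_marker.items()
            },
            "markers_chr6": self.markers_chr6,
            "markers_chr11": self.markers_chr11,
            "disease_haplotypes": self.disease_haplotypes,
            "affected_child_hla_pair": list(self.affected_child_hla_pair),
            "linked_mutations": self.linked_mutations,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FamilyReference":
        return cls(
            founder_alleles={
                parent: {int(i): {m: int(a) for m, a in alleles.items()}
                         for i, alleles in per.items()}
                for parent, per in d["founder_alleles"].items()
            },
            informativity_by_marker={
                m: InformativityClass(c) for m, c in d["informativity_by_marker"].items()
            },
            markers_chr6=list(d["markers_chr6"]),
            markers_chr11=list(d["markers_chr11"]),
            disease_haplotypes=dict(d["disease_haplotypes"]),
            affected_child_hla_pair=tuple(d["affected_child_hla_pair"]),  # type: ignore[arg-type]
            linked_mutations=dict(d.get("linked_mutations", {})),
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "FamilyReference":
        return cls.from_dict(json.loads(Path(path).read_text()))


def phase_trio(
    panel: Panel,
    father: Mapping[str, Genotype],
    mother: Mapping[str, Genotype],
    child: Mapping[str, Genotype],
    linked_mutations: Mapping[str, str] | None = None,
) -> FamilyReference:
    """Phase the four founder haplotypes from a father/mother/affected-child trio.

    Per marker, the unique Mendelian decomposition of the child's genotype
    identifies each parent's transmitted allele; that allele becomes founder 1.
    Markers whose decomposition leaves a side unresolved contribute only the
    resolved side (or nothing).  Raises :class:`MendelianError` on an
    impossible child genotype and :class:`PhasingError` if a chromosome has
    no informative marker at all.
    """
    founder: dict[str, dict[int, dict[str, int]]] = {
        FATHER: {1: {}, 2: {}},
        MOTHER: {1: {}, 2: {}},
    }
    informativity: dict[str, InformativityClass] = {}
    both_sides: dict[int, list[str]] = {6: [], 11: []}

    for marker in panel:
        name = marker.name
        if name not in father or name not in mother or name not in child:
            informativity[name] = InformativityClass.UNINFORMATIVE
            continue
        f, m, c = father[name], mother[name], child[name]
        for sample, gt in (("father", f), ("mother", m), ("child", c)):
            for a in gt.alleles:
                if not check_allele_size(marker, a):
                    warnings.warn(
                        f"{name}: {sample} allele {a} bp outside expected range "
                        f"{marker.size_min_bp}-{marker.size_max_bp}",
                        stacklevel=2,
                    )
        klass = assess_informativity(f, m, c)  # raises MendelianError
        informativity[name] = klass
        decomps = _decompositions(f.allele_pair, m.allele_pair, c.allele_pair)
        pat_alleles = {d[0] for d in decomps}
        mat_alleles = {d[1] for d in decomps}
        if klass in (InformativityClass.FULLY_INFORMATIVE, InformativityClass.PATERNAL_ONLY):
            transmitted = pat_alleles.pop()
            other = next(a for a in f.allele_pair if a != transmitted)
            founder[FATHER][1][name] = transmitted
            founder[FATHER][2][name] = other
        if klass in (InformativityClass.FULLY_INFORMATIVE, InformativityClass.MATERNAL_ONLY):
            transmitted = mat_alleles.pop()
            other = next(a for a in m.allele_pair if a != transmitted)
            founder[MOTHER][1][name] = transmitted
            founder[MOTHER][2][name] = other
        if klass is InformativityClass.FULLY_INFORMATIVE:
            both_sides[marker.chromosome].append(name)

    for chrom in (6, 11):
        informative = [
            m.name for m in panel.markers_on(chrom)
            if informativity.get(m.name, InformativityClass.UNINFORMATIVE)
            is not InformativityClass.UNINFORMATIVE
        ]
        if not informative:
            raise PhasingError(f"unphaseable: no informative marker on chromosome {chrom}")

    # diagnostic marker lists follow physical order
    order = {m.name: (m.chromosome, m.order_index) for m in panel}
    for chrom in (6, 11):
        both_sides[chrom].sort(key=lambda n: order[n][1])

    return FamilyReference(
        founder_alleles=founder,
        informativity_by_marker=informativity,
        markers_chr6=both_sides[6],
        markers_chr11=both_sides[11],
        linked_mutations=dict(linked_mutations or {}),
    )


def estimate_heterozygosity(genotypes: Sequence[Genotype]) -> float:
    """Observed heterozygosity: fraction of control samples with two distinct alleles."""
    if not genotypes:
        raise ValueError("empty control set")
    return sum(g.is_heterozygous for g in genotypes) / len(genotypes)


@dataclass
class CombinationRanking:
    """Result of family-specific combination selection."""

    ranked: list[tuple[PanelCombination, CoverageReport, int]]
    diagnostics: dict[str, list[str]]


def select_informative_combination(
    panel: Panel,
    family: FamilyReference,
    candidates: Iterable[PanelCombination],
) -> CombinationRanking:
    """Rank candidate multiplex mixes for one family.

    A combination qualifies when, counting only markers informative in this
    family, it still covers all seven regions.  Qualifying combinations are
    ranked by number of fully informative markers (descending), then by the
    evenness of HLA coverage (the minimum informative-marker count over the
    five HLA regions, descending), then alphabetically.  ``diagnostics``
    maps each failing combination to its uncovered regions.
    """
    ranked: list[tuple[PanelCombination, CoverageReport, int]] = []
    diagnostics: dict[str, list[str]] = {}
    for combo in candidates:
        markers = combo.resolve(panel)
        usable = [
            m for m in markers
            if family.informativity_by_marker.get(m.name, InformativityClass.UNINFORMATIVE)
            is not InformativityClass.UNINFORMATIVE
        ]
        trimmed = PanelCombination(combo.name, tuple(m.name for m in usable))
        report = validate_combination(trimmed, panel) if usable else CoverageReport(
            combination=combo.name, counts={}, missing_regions=list(Region), valid=False
        )
        report.combination = combo.name
        if report.valid:
            n_fully = sum(
                family.informativity_by_marker.get(m.name)
                is InformativityClass.FULLY_INFORMATIVE
                for m in usable
            )
            evenness = min(
                sum(1 for m in usable if m.region is r) for r in HLA_REGIONS
            )
            ranked.append((combo, report, n_fully, evenness))  # type: ignore[arg-type]
        else:
            diagnostics[combo.name] = [r.value for r in report.missing_regions]
    ranked.sort(key=lambda t: (-t[2], -t[3], t[0].name))
    return CombinationRanking(
        ranked=[(c, r, n) for c, r, n, _ in ranked], diagnostics=diagnostics
    )


def read_genotype_table(path: str | Path) -> dict[str, dict[str, Genotype]]:
    """Read a genotype TSV (``sample_id marker allele1 allele2``).

    A blank ``allele2`` denotes a homozygote; both the blank and the
    repeated-value conventions are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker": str})
    required = {"sample_id", "marker", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    out: dict[str, dict[str, Genotype]] = {}
    for row in df.itertuples(index=False):
        a1 = int(row.allele1)
        a2 = int(row.allele2) if pd.notna(row.allele2) else a1
        out.setdefault(str(row.sample_id), {})[str(row.marker)] = Genotype(
            marker=str(row.marker), alleles=(a1, a2)
        )
    return out


def write_genotype_table(
    samples: Mapping[str, Mapping[str, Genotype]], path: str | Path
) -> None:
    """Write genotypes in the TSV dialect (homozygotes as a repeated value)."""
    rows = []
    for sample_id in samples:
        for marker, gt in samples[sample_id].items():
            a1, a2 = gt.allele_pair
            rows.append(
                {"sample_id": sample_id, "marker": marker, "allele1": a1, "allele2": a2}
            )
    pd.DataFrame(rows, columns=["sample_id", "marker", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )
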