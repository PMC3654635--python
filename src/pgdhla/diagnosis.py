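"""Rule-based diagnosis of single-blastomere STR genotypes.

Given the phased family reference, each embryo's observed allele sets are
decomposed marker by marker into parental founder origins.  From the origin
vectors the engine detects recombination (minimal-switch: a crossover is
declared only between *resolved* markers, never imputed through missing or
ambiguous ones), calls whole-chromosome abnormalities, and composes the two
clinical calls: β-thalassemia status from the agreement of the founder
origins on the 5′ and 3′ flanks of the β-globin gene, and HLA match status
from identity of the chromosome-6 founder pair with the affected child's.

Evidence thresholds (how many markers must support a ploidy call, how many
HLA regions must resolve before declaring identity) are explicit,
overridable parameters: the clinical categories are established practice,
the thresholds are this implementation's.  Embryos with any ambiguous call
are never transferable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .family import FATHER, MOTHER, PARENTS, FamilyReference
from .panel import Panel, Region

__all__ = [
    "Origin",
    "LocusCall",
    "OriginAssignment",
    "RecombinationEvent",
    "DiagnosisThresholds",
    "EmbryoDiagnosis",
    "CycleSummary",
    "assign_origins",
    "detect_recombination",
    "call_ploidy",
    "call_disease_status",
    "call_hla_status",
    "diagnose_embryo",
    "summarize_cycle",
]


class Origin(enum.Enum):
    """Per-marker, per-parent founder attribution."""

    FOUNDER1 = 1
    FOUNDER2 = 2
    AMBIGUOUS = "AMBIGUOUS"
    MISSING = "MISSING"


class DiseaseStatus(str, enum.Enum):
    AFFECTED = "AFFECTED"
    CARRIER_PATERNAL = "CARRIER_PATERNAL"
    CARRIER_MATERNAL = "CARRIER_MATERNAL"
    NONCARRIER = "NONCARRIER"
    AMBIGUOUS = "AMBIGUOUS"


class HlaStatus(str, enum.Enum):
    IDENTICAL = "IDENTICAL"
    NONIDENTICAL = "NONIDENTICAL"
    AMBIGUOUS = "AMBIGUOUS"


CARRIER_STATUSES = (DiseaseStatus.CARRIER_PATERNAL, DiseaseStatus.CARRIER_MATERNAL)


@dataclass(frozen=True)
class LocusCall:
    """Origin decomposition of the observed alleles at one marker."""

    marker: str
    paternal: Origin
    maternal: Origin
    n_founder_alleles: int
    contamination_alleles: frozenset[int] = frozenset()
    # parent whose two founders account for both observed alleles while the
    # other parent is absent (uniparental pattern at this locus)
    same_parent_pair: str | None = None


@dataclass
class OriginAssignment:
    """Ordered per-marker origin calls for both chromosomes."""

    calls: dict[int, list[LocusCall]]  # chromosome -> ordered LocusCalls

    def vector(self, chromosome: int, parent: str) -> list[Origin]:
        side = "paternal" if parent == FATHER else "maternal"
        return [getattr(c, side) for c in self.calls[chromosome]]

    def markers(self, chromosome: int) -> list[str]:
        return [c.marker for c in self.calls[chromosome]]


@dataclass(frozen=True)
class RecombinationEvent:
    chromosome: int
    parent: str
    left_marker: str
    right_marker: str


@dataclass(frozen=True)
class DiagnosisThresholds:
    """Evidence thresholds for abnormality and identity calls."""

    min_markers_trisomy: int = 2
    min_markers_monosomy: int = 2
    min_markers_upd: int = 2
    min_hla_regions_identical: int = 3


@dataclass
class EmbryoDiagnosis:
    embryo_id: str
    disease_status: DiseaseStatus
    hla_status: HlaStatus
    recombinations: list[RecombinationEvent] = field(default_factory=list)
    abnormality: tuple[str, int] | None = None  # (kind, chromosome)
    suspected_ado: bool = False
    suspected_contamination: bool = False
    amplification_failure_count: int = 0
    transferable: bool = False

    def to_dict(self) -> dict:
        return {
            "embryo_id": self.embryo_id,
            "disease_status": self.disease_status.value,
            "hla_status": self.hla_status.value,
            "recombinations": [
                {
                    "chromosome": e.chromosome,
                    "parent": e.parent,
                    "between": [e.left_marker, e.right_marker],
                }
                for e in self.recombinations
            ],
            "abnormality": (
                {"kind": self.abnormality[0], "chromosome": self.abnormality[1]}
                if self.abnormality
                else None
            ),
            "flags": {
                "suspected_ADO": self.suspected_ado,
                "suspected_contamination": self.suspected_contamination,
                "amplification_failure_count": self.amplification_failure_count,
            },
            "transferable": self.transferable,
        }


def _decompose_locus(
    marker: str,
    observed: set[int],
    fa: tuple[int, int],
    ma: tuple[int, int],
) -> LocusCall:
    """Exhaustive decomposition of one locus into founder origins.

    Considers every (paternal founder, maternal founder) pair whose expected
    allele set contains the observed founder-attributable alleles (missing
    alleles are explicable by dropout).  Alleles carried by no founder are
    set aside as contamination.  When no two-founder pair explains the
    observation (extra founder alleles: triploid or uniparental patterns),
    origins fall back to per-parent allele presence.
    """
    founder_set = set(fa) | set(ma)
    contamination = frozenset(a for a in observed if a not in founder_set)
    attributable = set(observed) - contamination

    if not attributable:
        return LocusCall(marker, Origin.MISSING, Origin.MISSING, 0, contamination)

    compatible = [
        (p, m)
        for p in (1, 2)
        for m in (1, 2)
        if attributable <= {fa[p - 1], ma[m - 1]}
    ]

    def side_call(parent_alleles: tuple[int, int], candidates: set[int]) -> Origin:
        if not attributable & set(parent_alleles):
            return Origin.MISSING
        if len(candidates) == 1:
            return Origin(candidates.pop())
        return Origin.AMBIGUOUS

    if compatible:
        paternal = side_call(fa, {p for p, _ in compatible})
        maternal = side_call(ma, {m for _, m in compatible})
    else:
        # ≥3 founder alleles or a both-founders-of-one-parent pattern:
        # attribute by presence
        pat_present = {i for i in (1, 2) if fa[i - 1] in attributable}
        mat_present = {i for i in (1, 2) if ma[i - 1] in attributable}
        paternal = (
            Origin.MISSING if not pat_present
            else Origin(pat_present.pop()) if len(pat_present) == 1
            else Origin.AMBIGUOUS
        )
        maternal = (
            Origin.MISSING if not mat_present
            else Origin(mat_present.pop()) if len(mat_present) == 1
            else Origin.AMBIGUOUS
        )

    same_parent = None
    if len(attributable) == 2:
        if attributable == set(fa) and not attributable & set(ma):
            same_parent = FATHER
        elif attributable == set(ma) and not attributable & set(fa):
            same_parent = MOTHER

    return LocusCall(
        marker,
        paternal,
        maternal,
        len(attributable),
        contamination,
        same_parent,
    )


def assign_origins(
    observed: Mapping[str, set[int] | frozenset[int]],
    family: FamilyReference,
    panel: Panel,
) -> OriginAssignment:
    """Decompose an embryo's observed alleles into founder origins per marker.

    Only the family's diagnostic (fully informative) markers are used.
    Markers absent from ``observed`` are treated as failed loci (MISSING).
    """
    calls: dict[int, list[LocusCall]] = {6: [], 11: []}
    for chrom in (6, 11):
        for name in family.diagnostic_markers(chrom):
            fa = (
                family.founder_allele(FATHER, 1, name),
                family.founder_allele(FATHER, 2, name),
            )
            ma = (
                family.founder_allele(MOTHER, 1, name),
                family.founder_allele(MOTHER, 2, name),
            )
            alleles = set(observed.get(name, set()))
            calls[chrom].append(_decompose_locus(name, alleles, fa, ma))
    return OriginAssignment(calls=calls)


def detect_recombination(
    assignment: OriginAssignment, chromosomes: Sequence[int] = (6, 11)
) -> list[RecombinationEvent]:
    """Crossovers per parent: founder switches between consecutive resolved markers.

    Ambiguous and missing markers are skipped, not imputed; each event is
    reported with its nearest resolved flanking markers.  A 1→2→1 pattern
    yields two events (double recombination is detectable by design).
    """
    events: list[RecombinationEvent] = []
    for chrom in chromosomes:
        for parent in PARENTS:
            vector = assignment.vector(chrom, parent)
            markers = assignment.markers(chrom)
            resolved = [
                (m, o) for m, o in zip(markers, vector)
                if o in (Origin.FOUNDER1, Origin.FOUNDER2)
            ]
            for (m1, o1), (m2, o2) in zip(resolved, resolved[1:]):
                if o1 is not o2:
                    events.append(RecombinationEvent(chrom, parent, m1, m2))
    return events


def call_ploidy(
    assignment: OriginAssignment,
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
) -> tuple[tuple[str, int] | None, dict]:
    """Call whole-chromosome abnormalities from the origin decomposition.

    Trisomy: ≥2 markers on one chromosome with three distinct
    founder-attributable alleles — unless such loci occur on *both*
    chromosomes, which points to contamination of the whole cell instead.
    Monosomy: one parent missing at every marker of a chromosome.  UPD: one
    parent absent chromosome-wide while ≥2 loci carry both founder alleles
    of the other parent.  Isolated missing parents at single loci are
    flagged as suspected ADO.
    """
    flags = {
        "suspected_ado": False,
        "suspected_contamination": False,
        "amplification_failure_count": 0,
    }
    three_allele = {
        chrom: [c for c in calls if c.n_founder_alleles >= 3]
        for chrom, calls in assignment.calls.items()
    }
    if any(c.contamination_alleles for calls in assignment.calls.values() for c in calls):
        flags["suspected_contamination"] = True
    flags["amplification_failure_count"] = sum(
        1
        for calls in assignment.calls.values()
        for c in calls
        if c.n_founder_alleles == 0 and not c.contamination_alleles
    )

    trisomy_chroms = [
        chrom
        for chrom, loci in three_allele.items()
        if len(loci) >= thresholds.min_markers_trisomy
    ]
    if len(trisomy_chroms) == 2 or (
        trisomy_chroms and all(three_allele[c] for c in (6, 11))
    ):
        # excess alleles on both chromosomes: a contaminating cell, not ploidy
        flags["suspected_contamination"] = True
        trisomy_chroms = []
    if trisomy_chroms:
        return ("trisomy", trisomy_chroms[0]), flags

    for chrom, calls in assignment.calls.items():
        if len(calls) < 2:
            continue
        informative = [c for c in calls if c.n_founder_alleles > 0]
        if not informative:
            continue
        for parent in PARENTS:
            side = "paternal" if parent == FATHER else "maternal"
            other = MOTHER if parent == FATHER else FATHER
            parent_absent = all(
                getattr(c, side) is Origin.MISSING for c in informative
            )
            if not parent_absent:
                continue
            upd_loci = [c for c in informative if c.same_parent_pair == other]
            if len(upd_loci) >= thresholds.min_markers_upd:
                return ("upd", chrom), flags
            if len(informative) >= thresholds.min_markers_monosomy:
                return ("monosomy", chrom), flags

    # isolated per-locus absences with no chromosome-wide pattern
    for calls in assignment.calls.values():
        for c in calls:
            if c.n_founder_alleles > 0 and (
                c.paternal is Origin.MISSING or c.maternal is Origin.MISSING
            ):
                flags["suspected_ado"] = True
    return None, flags


def _flank_origin(
    assignment: OriginAssignment,
    panel: Panel,
    parent: str,
    region: Region,
) -> Origin | None:
    """Resolved founder origin at the marker nearest the gene on one flank."""
    calls = assignment.calls[11]
    side = "paternal" if parent == FATHER else "maternal"
    flank = [
        c for c in calls
        if panel[c.marker].region is region
        and getattr(c, side) in (Origin.FOUNDER1, Origin.FOUNDER2)
    ]
    if not flank:
        return None
    # markers are stored in physical order; the gene sits between the blocks
    nearest = flank[-1] if region is Region.BG_5PRIME else flank[0]
    return getattr(nearest, side)


def call_disease_status(
    assignment: OriginAssignment,
    family: FamilyReference,
    panel: Panel,
) -> DiseaseStatus:
    """β-thalassemia status from 5′/3′ flanking-marker agreement.

    Per parent, the transmitted haplotype is the founder index agreeing on
    both sides of the β-globin gene (nearest resolved marker each side);
    disagreement means a crossover spanned the gene and that parent's
    contribution — hence the whole call — is ambiguous.  Founder 1 is the
    disease haplotype for both parents by construction.
    """
    per_parent: dict[str, int | None] = {}
    for parent in PARENTS:
        five = _flank_origin(assignment, panel, parent, Region.BG_5PRIME)
        three = _flank_origin(assignment, panel, parent, Region.BG_3PRIME)
        if five is None or three is None or five is not three:
            per_parent[parent] = None
        else:
            per_parent[parent] = five.value
    pat, mat = per_parent[FATHER], per_parent[MOTHER]
    if pat is None or mat is None:
        return DiseaseStatus.AMBIGUOUS
    return {
        (1, 1): DiseaseStatus.AFFECTED,
        (1, 2): DiseaseStatus.CARRIER_PATERNAL,
        (2, 1): DiseaseStatus.CARRIER_MATERNAL,
        (2, 2): DiseaseStatus.NONCARRIER,
    }[(pat, mat)]


def call_hla_status(
    assignment: OriginAssignment,
    recombinations: Sequence[RecombinationEvent],
    abnormality: tuple[str, int] | None,
    panel: Panel,
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
) -> HlaStatus:
    """HLA match status against the affected child's founder pair (1, 1).

    Any chromosome-6 recombination or any resolved marker showing founder 2
    is decisive for non-identity.  Identity additionally requires at least
    one marker with both parental origins resolved in at least
    ``min_hla_regions_identical`` distinct HLA regions; with less
    resolution the call is ambiguous.
    """
    if any(e.chromosome == 6 for e in recombinations):
        return HlaStatus.NONIDENTICAL
    calls = assignment.calls[6]
    resolved_f2 = any(
        o is Origin.FOUNDER2
        for c in calls
        for o in (c.paternal, c.maternal)
    )
    if resolved_f2:
        return HlaStatus.NONIDENTICAL
    if abnormality is not None and abnormality[1] == 6:
        return HlaStatus.NONIDENTICAL
    fully_resolved_regions = {
        panel[c.marker].region
        for c in calls
        if c.paternal is Origin.FOUNDER1 and c.maternal is Origin.FOUNDER1
    }
    if len(fully_resolved_regions) >= thresholds.min_hla_regions_identical:
        return HlaStatus.IDENTICAL
    return HlaStatus.AMBIGUOUS


def diagnose_embryo(
    observed: Mapping[str, set[int] | frozenset[int]],
    family: FamilyReference,
    panel: Panel,
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
    embryo_id: str = "embryo",
) -> EmbryoDiagnosis:
    """Full diagnosis of one blastomere: origins → recombination → ploidy →
    disease and HLA status → transferability.

    An embryo is transferable only when no abnormality is called, the
    disease status is carrier or noncarrier, and the HLA status is decided
    (identity itself is a transfer *preference*, recorded in the summary,
    not a validity rule).
    """
    if not observed:
        raise ValueError("no genotypes supplied")
    assignment = assign_origins(observed, family, panel)
    recombinations = detect_recombination(assignment)
    abnormality, flags = call_ploidy(assignment, thresholds)
    disease = call_disease_status(assignment, family, panel)
    hla = call_hla_status(assignment, recombinations, abnormality, panel, thresholds)
    transferable = (
        abnormality is None
        and disease in (*CARRIER_STATUSES, DiseaseStatus.NONCARRIER)
        and hla is not HlaStatus.AMBIGUOUS
    )
    return EmbryoDiagnosis(
        embryo_id=embryo_id,
        disease_status=disease,
        hla_status=hla,
        recombinations=recombinations,
        abnormality=abnormality,
        suspected_ado=flags["suspected_ado"],
        suspected_contamination=flags["suspected_contamination"],
        amplification_failure_count=flags["amplification_failure_count"],
        transferable=transferable,
    )


@dataclass
class CycleSummary:
    """Counts per diagnostic category for one clinical cycle."""

    embryos: int = 0
    affected: int = 0
    carriers: int = 0
    carriers_paternal: int = 0
    carriers_maternal: int = 0
    noncarriers: int = 0
    hla_nonidentical: int = 0
    hla_identical: int = 0
    nonidentical_affected: int = 0
    nonidentical_carriers: int = 0
    nonidentical_noncarriers: int = 0
    identical_affected: int = 0
    identical_carriers: int = 0
    identical_noncarriers: int = 0
    abnormal: int = 0
    ambiguous: int = 0
    transferable: int = 0
    meta: dict = field(default_factory=dict)

    ROW_LABELS = {
        "Embryos biopsied": "embryos",
        "Affected": "affected",
        "Carriers": "carriers",
        "Noncarriers": "noncarriers",
        "HLA nonidentical": "hla_nonidentical",
        "HLA-identical": "hla_identical",
        "HLA nonidentical and affected": "nonidentical_affected",
        "HLA nonidentical and carriers": "nonidentical_carriers",
        "HLA nonidentical and noncarriers": "nonidentical_noncarriers",
        "HLA-identical and affected": "identical_affected",
        "HLA-identical and carriers": "identical_carriers",
        "HLA-identical and noncarriers": "identical_noncarriers",
    }

    def check_consistency(self) -> None:
        """Marginals must equal the sums of their cross categories."""
        decided = self.affected + self.carriers + self.noncarriers
        if decided + self.ambiguous != self.embryos:
            raise ValueError("disease-status counts do not sum to diagnosed embryos")
        if self.nonidentical_affected + self.nonidentical_carriers + self.nonidentical_noncarriers != self.hla_nonidentical:
            raise ValueError("nonidentical cross categories do not sum to marginal")
        if self.identical_affected + self.identical_carriers + self.identical_noncarriers != self.hla_identical:
            raise ValueError("identical cross categories do not sum to marginal")

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [(label, getattr(self, attr)) for label, attr in self.ROW_LABELS.items()]
        rows.append(("Abnormal", self.abnormal))
        rows.append(("Ambiguous", self.ambiguous))
        rows.append(("Transferable", self.transferable))
        return rows


def summarize_cycle(diagnoses: Sequence[EmbryoDiagnosis]) -> CycleSummary:
    """Tally one cycle's diagnoses into the standard reporting categories.

    Cross categories (HLA × disease) count only embryos decided on both
    axes; ambiguous embryos are excluded from the disease and HLA marginals
    and counted under ``ambiguous``.
    """
    if not diagnoses:
        raise ValueError("no diagnoses to summarize")
    s = CycleSummary(embryos=len(diagnoses))
    for d in diagnoses:
        if d.abnormality is not None:
            s.abnormal += 1
        if d.transferable:
            s.transferable += 1
        disease_decided = d.disease_status is not DiseaseStatus.AMBIGUOUS
        hla_decided = d.hla_status is not HlaStatus.AMBIGUOUS
        if not (disease_decided and hla_decided):
            s.ambiguous += 1
            continue
        if d.disease_status is DiseaseStatus.AFFECTED:
            s.affected += 1
        elif d.disease_status in CARRIER_STATUSES:
            s.carriers += 1
            if d.disease_status is DiseaseStatus.CARRIER_PATERNAL:
                s.carriers_paternal += 1
            else:
                s.carriers_maternal += 1
        else:
            s.noncarriers += 1
        identical = d.hla_status is HlaStatus.IDENTICAL
        if identical:
            s.hla_identical += 1
        else:
            s.hla_nonidentical += 1
        key = (
            "identical" if identical else "nonidentical",
            "affected" if d.disease_status is DiseaseStatus.AFFECTED
            else "carriers" if d.disease_status in CARRIER_STATUSES
            else "noncarriers",
        )
        setattr(s, f"{key[0]}_{key[1]}", getattr(s, f"{key[0]}_{key[1]}") + 1)
    s.check_consistency()
    return s
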