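"""Origin assignment (against an exhaustive-decomposition oracle),
recombination detection, ploidy calls, disease/HLA calls and cycle summaries."""

from itertools import product

import numpy as np
import pytest

from pgdhla.diagnosis import (
    CARRIER_STATUSES,
    DiseaseStatus,
    HlaStatus,
    Origin,
    assign_origins,
    call_disease_status,
    call_hla_status,
    call_ploidy,
    detect_recombination,
    diagnose_embryo,
    summarize_cycle,
)
from pgdhla.diagnosis import EmbryoDiagnosis
from pgdhla.diagnosis import _decompose_locus
from pgdhla.family import FATHER, MOTHER
from pgdhla.simulator import SimulationConfig, default_recomb_probs, simulate_cycle


# ---- helpers ----------------------------------------------------------------

def founder_alleles(family, name):
    fa = (family.founder_allele(FATHER, 1, name), family.founder_allele(FATHER, 2, name))
    ma = (family.founder_allele(MOTHER, 1, name), family.founder_allele(MOTHER, 2, name))
    return fa, ma


def observed_from_origins(family, chrom, paternal, maternal, drop=()):
    """Build observed allele sets from per-marker founder origins.

    ``paternal``/``maternal`` are per-marker founder indices or None (that
    parent's allele dropped); markers listed in ``drop`` are omitted entirely.
    """
    observed = {}
    names = family.diagnostic_markers(chrom)
    for name, p, m in zip(names, paternal, maternal):
        if name in drop:
            continue
        alleles = set()
        if p is not None:
            alleles.add(family.founder_allele(FATHER, p, name))
        if m is not None:
            alleles.add(family.founder_allele(MOTHER, m, name))
        observed[name] = alleles
    return observed


def full_observed(family, chr6=(1, 1), chr11=(1, 1), **kw):
    """Uniform-origin observed genotypes over both chromosomes."""
    n6 = len(family.diagnostic_markers(6))
    n11 = len(family.diagnostic_markers(11))
    obs = observed_from_origins(family, 6, [chr6[0]] * n6, [chr6[1]] * n6)
    obs.update(observed_from_origins(family, 11, [chr11[0]] * n11, [chr11[1]] * n11))
    return obs


# ---- origin assignment ------------------------------------------------------

def test_origin_assignment_examples(family, panel):
    name = family.markers_chr6[0]
    fa, ma = founder_alleles(family, name)

    call = _decompose_locus(name, {fa[1], ma[1]}, fa, ma)
    assert (call.paternal, call.maternal) == (Origin.FOUNDER2, Origin.FOUNDER2)

    call = _decompose_locus(name, {fa[0]}, fa, ma)
    assert (call.paternal, call.maternal) == (Origin.FOUNDER1, Origin.MISSING)

    call = _decompose_locus(name, {fa[0], fa[1], ma[1]}, fa, ma)
    assert call.n_founder_alleles == 3

    call = _decompose_locus(name, set(), fa, ma)
    assert (call.paternal, call.maternal) == (Origin.MISSING, Origin.MISSING)


def oracle_decompose(observed, fa, ma):
    """Exhaustive decomposition search over all (paternal, maternal) founder
    pairs; ambiguity whenever more than one pair explains the observation."""
    founder_set = set(fa) | set(ma)
    attributable = {a for a in observed if a in founder_set}
    pairs = [
        (p, m)
        for p, m in product((1, 2), (1, 2))
        if all(a in (fa[p - 1], ma[m - 1]) for a in attributable)
    ]

    def side(options, parent_alleles):
        if not any(a in parent_alleles for a in attributable):
            return Origin.MISSING
        return Origin(options[0]) if len(set(options)) == 1 else Origin.AMBIGUOUS

    if not attributable:
        return Origin.MISSING, Origin.MISSING
    if pairs:
        return side([p for p, _ in pairs], fa), side([m for _, m in pairs], ma)
    pat = [i for i in (1, 2) if fa[i - 1] in attributable]
    mat = [i for i in (1, 2) if ma[i - 1] in attributable]
    return (
        side(pat, fa) if pat else Origin.MISSING,
        side(mat, ma) if mat else Origin.MISSING,
    )


def test_origin_assignment_matches_exhaustive_search():
    """Random founder configurations (shared alleles allowed) and every
    observable allele subset agree with the oracle."""
    rng = np.random.default_rng(99)
    pool = [100, 102, 104, 106]
    for _ in range(300):
        fa = (int(rng.choice(pool)), int(rng.choice(pool)))
        ma = (int(rng.choice(pool)), int(rng.choice(pool)))
        if len(set(fa)) < 2 or len(set(ma)) < 2:
            continue  # diagnostic markers are heterozygous in both parents
        universe = sorted(set(fa) | set(ma) | {120})  # 120 = contaminant
        for r in range(len(universe) + 1):
            from itertools import combinations

            for subset in combinations(universe, r):
                observed = set(subset)
                call = _decompose_locus("M", observed, fa, ma)
                expect = oracle_decompose(observed, fa, ma)
                assert (call.paternal, call.maternal) == expect
                assert call.contamination_alleles == frozenset(observed - set(fa) - set(ma))


def test_contamination_allele_flagged_not_fatal(family, panel):
    obs = full_observed(family)
    name = family.markers_chr6[0]
    obs[name] = set(obs[name]) | {999}
    d = diagnose_embryo(obs, family, panel)
    assert d.suspected_contamination
    assert d.disease_status is not DiseaseStatus.AMBIGUOUS


# ---- recombination detection ------------------------------------------------

def test_single_switch_reported_between_flanking_markers(family, panel):
    names = family.diagnostic_markers(11)
    obs = full_observed(family)
    obs.update(observed_from_origins(family, 11, [1, 1, 2, 2, 2, 2], [1] * 6))
    events = detect_recombination(assign_origins(obs, family, panel))
    chr11 = [e for e in events if e.chromosome == 11]
    assert len(chr11) == 1
    assert (chr11[0].parent, chr11[0].left_marker, chr11[0].right_marker) == (
        FATHER, names[1], names[2]
    )


def test_double_recombination_yields_two_events(family, panel):
    obs = full_observed(family)
    obs.update(observed_from_origins(family, 11, [1, 2, 2, 2, 1, 1], [1] * 6))
    events = [e for e in detect_recombination(assign_origins(obs, family, panel))
              if e.chromosome == 11 and e.parent == FATHER]
    assert len(events) == 2


def test_missing_markers_are_skipped_not_imputed(family, panel):
    names = family.diagnostic_markers(11)
    obs = full_observed(family)
    # paternal allele absent at the middle marker; same founder on both sides
    obs.update(observed_from_origins(
        family, 11, [1, 1, None, 1, 1, 1], [1] * 6))
    assignment = assign_origins(obs, family, panel)
    assert assignment.vector(11, FATHER)[2] is Origin.MISSING
    assert [e for e in detect_recombination(assignment) if e.chromosome == 11] == []


# ---- ploidy -----------------------------------------------------------------

def test_trisomy_called_from_two_three_allele_markers(family, panel):
    obs = full_observed(family)
    for name in family.markers_chr6[:2]:
        fa, ma = founder_alleles(family, name)
        obs[name] = {fa[0], fa[1], ma[0]}
    abnormality, flags = call_ploidy(assign_origins(obs, family, panel))
    assert abnormality == ("trisomy", 6)


def test_three_allele_loci_on_both_chromosomes_suggest_contamination(family, panel):
    obs = full_observed(family)
    for name in family.markers_chr6[:2] + family.markers_chr11[:2]:
        fa, ma = founder_alleles(family, name)
        obs[name] = {fa[0], fa[1], ma[0]}
    abnormality, flags = call_ploidy(assign_origins(obs, family, panel))
    assert abnormality is None
    assert flags["suspected_contamination"]


def test_single_locus_dropout_is_ado_not_abnormality(family, panel):
    obs = full_observed(family)
    name = family.markers_chr6[0]
    fa, ma = founder_alleles(family, name)
    obs[name] = {ma[0]}  # paternal allele absent at one locus only
    abnormality, flags = call_ploidy(assign_origins(obs, family, panel))
    assert abnormality is None
    assert flags["suspected_ado"]


def test_monosomy_called_when_parent_missing_chromosome_wide(family, panel):
    n6 = len(family.diagnostic_markers(6))
    obs = full_observed(family)
    obs.update(observed_from_origins(family, 6, [None] * n6, [1] * n6))
    abnormality, _ = call_ploidy(assign_origins(obs, family, panel))
    assert abnormality == ("monosomy", 6)


def test_upd_called_when_both_alleles_from_one_parent(family, panel):
    obs = full_observed(family)
    for name in family.markers_chr11:
        _, ma = founder_alleles(family, name)
        obs[name] = {ma[0], ma[1]}  # maternal heterodisomy, no paternal allele
    abnormality, _ = call_ploidy(assign_origins(obs, family, panel))
    assert abnormality == ("upd", 11)


# ---- disease and HLA calls --------------------------------------------------

@pytest.mark.parametrize(
    "pat,mat,expected",
    [
        (1, 1, DiseaseStatus.AFFECTED),
        (1, 2, DiseaseStatus.CARRIER_PATERNAL),
        (2, 1, DiseaseStatus.CARRIER_MATERNAL),
        (2, 2, DiseaseStatus.NONCARRIER),
    ],
)
def test_disease_status_from_flanking_agreement(family, panel, pat, mat, expected):
    obs = full_observed(family, chr11=(pat, mat))
    assignment = assign_origins(obs, family, panel)
    assert call_disease_status(assignment, family, panel) is expected


def test_gene_spanning_recombination_is_ambiguous_and_blocks_transfer(family, panel):
    obs = full_observed(family)
    obs.update(observed_from_origins(family, 11, [1, 1, 1, 2, 2, 2], [2] * 6))
    d = diagnose_embryo(obs, family, panel)
    assert d.disease_status is DiseaseStatus.AMBIGUOUS
    assert not d.transferable


def test_hla_identical_requires_proband_pair_everywhere(family, panel):
    obs = full_observed(family, chr6=(1, 1), chr11=(1, 2))
    d = diagnose_embryo(obs, family, panel)
    assert d.hla_status is HlaStatus.IDENTICAL
    assert d.transferable  # carrier + identical is transferable


def test_hla_recombination_means_nonidentical(family, panel):
    n6 = len(family.diagnostic_markers(6))
    obs = full_observed(family, chr11=(2, 2))
    obs.update(observed_from_origins(
        family, 6, [1] * n6, [1] * (n6 - 2) + [2, 2]))
    d = diagnose_embryo(obs, family, panel)
    assert d.hla_status is HlaStatus.NONIDENTICAL
    assert any(e.chromosome == 6 for e in d.recombinations)


def test_any_resolved_founder2_means_nonidentical(family, panel):
    obs = full_observed(family, chr6=(2, 1), chr11=(2, 2))
    d = diagnose_embryo(obs, family, panel)
    assert d.hla_status is HlaStatus.NONIDENTICAL


def test_sparse_chr6_resolution_is_ambiguous(family, panel):
    keep = family.markers_chr6[:1]
    obs = full_observed(family)
    for name in family.markers_chr6:
        if name not in keep:
            obs[name] = set()
    d = diagnose_embryo(obs, family, panel)
    assert d.hla_status is HlaStatus.AMBIGUOUS
    assert not d.transferable


def test_all_loci_failed_is_fully_ambiguous(family, panel):
    obs = {name: set() for name in family.markers_chr6 + family.markers_chr11}
    d = diagnose_embryo(obs, family, panel)
    assert d.disease_status is DiseaseStatus.AMBIGUOUS
    assert d.hla_status is HlaStatus.AMBIGUOUS
    assert not d.transferable
    assert d.amplification_failure_count == len(obs)


def test_no_genotypes_is_an_error(family, panel):
    with pytest.raises(ValueError, match="no genotypes"):
        diagnose_embryo({}, family, panel)


# ---- composition properties -------------------------------------------------

def test_zero_noise_round_trip(panel, family, zero_noise_config):
    """Without artifacts the engine recovers the simulator's truth exactly."""
    embryos = simulate_cycle(family, panel, zero_noise_config(500, seed=21))
    for e in embryos:
        d = diagnose_embryo(e.observed, family, panel, embryo_id=e.embryo_id)
        assert d.disease_status.value == e.true_disease_status
        assert d.hla_status.value == e.true_hla_status
        assert d.abnormality is None and not d.recombinations


def test_affected_never_transferable_when_flanks_resolve(panel, family):
    """Safety: with dropout and locus failure (no contamination), a truly
    affected embryo is never transferable if the gene-adjacent markers
    resolved to their true origins — miscalls only via AMBIGUOUS."""
    cfg = SimulationConfig(
        n_embryos=2000,
        seed=31,
        recomb_prob_by_interval=default_recomb_probs(family, panel),
        ado_rate=0.15,
        locus_failure_rate=0.1,
    )
    names = family.diagnostic_markers(11)
    # the two markers immediately flanking the gene (last 5', first 3')
    adjacent = (2, 3)
    embryos = simulate_cycle(family, panel, cfg)
    n_checked = 0
    for e in embryos:
        if e.true_disease_status != "AFFECTED":
            continue
        d = diagnose_embryo(e.observed, family, panel, embryo_id=e.embryo_id)
        assignment = assign_origins(e.observed, family, panel)
        flanks_correct = all(
            assignment.vector(11, parent)[i] is Origin(true_vec[i])
            for parent, true_vec in (
                (FATHER, e.true_origin_by_marker[(11, FATHER)]),
                (MOTHER, e.true_origin_by_marker[(11, MOTHER)]),
            )
            for i in adjacent
        )
        if not flanks_correct:
            continue
        n_checked += 1
        assert d.disease_status in (DiseaseStatus.AFFECTED, DiseaseStatus.AMBIGUOUS)
        if d.disease_status is DiseaseStatus.AMBIGUOUS:
            assert not d.transferable
    assert n_checked > 100


def test_identical_fraction_never_increases_with_recombination(panel, family):
    """More crossovers cannot produce more HLA-identical calls."""
    fractions = []
    for p in (0.0, 0.05, 0.2):
        cfg = SimulationConfig(
            n_embryos=10_000,
            seed=77,
            recomb_prob_by_interval=default_recomb_probs(family, panel, p, p),
        )
        embryos = simulate_cycle(family, panel, cfg)
        calls = [
            diagnose_embryo(e.observed, family, panel).hla_status
            for e in embryos
        ]
        fractions.append(sum(c is HlaStatus.IDENTICAL for c in calls) / len(calls))
    assert fractions[0] >= fractions[1] >= fractions[2]


# ---- summaries --------------------------------------------------------------

def _diag(disease, hla, transferable=False):
    return EmbryoDiagnosis(
        embryo_id="E",
        disease_status=disease,
        hla_status=hla,
        transferable=transferable,
    )


def test_summary_reproduces_first_cycle_pattern(family):
    """11 diagnoses distributed as in the first clinical cycle tally to the
    printed marginals."""
    D, H = DiseaseStatus, HlaStatus
    diagnoses = (
        [_diag(D.AFFECTED, H.NONIDENTICAL)] * 1
        + [_diag(D.AFFECTED, H.IDENTICAL)] * 1
        + [_diag(D.CARRIER_PATERNAL, H.NONIDENTICAL)] * 3
        + [_diag(D.CARRIER_MATERNAL, H.NONIDENTICAL)] * 3
        + [_diag(D.CARRIER_PATERNAL, H.IDENTICAL)] * 1
        + [_diag(D.NONCARRIER, H.NONIDENTICAL)] * 2
    )
    s = summarize_cycle(diagnoses)
    assert (s.embryos, s.affected, s.carriers, s.noncarriers) == (11, 2, 7, 2)
    assert (s.hla_identical, s.hla_nonidentical) == (2, 9)
    assert (s.nonidentical_affected, s.nonidentical_carriers, s.nonidentical_noncarriers) == (1, 6, 2)
    assert (s.identical_affected, s.identical_carriers, s.identical_noncarriers) == (1, 1, 0)


def test_ambiguous_excluded_from_marginals():
    D, H = DiseaseStatus, HlaStatus
    s = summarize_cycle([_diag(D.AMBIGUOUS, H.AMBIGUOUS)])
    assert s.embryos == 1 and s.ambiguous == 1
    assert s.affected == s.carriers == s.noncarriers == 0
    assert s.hla_identical == s.hla_nonidentical == 0


def test_cross_categories_conserve_marginals(panel, family):
    rng = np.random.default_rng(5)
    D = list(DiseaseStatus)
    H = list(HlaStatus)
    diagnoses = [
        _diag(D[rng.integers(len(D))], H[rng.integers(len(H))]) for _ in range(200)
    ]
    s = summarize_cycle(diagnoses)
    decided = s.hla_identical + s.hla_nonidentical
    cross = (
        s.nonidentical_affected + s.nonidentical_carriers + s.nonidentical_noncarriers
        + s.identical_affected + s.identical_carriers + s.identical_noncarriers
    )
    assert cross == decided
    assert s.affected + s.carriers + s.noncarriers + s.ambiguous == s.embryos
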