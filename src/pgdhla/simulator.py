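"""Seeded simulator of single-blastomere STR genotypes.

Generates the observations the diagnosis engine has to interpret: for each
embryo, one meiosis per parent and chromosome (founder origin per marker,
with crossovers between adjacent markers, including an elevated rate at the
β-globin cluster hotspot), optional whole-chromosome abnormalities
(monosomy, trisomy, uniparental disomy), and the single-cell artifacts that
dominate one-cell PCR: per-allele allele dropout (ADO), whole-locus
amplification failure, and contamination.  Every injected event is logged so
that diagnoses can be scored against ground truth.

One embryo is one biopsied cell; mosaicism is not modelled, nor are peak
heights (allele *sets* only, as read from binned fragment sizes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .family import FATHER, MOTHER, PARENTS, FamilyReference
from .panel import Panel, Region

__all__ = [
    "SimulationConfig",
    "SimulatedEmbryo",
    "ArtifactEvent",
    "interval_key",
    "default_recomb_probs",
    "simulate_meiosis",
    "apply_abnormality",
    "apply_single_cell_artifacts",
    "simulate_cycle",
    "write_truth_table",
    "write_observed_genotypes",
]

Abnormality = Literal["monosomy", "trisomy", "upd"]
ABNORMALITIES: tuple[Abnormality, ...] = ("monosomy", "trisomy", "upd")

#: Default per-interval crossover probability per meiosis, and the elevated
#: default for the interval spanning the β-globin gene (a known hotspot).
DEFAULT_INTERVAL_PROB = 0.01
DEFAULT_HOTSPOT_PROB = 0.05


def interval_key(chromosome: int, left: str, right: str) -> str:
    """Config key for the interval between two adjacent markers."""
    return f"{chromosome}:{left}|{right}"


class SimulationConfig(BaseModel):
    """All stochastic rates of the simulator, plus the seed.

    ``recomb_prob_by_interval`` must name every adjacent-marker interval the
    meiosis will cross (keys from :func:`interval_key`); missing intervals
    are an error, never silently defaulted.  ``abnormality_rates`` maps
    chromosome ("6"/"11") to per-kind probabilities that must sum to ≤ 1.
    """

    n_embryos: int = Field(gt=0)
    seed: int = 0
    recomb_prob_by_interval: dict[str, float] = Field(default_factory=dict)
    ado_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    locus_failure_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    contamination_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    abnormality_rates: dict[str, dict[str, float]] = Field(default_factory=dict)

    @field_validator("recomb_prob_by_interval")
    @classmethod
    def _probs_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for key, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"interval {key}: probability {p} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _abnormalities_valid(self) -> "SimulationConfig":
        for chrom, rates in self.abnormality_rates.items():
            if chrom not in ("6", "11"):
                raise ValueError(f"abnormality_rates: unknown chromosome {chrom!r}")
            unknown = set(rates) - set(ABNORMALITIES)
            if unknown:
                raise ValueError(f"abnormality_rates[{chrom}]: unknown kinds {unknown}")
            if any(not 0 <= p <= 1 for p in rates.values()):
                raise ValueError(f"abnormality_rates[{chrom}]: probabilities outside [0, 1]")
            if sum(rates.values()) > 1.0 + 1e-12:
                raise ValueError(f"abnormality_rates[{chrom}]: probabilities sum to > 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def default_recomb_probs(
    family: FamilyReference,
    panel: Panel,
    default: float = DEFAULT_INTERVAL_PROB,
    hotspot: float = DEFAULT_HOTSPOT_PROB,
) -> dict[str, float]:
    """Per-interval crossover probabilities over the family's diagnostic markers.

    Every adjacent pair gets ``default`` except the chromosome-11 interval
    spanning the β-globin gene (last 5′ marker to first 3′ marker), which
    gets ``hotspot``.
    """
    probs: dict[str, float] = {}
    for chrom in (6, 11):
        names = family.diagnostic_markers(chrom)
        for left, right in zip(names, names[1:]):
            p = default
            if (
                chrom == 11
                and panel[left].region is Region.BG_5PRIME
                and panel[right].region is Region.BG_3PRIME
            ):
                p = hotspot
            probs[interval_key(chrom, left, right)] = p
    return probs


@dataclass
class ArtifactEvent:
    """One injected technical artifact, for truth-based scoring."""

    embryo_id: str
    kind: str  # "ADO" | "locus_failure" | "contamination"
    marker: str
    allele: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulatedEmbryo:
    """Ground truth and observed genotype of one simulated blastomere."""

    embryo_id: str
    # (chromosome, parent) -> founder index per diagnostic marker, in order;
    # trisomic chromosomes carry an extra entry under parent + "_extra".
    true_origin_by_marker: dict[tuple[int, str], list[int]]
    # founder index transmitted at the β-globin gene itself, per parent
    gene_origin: dict[str, int]
    true_disease_status: str = ""
    true_hla_status: str = ""
    true_abnormality: tuple[str, int] | None = None  # (kind, chromosome)
    observed: dict[str, frozenset[int]] = field(default_factory=dict)
    artifact_log: list[ArtifactEvent] = field(default_factory=list)


def simulate_meiosis(
    family: FamilyReference,
    parent: str,
    chromosome: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[int]:
    """One meiosis: founder origin (1 or 2) at each ordered diagnostic marker.

    The first marker's origin is a fair coin; a crossover switches the origin
    between adjacent markers independently with the configured interval
    probability.  Raises ``KeyError`` for any interval absent from the config.
    """
    names = family.diagnostic_markers(chromosome)
    if not names:
        raise ValueError(f"no diagnostic markers on chromosome {chromosome}")
    origin = 1 if rng.random() < 0.5 else 2
    vector = [origin]
    for left, right in zip(names, names[1:]):
        key = interval_key(chromosome, left, right)
        if key not in config.recomb_prob_by_interval:
            raise KeyError(f"no recombination probability configured for interval {key}")
        if rng.random() < config.recomb_prob_by_interval[key]:
            origin = 3 - origin
        vector.append(origin)
    return vector


def _gene_origin(
    family: FamilyReference,
    panel: Panel,
    vector: Sequence[int],
    rng: np.random.Generator,
) -> int:
    """Founder origin at the β-globin gene itself, given a chr11 origin vector.

    The gene sits inside the hotspot interval (between the 5′ and 3′ marker
    blocks).  If the flanking markers agree the gene shares their origin;
    if a crossover separated them, the breakpoint falls on either side of
    the gene with probability 1/2.
    """
    names = family.diagnostic_markers(11)
    five = [i for i, n in enumerate(names) if panel[n].region is Region.BG_5PRIME]
    three = [i for i, n in enumerate(names) if panel[n].region is Region.BG_3PRIME]
    if not five or not three:
        raise ValueError("chromosome 11 diagnostic markers must flank the gene on both sides")
    left, right = vector[five[-1]], vector[three[0]]
    if left == right:
        return left
    return left if rng.random() < 0.5 else right


def apply_abnormality(
    embryo: SimulatedEmbryo,
    chromosome: int,
    kind: Abnormality,
    family: FamilyReference,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedEmbryo:
    """Impose a whole-chromosome abnormality on a simulated embryo.

    monosomy removes one (uniformly chosen) parental contribution; trisomy
    adds an independently recombined extra copy from a uniformly chosen
    parent; UPD replaces one parent's contribution with a second independent
    copy from the other parent.
    """
    if kind not in ABNORMALITIES:
        raise ValueError(f"unknown abnormality kind {kind!r}")
    parent = PARENTS[int(rng.integers(2))]
    other = MOTHER if parent == FATHER else FATHER
    if kind == "monosomy":
        del embryo.true_origin_by_marker[(chromosome, parent)]
    elif kind == "trisomy":
        extra = simulate_meiosis(family, parent, chromosome, config, rng)
        embryo.true_origin_by_marker[(chromosome, parent + "_extra")] = extra
    else:  # upd: both copies from `other`
        del embryo.true_origin_by_marker[(chromosome, parent)]
        extra = simulate_meiosis(family, other, chromosome, config, rng)
        embryo.true_origin_by_marker[(chromosome, other + "_extra")] = extra
    embryo.true_abnormality = (kind, chromosome)
    return embryo


def _true_observed(
    embryo: SimulatedEmbryo, family: FamilyReference
) -> dict[str, set[int]]:
    """Pre-artifact observed alleles: union of all transmitted founder alleles."""
    observed: dict[str, set[int]] = {}
    for chrom in (6, 11):
        names = family.diagnostic_markers(chrom)
        for (c, carrier), vector in embryo.true_origin_by_marker.items():
            if c != chrom:
                continue
            parent = carrier.removesuffix("_extra")
            for name, founder in zip(names, vector):
                observed.setdefault(name, set()).add(
                    family.founder_allele(parent, founder, name)
                )
    return observed


def apply_single_cell_artifacts(
    embryo: SimulatedEmbryo,
    family: FamilyReference,
    panel: Panel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedEmbryo:
    """Overlay ADO, locus failure and contamination on the true genotype.

    ADO drops each allele of a heterozygous locus independently; a locus
    losing both alleles stays empty (distinguishable from locus failure only
    in the artifact log).  Contamination is a per-embryo event (a carried-over
    cell): when triggered, every marker gains one extraneous allele drawn
    uniformly from the marker's expected size range on a 2-bp grid — it may
    coincide with a parental allele, in which case it is logged but invisible.
    """
    truth = _true_observed(embryo, family)
    contaminated = rng.random() < config.contamination_rate
    observed: dict[str, frozenset[int]] = {}
    for name, alleles in truth.items():
        kept = set(alleles)
        if len(alleles) > 1:  # heterozygous: per-allele dropout
            for a in sorted(alleles):
                if rng.random() < config.ado_rate:
                    kept.discard(a)
                    embryo.artifact_log.append(
                        ArtifactEvent(embryo.embryo_id, "ADO", name, a)
                    )
        if rng.random() < config.locus_failure_rate:
            kept = set()
            embryo.artifact_log.append(
                ArtifactEvent(embryo.embryo_id, "locus_failure", name)
            )
        if contaminated:
            marker = panel[name]
            lo = (marker.size_min_bp + 1) // 2
            hi = marker.size_max_bp // 2
            extra = int(rng.integers(lo, hi + 1)) * 2
            kept.add(extra)
            embryo.artifact_log.append(
                ArtifactEvent(embryo.embryo_id, "contamination", name, extra)
            )
        observed[name] = frozenset(kept)
    embryo.observed = observed
    return embryo


_DISEASE_BY_PAIR = {
    (1, 1): "AFFECTED",
    (1, 2): "CARRIER_PATERNAL",
    (2, 1): "CARRIER_MATERNAL",
    (2, 2): "NONCARRIER",
}


def _truth_labels(embryo: SimulatedEmbryo, family: FamilyReference) -> None:
    """Set true disease / HLA status from the gene origins and chr6 vectors."""
    pair = (embryo.gene_origin[FATHER], embryo.gene_origin[MOTHER])
    embryo.true_disease_status = _DISEASE_BY_PAIR[pair]
    pat = embryo.true_origin_by_marker.get((6, FATHER))
    mat = embryo.true_origin_by_marker.get((6, MOTHER))
    identical = (
        embryo.true_abnormality is None
        and pat is not None
        and mat is not None
        and all(v == 1 for v in pat)
        and all(v == 1 for v in mat)
    )
    embryo.true_hla_status = "IDENTICAL" if identical else "NONIDENTICAL"


def simulate_cycle(
    family: FamilyReference,
    panel: Panel,
    config: SimulationConfig,
) -> list[SimulatedEmbryo]:
    """Simulate a PGD cycle: ``n_embryos`` independent single blastomeres.

    Fully reproducible: identical (family, config) inputs give identical
    embryos, observations and logs.
    """
    rng = np.random.default_rng(config.seed)
    embryos: list[SimulatedEmbryo] = []
    for i in range(config.n_embryos):
        embryo = SimulatedEmbryo(
            embryo_id=f"E{i + 1:04d}",
            true_origin_by_marker={},
            gene_origin={},
        )
        chr11_vectors: dict[str, list[int]] = {}
        for chrom in (6, 11):
            for parent in PARENTS:
                vector = simulate_meiosis(family, parent, chrom, config, rng)
                embryo.true_origin_by_marker[(chrom, parent)] = vector
                if chrom == 11:
                    chr11_vectors[parent] = vector
        for parent in PARENTS:
            embryo.gene_origin[parent] = _gene_origin(
                family, panel, chr11_vectors[parent], rng
            )
        for chrom in (6, 11):
            rates = config.abnormality_rates.get(str(chrom), {})
            if rates:
                kinds = list(ABNORMALITIES)
                probs = [rates.get(k, 0.0) for k in kinds]
                draw = rng.random()
                acc = 0.0
                for kind, p in zip(kinds, probs):
                    acc += p
                    if draw < acc:
                        apply_abnormality(embryo, chrom, kind, family, config, rng)
                        break
        _truth_labels(embryo, family)
        apply_single_cell_artifacts(embryo, family, panel, config, rng)
        embryos.append(embryo)
    return embryos


def write_observed_genotypes(
    embryos: Iterable[SimulatedEmbryo], path: str | Path
) -> None:
    """Write observed single-cell allele sets in the genotype TSV dialect.

    Loci with 0 or ≥3 observed alleles cannot be represented as a two-allele
    row; 0-allele loci are written with blank alleles and ≥3-allele loci as a
    comma-joined ``allele2`` list (readable back by the diagnosis CLI).
    """
    lines = ["sample_id\tmarker\tallele1\tallele2"]
    for e in embryos:
        for marker, alleles in e.observed.items():
            ordered = sorted(alleles)
            if not ordered:
                lines.append(f"{e.embryo_id}\t{marker}\t\t")
            elif len(ordered) == 1:
                lines.append(f"{e.embryo_id}\t{marker}\t{ordered[0]}\t{ordered[0]}")
            else:
                rest = ",".join(str(a) for a in ordered[1:])
                lines.append(f"{e.embryo_id}\t{marker}\t{ordered[0]}\t{rest}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_observed_genotypes(path: str | Path) -> dict[str, dict[str, set[int]]]:
    """Read single-cell allele sets written by :func:`write_observed_genotypes`."""
    out: dict[str, dict[str, set[int]]] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[:4] != ["sample_id", "marker", "allele1", "allele2"]:
        raise ValueError("unexpected genotype table header")
    for line in lines[1:]:
        if not line.strip():
            continue
        sample, marker, a1, a2 = line.split("\t")
        alleles: set[int] = set()
        if a1.strip():
            alleles.add(int(a1))
        for tok in a2.split(","):
            if tok.strip():
                alleles.add(int(tok))
        out.setdefault(sample, {})[marker] = alleles
    return out


def write_truth_table(embryos: Iterable[SimulatedEmbryo], path: str | Path) -> None:
    """Write the per-embryo ground truth (for scoring diagnoses)."""
    lines = ["embryo_id\ttrue_disease_status\ttrue_hla_status\ttrue_abnormality"]
    for e in embryos:
        ab = f"{e.true_abnormality[0]}:chr{e.true_abnormality[1]}" if e.true_abnormality else ""
        lines.append(f"{e.embryo_id}\t{e.true_disease_status}\t{e.true_hla_status}\t{ab}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_artifact_log(embryos: Iterable[SimulatedEmbryo], path: str | Path) -> None:
    events = [ev.to_dict() for e in embryos for ev in e.artifact_log]
    Path(path).write_text(json.dumps(events, indent=2) + "\n")
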