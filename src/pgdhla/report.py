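"""Reporting, packaged clinical-cycle data, and end-to-end orchestration.

Ties the stages together — load panel → phase family → simulate a cycle →
diagnose every embryo → summarise — writing all artifacts (family JSON,
genotype and truth TSVs, per-embryo diagnoses, cycle summary) plus a run
manifest with input digests, the seed and a config snapshot, so any report
can be traced to the exact inputs that produced it.

Also ships the reference cycle-outcome counts of the two clinical cycles of
the first family treated with this strategy, as a packaged TSV with a
checksum, for bookkeeping checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .diagnosis import CycleSummary, DiagnosisThresholds, diagnose_embryo, summarize_cycle
from .family import FamilyReference, Genotype, phase_trio, read_genotype_table
from .panel import Panel, default_panel, load_panel
from .simulator import (
    SimulationConfig,
    default_recomb_probs,
    simulate_cycle,
    write_artifact_log,
    write_observed_genotypes,
    write_truth_table,
)

__all__ = [
    "RunManifest",
    "load_table2_mirror",
    "synthetic_demo_trio",
    "run_end_to_end",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every report bundle."""

    tool_version: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    config_snapshot: dict = field(default_factory=dict)
    started_utc: str = ""
    finished_utc: str = ""

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _data_file(name: str) -> Path:
    with resources.as_file(resources.files("pgdhla.data") / name) as p:
        return Path(p)


def load_table2_mirror() -> tuple[CycleSummary, CycleSummary]:
    """Load the packaged clinical cycle-outcome counts as two summaries.

    Verifies the file checksum and the internal consistency of the counts
    (cross categories must sum to their marginals) before returning one
    :class:`CycleSummary` per cycle.
    """
    path = _data_file("table2_cycles.tsv")
    expected = json.loads(_data_file("checksums.json").read_text())
    digest = _sha256(path)
    if digest != expected["table2_cycles.tsv"]:
        raise ValueError("packaged cycle table failed its checksum")
    df = pd.read_csv(path, sep="\t", dtype={"row": str})
    rows = {str(r.row): (int(r.cycle1), int(r.cycle2)) for r in df.itertuples(index=False)}
    summaries = []
    for i in range(2):
        s = CycleSummary()
        for label, attr in CycleSummary.ROW_LABELS.items():
            setattr(s, attr, rows[label][i])
        s.meta = {
            label: rows[label][i]
            for label in (
                "Number of oocytes retrieved",
                "MII oocytes",
                "2-pronuclei zygotes",
                "Embryos transferred",
            )
        }
        s.check_consistency()
        summaries.append(s)
    return summaries[0], summaries[1]


def synthetic_demo_trio(panel: Panel) -> dict[str, dict[str, Genotype]]:
    """A synthetic, fully informative demo trio (stand-in reference family).

    Not a real family: at every marker the father carries the two smallest
    grid alleles of the expected size range, the mother the next two, and
    the affected child inherits the first allele of each parent — so founder
    1 of each parent (the transmitted, disease-linked haplotype) is the
    smaller allele everywhere.
    """
    father: dict[str, Genotype] = {}
    mother: dict[str, Genotype] = {}
    child: dict[str, Genotype] = {}
    for m in panel:
        b = m.size_min_bp
        father[m.name] = Genotype(m.name, (b, b + 2))
        mother[m.name] = Genotype(m.name, (b + 4, b + 6))
        child[m.name] = Genotype(m.name, (b, b + 4))
    return {"FATHER": father, "MOTHER": mother, "CHILD": child}


def demo_family_reference(panel: Panel | None = None) -> FamilyReference:
    """Phase the synthetic demo trio against the packaged panel."""
    panel = panel or default_panel()
    trio = synthetic_demo_trio(panel)
    return phase_trio(
        panel,
        trio["FATHER"],
        trio["MOTHER"],
        trio["CHILD"],
        linked_mutations={"father": "IVS-1-nt1[G>A]", "mother": "CD39[C>T]"},
    )


def run_end_to_end(
    panel_file: str | Path | None,
    trio_file: str | Path | None,
    config: SimulationConfig,
    outdir: str | Path,
    proband: str = "CHILD",
    father: str = "FATHER",
    mother: str = "MOTHER",
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
) -> tuple[CycleSummary, RunManifest]:
    """Panel → family → simulate → diagnose → report, under one seed.

    With ``panel_file``/``trio_file`` None the packaged panel and synthetic
    demo family are used.  If the config carries no recombination map, the
    per-interval defaults for the phased family are filled in.  Writes
    family.json, genotypes.tsv, truth.tsv, diagnoses.json, summary.tsv and
    manifest.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__,
        seed=config.seed,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )

    panel = load_panel(panel_file) if panel_file else default_panel()
    if panel_file:
        manifest.input_digests["panel"] = _sha256(Path(panel_file))
    if trio_file:
        manifest.input_digests["trio"] = _sha256(Path(trio_file))
        samples = read_genotype_table(trio_file)
        family = phase_trio(panel, samples[father], samples[mother], samples[proband])
    else:
        family = demo_family_reference(panel)

    if not config.recomb_prob_by_interval:
        config = config.model_copy(
            update={"recomb_prob_by_interval": default_recomb_probs(family, panel)}
        )
    manifest.config_snapshot = config.model_dump()

    family.write_json(outdir / "family.json")
    embryos = simulate_cycle(family, panel, config)
    write_observed_genotypes(embryos, outdir / "genotypes.tsv")
    write_truth_table(embryos, outdir / "truth.tsv")
    write_artifact_log(embryos, outdir / "artifacts.json")

    diagnoses = [
        diagnose_embryo(e.observed, family, panel, thresholds, embryo_id=e.embryo_id)
        for e in embryos
    ]
    (outdir / "diagnoses.json").write_text(
        json.dumps([d.to_dict() for d in diagnoses], indent=2) + "\n"
    )
    summary = summarize_cycle(diagnoses)
    pd.DataFrame(summary.to_rows(), columns=["row", "count"]).to_csv(
        outdir / "summary.tsv", sep="\t", index=False
    )
    manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    manifest.write_json(outdir / "manifest.json")
    return summary, manifest
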