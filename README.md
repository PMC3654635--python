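# pgdhla

STR-linkage preimplantation genetic diagnosis (PGD) with HLA matching, for
β-thalassemia families seeking a sibling stem-cell donor.

## What it does

When a couple has a child with β-thalassemia major, PGD combined with HLA
typing (PGD-HLA) lets them select IVF embryos that are both unaffected and
HLA-identical to the sick sibling, whose only curative option is a
stem-cell transplant from a matched donor.  On a single biopsied
blastomere, neither direct mutation assays nor sequence-based HLA typing
are practical, so diagnosis is by **linkage**: polymorphic short tandem
repeats (STRs) flanking the β-globin gene (*HBB*, chromosome 11) and
spanning the HLA complex (chromosome 6) are amplified in one multiplex PCR
and traced back to the four parental founder haplotypes.

`pgdhla` implements the computational side of that workflow:

- **`pgdhla.panel`** — the 26-marker panel (20 HLA + 6 β-globin) with
  primers, dyes and amplicon size ranges; validation of multiplex marker
  combinations against the seven-region coverage rule (five HLA intervals
  recommended for clinical HLA typing + both *HBB* flanks); FASTA primer
  export.
- **`pgdhla.family`** — marker informativity grading and trio phasing.
  Founder haplotype 1 of each parent is, by convention, the one transmitted
  to the affected child, so the disease haplotypes and the HLA-identical
  founder pair are (1, 1).
- **`pgdhla.simulator`** — a seeded generator of single-blastomere
  genotypes: meiosis with per-interval recombination (β-globin hotspot
  included), monosomy/trisomy/uniparental disomy, allele dropout (ADO),
  locus amplification failure and contamination, with a full artifact log
  for truth-based scoring.
- **`pgdhla.diagnosis`** — the rule-based engine: founder origin
  assignment, minimal-switch recombination detection, ploidy calls,
  β-thalassemia status from 5′/3′ flanking agreement, HLA match status, and
  transferability.
- **`pgdhla.report` / `pgdhla.cli`** — end-to-end orchestration with a run
  manifest, packaged reference cycle counts, and the `pgdhla` command.

The model in brief: at each informative marker an embryo's observed allele
set *O* is decomposed against the founder alleles (f₁, f₂ | m₁, m₂); a
parental origin is called when exactly one founder pair (p, m) with
O ⊆ {f_p, m_m} is compatible.  Disease status follows the founder index
agreeing on both sides of *HBB* (a 5′/3′ disagreement = gene-spanning
crossover = ambiguous, not transferable); HLA identity requires the founder
pair (1, 1) across the complex with no recombination, which any crossover
or founder-2 marker refutes.

## Worked example

```sh
pgdhla demo --outdir demo_run --seed 7 --n 16
```

simulates 16 blastomeres from the packaged synthetic demo family under the
default rates (crossover probability 0.01 per marker interval, 0.05 at the
β-globin hotspot; no artifacts) and diagnoses each one:

```
Embryos biopsied	16
Affected	3
Carriers	10
Noncarriers	2
HLA nonidentical	14
HLA-identical	1
HLA nonidentical and affected	3
HLA nonidentical and carriers	9
HLA nonidentical and noncarriers	2
HLA-identical and affected	0
HLA-identical and carriers	1
HLA-identical and noncarriers	0
Abnormal	0
Ambiguous	1
Transferable	12
```

Reading it: each embryo draws one of four founder combinations per
chromosome, so on average 1/4 are affected (here 3/16) and 1/4 are
HLA-identical to the affected sibling (here 1/16 — the single embryo worth
transferring, and it is a healthy carrier).  One embryo is `Ambiguous`: a
crossover spanned the β-globin gene, so its disease status cannot be called
from flanking markers and it is excluded from transfer.  `demo_run/`
contains the phased family (`family.json`), simulated genotypes and truth
tables, per-embryo diagnoses and a manifest with the seed and input
digests; the same seed reproduces the run byte for byte.

The library mirrors the CLI one-to-one:

```python
import pgdhla as pg

panel = pg.default_panel()
for combo in pg.default_combinations():
    print(combo.name, pg.validate_combination(combo, panel).valid)
```

prints `mix1 True` … `mix6 True`: all six packaged multiplex mixes cover
the seven required regions.

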