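# Methods

## Problem setting

Couples at risk of transmitting β-thalassemia can combine preimplantation
genetic diagnosis (PGD) with HLA matching to select IVF embryos that are
both unaffected and tissue-compatible with an already affected sibling, who
can then receive cord-blood haematopoietic stem cells at delivery.  Because
direct mutation assays and allele-level HLA typing are impractical on the
few picograms of DNA in a single blastomere, diagnosis is done by *linkage*:
a panel of short tandem repeats (STRs) tightly linked to the β-globin gene
(HBB, chromosome 11) and spread across the HLA complex (chromosome 6) is
amplified in one multiplex PCR, and each embryo's marker alleles are traced
back to the four parental founder haplotypes.

`pgdhla` implements the computational core of that workflow: panel
modelling and coverage validation, trio-based phasing, a single-cell
genotype simulator, and the rule-based diagnosis engine.

## Marker panel and coverage rule

The packaged panel holds 26 markers: 20 across the HLA complex and 6
flanking HBB (three 5′, three 3′, so any crossover at the known β-globin
cluster recombination hotspot is bracketed and detectable, including double
crossovers).  Each marker carries its chromosome, a region tag, a rank
along the chromosome (`order_index`; physical coordinates are not
modelled), primer pair, fluorescent dye and an expected amplicon size range
(bounds inclusive — the source ranges are printed without stating
openness).

A marker combination is *valid* when all seven regions are covered: the
five HLA intervals recommended for clinical HLA typing (upstream of HLA-A,
HLA-A–HLA-B, HLA-B–HLA-DRA, HLA-DRA–HLA-DQB1, downstream of HLA-DQB1) plus
both HBB flanks.  The six packaged multiplex mixes each cover all seven
with 5 HLA + 2 HBB markers.

Region assignments for a handful of markers that appear in the panel but in
no packaged combination follow the panel's map layout and are recorded in
the packaged TSV, which is the single source of truth; one marker name that
is spelled two ways in the source material ("TAP1-CA"/"TAP1A-CA") is
normalised to `TAP1-CA` throughout.  Marker names are matched after
stripping whitespace and upper-casing.

## Informativity and phasing

A marker side (paternal or maternal) is *informative* for a family when
that parent is heterozygous and **every** genotype an embryo of this couple
could show determines that parent's transmitted allele uniquely.  Markers
are graded FULLY_INFORMATIVE / PATERNAL_ONLY / MATERNAL_ONLY /
UNINFORMATIVE accordingly; the grade depends only on the parental
genotypes, and configurations in which *some* embryo genotype would be
origin-ambiguous are downgraded even if the proband's own genotype happens
to resolve.  This conservative choice avoids markers that could mislead at
diagnosis time.

Phasing assumes no recombination within the proband: at each informative
marker, the unique Mendelian decomposition of the affected child's genotype
identifies the transmitted parental allele, which becomes **founder 1** of
that parent.  Hence, by construction, both index-1 haplotypes on
chromosome 11 are the disease haplotypes (in the reference case family,
IVS-1-nt1[G>A] paternal and CD39[C>T] maternal), and an HLA-identical
embryo is one inheriting founder pair (1, 1) on chromosome 6.  Allele
equality is exact integer base-pair equality; fragment tables are assumed
pre-binned.  Observed (not expected) heterozygosity is used for the >30%
marker screen, matching how the panel was originally screened on 30
controls.

Family-specific combination selection re-validates each mix using only
markers informative in that family, ranks by count of fully informative
markers, breaks ties by the minimum informative count over the five HLA
regions (an "evenly spaced" criterion), and finally alphabetically, so the
ranking is deterministic.

## Single-cell simulator

The simulator generates what the engine must interpret, over the family's
fully informative markers:

- **Meiosis.** Per parent and chromosome, the first marker's founder origin
  is a fair coin and crossovers occur independently between adjacent
  markers.  Default interval probability **0.01**, with **0.05** for the
  chromosome-11 interval spanning HBB, reflecting the named hotspot; both
  are configurable per interval and an interval missing from the
  configuration is an error, never a silent default.  These defaults are
  this package's modelling choice — plausible per-meiosis magnitudes for
  marker panels spanning a few megabases — not measured rates.
- **Gene origin.** HBB itself sits inside the hotspot interval.  When a
  crossover separates the flanking markers, the breakpoint falls on either
  side of the gene with probability 1/2.  This keeps the marker-to-marker
  switch probability exactly the configured value while giving an exact
  truth label for disease status.
- **Abnormalities.** Monosomy removes one parental contribution; trisomy
  adds an independently recombined extra copy from a uniformly chosen
  parent; uniparental disomy replaces one parent's contribution with a
  second independent copy from the other parent.  Trisomic copies recombine
  independently; no specific non-disjunction mechanism is modelled.
- **Artifacts.** Allele dropout (ADO) removes each allele of a heterozygous
  locus independently with `ado_rate`; when both drop the locus is observed
  empty (distinguishable from whole-locus amplification failure only in the
  artifact log) so the engine is exercised on total-dropout loci.
  `locus_failure_rate` erases a locus outright.  Contamination is a
  per-embryo event — emulating a carried-over foreign cell — that adds one
  extraneous allele at every marker, drawn uniformly from the marker's
  expected size range on a 2-bp grid; a contaminant equal to a parental
  allele is logged but invisible.  Every injected event is logged.

One embryo is one biopsied cell.  The simulator does **not** model
mosaicism, PCR stutter, peak heights or dosage, preferential amplification,
or partial (sub-chromosomal) aneuploidy; passing tests therefore speak to
the engine's logic under set-based genotypes, not to electropherogram
interpretation on real traces.

## Diagnosis engine

1. **Origin assignment.** At each marker the observed allele set is
   decomposed against the four founder alleles: every (paternal founder,
   maternal founder) pair whose expected allele set contains the observed
   founder-attributable alleles is considered compatible (missing alleles
   are explicable by dropout).  A parent's origin is the unique compatible
   founder index, MISSING when none of that parent's alleles is observed,
   AMBIGUOUS otherwise.  Alleles carried by no founder are set aside as
   possible contamination — flagged, never fatal.
2. **Recombination.** Crossovers are founder-index switches between
   consecutive *resolved* markers; ambiguous/missing entries are skipped,
   never imputed, so a breakpoint is only ever placed between two resolved
   markers (minimal-switch parsimony).  A 1→2→1 vector yields two events.
3. **Ploidy.** Trisomy requires ≥2 markers on one chromosome with three
   distinct founder-attributable alleles — unless three-allele loci occur
   on both chromosomes, which is read as whole-cell contamination instead
   (a cross-chromosome disambiguation rule of this implementation).
   Monosomy requires one parent MISSING at every informative marker (≥2
   markers); UPD additionally requires ≥2 loci carrying both founder
   alleles of the remaining parent.  Isodisomic UPD is
   marker-indistinguishable from monosomy without dosage and is called
   monosomy.  Isolated single-locus absences are flagged as suspected ADO.
4. **Disease status.** Per parent, the transmitted HBB haplotype is the
   founder index agreeing at the nearest resolved marker on each side of
   the gene; a 5′/3′ disagreement means a crossover spanned the gene and
   the call is AMBIGUOUS.  Direct mutation genotyping is not performed —
   the diagnosis is purely linkage-based.
5. **HLA status.** Any chromosome-6 recombination, any resolved founder-2
   marker, or any chromosome-6 abnormality is decisive for NONIDENTICAL.
   IDENTICAL additionally requires both parental origins resolved to
   founder 1 in at least 3 distinct HLA regions; less resolution gives
   AMBIGUOUS.
6. **Transferability.** `transferable` iff no abnormality, disease status
   is carrier or noncarrier, and HLA status is decided.  Preference for
   HLA-identical embryos is a reporting matter, not a validity rule.
   Ambiguous embryos are never transferable — the conservative clinical
   default.

The evidence thresholds in 3 and 5 (≥2 markers; ≥3 regions) are this
implementation's choices — the clinical categories themselves do not come
with printed thresholds — and are overridable via `DiagnosisThresholds`.

## Numerical and reproducibility choices

All randomness flows through one `numpy.random.Generator` seeded from the
simulation config; identical inputs give byte-identical outputs.  The
packaged reference tables ship with SHA-256 checksums verified at load.
The packaged demo family is **synthetic** (the real case family's
haplotypes are not publicly tabulated): four distinct alleles per marker on
a 2-bp grid inside each marker's size range, fully informative everywhere —
the best case the informativity screen is designed to find.

Test problem sizes: the phasing oracle runs 1,000 random trios over six
markers; Mendelian-fraction and recombination-monotonicity checks use
10,000 simulated embryos; ADO-recovery checks use ~10,000 heterozygous loci
per rate.  Statistical assertions use three-standard-error bands, so each
has a ≈0.3% false-alarm rate under the model; seeds are fixed for
reproducibility.

## Known limitations

- Purely rule-based: no likelihoods, no posterior over haplotypes; markers
  partially informative for a specific child genotype are discarded rather
  than exploited.
- Semi-informative families (few fully informative markers) reduce the
  diagnostic marker set; the engine then returns AMBIGUOUS more often
  rather than guessing.
- Recombination is at most one crossover per interval per meiosis; double
  crossovers within a single interval are not generated (they are,
  however, detectable across intervals).
- No dosage: balanced abnormalities invisible to allele *sets* (e.g.
  isodisomy vs monosomy) collapse to the conservative call.
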