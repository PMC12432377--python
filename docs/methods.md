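# Methods

`tcrtrack` quantifies the tumor-reactive CD8 T-cell repertoire from paired
blood and tumor clonotype tables. This note documents the models and
procedures the package implements, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Repertoire model and filtering

A clonotype is a (chain, V gene, J gene, CDR3 amino-acid sequence) tuple
with a read/UMI count. Gene calls are truncated at the first `*` to gene
level because allele-level calls from short-read bulk TCR-seq are
unreliable and all downstream statistics are gene-level. Records with stop
codons or non-standard residues are dropped (counted and logged). Rows
sharing a clonotype key are aggregated by summing counts *before* the
abundance filter (default `min_count = 10`) is applied, so two
sub-threshold rows of the same clonotype can jointly survive; proportions
`p_i` are recomputed over the survivors. All diversity and matching
statistics operate on the filtered table — whether they could instead be
computed pre-filter is a genuinely open choice, and post-filter was chosen
for internal consistency (every stage sees the same repertoire).

Diversity statistics: unique clonotype and CDR3 counts; Shannon index
`H = −Σ p_i ln p_i` in nats (the common repertoire-analysis default; the
log base is a parameter); top-N occupancy (percent of repertoire space in
the N most expanded clonotypes, saturating at 100 when fewer than N exist,
with ties at the N-th rank broken by lexicographic CDR3 order for
determinism); V–J rearrangement usage weighted per unique clonotype by
default (count-weighted mode available); and pairwise shared-CDR3 counts
between samples.

## Specificity clustering

CDR3s predicted to share specificity are linked by two edge types, in the
style of GLIPH2:

* **global**: equal full length and Hamming distance ≤ 1 over the
  *interiors* (CDR3 minus 3 leading and 2 trailing conserved residues);
* **local**: both interiors contain a k-mer (k ∈ {2,3,4}) that is enriched
  in the analysed set versus a reference repertoire — retained when it
  occurs in ≥ 3 distinct sample CDR3s, its fold enrichment is ≥ 10
  (pseudocount 1 in the reference numerator when the reference count is 0),
  and the one-sided Fisher exact p ≤ 1e-3 on the 2×2 containment table.

These thresholds are the published GLIPH2 conventions; they are all
configurable. Empty interiors (CDR3 shorter than head + tail trim) are
excluded from both motif search and global pairing — an empty interior
carries no sequence information, and pairing on it would link arbitrary
short CDR3s. Clusters are connected components of the edge graph
(singletons included); components, cluster ids and all outputs are
invariant to input order and sample relabeling. The reference repertoire
for motif enrichment is user-supplied; the pipeline's fallback is the
pooled TIL CDR3s of the *other* patients minus all reactive CDR3s, since a
bundled naive reference cannot be redistributed. Local edges connect CDR3s
sharing any retained motif regardless of its position in the interior.

## Blood→tumor tracking and pathogen annotation

`exact_match_fraction` = (unique TIL clonotypes whose CDR3 equals any
blood-reactive CDR3) / (total unique TIL clonotypes). The numerator counts
clonotypes, not distinct CDR3 strings, so numerator and denominator share
units — a CDR3 carried by two V/J-distinct TIL clonotypes contributes
twice; `count_sequences=True` switches to string counting. Matching is
CDR3aa-only ("fully matched" at the amino-acid level); `require_vj=True`
tightens it. The cluster-extended fraction additionally counts TIL
clonotypes whose CDR3 is similar (same cluster) but not identical to a
reactive CDR3, so extended ≥ exact always. Extension is applied to TRB by
default. Patients with no detectable blood-reactive repertoire are reported
as missing, not zero: absence of a measurable response is a different state
from a low tumor-reactive TIL fraction.

Pathogen annotation: a TIL clonotype is pathogen-specific when its CDR3
equals an epitope-database entry whose antigen species is on the pathogen
list (host species excluded) *and* whose restricting HLA matches the
patient — exact at two-field resolution, prefix match when the database
entry is group-level only (the database mixes resolutions).

The cohort report groups per-patient fractions by lymph-node status (ND
excluded from the two-group comparison, retained per patient) and
histology, with medians and a Mann-Whitney rank test attached as a
descriptive convenience (no multiplicity correction — these are per-figure
style summaries, not the package's inferential claim).

## Assay formulas

* Relative proliferation: `max(0, f_loaded − f_unloaded)` of CFSE-low CD25+
  frequencies; responder call is strictly `f_loaded > f_unloaded`.
* Cytotoxicity: `100 − ((%target/%reference) / (%target_ctrl/%reference_ctrl)) × 100`.
  Left unclamped by default: values below zero indicate target outgrowth
  relative to control and are meaningful; a `clamp` flag zeroes them.
* Relative green intensity: coculture TII minus both monoculture TIIs,
  vectorized over timepoints.
* Sampling adequacy: probability of missing a clone of frequency `f` among
  `n` sequenced cells is `exp(−n·f)` under Poisson sampling.
* Antigen expression: expressed iff value ≥ 5 (inclusive) on the table's
  given normalized scale — no internal re-normalization; shared-antigen
  sets intersect per-group unions (`any_per_group`) or all samples
  (`all_samples`). The cancer/testis antigen list is a user input.

## Signature scoring

`module_score` implements the binned-control construction: genes are ranked
by mean expression (ties by gene name) and cut into `n_bins = 24`
equal-size bins, remainder genes assigned to the lowest bins; each
signature gene draws `n_ctrl = 100` control genes from its own bin,
excluding all signature genes — without replacement when the bin holds
enough eligible genes, with replacement otherwise. The per-cell score is
the mean over signature genes minus the mean over the pooled control draw
(one pooled mean, not per-gene paired differences, following the standard
single-cell convention). Scores are bit-reproducible given (matrix,
signature, seed) and invariant to gene/cell order and to adding a constant
to every gene. Input normalization is `ln(1 + count/total × 1e4)` per cell;
zero-total cells are excluded with a warning. `purify_cd8` drops cells with
imputed CD4 > 0.5 and CD8 = 0, plus cells with more than 5,000 detected
genes; `top_cluster_frequency` finds the cluster with the highest mean
score (ties broken by label order and flagged) and reports each patient's
percentage of cells in it. The signature gene list is an input; no specific
list is bundled beyond test fixtures.

## Synthetic-data generator

The generator emits every input the pipeline consumes, plus exact ground
truth. Defaults encode the cohort design the package targets: 15 patients
with paired TCR data split 10 node-negative / 5 node-positive, 47
blood-reactive clonotypes per patient (a realistic median for lysate-driven
expansion products), 150 TIL clonotypes, true shared-clonotype fractions
θ = 0.05 (node-negative) vs 0.01 (node-positive) so the node-positive group
carries fewer tumor-reactive TILs, Zipf clone-size exponent 2.0, CDR3
lengths 10–20 peaked at 14–15, a 2% pathogen spike and 2 near-miss plants
per patient.

Plantings are exact, not expected: ⌈θ·n_til⌉ TIL clonotypes copy reactive
CDR3s; near misses differ from a reactive CDR3 by exactly one interior
residue; pathogen spikes copy database CDR3s whose restricting allele is in
the patient's typing; background CDR3s are rejection-sampled against all
planted sets. Clone counts are drawn as `(min_count − 1) + Zipf(a)`, so all
clonotypes survive the default filter and filtering is exercised separately
through the explicit low-count injection mode. CDR3 interiors are uniform
over the 20 amino acids, with an optional positional-motif mode for
enrichment testing. All randomness derives from one root seed via
`SeedSequence` spawning.

What the generator does **not** emulate: VDJ recombination biology
(insertion/deletion machinery, positional amino-acid bias, convergent
recombination), sequencing error, shared/public clonotypes across patients,
or exhaustion-correlated expression structure. Passing recovery tests
therefore demonstrates correctness of the *computations* under the stated
statistical structure, not robustness to the full messiness of patient
data — in particular, real repertoires can contain coincidental one-mismatch
neighbours that the clean simulation excludes by construction.

The expression simulator draws gamma-mixed Poisson (negative-binomial-like)
counts with lognormal gene rates and cell size factors, multiplying
signature-gene rates by `exp(δ)` in a spiked subset (defaults: 1,000 genes,
500 cells, 50 signature genes, δ = 1.0, 30% spiked).

## Problem sizes and numerical conventions

Recovery checks run at deliberately modest sizes chosen to give tight
Monte-Carlo behaviour while keeping the suite quick: θ-recovery at
n_til = 1000 over 20 seeds; clustering-versus-oracle on 100 random 50-node
instances; signature recovery over 100 seeds of 1,000 × 500 matrices;
group-ordering recovery over 20 cohort simulations. Fisher exact p-values
come from `scipy.stats.fisher_exact` (validated in tests against a direct
hypergeometric tail); components from `networkx` (validated against a
brute-force transitive closure). Proportions must sum to 1 within 1e-9;
score reproducibility is exact (bit-for-bit), not approximate.

## Known limitations

* Motif enrichment needs a sensible reference repertoire; with a tiny or
  biased reference the Fisher test is underpowered and local edges vanish
  (global edges are unaffected).
* O(n²)-per-length-bucket global pairing is fine for repertoires up to a
  few tens of thousands of unique CDR3s but is not engineered for
  atlas-scale inputs; the same holds for the dense expression container.
* TRA/TRB are treated independently; paired-chain (single-cell) clonotypes
  are out of scope.
* The packaged 23-patient roster ships for roster-level tallies only; no
  patient sequence data is included or reproduced.
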