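# Methods

## The problem

In bacterial operons, neighbouring cistrons are usually separated by
fewer than ~25–30 nucleotides — too little room for a terminating
ribosome and a de-novo-initiating ribosome to coexist, so downstream
cistrons are often translated by *re-initiation*: the terminating
ribosome stays on the mRNA and resumes at a nearby start codon. A
stable mRNA secondary structure immediately 3' of a stop codon — a
**ribosome termination structure (RTS)** — can insulate against
re-initiation. `rtscan` quantifies the genomic signature of such
structures: local folding-energy landscapes around stop codons, the
excess of native folding stability over a composition-preserving null
(ΔLFE), and a rule-based per-gene RTS call, stratified by gene-pair
topology (intergenic distance, strand, operon position).

## Local folding energy and ΔLFE

Every gene that passes QC (CDS ≥ 40 nt, length divisible by 3, no
internal in-frame stop, terminal stop codon present) contributes one
energy per *window opening position* `p ∈ [−100, +100]`, where `p` is
the mRNA-sense offset of the window's 5'-most nucleotide from the first
nucleotide after the stop codon. Windows are 40 nt, stepped by 1 nt,
folded in isolation with the minimum-free-energy model (ViennaRNA,
default Turner parameters, 37 °C); energies are kcal·mol⁻¹ per window
and are ≤ 0 by construction.

The null model holds the amino-acid sequence and the nucleotide/codon
composition fixed: synonymous codons are permuted uniformly within each
CDS (N-containing codons, terminal stops, and bases covered by more
than one CDS stay in place; minus-strand CDSs are permuted in mRNA
sense), and each contiguous non-coding region has its nucleotides
permuted. For R randomized genomes (default R = 20),

    ΔLFE(p) = ΔG_native(p) − (1/R) · Σ_r ΔG_randomized_r(p)

so negative ΔLFE means the native sequence folds more stably than its
composition explains. Per-position landscapes report mean, median, SD
and quartiles over genes, for any gene grouping (distance class, strand
class, operon position, abundance quantile).

Sign convention note: ΔLFE is defined here as native minus randomized,
which makes "more stable than expected" negative; this matches how
landscape minima are interpreted throughout (an excess of stability is
a dip).

## The RTS call

A gene is called RTS⁺ when all three hold:

1. **topology** — the downstream neighbour (in the gene's own reading
   direction) is ≥ 25 nt away, or on the opposite strand, or absent;
2. **run** — ≥ 5 consecutive windows opening within [−10, +20] have
   ΔLFE < 0;
3. **depth** — within the selected run (longest; 5'-most on ties) the
   *native* window energy reaches ≤ −6 kcal·mol⁻¹·window⁻¹.

Terminal genes with no downstream neighbour are treated as
topology-eligible (like opposite-strand pairs). Genes with missing
windows inside the opening range are reported uncallable and excluded
from fractions. All thresholds are configuration (`RtsModelConfig`)
with the defaults above; the call is monotone in each threshold
(stricter settings never add calls), which the test suite verifies
against a brute-force run-enumeration oracle.

## Synthetic genomes and what they do (not) show

`rtscan.synth.make_genome` lays out `n_genes` coding sequences on one
contig. Codons are drawn i.i.d. from a codon-usage model (default:
uniform amino acids, uniform codons within each synonymous family; an
E. coli-like usage table ships as `ECOLI_LIKE_USAGE`), intergenic
sequence is i.i.d. with configurable GC (default 25%, emulating AT-rich
bacterial intergenic DNA), intergenic lengths are uniform in a
configurable range, a configurable fraction of genes is
reverse-complemented in place, and consecutive genes are grouped into
operons. Optionally a perfect G:C-stem hairpin (stem 12, loop GAAA by
default, ΔG well below −15) is planted with its 5' end at a chosen
offset after the stop codon of a chosen fraction of genes, *replacing*
intergenic sequence so distances stay exact.

Because every unit (codon given amino acid, intergenic base) is drawn
i.i.d., an un-planted genome is *exactly* a draw from the randomization
null: expected ΔLFE is zero at every position, which calibrates the
landscape machinery end to end. Planted hairpins give positive ground
truth for recovery tests.

What the generator does **not** emulate: real codon autocorrelation,
promoters/terminators and RBS motifs, transcription-unit structure,
skewed gene-length and intergenic-length distributions, sequencing
ambiguity (N runs), or selection of any kind. Passing the synthetic
tests therefore demonstrates the *machinery* (coordinates, shuffling,
folding, calling, statistics) is correct — not that real genomes will
show any particular effect size.

Two empirical facts about the synthetic conditions matter when reading
test results:

* **Chance structures are common.** At 25% GC, a random 40-mer folds to
  ≤ −6 kcal/mol with probability ≈ 0.07, and a gene's opening range
  exposes ~6 effectively independent windows, so the three-condition
  model calls ~20–25% of *unplanted* genes RTS⁺. These are genuine
  stop-proximal hairpins that arise by chance — the detector is right
  to find them; they count as false positives only against the
  planted-truth labels. Raising intergenic GC toward realistic
  bacterial values (~40%) raises this floor further.
* **Per-position null means are noisy.** Per-gene ΔLFE has SD ≈ 2.2
  kcal/mol under the null, so with 200 genes each per-position mean has
  SEM ≈ 0.16, and the maximum |mean| over the landscape is typically
  0.3–0.45 even though the expectation is exactly zero (verified by an
  exchangeability argument and by composition checks). The grand mean
  over positions is a far tighter calibration statistic (|grand mean|
  ≈ 0.02 at these sizes).

### Localizing a planted element

A structural element shorter than the window produces a *plateau* of
deep windows: every opening in `[offset + len − width, offset]` fully
contains it. The raw argmin therefore sits near where the window is
*centred* on the element (offset + (len − width)/2 ≈ −1 for a 28-nt
hairpin at +5), while the element's 5'-end offset is the plateau's 3'
edge. `landscape.localize_minimum` reports both: the raw argmin and the
recovered element offset (the 3'-most opening position whose mean is at
least 90% of the way down to the global minimum). On the standard
planted benchmark the recovered offset equals +5 exactly.

Landscapes are indexed by window *opening* position throughout; a
center-indexed presentation (a pure axis relabeling by +width/2,
`landscape.shift_convention`) is available because both conventions
appear in the literature. The relabeling cannot change which windows
are deep, so detection and localization are convention-independent.

## Library computations

The synthetic-operon library places 24 random nucleotides after a fixed
hexamer (ACTAGT) that follows the proximal gene's UAG stop; the clone
window for ΔG_fold is the 37-mer starting +9 nt from the stop's first
nucleotide — exactly the variable region plus the fixed suffix
AAGGGCGAGGAGC in the default plasmid context (both flanks are
configuration). Reads are filtered on the downstream reporter's frame
(offsets 0, 3, …, 21): any in-frame stop rejects, an in-frame
ATG/GTG/TTG is required. Per-bin ΔG_fold is the count-weighted mean
with a seeded percentile-bootstrap CI (default 99%, 10⁴ resamples;
bootstrap chosen because it is assumption-light and reproducible). The
theoretical library simulator draws uniform-composition sequences under
three schemes (constrained 37-mers, filtered 24-mers + suffix,
unconstrained 37-mers); for in-frame filters on i.i.d. sequence the
acceptance probability has the closed form
(1 − p_stop)^k − (1 − p_stop − p_start)^k, used as the analytic check.

## Statistics

Small experimental samples (n = 6–8 bins/clones) need exact inference:
`stats.spearman_exact` enumerates all n! rank permutations (n ≤ 9,
tie-free), computes S = Σd², and doubles the observed S-tail (capped at
1). This reproduces, from first principles: p = 2/720 ≈ 0.0028 for a
perfect monotone n=6 relation, p = 12/720 ≈ 0.017 for S=2 at n=6, and
the closed form ρ = 1 − 6S/(n(n²−1)) gives 0.94 (S=2, n=6) and 0.80
(S=6479, n=58). Wilcoxon signed-rank, Mann–Whitney U and Pearson tests
wrap scipy; results carry the effective n (the pipeline convention of
pooling genes × randomization repetitions is supported, and the result
object records the underlying gene count so the pseudo-replication
stays visible). Reported p-values below 10⁻³⁰ are *formatted* as
"<1e-30"; the raw value is retained.

## Numerical choices and edge cases

* Windows that run off a contig, or with > 10% ambiguous bases, are
  omitted, never padded; a ΔLFE position is used only where the native
  window and all replicate windows exist.
* DNA is transcribed T→U on entry to the folding engine; engine name
  and parameter set are recorded with every energy series.
* The fallback engine (pair-maximisation DP, GC −3 / AU −2 / GU −1,
  3-nt minimum loop) honours the same contracts but its absolute
  energies are not Turner-comparable; the −6 kcal/mol call threshold is
  meaningful only under the production engine.
* Longest-run tie-break: 5'-most. ΔLFE run condition uses strict < 0
  (ties are measure-zero with real energies).
* Randomization replicate r of master seed s uses the independent
  stream SeedSequence([s, r]), so any replicate is reproducible in
  isolation.
* Circular genomes are not modelled; contig-terminal genes simply lose
  out-of-range windows.

## Problem sizes used by the test suite

Unit tests run on genomes of 5–60 genes. The two end-to-end landscape
tests use 200-gene genomes with R = 20 randomizations (the null
calibration over the full ±100 landscape; the planted-hairpin recovery
over ±25), sizes chosen so each completes in minutes with the
production engine while keeping per-position SEM near 0.16 kcal/mol.
The library simulator tests use 10³ draws (the theoretical-distribution
machinery is identical at any n).

## Known limitations

* The RTS model's absolute −6 kcal/mol threshold is engine- and
  parameter-set-specific; cross-version energy drift of ±0.2 kcal/mol
  is expected and tolerated where reference values are pinned.
* The three-condition model cannot distinguish a selected RTS from a
  chance hairpin of equal stability; on random sequence it has a
  ~0.2 chance-call floor (see above). Genome-wide fractions therefore
  mix selection and base-composition effects.
* Pooling genes × repetitions as independent observations (the
  effective-n convention) overstates significance; both counts are
  reported so users can correct for it.
* Multi-part CDSs are merged to their genomic span (adequate for
  bacteria, wrong for spliced genes).
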