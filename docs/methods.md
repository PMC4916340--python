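# Methods

## Tag anatomy and the virtual reference

A DGE tag is the 21-mer formed by the NlaIII anchor (CATG) plus the 17
bases MmeI cuts downstream of it; sequencing reads are 49 bp (tag +
3′ adaptor). The virtual reference predicts, per transcript, the tag
at the 3′-most *usable* CATG: a site needs ≥ 17 downstream bases and no
ambiguous base (N) in its 21-base window, otherwise the next site toward
5′ is taken. By default one site per gene is extracted
(`sites_per_gene=1`); multi-site extraction is available because tag
libraries occasionally capture partial digests, but expression counting
assumes the 3′-most convention. Identical 21-mers shared by more than
one gene are all flagged ambiguous — ambiguity is a property of the
21-mer, so the flag is symmetric across its carriers.

Matching operates on the full 21-mer including the anchor: the anchor is
part of every sequenced tag, and keeping it makes the exact-match step a
plain dictionary lookup. One-mismatch matching is defined as equivalence
to enumerating the 63 single-substitution neighbours of the query; the
implementation does exactly that against hash maps of sense and
reverse-complemented reference tags, which is O(63·distinct tags)
regardless of reference size.

## Cleaning and the antisense consequence

A read is clean when its leading 21-mer begins with CATG and contains no
ambiguous base; reads that instead begin with the adaptor are tallied as
adaptor-only. Base-call quality strings are ignored — quality filtering
belongs upstream of tag counting, and the clean-tag definition used here
filters only ambiguous bases.

One structural consequence: a tag emitted from the reverse-complement
strand of a transcript's canonical tag cannot itself begin with CATG
(its CATG sits at the 3′ end), so such reads fail the anchor filter and
appear as a clean-rate deficit roughly equal to the antisense fraction
rather than as antisense-classified matches. The antisense matching
tiers (query equal to, or one mismatch from, the reverse complement of a
reference tag) therefore matter for tag tables assembled without the
anchor filter — pre-counted TSV input, or reads cleaned by other
criteria — and are exercised that way in the tests.

## The exact test

Under equal expression, the probability of observing `y` tags in a
library of `N2` clean tags given `x` tags in a library of `N1` is

    P(y|x) = (N2/N1)^y (x+y)!/(x! y!) (1 + N2/N1)^−(x+y+1),

the negative binomial NB(x+1, N1/(N1+N2)) in `y`. The point probability
is evaluated in log space with log-gamma (stable to ≥ 12 significant
digits against arbitrary-precision evaluation up to counts in the
thousands); tail sums use the negative-binomial CDF.

Two-sided p-values use the conditional form of the same model: given the
total n = x + y, the first-library count is Binomial(n, N1/(N1+N2)), and
p = min(1, 2·min(P(Bin ≤ x), P(Bin ≥ x))). The binomial upper-left tail
equals the tag-count upper tail Σ_{k≥y} P(k|x) identically, so this is
the same doubled-tail construction — but, unlike doubling raw
negative-binomial tails (which differ by one probability atom under
library exchange), it is *exactly* invariant under
(x, y, N1, N2) → (y, x, N2, N1). One-sided alternatives (`less`,
`greater`) expose the raw tails.

Multiple testing uses Bonferroni by default — the adjusted value is
labelled FDR in written outputs to match the terminology DGE studies
conventionally use for it — with Benjamini–Hochberg available via
`adjust="bh"`. The family size is the number of genes actually tested:
genes below the TPM floor (default 10) in *both* libraries are excluded
before testing. Zero counts are replaced by a default of one tag on the
count scale, before normalisation, and the substitution feeds both the
log₂ ratio and the test input; ratios are computed on TPM because the
two libraries differ in depth. Calls require adjusted p below the
threshold (default 0.001) *and* |log₂ ratio| ≥ 1.

## Library summaries

The copy-number distribution bins distinct tags at <2, 2–5, 6–10, 11–20,
21–50, 51–100 and >100 copies; percentages are over distinct tags,
printed to two decimals with round-half-even. Both the number of
distinct tags and the number of distinct tags seen ≥ 2 times ("unique
tags" in the usual library-report sense) are exported, since library
reports use both denominators. The saturation curve subsamples the
clean-tag multiset without replacement in a seeded random order and
records distinct genes detected (≥ 1 matched tag, sense or antisense)
at each depth checkpoint; it is non-decreasing by construction.

## JIP-test

Marks are read at their defining times — Fo at 50 µs (not the 10 µs
first sample; Fo is conventionally taken at 50 µs on this instrument
class), Fk at 300 µs, Fj at 2 ms, Fi at 30 ms — by nearest-sample
lookup, falling back to linear interpolation (and flagging the mark)
when no sample lies within half the nominal acquisition step (10 µs up
to 2 ms, 1 ms after). Fm is the maximum of the whole trace.

Derived parameters follow the standard JIP-test definitions listed in
the README. Two of them are conventions the analysis had to fix:
Mo = 4(Fk − Fo)/(Fm − Fo) (the standard initial-slope estimate, in
ms⁻¹ given the 250-µs spacing between Fo and Fk), and
δ_Ro = (Fm − Fi)/(Fm − Fj) (the RE_o/ET_o form — the efficiency with
which an electron moves from reduced plastoquinone to the PSI end
acceptors). ABS/CS defaults to the Fo proxy (ABS/CS_o) and is
overridable. Degenerate inputs: Fm = Fo is rejected (no variable
fluorescence); Fj = Fo leaves Wk undefined (NaN with warning); Mo = 0
leaves RC_QA undefined.

Note that Fm, being a maximum over ~1,200 samples, is biased upward by
noise of order σ√(2 ln n); parameter-recovery tests on noisy transients
account for this rather than treating Fm as an unbiased mark.

## Synthetic data

The generator produces every input the pipeline consumes, from one
seeded random stream per run (identical configuration ⇒ bit-identical
artifacts):

* **Transcriptome** — `n_genes` sequences (default length 300–2,000 bp),
  each either guaranteed one usable CATG site or guaranteed CATG-free,
  controlled by `catg_probability`.
* **Tag libraries** — per-gene abundances are log-normal (σ = 1.5 by
  default, giving the heavy-tailed count spectrum real libraries show,
  where roughly half of distinct tags are singletons) and renormalised.
  A `deg_fraction` (default 5%) of taggable genes is perturbed in
  condition 2 by 2^±`log2_effect` (default ±2), half up and half down so
  the library composition stays comparable; the recorded per-gene
  `log2fc` is the designed effect (0 for null genes) — renormalisation
  shifts all abundances by a common factor that is negligible under the
  symmetric design and is absorbed into the composition, not attributed
  to null genes. Each library draws `depth_per_library` tags
  multinomially (default 100,000; the recovery analyses use 10⁶),
  emits the canonical 21-mer (reverse-complemented with probability
  `antisense_fraction`, default 0.18, the magnitude reported for real
  DGE libraries), applies per-base substitution errors
  (`error_rate`, default 10⁻³) and pads with a fixed constant adaptor
  to 49 bp. The true adapters of commercial kits are proprietary; any
  constant serves, since the pipeline treats the adaptor as opaque.
* **OJIP transients** — Fo plus three saturating-exponential phases
  starting at 50 µs with half-times near the J, I and P rises (0.4 ms,
  6 ms, 120 ms); the amplitudes solve a linear system so the curve
  passes exactly through the target Fj, Fi at 2 ms, 30 ms and reaches
  Fm at the end of the 1-s acquisition grid (10 µs steps to 2 ms, 1 ms
  steps after). Optional i.i.d. Gaussian noise.
* **Ct tables** — each gene's control ΔCt is drawn once (uniform 1–8
  cycles above the reference Ct of 20); treatment wells are shifted by
  −log₂(fold) (or −log_eff for other efficiencies), so the ΔΔCT
  estimator returns the designed folds exactly at zero noise. Three
  biological × three technical replicates by default.

What the generator does **not** emulate: base-call quality profiles, PCR
duplication, indels, positional error biases, genuine antisense
transcription units (antisense reads are modelled as reverse-complement
emissions of the sense tag), biological replicate variability in the tag
counts (the two libraries are single multinomial draws, matching the
pooled-library design such experiments use), or qPCR efficiency
variation. Passing tests therefore demonstrate correctness of the
computations and calibration of the test under the stated sampling
model, not robustness to those real-data complications.

## Numerical and design notes

* Percentages are rounded half-even: 2 decimals for library summaries,
  1 for match rates and category tables — matching how such tables are
  conventionally printed.
* Saturation subsampling is without replacement (depth accumulation),
  seeded for reproducibility.
* Ambiguous tags (multiple candidate genes at the winning tier) are
  dropped from gene counts rather than fractionally allocated; sense
  beats antisense at equal mismatch tier; antisense counts never enter
  expression values and are reported separately.
* Ct technical replicates are averaged within biological replicate
  before any group statistics, the qbase-style hierarchy.
* The qPCR amplification efficiency is fixed at 2 unless overridden —
  the ΔΔCT assumption.

## Known limitations

* Genome alignment of unmatched tags, repeat masking and spliced
  coordinates are out of scope; the reference is transcript-space only.
* The exact test models sampling noise only; with biological replicates
  a dispersion-aware model (e.g. a negative-binomial GLM) is the right
  tool, and calls made here on pooled libraries inherit that caveat.
* Copy-number percentages are reported over all distinct tags; reports
  that first drop singletons will differ accordingly (both counts are
  exported).
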