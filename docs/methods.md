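# Methods

`repdyn` implements a longitudinal analysis of bulk TCRβ repertoires and
paired immune markers as used in perioperative immunotherapy monitoring:
blood drawn at baseline (Pre), one week after checkpoint blockade (PI), two
weeks after a local intervention such as cryoablation (PC) and six weeks
post-surgery (PS), optionally alongside tissue-site samples sequenced at
shallower (survey) depth.

## Clone tables and the productive filter

The unit of input is a processed clone-abundance table: one tab-separated
file per sample listing CDR3 amino-acid sequences with template counts, as
produced by bulk immunosequencing platforms.  A *clone* is defined by its
CDR3 amino-acid sequence alone; nucleotide-level rearrangements and V/J gene
calls, when present in an export, are deliberately collapsed, because
convergent rearrangements encoding the same CDR3 are the same functional
clone for frequency-tracking purposes.

Rows are dropped as non-productive when the CDR3 is empty, contains a stop
(`*`) or ambiguity (`X`) character or any symbol outside the 20-letter
amino-acid alphabet, or when a frame-annotation column exists and is not an
in-frame/productive flag.  The number of discarded rows is tallied per file
and surfaced in pipeline QC.  Frequencies are always recomputed as
`count / post-filter total`; a frequency column in the input is never
trusted.  After aggregation the table satisfies: unique clone keys, counts
≥ 1, frequencies summing to 1 within 1e-9.

## Clonality: the Simpson index

Repertoire diversity is summarized by the Simpson index over normalized
clone frequencies,

    S = Σ_i p_i²,

the probability that two templates sampled at random belong to the same
clone: 1 for a monoclonal sample, 1/K for a uniform K-clone sample, larger
for more clonal (less diverse) repertoires.  The plug-in form on frequencies
is the default because the downstream overlap statistic is defined on the
same quantities; the without-replacement estimator
Σ n_i(n_i−1) / (N(N−1)) is available behind `unbiased=True` for users who
care about small-sample bias, but is not used by the pipeline.  The plug-in
estimator is biased upward by approximately `(1−S)/depth` at finite
sequencing depth — visible in the `downsample` utility's depth sweeps — and
this bias is one reason survey-resolution tissue samples should not be
naively compared with deep-resolution blood on raw Simpson values.

## Overlap: the Morisita–Horn index

Similarity between two samples is

    M(x, y) = 2 Σ_i x_i y_i / (Σ_i x_i² + Σ_i y_i²)

over the union of clones, with frequency 0 where a clone is absent.  The
numerator factor 2 against the sum of the two Simpson indices is the only
normalization under which identical samples score exactly 1; disjoint
samples score exactly 0.  The statistic is dominated by abundant clones:
replacing a sample's low-frequency tail (≈1% of mass) with novel clones
moves M by far less than 0.05.  Numerically, the cross term and both Simpson
terms are accumulated in a single pass over the sorted clone union so the
identical-sample case returns exactly 1.0 rather than 1±ulp.

## Expansion calling

A clone is *expanded* from a reference to a comparison sample when both

1. its frequency increases more than 2-fold (`fold_change > 2`, strict), and
2. the two-sided Fisher exact p-value of the 2×2 table
   `(count_ref, total_ref − count_ref; count_cmp, total_cmp − count_cmp)`
   is below 0.05.

The conjunction is what filters sampling noise: small clones fluctuate
wildly in relative terms (1 → 3 templates out of 100,000 is a 3-fold change
with p ≈ 0.37), while the same fold on an abundant clone is overwhelming
evidence.  Clones absent from the reference receive an infinite fold change
and remain eligible through the Fisher criterion alone — absence-to-presence
is the extreme increase and must not be dropped; clones absent from the
comparison are never expanded.  No multiple-testing correction is applied by
default (the criterion is a raw-p rule); Benjamini–Hochberg adjustment of
the significance half is available behind `bh=True` via statsmodels.

The Fisher p-value is the classical two-sided sum of hypergeometric
probabilities of all tables with the observed margins that are at most as
probable as the observed table.  For grand totals N ≤ 2000 the inclusion
set is decided in exact integer arithmetic (binomial-coefficient weights,
exact tie handling), so enumeration-oracle comparisons hold at 1e-10.  For
repertoire-scale totals the weights are evaluated with log-gamma functions
and a 1e-7 relative tie guard (the same guard scipy and R use); at such
depths genuinely tied non-identical tables do not arise in practice.
Per-comparison memoization on `(count_ref, count_cmp)` makes whole-repertoire
calls cheap, since most clones are singletons sharing a handful of count
pairs.

No depth normalization is applied between samples of different resolution;
the Fisher test conditions on the observed totals.  A seeded `downsample`
utility (multivariate hypergeometric by default, multinomial optionally)
exists for users who want matched-depth sensitivity analyses.

### Tracking

Given an anchor comparison (default Pre → PC), the expanded clone set is
fixed and its aggregate frequency (sum of member frequencies, 0 where
absent) is reported at every timepoint of the series.  This is the standard
way to visualize whether clones that expanded after an intervention persist,
contract or pre-existed.

## Marker kinetics

Flow-cytometry population frequencies and serum cytokine concentrations
(pg/ml) enter as a subject × analyte × timepoint matrix.  Therapy effect is
described per subject as the log fold change relative to that subject's own
baseline — removing between-subject baseline variability — with base 10 for
marker/cytokine heatmaps and base 2 where clone-style fold changes are
wanted.  Cohort summaries are arithmetic means of log FC with per-cell n.
Derived ratios (e.g. CD8⁺ effector over Foxp3⁺CD4⁺ regulatory cells, or CD8⁺
over the immunosuppressive CD4⁺PD-1hi subset) are elementwise per subject
and timepoint; a zero denominator yields a missing value, never infinity.

Values below a declared lower limit of detection are floored at the LLOD
before any log transform and the floored count is reported; with no declared
LLOD, zeros propagate as missing rather than −∞.  This substitution rule is
a convention (assay vendors do not dictate one); surfacing the count keeps
it auditable.

Two-timepoint tests are classical paired t tests on per-subject differences
(two-sided, n−1 df, pairwise-complete subjects).  Degenerate inputs follow a
documented contract: identical columns give t = 0, p = 1; zero-variance
nonzero differences are flagged `degenerate` with a missing p rather than a
fabricated 0.  Calibration note: on raw lognormal-noise data with ~10
subjects the paired t is slightly conservative (empirical null rejection
≈ 0.03 at α = 0.05) because lognormal differences are heavy-tailed; applied
on the log scale — where the marker stage applies it — differences are
normal and the empirical null rejection rate sits at α.  This is the usual
argument for testing cytokine kinetics on log fold changes.

## Synthetic data

The generator exists so that every stage can be verified against known
truth; its defaults are the package's reference study conditions.

* **Abundance.** True baseline frequencies follow a Zipf law with exponent
  1.2 over 5000 clones (a lognormal alternative is available).  This gives
  the heavy-tailed, few-dominant-clones structure real repertoires show —
  the default truth has a top clone near 20% of the repertoire, matching the
  "one very dominant clone" regime seen in highly clonal patients.
* **Expansions** are injected on the true frequency vector (selected clones
  multiplied by a fold, then renormalized) *before* sampling — biological
  expansion, not observation noise — so recovery tests are meaningful.  The
  default injects, at PC only: 2 clones ×4 from the large strata (baseline
  frequency in (0.05, 1]) and 20 clones ×4 from the mid strata ([1e-3,
  1e-2)).  The large-clone event is what makes ground-truth clonality peak
  at PC: with a dominant clone in the baseline, boosting only mid-frequency
  clones *dilutes* the dominant clone on renormalization and lowers Σp².
  Renormalization also compresses every effective fold by the factor
  1 + (fold−1)·(selected mass); recovery experiments therefore use
  mid-stratum-only injections, where the compression is a few percent.
* **Observation.** Each observed table is a multinomial draw of the
  timepoint's template depth from the true frequencies — deep resolution
  (1e5 templates) for blood, survey resolution (1e4) for tissue
  compartments by default.
* **Compartments.** A tissue compartment shares a fraction `s_share` of
  clone identities with blood; shared clones keep their blood baseline
  frequency up to lognormal perturbation (log-sd 0.5 by default), the rest
  are novel identities.  Overlap with blood rises monotonically with
  `s_share`, reaching ≈1 at full sharing with no perturbation.
* **Analytes.** Subject baselines are lognormal (log10 sd 0.3 around a
  per-analyte mean), timepoint values multiply in a true effect and
  lognormal noise (log10 sd 0.1); cohorts default to 10 subjects.
* **Labels** are synthetic CDR3-like strings (`C` + 8–16 residues + `F`) so
  every fixture passes the productive filter.  Seeds are mandatory; the same
  config and seed give byte-identical emitted files.

What the generator does **not** emulate: V(D)J recombination statistics or
sequence-dependent generation probabilities, PCR/sequencing error (clones
are never misassigned), longitudinal autocorrelation of the unexpanded
background (each timepoint resamples the same truth), batch effects, or
censoring mechanisms beyond a simple LLOD.  Passing tests therefore
demonstrate correctness of the statistics under idealized multinomial
sampling — they do not certify robustness to assay artifacts in real data.

## Numerical and design choices

* Rank-frequency ties break lexicographically on CDR3; all outputs are
  sorted so identical inputs give byte-identical files.
* `-log10 p` in volcano exports is capped (default 300) for plotting;
  infinite/zero fold-change clones go to a sidecar table instead of being
  dropped.
* The expansion 2×2 table construction and thresholds are echoed in every
  run's metadata; the comparison anchor (default PC vs Pre) is always
  explicit in outputs.
* Tissue-site labels live in the same namespace as blood timepoints and
  sort after them, so tissue runs need no special casing.
* Problem sizes in the test and acceptance suites (5000-clone repertoires at
  depth 1e5, 20 null seeds, 1000 analyte replicates, exhaustive Fisher
  enumeration to margins 25 with a deterministic grid to 200) were chosen as
  the smallest scales at which the asserted behaviour is statistically
  unambiguous.

## Known limitations

* Simpson and Morisita values at different sequencing depths are not
  bias-corrected; cross-resolution comparisons should use `downsample`.
* The expansion caller tests increase only; contraction is reported
  descriptively via fold_change < 1 but never flagged.
* Aggregate tracked frequency can double-count nothing but can mask
  member-level heterogeneity; member lists are retained for per-clone plots.
* With `bh=True` the reported `p_value` stays raw; only the expanded flag
  uses adjusted values.
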