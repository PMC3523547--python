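# Methods

## The screening model

`surfscreen` implements a transcript-level screen for candidate
immunotherapy targets: cell-surface proteins whose transcripts are
over-expressed in a tumor cohort relative to normal tissue.  The screen has
four stages.

**1. Differential statistic.**  For each probe *g* and tumor cohort *d*,
the cohort's arrays (group 1, size *n₁*) are compared with the pooled
normal-tissue panel (group 2, size *n₂*, default 15 arrays — one each from
lung, liver, kidney, heart, adrenal, cerebrum, cerebellum, uterus, testes,
stomach, spleen, bladder, skeletal muscle, prostate, ovary) with the
pooled-variance (Student) two-sample t-statistic

    T = (x̄ − ȳ) / (s_p √(1/n₁ + 1/n₂)),
    s_p² = [(n₁−1)s₁² + (n₂−1)s₂²] / (n₁ + n₂ − 2),   df = n₁ + n₂ − 2,

with unbiased sample variances.  T > 0 means over-expression in tumor.  The
two-sided p-value 2·(1 − F(|T|; df)) is evaluated through the regularized
incomplete beta function (`scipy.special.stdtr`), which stays exact for
p-values far below the ~1e−16 floor at which the naive 1 − CDF subtraction
loses all precision; the packaged reference tables contain p-values down to
~1e−20.

The pooled (equal-variance) form rather than Welch's statistic is a
deliberate identification: with a 15-array normal panel, df = n₁ + 13
reproduces the reference tables' printed p-values from their printed T
values in every disease except the flagged ASPS anomaly (see below), which
a Welch df cannot do.  The same evidence fixes the comparator as all 15
normal arrays pooled as individual observations, not a single averaged
expression score; a `per_tissue_means` mode (collapse each tissue to its
mean before testing) is provided for sensitivity analysis and coincides
with the default when the panel has one array per tissue.

**2. Surface filter.**  Localization evidence records
(subject, compartment term, source ∈ {CURATION_OVERRIDE, LITERATURE,
PROTEIN_DB, GO, CHIP_ANNOTATION}) are merged and resolved to one of four
calls by a fixed precedence: any surface-vocabulary term ⇒ `CELL_SURFACE`
(a protein on the surface *and* in another compartment is kept); else any
internal-vocabulary term (mitochondria, nuclear envelope, Golgi, ER,
endosome, lysosome, vesicle) ⇒ `INTERNAL_MEMBRANE_ONLY`; else a bare
"membrane" token ⇒ `UNKNOWN_MEMBRANE`; else `NON_MEMBRANE`.  Matching is
case-insensitive substring containment against configurable vocabularies —
deterministic and auditable, not free-text inference.  A curation-override
table dominates all evidence, mechanizing per-gene literature judgments.
`UNKNOWN_MEMBRANE` subjects are excluded from the surface set unless
`include_unknown_membrane` is set, since such tags only merit inclusion
after manual review.  Unannotated probes count as `NON_MEMBRANE` and are
logged.

**3. Selection.**  Probes are ranked by descending T (ties broken by probe
ID for cross-platform determinism).  Hits are counted one-sided and
strictly (T > τ, default τ = 10 — a deliberately extreme cutoff; a cohort
with zero hits is not without targets, merely globally closer to the
normal surface landscape).  The top k = 25 ranked probes that pass the
surface filter form the disease's target table.  p-values are reported
raw: no multiple-testing correction is applied, because the screen ranks
by T and treats p as descriptive.  Zero-pooled-variance probes are
excluded with a logged warning, never reported as ±∞.

**4. Aggregation.**  Target tables are compared across diseases by
canonical gene symbol.  Symbol normalization uses an alias table (the
packaged one covers the compound forms in the reference lists, e.g.
`CD146/MCAM` → `MCAM`); an unmapped slash-compound falls back to the
segment after the final "/", upper-cased.  Each disease contributes at
most once per gene regardless of duplicate probes.  Per-disease T
distributions are summarized as min/q1/median/q3/max/mean with type-7
(linear-interpolation) quartiles — the convention is irrelevant to the
min/max/mean values quoted in text — and displayed with half-even rounding
to one decimal (19.85 → 19.8, 9.96 → 10.0).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` (τ) | 10 | strict one-sided hit cutoff on T |
| `top_k` (k) | 25 | target-list length per disease |
| `min_group_size` | 6 | smallest screenable tumor cohort ("more than five") |
| normal panel | 15 tissues | comparator group; configurable tissue list |
| `include_unknown_membrane` | off | admit bare-"membrane" annotations |
| `log2` | off | log2(v+1) before screening (T is scale-dependent only through means/variances) |
| `normal_mode` | `pooled_samples` | or `per_tissue_means` sensitivity mode |

Expression values are taken as already-normalized summary intensities; no
chip-level preprocessing, batch correction, or imputation is performed
(missing cells are hard errors, because silent imputation would change T).

## Synthetic data generator

`generate_dataset` emulates the study design the screen expects: 12 tumor
cohorts with sizes {Pre-B_ALL 9, ARMS 12, ASPS 7, GBM 7, NBL-MYCNA 24,
STS 6, OS 17, HBL 7, EWS 19, ERMS 9, NBL 15, DSRCT 8} and a 15-array
normal panel, one array per tissue.  Per probe, baseline
b_g ~ N(μ_b = 8, σ_b² = 4) (a log2-like intensity scale) is shared across
samples; each cell adds N(0, σ² = 1) noise; planted probes add a shift
δ = 3 (noise-SD units) to one cohort's tumor samples.  A fraction
(default 15%) of probes receives surface compartment terms — every seventh
of them also an internal term, to exercise the both-compartments inclusion
rule — and planted probes are drawn only from that pool, so ground-truth
recovery is measured through the full filter + rank path.  All draws come
from a single seeded generator in fixed order, making datasets
bit-identical per (config, seed).

Because the downstream statistic sees only group means and variances, the
additive Gaussian model is the simplest structure that exercises every
pipeline contract.  What it does **not** emulate: probe-level
cross-hybridization, mean-variance coupling of real array intensities,
batch and array artifacts, correlated probes within a gene, or realistic
annotation noise.  Passing recovery/calibration tests therefore
demonstrates correctness of the screening machinery under its own
assumptions, not robustness to real microarray pathologies.

## Packaged reference tables

The package ships a checksummed transcription of published per-disease
top-25 surface-target tables for the 12 cohorts (probe ID, gene symbol, T,
p), plus cohort sizes and published above-threshold hit counts.  These
anchor the offline checks: p-from-T reproduction at df = n₁ + 13,
cross-disease sharing counts (MCAM 8, GPC2 8, MTDH 4 of 12), and the
presented T ranges (e.g. ARMS 27.7–10.0).  Three transcription anomalies
are flagged in the loaded metadata and exempted from consistency checks:
the ASPS p-values are inconsistent with df = 20 (they imply df ≈ 27–28;
unexplained at source), one OS row prints p = 7.90E−01 where ~7.9E−10 is
evidently meant, and the STS list duplicates a printed rank (ranks are
stored positionally).

## Numerical and design choices

- **p-from-T agreement bound.** Printed T values carry two decimals, so a
  recomputed p can differ in its last digit; the consistency test brackets
  each printed p by the tail probabilities at T ± 0.005 (with half-ulp
  slack for the printed p's own 3-digit rounding).  Five rows that happen
  to reproduce exactly at three significant figures are asserted exactly.
- **Tie-breaks.** Equal T orders by probe ID ascending; sorting is stable
  mergesort, so output is platform-independent.
- **Determinism.** Report bundles contain no timestamps; two runs on
  identical inputs are byte-identical.
- **Degenerate inputs.** Normal panels of fewer than two arrays, groups of
  fewer than two values, zero pooled variance, negative values under log2,
  empty symbols, and unknown evidence sources or calls are all hard errors
  (or, for zero variance, logged exclusions) rather than silent NaNs.
- **Problem sizes.** The calibration suite uses 5,000 probes for the null
  Kolmogorov–Smirnov check (KS < 0.05 against Student-t(df) per cohort,
  zero hits above τ = 10 across all 12 cohorts) and five replicate seeds of
  4,000 probes for planted-target recovery (≥ 90% of 25 planted targets
  per disease recovered in the top-25 surface list; observed ≈ 99%).
  These sizes give stable statistics while keeping the default suite fast.

## Known limitations

- Annotation quality bounds the screen: the term vocabularies are a
  reasoned reconstruction, user-overridable, and no transmembrane-topology
  prediction or live database lookup is attempted.
- Probe-level reporting means one gene can occupy several top-25 slots via
  multiple probes; collapsing to genes happens only at aggregation.
- Raw p-values at tens of thousands of probes demand external correction
  if used inferentially.
- The generator's Gaussian model makes no claim about real-array intensity
  distributions (see above).
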