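# Methods

This note documents the models, defaults, numerical choices, and known
limitations of the `drugscreen` pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Plate design and normalization

Screens are laid out on 384-well plates (rows A–P, columns 1–24). The outer
two rows and columns are an unseeded buffer ring against evaporation edge
effects; the seeded 12×20 interior carries 18 vehicle (DMSO) wells at fixed,
deterministic positions and triplicate six-point 1:3 dilution series
(10 µM down to 0.04 µM) for up to 12 compounds per plate per arm. Larger
panels split across plates; they are never truncated.

Normalization is strictly per plate: relative CTG intensity =
raw luminescence / mean vehicle luminescence on the same plate. Plates
without a usable vehicle set fail loudly rather than borrowing a global
mean. Relative viability is *not* clipped to [0, 1]; values above 1
(growth stimulation) flow into fitting unchanged. No outlier exclusion is
applied before the vehicle mean. Normalization is scale-invariant per
plate and leaves the vehicle mean at exactly 1.

## LL.4 dose-response model

`f(x) = c + (d − c) / (1 + (x/e)^b)`, fitted by Levenberg–Marquardt least
squares on all replicate points with an analytic Jacobian. Choices:

- **Parameterization**: the midpoint is optimized as log(e) so e > 0 is
  structural; c, d are unbounded and b unconstrained in sign.
- **Initialization**: d from the response at the lowest dose (or the 0-µM
  anchor when present), c from the highest dose, e at the geometric
  mid-dose; slope starts {1, 2, 0.5, −1}, keeping the lowest-RSS solution,
  ties broken toward the smaller |b|.
- **Canonicalization**: for x > 0 the surface is invariant under
  (b, c, d) → (−b, d, c); fits are canonicalized to d ≥ c so the ceiling is
  always the zero-dose response. The swap is skipped when a 0-µM anchor is
  present, since the anchor already pins d.
- **Degenerate data**: a flat response (range < 1e−12) short-circuits to
  c = d = mean with `converged = False`; flat margins abort CI maps.
- **Zero doses** never enter screen fits; in grid margin fits the single
  0-µM vehicle cell is included as a ceiling anchor with model value d.

**EC-p** is computed by closed-form inversion,
x = e·((d − c)/(y − c) − 1)^(1/b). Two target conventions exist in practice
— p% of the fitted response range ("maximal response") and an absolute
viability of 1 − p/100 ("growth inhibition") — and both are implemented;
`relative` is the default and the CLI exposes `--ec-mode`. Targets outside
the open response interval (c, d) return NaN (undefined), never an
extrapolated dose.

**AUC** is the trapezoidal integral of the *fitted* curve on a 201-point
uniform log10-dose grid, divided by the log10 window width. The fitted
curve (rather than the observed points) is used so the metric is smooth in
the parameters; 201 points put the quadrature error near 5e−7 for typical
curves, far below fitting noise. The normalization makes an inert drug
score exactly 1 over any window, so "lower AUC = more sensitive" reads
directly.

## Delta-AUC ranking

Deltas are computed from one pooled-triplicate fit per arm (not
per-replicate fits). z-scoring uses the sample (n−1) standard deviation by
default — the population convention is one flag away (`ddof=0`) and is
covered by tests. Lines whose deltas are all equal (sd below 1e−12 of the
delta scale) get z = 0 and a degeneracy flag; single-drug lines get
undefined z with a warning. The median z ignores missing lines; drugs with
z in at most half the lines are flagged low-confidence. Ties in median z
are broken lexicographically so rankings are total and deterministic.

## Loewe combination index

Margins come from the grid's own zero-dose row/column rather than a
separate single-agent screen — this keeps every grid self-contained and
guarantees the reference curves saw the same plate, passage, and noise as
the interior cells. CI is computed on triplicate means. Cells whose mean
effect lies outside the open response range of either margin curve — plus a
guard band of 1e−4 of the response range at each asymptote (`clip_tol`) —
are undefined: the inversion has no positive finite solution there, and
without the guard band a cell measured exactly at a fitted asymptote could
invert to an arbitrarily extreme dose through float error alone. Undefined
cells propagate as explicit NaNs (white tiles); they are never
interpolated. Display rescaling of the log2(CI) gradient never alters
stored values.

## Synthetic-data generator

The generators define the study conditions; their defaults are fixed, not
tuning knobs.

- **Noise**: multiplicative mean-one lognormal on raw intensity and tumour
  volume, with σ² = ln(1 + CV²). Viability assays are scale-noisy, and the
  mean-one construction keeps expected signals unbiased. Default CV = 5%
  for screens; tests that need exact closure set CV = 0.
- **Screen defaults**: seven ovarian cell lines, a 12-compound panel with
  EC50s log-spaced from 0.3 to 30 µM (sub-µM hits through
  inactive-at-10-µM), slopes 0.8–2, floors 0–0.25. One compound (cmpd04) is
  planted as the cooperative partner: its EC50 is divided by 3 in the
  sensitized arm; all others shift by 1. Twelve compounds fill exactly one
  plate per arm, keeping a 200-seed Monte-Carlo of the full pipeline at
  desk scale while spanning the potency range of a realistic library.
- **Grids**: nine-point 1:3 series from 10 µM plus a true 0 µM per axis,
  triplicate. The planted surface solves the Loewe dose-equivalence
  equation a/A(E) + b/B(E) = 1/k for the effect E (closed form f(k(a+b))
  for identical agents); k = 1 is exactly additive, k > 1 supra-additive
  (measured CI = 1/k), k < 1 sub-additive. When the dose-equivalent sum
  exceeds what the weaker margin can express, the surface saturates at the
  shared floor rather than extrapolating past an asymptote.
- **Omics**: 500 proteins (2 cell lines) and 2,000 genes (3 cell lines) by
  default; 12 planted stabilized proteins (log2FC ≈ 1.5, p ≈ 1e−8 in both
  proteome lines, gene log2FC drawn below 0.5 in all transcriptome lines),
  5 of them placed in the pathway union (5 GMT sets of 40 genes). q-values
  are Benjamini–Hochberg adjustments per line. Null log2FCs are N(0, 0.3)
  for proteins and N(0, 0.35) for genes — the latter leaves roughly
  three-quarters of genes passing the non-upregulation filter, a realistic
  fraction. Effect sizes and p-values are drawn independently rather than
  from a generative abundance model; the tables exercise the filter logic,
  not differential-abundance estimation.
- **Tumours**: per-arm log2-linear growth, β₀ = 7.17 (≈144 mm³, a 0.65 cm
  enrollment diameter) with per-animal N(0, 0.15) variation, measurement
  days {0, 2, 4, 7, 9, 11, 14}, five animals per arm. Default rates
  (vehicle 0.28, cisplatin 0.25, treated 0.10 log2 mm³/day) emulate a
  cisplatin-resistant model in which only the investigational arm slows
  growth. L and W are back-computed under L = W so the ellipsoid formula
  reproduces the simulated volume exactly.
- **Determinism**: all draws flow from `numpy.random.default_rng` seeded
  with (config seed, stream id), one stream per generator, so outputs are
  byte-identical for a fixed config and independent across generators.
- **Ground truth** is always emitted alongside the tables (JSON sidecars
  via the CLI), so recovery tests never re-derive planted values from noisy
  data.

What the generator does **not** emulate: plate-to-plate batch effects,
spatial edge/evaporation gradients inside the seeded interior,
liquid-handling errors, dose-dependent (heteroscedastic) noise, correlated
protein/gene effects from a shared biological driver, or censoring and
dropout in animal studies. Passing tests therefore demonstrate correctness
of the analysis chain under clean multiplicative noise — not robustness to
these real-world artifacts.

## Growth statistics

Time is measured in days post-treatment initiation. Growth rates are fit
on whatever timepoints an animal has (no censoring rule); animals need at
least two distinct days. Arm comparison: Kruskal–Wallis omnibus on the
per-animal slopes, pairwise Welch t-tests (two-sided by default,
per-comparison sidedness configurable), Bonferroni factor equal to the
number of pairwise tests actually performed. Arms with one animal are
excluded with a warning. Mixed-design ANOVA and survival analysis are
deliberately out of scope — standard implementations exist elsewhere and
need no re-derivation here.

## Nomination cascade

All thresholds are strict inequalities (log2FC > 0, q < 0.05,
log2FC < 0.5); boundary values are excluded. The protein→gene mapping is an
explicit input; unmapped proteins are excluded with a logged count.  Genes
absent from the transcriptome are conservatively treated as failing the
non-upregulation filter; `missing_gene_passes=True` (with the gene
universe) flips this. q-values are consumed as given — recomputing them
from raw data is upstream of this package.

## Problem sizes

The test suite's Monte-Carlo checks use 200 seeds throughout: full
seven-line, 12-drug, two-arm screens for ranking recovery; single-probe
plates for EC50 recovery at CV 5%; single-grid margin refits; and
single-animal growth fits at CV 10%. The brute-force nomination oracle
runs on a 5,000-protein × 20,000-gene table. These sizes make every oracle
exactly recomputable at a desk while leaving the statistical behaviour of
the estimators visible.

## Known limitations

- The LL.4 fitter is unweighted; heteroscedastic weighting and
  five-parameter asymmetry are out of scope.
- The Loewe construction assumes monotone margins with a common attainable
  effect range; response-surface models (BRAID, MuSyC) and other synergy
  scores (Bliss, HSA, ZIP) are out of scope.
- The grid generator emits grids as standalone tables rather than placing
  two grids per physical 384-well plate; the (0,0) vehicle triplicate is
  the normalization reference.
- Rankings from a 12-compound panel have coarser z-score granularity than
  a full library; the z-scale (not the ranking logic) depends on panel
  composition.
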