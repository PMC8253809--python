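# Methods

## Plate normalization and quality control

Raw luminescence (RLU) is proportional to viable-cell ATP and spans
orders of magnitude, with measurement error roughly proportional to
signal. Single-agent plates are therefore log2-transformed before
normalization; combination grids are normalized on the linear scale
(their downstream surface fit expects untransformed fractional effects).
Percent activity is

    100 · (mean(neg) − x) / (mean(neg) − mean(pos))

computed on the working scale, where `neg` are vehicle (DMSO) wells and
`pos` a saturating cytotoxic control (staurosporine). The quantity is
deliberately not clamped to [0, 100]: overshoot carries information that
the curve-fit constraints (below) absorb. On the log2 scale the
normalization is invariant under uniform multiplicative rescaling of raw
RLU, which makes results insensitive to detector gain.

Plate quality uses the Z′ factor,
`z′ = 1 − 3·(sd(neg)+sd(pos))/|mean(neg)−mean(pos)|`, computed on the
same scale as normalization with sample (n−1) standard deviations.
Plates with z′ below a configurable threshold (default 0.5, the
classical screening cutoff) are excluded from pooling; coincident
control means produce an error record rather than a number.

## Dose–response model

Pooled replicate points (concatenated, never averaged) are fit with the
log-logistic curve

    f(x) = y0 + (yFin − y0) / (1 + exp(h·(ln x − ln EC50)))

under box constraints: h ∈ [−10, 0] (activity non-decreasing in dose),
EC50 ∈ [10⁻¹¹, 10⁻⁴] M. The three-parameter variant fixes y0 = 0 and
boxes yFin in [0, max median activity]; the four-parameter variant boxes
both y0 and yFin by the range of per-concentration median activities.
The medians act as a data-driven guard against runaway asymptotes.

Fitting is bounded least squares (trust-region reflective) over
(y0, yFin, h, ln EC50), with nine deterministic starts crossing
h ∈ {−0.5, −2, −8} with EC50 at the 25th/50th/75th percentiles of the
tested concentrations. Model choice is by the Gaussian least-squares
AICc,

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),

with ties (|Δ| < 1e−9) resolved toward fewer parameters. A perfect fit
(RSS = 0) is treated as AICc = −∞.

When no sigmoid start converges, or when the best sigmoid RSS exceeds 10×
the RSS of a smoothing spline while also exceeding a mean-squared
residual of 1 %² per point (so near-perfect fits are never displaced by
an even-more-perfect spline), the pair falls back to a cubic smoothing
spline of activity vs log10 concentration with GCV-selected penalty.
Replicates at one concentration are collapsed to their mean with count
weights, mirroring how classical smoothing-spline implementations handle
ties; the spline is evaluated flat (constant) outside the observed dose
range. Fewer than four distinct concentrations marks the pair unfit.

AUC is the trapezoid integral of the selected curve over
u = log10 x on a uniform 701-point grid (100 points per decade) spanning
[10⁻¹¹, 10⁻⁴] M regardless of the tested range, in %·decade units;
doubling the grid changes the result by far less than 0.01%. EC50 is
reported as the fitted inflection concentration — the midpoint of the
transition between y0 and yFin — even when yFin is below 50% absolute
activity; spline fits carry no EC50.

### Identifiability at the window edges

With a 10-point threefold series from 35 µM the lowest tested dose is
≈1.8 nM. Two consequences worth knowing:

- the yFin box (max of median activities) sits slightly below a curve's
  true asymptote whenever the top dose does not fully saturate the
  response, so "exact" asymptote recovery is only possible for curves
  whose plateau is effectively reached in-window;
- a nonzero zero-dose baseline (y0 > 0) is only detectable when doses
  below the transition are observed. If the true EC50 sits at or below
  the lowest tested dose, a three-parameter curve rising from zero just
  below the window fits equally well and AICc correctly prefers it.

## Sensitivity profiling

Per-drug AUC rows minus their median across cell lines give the
selectivity view; its per-drug median is identically zero. The most
selective drug for a line is the argmax of normalized AUC (lexicographic
tie-break, ties flagged). Pan-sensitive lines — elevated response to
nearly every drug, which distorts cross-line comparison — are flagged
when their median normalized AUC exceeds the across-line median by
k·MAD (k = 3 default; MAD is normal-consistent, 1.4826× the raw median
absolute deviation, so k = 3 corresponds to ≈3σ under Gaussian noise).
The detector's false-flag rate is quoted per line tested; over
exchangeable simulated screens it is ≈2% at k = 3 — higher than the
Gaussian 3σ tail because the MAD over 16 line medians is itself a noisy
estimate.

"Most active" drugs are ranked by per-drug median AUC (mean available as
an option); the top round(fraction·n) (default 25%) are z-scored per
drug with sample (n−1) sd — constant rows are dropped — and clustered
agglomeratively over both axes with distance 1 − Pearson (pairwise
complete for missing entries) and average linkage. Rows and columns are
pre-sorted by identifier before linkage so leaf orders are deterministic.
Z-scoring operates on raw AUC rows by default (normalized AUC via a
switch). Missing matrix entries are excluded from medians, means and
correlations, never imputed.

## Combination response surface

With σ = √(n_A·n_B) and scaled doses D_A = (a/EC50_A)^(n_A/σ),
D_B = (b/EC50_B)^(n_B/σ), the combined dose is
D = D_A + D_B + κ·√(D_A·D_B) and the effect is
E0 + (Ef − E0)·D^σ/(1 + D^σ). This is the equal-maximal-effect form of
the combined-dose response surface: both agents share E0 and Ef, each
keeps its own potency and slope, and κ captures the interaction. Two
contracts pin the parameterization down: at zero dose of either agent
the surface reduces exactly to the other agent's Hill curve, and at
κ = 0 with equal slopes the iso-effect contours are the straight Loewe
lines between single-agent iso-doses. κ is constrained to (−2, 100];
−2 is the algebraic limit below which the combined dose can go negative.
Variants with distinct per-drug maximal effects are out of scope.

Surface fitting is bounded least squares over
(E0, Ef, ln EC50_A, ln EC50_B, n_A, n_B, κ), started from independent
Hill fits of the two single-agent edges crossed with κ ∈ {−1, 0, 2};
grids must include both zero-dose edges and ≥9 interior cells. The
interaction class is the sign of κ̂ with a ±0.1 dead band (the sign is
the semantic; the band absorbs estimation noise). An optional
percentile bootstrap (200 case resamples of cell residuals, seeded)
gives a κ interval.

Isoboles are traced by root-finding the level set column-wise; for
antagonistic surfaces the required partner dose can exceed the
single-agent iso-dose and the bracket is expanded accordingly.

### Index of achievable efficacy

IAE answers "how much of a realistic dose window achieves a target
effect". The surface is evaluated on a 201×201 log10-uniform grid over
[cmax·10⁻⁴, cmax]² (default cmax = 1 µM, threshold 50% viability
reduction; the 4-decade lower extent mirrors typical tested ranges).
With p the achieving fraction of grid cells, IAE = √(1/(1−p)): exactly
1.0 when the threshold is never met — matching the reported-value
semantics for weakly efficacious combinations — monotone in p, and
capped at 10³ when the failure region is empty. The index is invariant
under relabeling the two drugs. Because the window is a discrete grid,
constructed half-achieving surfaces give √2 only to within the grid
resolution (±0.01 at 201 points per axis).

## Synthetic screens

The simulator writes the same layout/read tables the pipeline parses. A
simulated 384-well plate carries one cell line, 16 negative + 16
positive control wells (columns 1–2), and up to 32 drugs' 10-point
series; real plate maps vary and this one is simply a documented
default. Control RLU are centered at 10⁶ (vehicle) and 10⁵ (cytotoxic);
compound wells interpolate between the control means on the log2 scale
according to the pair's true curve, so at zero noise percent-activity
normalization returns the truth exactly. Noise is multiplicative
log-normal on RLU (luminescence error is scale-proportional) with 5% CV
by default, which yields plate z′ around 0.85–0.9 — comparable to a
well-behaved automated screen.

Truth curves draw log10 EC50 ~ U[−9, −5.5] (so some transitions sit
near or past the window edges, as in real screens), hill ~ U[−4, −0.5],
yFin ~ U[30, 110], y0 = 0. Designated baseline-shift records use
y0 = 20 and draw log10 EC50 ~ U[−7.5, −6] so the zero-dose plateau is
observed — per the identifiability note above, a baseline outside the
sampled window is not a detectable baseline. An optional pan-sensitive
line adds a constant activity boost across all drugs. Combination grids
add Gaussian noise (default sd 3% activity) to a true surface.

What the simulator does not emulate: spatial plate artifacts (edge
effects, drift), carry-over, compound degradation, biological structure
linking lines (mutations, subgroups), or replicate-to-replicate batch
effects. Passing tests therefore demonstrate correctness of the
analytics under idealized error models, not robustness to systematic
artifacts — spatial correction methods are deliberately out of scope.

## Problem sizes in the checks

The verification suite uses simulated screens of 25–30 drugs × 4 lines
(100–120 curves) at 5% CV, 100 noisy 9×9 combination grids for sign
accuracy, and 100–200 AUC-level screens of 93 drugs × 16 lines for the
outlier-detector rates; these sizes give stable rates while keeping the
whole suite fast to re-run.
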