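"""Constrained log-logistic dose-response fitting and AUC.

Percent-activity points pooled over replicates are fit with the
log-logistic (sigmoidal) model

    f(x) = y0 + (yFin - y0) / (1 + exp(h * (ln x - ln EC50)))

with hill slope h constrained to [-10, 0] (so the curve is non-decreasing
in concentration) and EC50 to [1e-11, 1e-4] M.  Two variants are fit: a
three-parameter model with the zero-dose response y0 fixed at 0, and a
four-parameter model with y0 free.  yFin (and y0 in the 4-parameter case)
are boxed by the per-concentration median activities.  The variant with
the lower small-sample-corrected Akaike criterion (AICc, Gaussian
least-squares form) is kept; if the sigmoid cannot be fit, a
cross-validated cubic smoothing spline of activity against log10
concentration is used instead.  The activity AUC is the trapezoid
integral of the selected curve over log10 concentration on
[1e-11, 1e-4] M, in %*decade units (0 = inert, 700 = fully active over
all seven decades).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseDataset",
    "ConcentrationMedians",
    "SigmoidFit",
    "CurveSummary",
    "loglogistic",
    "pool_replicates",
    "concentration_medians",
    "fit_sigmoid",
    "aicc",
    "select_model",
    "fit_spline_fallback",
    "compute_auc",
    "ec50_from_fit",
    "summarize_curve",
    "fit_activity_table",
]

AUC_LO = 1e-11  # M, lower integration bound
AUC_HI = 1e-4  # M, upper integration bound
AUC_GRID = 701  # 100 points per decade over 7 decades
HILL_BOUNDS = (-10.0, 0.0)
EC50_BOUNDS = (1e-11, 1e-4)
# sigmoid is abandoned when its best RSS exceeds this multiple of the spline RSS
SPLINE_GUARD_FACTOR = 10.0
# ... but only when the sigmoid misfit is non-trivial (mean squared residual
# above this floor, %^2); otherwise both curves describe the data
GUARD_MSR_FLOOR = 1.0


@dataclass
class DoseResponseDataset:
    """Pooled (concentration, % activity) points for one drug x cell-line pair.

    Replicate points are kept, never averaged.
    """

    compound_id: str
    cell_line: str
    concentrations: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.concentrations.shape != self.activities.shape:
            raise ValueError("concentration/activity length mismatch")
        if self.concentrations.size and np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")

    @property
    def n_points(self) -> int:
        return int(self.concentrations.size)

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)


@dataclass
class ConcentrationMedians:
    concentrations: np.ndarray  # distinct, ascending
    medians: np.ndarray
    min_median: float
    max_median: float


@dataclass
class SigmoidFit:
    model: str  # three_param | four_param
    y0: float
    yfin: float
    hill: float
    ec50: float
    rss: float
    n: int
    k: int
    aicc: float
    converged: bool

    def __call__(self, x) -> np.ndarray:
        return loglogistic(x, self.y0, self.yfin, self.hill, self.ec50)


@dataclass
class CurveSummary:
    """Per (drug, line) result: selected curve kind, AUC, and diagnostics."""

    compound_id: str
    cell_line: str
    fit_kind: str  # sigmoid | spline | unfit
    auc: float | None
    ec50: float | None
    selected_model: str | None
    fit: SigmoidFit | None = None
    rss: float | None = None
    aicc: float | None = None
    note: str | None = None


def loglogistic(x, y0: float, yfin: float, hill: float, ec50: float) -> np.ndarray:
    """Evaluate the log-logistic curve; non-decreasing in x for hill <= 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return y0 + (yfin - y0) / (1.0 + np.exp(hill * (np.log(x) - np.log(ec50))))


def pool_replicates(datasets: list[DoseResponseDataset]) -> DoseResponseDataset:
    """Concatenate replicate measurements of one drug x cell-line pair.

    Points are pooled, not averaged; the result is sorted by concentration
    (activity as secondary key) so it is independent of input order.
    """
    if not datasets:
        raise ValueError("no replicate datasets to pool")
    first = datasets[0]
    for d in datasets[1:]:
        if (d.compound_id, d.cell_line) != (first.compound_id, first.cell_line):
            raise ValueError("replicates must share compound and cell line")
    conc = np.concatenate([d.concentrations for d in datasets])
    act = np.concatenate([d.activities for d in datasets])
    order = np.lexsort((act, conc))
    return DoseResponseDataset(first.compound_id, first.cell_line, conc[order], act[order])


def concentration_medians(dataset: DoseResponseDataset) -> ConcentrationMedians:
    """Median activity at each distinct concentration (midpoint for even counts)."""
    if dataset.n_points == 0:
        raise ValueError("empty dataset")
    concs = np.unique(dataset.concentrations)
    meds = np.array(
        [np.median(dataset.activities[dataset.concentrations == c]) for c in concs]
    )
    return ConcentrationMedians(concs, meds, float(meds.min()), float(meds.max()))


def aicc(n: int, k: int, rss: float) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    AICc = n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if rss <= 0:
        # perfect fit: push the criterion to -inf so it always wins
        return float("-inf")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _fit_box(model: str, medians: ConcentrationMedians) -> tuple[np.ndarray, np.ndarray]:
    """Parameter bounds (lower, upper).

    three_param: (yfin, hill, ln_ec50) with y0 fixed at 0 and yfin boxed
    by [0, max median]; four_param: (y0, yfin, hill, ln_ec50) with y0 and
    yfin boxed by the median range.
    """
    lo_med, hi_med = medians.min_median, medians.max_median
    eps = max(1e-6, 1e-9 * max(abs(lo_med), abs(hi_med)))
    ln_lo, ln_hi = np.log(EC50_BOUNDS[0]), np.log(EC50_BOUNDS[1])
    if model == "three_param":
        yfin_lo, yfin_hi = min(0.0, hi_med), max(0.0, hi_med)
        lower = np.array([yfin_lo, HILL_BOUNDS[0], ln_lo])
        upper = np.array([yfin_hi + eps, HILL_BOUNDS[1], ln_hi])
    elif model == "four_param":
        lower = np.array([lo_med, lo_med, HILL_BOUNDS[0], ln_lo])
        upper = np.array([hi_med + eps, hi_med + eps, HILL_BOUNDS[1], ln_hi])
    else:
        raise ValueError(f"unknown model {model!r}")
    return lower, upper


def fit_sigmoid(
    dataset: DoseResponseDataset,
    medians: ConcentrationMedians | None = None,
    model: str = "four_param",
) -> SigmoidFit:
    """Box-constrained least-squares log-logistic fit with deterministic multi-starts.

    Starts combine hill in {-0.5, -2, -8} with EC50 at the 25th/50th/75th
    percentiles of the tested concentrations; the best RSS within the box
    wins.  ``converged`` is False when no start succeeds.
    """
    if medians is None:
        medians = concentration_medians(dataset)
    k = 3 if model == "three_param" else 4
    if dataset.n_distinct < 2 or dataset.n_points < k + 2:
        return SigmoidFit(model, 0.0, 0.0, 0.0, np.nan, np.inf, dataset.n_points,
                          k, np.inf, converged=False)
    lower, upper = _fit_box(model, medians)
    x, y = dataset.concentrations, dataset.activities
    lnx = np.log(x)
    three = model == "three_param"

    def residuals(theta):
        if three:
            y0, (yfin, hill, ln_ec50) = 0.0, theta
        else:
            y0, yfin, hill, ln_ec50 = theta
        with np.errstate(over="ignore"):
            return y0 + (yfin - y0) / (1.0 + np.exp(hill * (lnx - ln_ec50))) - y

    y0_start = 0.0 if three else float(np.clip(medians.medians[0], lower[0], upper[0]))
    yfin_start = float(np.clip(medians.max_median, lower[-3], upper[-3]))
    best = None
    for hill0 in (-0.5, -2.0, -8.0):
        for q in (25, 50, 75):
            ec0 = np.clip(np.percentile(x, q), *EC50_BOUNDS)
            start = [yfin_start, hill0, np.log(ec0)]
            if not three:
                start = [y0_start] + start
            theta0 = np.clip(np.array(start), lower, upper)
            try:
                res = least_squares(residuals, theta0, bounds=(lower, upper),
                                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if not res.success or not np.all(np.isfinite(res.x)):
                continue
            rss = float(res.cost * 2.0)
            if best is None or rss < best[0]:
                best = (rss, res.x)
    if best is None:
        return SigmoidFit(model, 0.0, 0.0, 0.0, np.nan, np.inf, dataset.n_points,
                          k, np.inf, converged=False)
    rss, theta = best
    if three:
        y0, (yfin, hill, ln_ec50) = 0.0, theta
    else:
        y0, yfin, hill, ln_ec50 = theta
    n = dataset.n_points
    crit = aicc(n, k, rss) if n > k + 1 else np.inf
    return SigmoidFit(model, float(y0), float(yfin), float(hill),
                      float(np.exp(ln_ec50)), rss, n, k, crit, converged=True)


def select_model(fit3: SigmoidFit, fit4: SigmoidFit) -> SigmoidFit:
    """Pick the converged fit with the lower AICc; ties favor fewer parameters."""
    if fit3.converged and fit4.converged:
        if abs(fit3.aicc - fit4.aicc) < 1e-9:
            return fit3
        return fit3 if fit3.aicc < fit4.aicc else fit4
    if fit3.converged:
        return fit3
    if fit4.converged:
        return fit4
    raise RuntimeError("neither sigmoid model converged; spline fallback required")


def _spline_curve(dataset: DoseResponseDataset):
    """GCV smoothing spline of activity vs log10 concentration.

    Replicates at one concentration are collapsed to their mean with
    count weights.  Returns (curve(u), rss_at_data) with flat (constant)
    extrapolation outside the observed log10-concentration range.
    """
    u = np.log10(dataset.concentrations)
    uu, inverse, counts = np.unique(u, return_inverse=True, return_counts=True)
    ymean = np.zeros_like(uu)
    np.add.at(ymean, inverse, dataset.activities)
    ymean /= counts
    try:
        spl = make_smoothing_spline(uu, ymean, w=counts.astype(float))
    except Exception:
        spl = make_smoothing_spline(uu, ymean, w=counts.astype(float), lam=1e-3)
    lo, hi = uu[0], uu[-1]

    def curve(uq):
        uq = np.asarray(uq, dtype=float)
        return spl(np.clip(uq, lo, hi))

    rss = float(np.sum((curve(u) - dataset.activities) ** 2))
    return curve, rss


def fit_spline_fallback(
    dataset: DoseResponseDataset, auc_lo: float = AUC_LO, auc_hi: float = AUC_HI
) -> CurveSummary:
    """Smoothing-spline curve for datasets the sigmoid cannot describe.

    Requires >= 4 distinct concentrations; otherwise the pair is marked
    unfit with no AUC.
    """
    if dataset.n_distinct < 4:
        return CurveSummary(dataset.compound_id, dataset.cell_line, "unfit",
                            auc=None, ec50=None, selected_model=None,
                            note="fewer than 4 distinct concentrations")
    curve, rss = _spline_curve(dataset)
    auc = compute_auc(curve, auc_lo, auc_hi, on_log10_scale=True)
    return CurveSummary(dataset.compound_id, dataset.cell_line, "spline",
                        auc=auc, ec50=None, selected_model=None, rss=rss)


def compute_auc(
    curve,
    lo: float = AUC_LO,
    hi: float = AUC_HI,
    n_grid: int = AUC_GRID,
    on_log10_scale: bool = False,
) -> float:
    """Trapezoid AUC of a curve over log10 concentration in [lo, hi] M.

    ``curve`` maps molar concentration (or log10 M when
    ``on_log10_scale``) to % activity; the result is in %*decade units.
    """
    if lo >= hi:
        raise ValueError("AUC bounds must satisfy lo < hi")
    u = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    y = curve(u) if on_log10_scale else curve(10.0**u)
    return float(np.trapezoid(y, u))


def ec50_from_fit(fit: SigmoidFit) -> float | None:
    """EC50 of a converged sigmoid fit: the inflection concentration at which
    the response is halfway between y0 and yFin (even if yFin itself is
    below a 50% absolute-effect threshold)."""
    return fit.ec50 if fit.converged else None


def summarize_curve(
    dataset: DoseResponseDataset, auc_lo: float = AUC_LO, auc_hi: float = AUC_HI
) -> CurveSummary:
    """Full single-pair pipeline: 3p/4p fits, AICc selection, spline guard, AUC."""
    if dataset.n_distinct < 2:
        return CurveSummary(dataset.compound_id, dataset.cell_line, "unfit",
                            auc=None, ec50=None, selected_model=None,
                            note="fewer than 2 distinct concentrations")
    medians = concentration_medians(dataset)
    fit3 = fit_sigmoid(dataset, medians, "three_param")
    fit4 = fit_sigmoid(dataset, medians, "four_param")
    spline_rss = None
    if dataset.n_distinct >= 4:
        try:
            _, spline_rss = _spline_curve(dataset)
        except Exception:
            spline_rss = None
    try:
        fit = select_model(fit3, fit4)
    except RuntimeError:
        return fit_spline_fallback(dataset, auc_lo, auc_hi)
    # pathological boundary fits: spline does an order of magnitude better
    # and the sigmoid misfit is non-trivial
    if (spline_rss is not None and spline_rss > 0
            and fit.rss > SPLINE_GUARD_FACTOR * spline_rss
            and fit.rss / fit.n > GUARD_MSR_FLOOR):
        return fit_spline_fallback(dataset, auc_lo, auc_hi)
    auc = compute_auc(fit, auc_lo, auc_hi)
    return CurveSummary(dataset.compound_id, dataset.cell_line, "sigmoid",
                        auc=auc, ec50=ec50_from_fit(fit), selected_model=fit.model,
                        fit=fit, rss=fit.rss, aicc=fit.aicc)


def fit_activity_table(
    activities: pd.DataFrame, auc_lo: float = AUC_LO, auc_hi: float = AUC_HI
) -> pd.DataFrame:
    """Fit every (compound, cell line) pair of a long activity table.

    Input columns: compound_id, cell_line, concentration_M, activity_pct
    (replicate_id optional; replicate rows are pooled).  Returns the fits
    table (one row per pair) used by the profiling stage.
    """
    rows = []
    for (cid, line), grp in activities.groupby(["compound_id", "cell_line"], sort=True):
        # sort points so results are independent of replicate file order
        grp = grp.sort_values(["concentration_M", "activity_pct"], kind="mergesort")
        ds = DoseResponseDataset(str(cid), str(line),
                                 grp["concentration_M"].to_numpy(),
                                 grp["activity_pct"].to_numpy())
        s = summarize_curve(ds, auc_lo, auc_hi)
        f = s.fit
        rows.append(dict(
            compound_id=s.compound_id, cell_line=s.cell_line, fit_kind=s.fit_kind,
            model=s.selected_model, y0=f.y0 if f else np.nan,
            yFin=f.yfin if f else np.nan, hill=f.hill if f else np.nan,
            ec50_M=s.ec50 if s.ec50 is not None else np.nan,
            rss=s.rss if s.rss is not None else np.nan,
            aicc=s.aicc if s.aicc is not None else np.nan,
            auc=s.auc if s.auc is not None else np.nan,
            converged=f.converged if f else False,
        ))
    return pd.DataFrame(rows, columns=[
        "compound_id", "cell_line", "fit_kind", "model", "y0", "yFin", "hill",
        "ec50_M", "rss", "aicc", "auc", "converged"])
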