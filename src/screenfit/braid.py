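"""Two-drug response surfaces with a kappa interaction parameter.

The combined action of two drugs is modeled by a Hill-type response
surface over the dose plane.  With sigma = sqrt(nA * nB) and scaled
doses DA = (a / EC50A)^(nA/sigma), DB = (b / EC50B)^(nB/sigma), the
combined dose is

    D = DA + DB + kappa * sqrt(DA * DB)

and the effect is E0 + (Ef - E0) * D^sigma / (1 + D^sigma).  Setting one
dose to zero recovers that drug's single-agent Hill curve exactly, and
kappa = 0 with equal slopes reduces to Loewe additivity (straight-line
isoboles).  kappa > 0 means the drugs potentiate each other (synergy),
kappa < 0 antagonism; kappa <= -2 would allow a negative combined dose
and is excluded.

Efficacy of a combination within a capped concentration window is
summarized by the index of achievable efficacy (IAE): the fraction of a
log-uniform dose window achieving a threshold effect (default 50%
viability reduction at doses <= 1 uM), mapped through
iae = sqrt(1 / (1 - fraction)) so 1.0 means the threshold is never
reached and larger values mean a larger achieving region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "BraidParameters",
    "BraidFit",
    "IAEResult",
    "braid_effect",
    "fit_braid",
    "classify_interaction",
    "isobole",
    "compute_iae",
    "grid_from_table",
    "CombinationGrid",
]

KAPPA_MIN = -2.0  # exclusive algebraic limit
KAPPA_MAX = 100.0
IAE_CAP = 1e3
IAE_GRID = 201
IAE_DECADES = 4  # window spans [cmax * 10^-4, cmax]


@dataclass
class BraidParameters:
    """Response-surface parameters; doses in molar, effects in % activity."""

    e0: float
    ef: float
    ec50_a: float
    ec50_b: float
    n_a: float
    n_b: float
    kappa: float

    def __post_init__(self) -> None:
        if self.ef <= self.e0:
            raise ValueError("Ef must exceed E0")
        if self.n_a <= 0 or self.n_b <= 0:
            raise ValueError("Hill slopes must be positive")
        if self.ec50_a <= 0 or self.ec50_b <= 0:
            raise ValueError("EC50 values must be positive")
        if self.kappa <= KAPPA_MIN:
            raise ValueError("kappa must exceed -2 (combined-dose positivity)")

    def swapped(self) -> "BraidParameters":
        return BraidParameters(self.e0, self.ef, self.ec50_b, self.ec50_a,
                               self.n_b, self.n_a, self.kappa)


@dataclass
class CombinationGrid:
    """Viability-reduction measurements over a 2-D dose grid (zero doses included)."""

    drug_a: str
    drug_b: str
    doses_a: np.ndarray  # ascending, includes 0
    doses_b: np.ndarray
    effects: np.ndarray  # shape (len(doses_a), len(doses_b)), % activity

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        for d in (self.doses_a, self.doses_b):
            if np.any(np.diff(d) <= 0):
                raise ValueError("dose lists must be strictly ascending")
        if self.effects.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("effect matrix shape does not match dose lists")


@dataclass
class BraidFit:
    params: BraidParameters
    rss: float
    n_cells: int
    converged: bool
    kappa_ci: tuple[float, float] | None = None


@dataclass
class IAEResult:
    threshold_effect: float
    cmax: float
    iae: float
    achieving_fraction: float


def braid_effect(params: BraidParameters, dose_a, dose_b) -> np.ndarray:
    """Evaluate the response surface at dose pairs (broadcasting, doses >= 0)."""
    a = np.asarray(dose_a, dtype=float)
    b = np.asarray(dose_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("doses must be non-negative")
    sigma = np.sqrt(params.n_a * params.n_b)
    da = (a / params.ec50_a) ** (params.n_a / sigma)
    db = (b / params.ec50_b) ** (params.n_b / sigma)
    d = da + db + params.kappa * np.sqrt(da * db)
    with np.errstate(over="ignore"):
        ds = d**sigma
        frac = np.where(np.isinf(ds), 1.0, ds / (1.0 + ds))
    out = params.e0 + (params.ef - params.e0) * frac
    return out if out.ndim else float(out)


def _hill_edge_fit(doses: np.ndarray, effects: np.ndarray) -> tuple[float, float, float, float]:
    """Single-agent Hill fit (e0, ef, ec50, n) on one grid edge, used for starts."""
    pos = doses > 0
    e0_guess = float(effects[~pos].mean()) if (~pos).any() else float(effects.min())
    ef_guess = float(effects.max())
    if ef_guess <= e0_guess:
        ef_guess = e0_guess + 1.0
    logd = np.log(doses[pos])

    def resid(theta):
        e0, ef, ln_ec, n = theta
        h = 1.0 / (1.0 + np.exp(-n * (logd - ln_ec)))
        r = e0 + (ef - e0) * h - effects[pos]
        if (~pos).any():
            r = np.concatenate([r, np.full((~pos).sum(), e0) - effects[~pos]])
        return r

    ln_mid = float(np.median(logd))
    lo = [-50.0, 5.0, np.log(1e-12), 0.05]
    hi = [60.0, 200.0, np.log(1e-3), 10.0]
    best = None
    for n0 in (0.7, 1.5, 3.0):
        x0 = np.clip([e0_guess, ef_guess, ln_mid, n0], lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return e0_guess, ef_guess, float(np.exp(ln_mid)), 1.0
    e0, ef, ln_ec, n = best.x
    return float(e0), float(ef), float(np.exp(ln_ec)), float(n)


def fit_braid(grid: CombinationGrid, bootstrap: int = 0, seed: int | None = None) -> BraidFit:
    """Bounded least-squares fit of the response surface to a dose grid.

    Requires both single-agent edges (zero-dose row and column) and at
    least 9 interior cells.  Starts are built from independent Hill fits
    of the two edges crossed with kappa in {-1, 0, 2}.
    """
    if grid.doses_a[0] != 0 or grid.doses_b[0] != 0:
        raise ValueError("grid must include zero-dose single-agent edges")
    n_interior = (grid.doses_a.size - 1) * (grid.doses_b.size - 1)
    if n_interior < 9:
        raise ValueError("grid needs >= 9 interior (both-drug) cells")
    a_mesh, b_mesh = np.meshgrid(grid.doses_a, grid.doses_b, indexing="ij")
    a_flat, b_flat, y = a_mesh.ravel(), b_mesh.ravel(), grid.effects.ravel()

    e0a, efa, ec_a, n_a0 = _hill_edge_fit(grid.doses_a, grid.effects[:, 0])
    e0b, efb, ec_b, n_b0 = _hill_edge_fit(grid.doses_b, grid.effects[0, :])
    e0_start = 0.5 * (e0a + e0b)
    ef_start = max(efa, efb, float(y.max()))

    lo = np.array([-50.0, 5.0, np.log(1e-12), np.log(1e-12), 0.05, 0.05,
                   KAPPA_MIN + 1e-6])
    hi = np.array([60.0, 200.0, np.log(1e-3), np.log(1e-3), 10.0, 10.0, KAPPA_MAX])

    def resid(theta):
        e0, ef, ln_a, ln_b, na, nb, kappa = theta
        p = BraidParameters(e0, max(ef, e0 + 1e-6), np.exp(ln_a), np.exp(ln_b),
                            na, nb, kappa)
        return braid_effect(p, a_flat, b_flat) - y

    best = None
    for kappa0 in (-1.0, 0.0, 2.0):
        x0 = np.clip(
            [e0_start, max(ef_start, e0_start + 10.0), np.log(ec_a), np.log(ec_b),
             n_a0, n_b0, kappa0], lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12,
                                ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        dummy = BraidParameters(0.0, 100.0, ec_a, ec_b, max(n_a0, 0.1),
                                max(n_b0, 0.1), 0.0)
        return BraidFit(dummy, np.inf, y.size, converged=False)
    e0, ef, ln_a, ln_b, na, nb, kappa = best.x
    params = BraidParameters(float(e0), float(max(ef, e0 + 1e-6)),
                             float(np.exp(ln_a)), float(np.exp(ln_b)),
                             float(na), float(nb), float(kappa))
    fit = BraidFit(params, float(2.0 * best.cost), y.size, converged=True)
    if bootstrap > 0:
        fit.kappa_ci = _bootstrap_kappa(grid, bootstrap, seed)
    return fit


def _bootstrap_kappa(grid: CombinationGrid, n_boot: int, seed: int | None) -> tuple[float, float]:
    """Percentile CI for kappa from case-resampled grid cells."""
    rng = np.random.default_rng(seed)
    a_mesh, b_mesh = np.meshgrid(grid.doses_a, grid.doses_b, indexing="ij")
    fit0 = fit_braid(grid)
    kappas = []
    n = grid.effects.size
    flat = grid.effects.ravel()
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = flat.copy()
        # keep grid geometry; resample residual structure by cell reassignment
        pred = braid_effect(fit0.params, a_mesh, b_mesh).ravel()
        resampled = pred + (flat - pred)[idx]
        g = CombinationGrid(grid.drug_a, grid.drug_b, grid.doses_a, grid.doses_b,
                            resampled.reshape(grid.effects.shape))
        f = fit_braid(g)
        if f.converged:
            kappas.append(f.params.kappa)
    if not kappas:
        return (np.nan, np.nan)
    return (float(np.percentile(kappas, 2.5)), float(np.percentile(kappas, 97.5)))


def classify_interaction(fit: BraidFit, tol: float = 0.1) -> str:
    """Sign of kappa with a dead band: synergistic (> tol), antagonistic
    (< -tol), else additive."""
    if not fit.converged:
        raise ValueError("cannot classify a non-converged fit")
    k = fit.params.kappa
    if k > tol:
        return "synergistic"
    if k < -tol:
        return "antagonistic"
    return "additive"


def isobole(
    params: BraidParameters,
    effect_level: float,
    dose_max_a: float | None = None,
    dose_max_b: float | None = None,
    n_points: int = 101,
) -> np.ndarray:
    """Trace the iso-effect contour {(dA, dB): effect = level} as a polyline.

    Returns an (m, 2) array of dose pairs with dB non-increasing in dA.
    Levels at or above Ef are unattainable and yield an empty array.
    """
    if effect_level >= params.ef or effect_level <= params.e0:
        return np.empty((0, 2))
    # single-agent doses reaching the level bound the contour:
    # D^sigma = frac/(1-frac) =: t, and alone D^sigma = (dose/EC50)^n
    sigma = np.sqrt(params.n_a * params.n_b)
    frac = (effect_level - params.e0) / (params.ef - params.e0)
    t = frac / (1.0 - frac)
    da_solo = params.ec50_a * t ** (1.0 / params.n_a)
    db_solo = params.ec50_b * t ** (1.0 / params.n_b)
    amax = dose_max_a if dose_max_a is not None else da_solo
    amax = min(amax, da_solo)
    pts = []
    for a in np.linspace(0.0, amax, n_points):

        def g(b):
            return float(braid_effect(params, a, b)) - effect_level

        hi_b = db_solo * 1.0000001
        if g(hi_b) < 0:  # kappa < 0 can push the needed dB above the solo dose
            hi_b = db_solo
            while g(hi_b) < 0 and hi_b < params.ec50_b * 1e6:
                hi_b *= 2.0
            if g(hi_b) < 0:
                continue
        if g(0.0) >= 0:
            b = 0.0
        else:
            b = brentq(g, 0.0, hi_b, xtol=1e-18, rtol=1e-14)
        pts.append((a, b))
        if b == 0.0:
            break
    return np.asarray(pts)


def compute_iae(
    params: BraidParameters, threshold: float = 50.0, cmax: float = 1e-6
) -> IAEResult:
    """Index of achievable efficacy on a log-uniform dose window.

    The surface is evaluated on a 201x201 log10-uniform grid over
    [cmax*1e-4, cmax]^2; with p the fraction of cells reaching the
    threshold effect, iae = sqrt(1/(1-p)), equal to 1.0 when nothing
    achieves the threshold and capped at 1e3 when everything does.
    """
    lo = cmax * 10.0 ** (-IAE_DECADES)
    grid = np.logspace(np.log10(lo), np.log10(cmax), IAE_GRID)
    a, b = np.meshgrid(grid, grid, indexing="ij")
    eff = braid_effect(params, a, b)
    frac = float(np.mean(eff >= threshold))
    if frac >= 1.0:
        iae = IAE_CAP
    else:
        iae = min(float(np.sqrt(1.0 / (1.0 - frac))), IAE_CAP)
    return IAEResult(threshold, cmax, iae, frac)


def grid_from_table(table: pd.DataFrame, drug_a: str = "A", drug_b: str = "B") -> CombinationGrid:
    """Build a CombinationGrid from a long table
    (dose_a_M, dose_b_M, activity_pct[, replicate_id]); replicates are
    averaged per cell."""
    cell = table.groupby(["dose_a_M", "dose_b_M"])["activity_pct"].mean().unstack()
    doses_a = cell.index.to_numpy(dtype=float)
    doses_b = cell.columns.to_numpy(dtype=float)
    if cell.isna().any().any():
        raise ValueError("combination table does not cover a complete grid")
    return CombinationGrid(drug_a, drug_b, doses_a, doses_b, cell.to_numpy())
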