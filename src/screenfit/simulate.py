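"""Ground-truth screen simulation.

Every pipeline stage is exercised against synthetic screens whose truth
is known: each (drug, line) pair gets a true log-logistic activity curve,
wells get raw RLU values derived from that curve and the plate's control
window, and multiplicative log-normal noise emulates luminescence
measurement error (scale-proportional, default 5% CV).  Combination
grids are generated from a kappa-parameterized response surface with
additive Gaussian noise.  All generators are reproducible given a seed.

A simulated plate carries one cell line, up to 32 drugs' 10-point
dilution series, and 16 negative + 16 positive control wells (384-well
geometry); triplicates are three plates with independent noise.  The
compound-well signal is placed on the log2 scale between the control
means so that, at zero noise, percent-activity normalization recovers
the true curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .braid import BraidParameters, CombinationGrid, braid_effect
from .doseresponse import loglogistic
from .plate import (
    COMPOUND,
    EMPTY,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    DilutionSeries,
    PlateRead,
    WellAnnotation,
    build_dilution_series,
)

__all__ = [
    "ScreenTruth",
    "ComboTruth",
    "CurveTruth",
    "default_layout",
    "simulate_plate",
    "simulate_screen",
    "simulate_combination_grid",
    "sample_truth",
]

N_ROWS, N_COLS = 16, 24  # 384-well plate
N_CONTROL = 16  # wells per control group
DRUGS_PER_PLATE = 32
DEFAULT_TOP_CONC = 35e-6  # M, mean top concentration of the emulated screens
DEFAULT_NEG_MEAN = 1e6  # RLU, vehicle-control signal
DEFAULT_POS_MEAN = 1e5  # RLU, cytotoxic-control signal
DEFAULT_CV = 0.05  # multiplicative log-normal noise


@dataclass
class CurveTruth:
    """True activity curve for one (drug, line) pair."""

    compound_id: str
    cell_line: str
    y0: float
    yfin: float
    hill: float
    ec50: float

    def activity(self, conc) -> np.ndarray:
        return loglogistic(conc, self.y0, self.yfin, self.hill, self.ec50)


@dataclass
class ScreenTruth:
    """Ground truth for a whole screen."""

    curves: dict[tuple[str, str], CurveTruth]
    neg_mean: float = DEFAULT_NEG_MEAN
    pos_mean: float = DEFAULT_POS_MEAN
    cv: float = DEFAULT_CV
    seed: int | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(compound_id=c.compound_id, cell_line=c.cell_line, y0=c.y0,
                  yFin=c.yfin, hill=c.hill, ec50_M=c.ec50)
             for c in self.curves.values()]
        )


@dataclass
class ComboTruth:
    """Ground truth for one combination grid."""

    params: BraidParameters
    doses_a: np.ndarray
    doses_b: np.ndarray
    noise_sd: float = 3.0  # additive, % activity units
    seed: int | None = None

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ValueError("combination truth must include zero-dose edges")


def default_layout(
    plate_id: str,
    compound_ids: list[str],
    series: DilutionSeries,
) -> dict[tuple[int, int], WellAnnotation]:
    """384-well layout: 16 neg + 16 pos controls in the first two columns,
    then one dilution series per drug filled row-major."""
    if len(compound_ids) > DRUGS_PER_PLATE:
        raise ValueError(f"at most {DRUGS_PER_PLATE} drugs fit on one plate")
    wells: dict[tuple[int, int], WellAnnotation] = {}
    for r in range(1, N_ROWS + 1):
        wells[(r, 1)] = WellAnnotation(plate_id, r, 1, NEGATIVE_CONTROL)
        wells[(r, 2)] = WellAnnotation(plate_id, r, 2, POSITIVE_CONTROL)
    slots = [(r, c) for r in range(1, N_ROWS + 1) for c in range(3, N_COLS + 1)]
    i = 0
    for cid in compound_ids:
        for conc in series.concentrations:
            r, c = slots[i]
            wells[(r, c)] = WellAnnotation(plate_id, r, c, COMPOUND, cid, conc)
            i += 1
    for r, c in slots[i:]:
        wells[(r, c)] = WellAnnotation(plate_id, r, c, EMPTY)
    return wells


def simulate_plate(
    truth: ScreenTruth,
    layout: dict[tuple[int, int], WellAnnotation],
    cell_line: str,
    seed: int | None = None,
    exposure_days: int = 7,
) -> PlateRead:
    """Simulate raw RLU for one plate.

    The compound-well signal interpolates between the control means on
    the log2 scale according to the true activity, then log-normal noise
    with the configured CV multiplies every well.  Zero CV gives an exact
    normalization round trip.
    """
    rng = np.random.default_rng(seed)
    log_window = np.log2(truth.neg_mean) - np.log2(truth.pos_mean)
    sigma = np.sqrt(np.log1p(truth.cv**2))  # lognormal sd from CV
    values: dict[tuple[int, int], float] = {}
    for well, ann in sorted(layout.items()):
        if ann.role == NEGATIVE_CONTROL:
            mean = truth.neg_mean
        elif ann.role == POSITIVE_CONTROL:
            mean = truth.pos_mean
        elif ann.role == COMPOUND:
            key = (ann.compound_id, cell_line)
            if key not in truth.curves:
                raise ValueError(f"no truth curve for {key}")
            act = float(truth.curves[key].activity(ann.concentration))
            mean = 2.0 ** (np.log2(truth.neg_mean) - act / 100.0 * log_window)
        else:
            values[well] = 1.0  # inert filler; empty wells are never normalized
            continue
        noise = np.exp(rng.normal(0.0, sigma)) if truth.cv > 0 else 1.0
        values[well] = float(mean * noise)
    return PlateRead(layout[next(iter(layout))].plate_id, cell_line, values,
                     exposure_days, scale="raw")


def sample_truth(
    compound_ids: list[str],
    cell_lines: list[str],
    rng: np.random.Generator,
    baseline_pairs: set[tuple[str, str]] | None = None,
    outlier_lines: dict[str, float] | None = None,
) -> ScreenTruth:
    """Draw per-(drug, line) curve truths.

    log10 EC50 ~ U[-9, -5.5], hill ~ U[-4, -0.5], yFin ~ U[30, 110],
    y0 = 0 except for designated baseline-shift pairs (y0 = 20).
    Baseline-shift pairs draw log10 EC50 from U[-7.5, -6] instead, so the
    zero-dose plateau lies inside the tested dilution window: a baseline
    is only identifiable when doses below the transition are observed.
    ``outlier_lines`` maps a line id to a uniform activity boost (%)
    applied to every drug, emulating pan-sensitivity.
    """
    baseline_pairs = baseline_pairs or set()
    outlier_lines = outlier_lines or {}
    curves: dict[tuple[str, str], CurveTruth] = {}
    for cid in compound_ids:
        for line in cell_lines:
            shifted = (cid, line) in baseline_pairs
            if shifted:
                ec50 = 10.0 ** rng.uniform(-7.5, -6.0)
            else:
                ec50 = 10.0 ** rng.uniform(-9.0, -5.5)
            hill = rng.uniform(-4.0, -0.5)
            yfin = rng.uniform(30.0, 110.0)
            y0 = 20.0 if shifted else 0.0
            boost = outlier_lines.get(line, 0.0)
            curves[(cid, line)] = CurveTruth(cid, line, y0 + boost, yfin + boost,
                                             hill, ec50)
    return ScreenTruth(curves)


def simulate_screen(
    n_drugs: int,
    n_lines: int,
    dilution: DilutionSeries | None = None,
    replicates: int = 3,
    seed: int | None = None,
    cv: float = DEFAULT_CV,
    baseline_fraction: float = 0.0,
    outlier_line_boost: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ScreenTruth]:
    """Simulate a full factorial screen.

    Returns (layout frame, reads frame, truth).  Defaults emulate the
    canonical assay: 10-point threefold dilutions from 35 uM, tested in
    triplicate with 7-day exposure.  ``baseline_fraction`` designates a
    random fraction of pairs with a 20% zero-dose baseline (for model
    selection checks); ``outlier_line_boost`` adds a pan-sensitive line
    boosted by that many % on every drug.
    """
    rng = np.random.default_rng(seed)
    if dilution is None:
        dilution = build_dilution_series(DEFAULT_TOP_CONC, 10, 3.0)
    compound_ids = [f"DRUG{i:03d}" for i in range(1, n_drugs + 1)]
    cell_lines = [f"LINE{i:02d}" for i in range(1, n_lines + 1)]
    baseline_pairs: set[tuple[str, str]] = set()
    if baseline_fraction > 0:
        for cid in compound_ids:
            for line in cell_lines:
                if rng.random() < baseline_fraction:
                    baseline_pairs.add((cid, line))
    outliers = {}
    if outlier_line_boost is not None and cell_lines:
        outliers[cell_lines[-1]] = outlier_line_boost
    truth = sample_truth(compound_ids, cell_lines, rng, baseline_pairs, outliers)
    truth.cv = cv
    truth.seed = seed

    layout_rows, read_rows = [], []
    n_batches = int(np.ceil(n_drugs / DRUGS_PER_PLATE)) if n_drugs else 0
    for line in cell_lines:
        for batch in range(n_batches):
            drugs = compound_ids[batch * DRUGS_PER_PLATE:(batch + 1) * DRUGS_PER_PLATE]
            for rep in range(1, replicates + 1):
                plate_id = f"{line}-B{batch + 1}-R{rep}"
                layout = default_layout(plate_id, drugs, dilution)
                plate = simulate_plate(truth, layout, line,
                                       seed=int(rng.integers(0, 2**31)))
                for (r, c), ann in sorted(layout.items()):
                    layout_rows.append(dict(
                        plate_id=plate_id, row=r, col=c, role=ann.role,
                        compound_id=ann.compound_id or "",
                        concentration_M=ann.concentration))
                for (r, c), v in sorted(plate.values.items()):
                    if layout[(r, c)].role == EMPTY:
                        continue
                    read_rows.append(dict(plate_id=plate_id, cell_line=line,
                                          row=r, col=c, rlu=v))
    layout_df = pd.DataFrame(layout_rows, columns=["plate_id", "row", "col", "role",
                                                   "compound_id", "concentration_M"])
    layout_df = layout_df[layout_df["role"] != EMPTY].reset_index(drop=True)
    reads_df = pd.DataFrame(read_rows, columns=["plate_id", "cell_line", "row",
                                                "col", "rlu"])
    return layout_df, reads_df, truth


def simulate_combination_grid(truth: ComboTruth, seed: int | None = None) -> CombinationGrid:
    """Generate a noisy combination grid from a true response surface."""
    rng = np.random.default_rng(seed if seed is not None else truth.seed)
    a, b = np.meshgrid(truth.doses_a, truth.doses_b, indexing="ij")
    eff = braid_effect(truth.params, a, b)
    if truth.noise_sd > 0:
        eff = eff + rng.normal(0.0, truth.noise_sd, size=eff.shape)
    return CombinationGrid("A", "B", truth.doses_a, truth.doses_b, eff)
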