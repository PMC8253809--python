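"""Plate-level data structures, normalization, and quality control.

A screening plate carries raw luminescence (RLU) per well.  Wells are
annotated by a layout as negative controls (vehicle/DMSO), positive
controls (a cytotoxic reference such as staurosporine), compound wells
(with a compound id and molar concentration), or empty.  Raw RLU are
log2-transformed (single-agent screens) and normalized against the
control wells to percent activity:

    activity = 100 * (mean(neg) - value) / (mean(neg) - mean(pos))

so 0% means the well looks like the vehicle control and 100% means it
looks like the fully cytotoxic control.  Plate quality is summarized by
the Z-prime factor

    z' = 1 - 3*(sd(neg) + sd(pos)) / |mean(neg) - mean(pos)|

computed on the same scale used for normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "WellAnnotation",
    "PlateRead",
    "NormalizedPlate",
    "QCRecord",
    "DilutionSeries",
    "build_dilution_series",
    "transform_plate",
    "percent_activity",
    "zprime",
    "qc_filter",
    "read_layout",
    "read_plate_reads",
    "plates_from_frames",
    "normalize_screen",
]

# canonical well roles
NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
COMPOUND = "compound"
EMPTY = "empty"

WellRole = str
ROLES = frozenset({NEGATIVE_CONTROL, POSITIVE_CONTROL, COMPOUND, EMPTY})


@dataclass(frozen=True)
class WellAnnotation:
    """Role annotation for one well of one plate.

    ``row`` and ``col`` are 1-based.  Compound wells must carry a
    ``compound_id`` and a positive molar ``concentration``; control and
    empty wells must carry neither.
    """

    plate_id: str
    row: int
    col: int
    role: WellRole
    compound_id: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == COMPOUND:
            if self.compound_id is None or self.concentration is None:
                raise ValueError(
                    f"compound well {self.plate_id}:{self.row},{self.col} "
                    "requires compound_id and concentration"
                )
            if self.concentration <= 0:
                raise ValueError("compound concentration must be > 0 M")
        elif self.compound_id is not None or self.concentration is not None:
            raise ValueError(
                f"{self.role} well {self.plate_id}:{self.row},{self.col} "
                "must not carry compound_id/concentration"
            )


@dataclass
class PlateRead:
    """Raw (or transformed) per-well values for one plate of one cell line."""

    plate_id: str
    cell_line: str
    values: dict[tuple[int, int], float]
    exposure_days: int = 7
    scale: str = "raw"  # raw | log2 | linear

    def __post_init__(self) -> None:
        if self.scale == "raw" and any(v <= 0 for v in self.values.values()):
            raise ValueError(f"plate {self.plate_id}: raw RLU must be positive")


@dataclass
class NormalizedPlate:
    """Percent activity per compound well; values are not clamped to [0, 100]."""

    plate_id: str
    cell_line: str
    activities: dict[tuple[int, int], float]
    scale_used: str


@dataclass
class QCRecord:
    """Z-prime quality record for one plate; ``error`` set when z' is undefined."""

    plate_id: str
    zprime: float
    n_neg: int
    n_pos: int
    passed: bool
    error: str | None = None


@dataclass
class DilutionSeries:
    """Descending geometric concentration series (molar)."""

    top_concentration: float
    n_points: int
    fold: float
    concentrations: list[float] = field(default_factory=list)


def build_dilution_series(
    top_concentration: float, n_points: int, fold: float = 3.0
) -> DilutionSeries:
    """Build an ``n_points``-point serial dilution from ``top_concentration``.

    Point *i* is ``top / fold**i``, so a 10-point threefold series spans a
    3**9 = 19683-fold concentration range.  ``fold`` is ignored for a
    single-point series.
    """
    if top_concentration <= 0:
        raise ValueError("top concentration must be > 0 M")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points > 1 and fold <= 1:
        raise ValueError("dilution fold must be > 1")
    concs = [top_concentration / fold**i for i in range(n_points)]
    return DilutionSeries(top_concentration, n_points, fold, concs)


def transform_plate(plate: PlateRead, scale: str = "log2") -> PlateRead:
    """Return the plate on the requested scale (value-wise log2, or identity)."""
    if scale not in ("log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if plate.scale != "raw":
        raise ValueError(f"plate {plate.plate_id} already on scale {plate.scale!r}")
    if scale == "linear":
        values = dict(plate.values)
    else:
        if any(v <= 0 for v in plate.values.values()):
            raise ValueError(
                f"plate {plate.plate_id}: log2 transform requires positive RLU"
            )
        values = {w: math.log2(v) for w, v in plate.values.items()}
    return PlateRead(plate.plate_id, plate.cell_line, values, plate.exposure_days, scale)


def _control_values(
    plate: PlateRead, layout: dict[tuple[int, int], WellAnnotation]
) -> tuple[np.ndarray, np.ndarray]:
    neg, pos = [], []
    for well, value in plate.values.items():
        ann = layout.get(well)
        if ann is None:
            raise ValueError(
                f"plate {plate.plate_id}: well {well} read but absent from layout"
            )
        if ann.role == NEGATIVE_CONTROL:
            neg.append(value)
        elif ann.role == POSITIVE_CONTROL:
            pos.append(value)
    return np.asarray(neg, dtype=float), np.asarray(pos, dtype=float)


def percent_activity(
    plate: PlateRead, layout: dict[tuple[int, int], WellAnnotation]
) -> NormalizedPlate:
    """Normalize compound wells to percent activity against plate controls.

    Computed on the plate's current (transformed) scale; 0% = negative
    control level, 100% = positive control level.  Raises on degenerate
    controls (equal means) because the normalization is then undefined.
    """
    if plate.scale == "raw":
        raise ValueError("transform_plate must be applied before normalization")
    neg, pos = _control_values(plate, layout)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError(
            f"plate {plate.plate_id}: need >= 2 wells per control group "
            f"(got {len(neg)} neg, {len(pos)} pos)"
        )
    mean_neg, mean_pos = neg.mean(), pos.mean()
    if mean_neg == mean_pos:
        raise ValueError(
            f"plate {plate.plate_id}: control means coincide, normalization undefined"
        )
    activities = {
        well: 100.0 * (mean_neg - value) / (mean_neg - mean_pos)
        for well, value in plate.values.items()
        if layout[well].role == COMPOUND
    }
    return NormalizedPlate(plate.plate_id, plate.cell_line, activities, plate.scale)


def zprime(
    plate: PlateRead,
    layout: dict[tuple[int, int], WellAnnotation],
    threshold: float = 0.5,
) -> QCRecord:
    """Z-prime factor of the plate's control separation (sample sd, n-1).

    z' = 1 - 3*(sd(neg) + sd(pos)) / |mean(neg) - mean(pos)|; at most 1,
    reached only when both control groups have zero spread.
    """
    neg, pos = _control_values(plate, layout)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError(
            f"plate {plate.plate_id}: need >= 2 wells per control group for z'"
        )
    sep = abs(neg.mean() - pos.mean())
    if sep == 0:
        return QCRecord(plate.plate_id, float("-inf"), len(neg), len(pos),
                        passed=False, error="control means coincide")
    z = 1.0 - 3.0 * (neg.std(ddof=1) + pos.std(ddof=1)) / sep
    return QCRecord(plate.plate_id, z, len(neg), len(pos), passed=z >= threshold)


def qc_filter(
    records: list[QCRecord], threshold: float = 0.5
) -> tuple[list[str], list[str]]:
    """Partition plate ids into (passed, failed) by z' >= threshold."""
    if threshold >= 1:
        raise ValueError("qc threshold must be < 1 (z' never exceeds 1)")
    passed = [r.plate_id for r in records if r.error is None and r.zprime >= threshold]
    failed = [r.plate_id for r in records if r.error is not None or r.zprime < threshold]
    return passed, failed


# ---------------------------------------------------------------------------
# I/O: layouts and reads travel as delimited text
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ["plate_id", "row", "col", "role", "compound_id", "concentration_M"]
READS_COLUMNS = ["plate_id", "cell_line", "row", "col", "rlu"]


def read_layout(path) -> pd.DataFrame:
    """Read a layout CSV (plate_id,row,col,role,compound_id,concentration_M)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "compound_id": str})
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    return df


def read_plate_reads(path) -> pd.DataFrame:
    """Read a plate-reads CSV (plate_id,cell_line,row,col,rlu)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "cell_line": str})
    missing = set(READS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads file missing columns: {sorted(missing)}")
    return df


def layout_index(layout: pd.DataFrame) -> dict[str, dict[tuple[int, int], WellAnnotation]]:
    """Group a layout frame into per-plate well->annotation maps."""
    plates: dict[str, dict[tuple[int, int], WellAnnotation]] = {}
    for rec in layout.itertuples(index=False):
        well = (int(rec.row), int(rec.col))
        cid = rec.compound_id if isinstance(rec.compound_id, str) and rec.compound_id else None
        conc = None if pd.isna(rec.concentration_M) else float(rec.concentration_M)
        ann = WellAnnotation(str(rec.plate_id), *well, rec.role, cid, conc)
        wells = plates.setdefault(ann.plate_id, {})
        if well in wells:
            raise ValueError(f"duplicate layout entry for {ann.plate_id}:{well}")
        wells[well] = ann
    return plates


def plates_from_frames(
    reads: pd.DataFrame, exposure_days: int = 7
) -> list[PlateRead]:
    """Assemble PlateRead objects from a long-format reads frame."""
    plates = []
    for (plate_id, cell_line), grp in reads.groupby(["plate_id", "cell_line"], sort=True):
        values = {
            (int(r.row), int(r.col)): float(r.rlu) for r in grp.itertuples(index=False)
        }
        if len(values) != len(grp):
            raise ValueError(f"duplicate well reads on plate {plate_id}")
        plates.append(PlateRead(str(plate_id), str(cell_line), values, exposure_days))
    return plates


def normalize_screen(
    layout: pd.DataFrame,
    reads: pd.DataFrame,
    scale: str = "log2",
    qc_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run transform -> z' QC -> percent-activity over a whole screen.

    Returns ``(activities, qc)``: a long activity table
    (compound_id, cell_line, concentration_M, activity_pct, replicate_id)
    with failed-QC plates excluded, and the per-plate QC report.
    """
    layouts = layout_index(layout)
    plates = plates_from_frames(reads)
    qc_rows, act_rows = [], []
    records: dict[str, QCRecord] = {}
    transformed: dict[str, tuple[PlateRead, dict]] = {}
    for plate in plates:
        if plate.plate_id not in layouts:
            raise ValueError(f"plate {plate.plate_id} has reads but no layout")
        wells = layouts[plate.plate_id]
        tp = transform_plate(plate, scale)
        rec = zprime(tp, wells, qc_threshold)
        records[plate.plate_id] = rec
        transformed[plate.plate_id] = (tp, wells)
        qc_rows.append(
            dict(plate_id=rec.plate_id, zprime=rec.zprime, n_neg=rec.n_neg,
                 n_pos=rec.n_pos, passed=rec.passed)
        )
    passed, _failed = qc_filter(list(records.values()), qc_threshold)
    for plate_id in passed:
        tp, wells = transformed[plate_id]
        norm = percent_activity(tp, wells)
        for well, act in norm.activities.items():
            ann = wells[well]
            act_rows.append(
                dict(compound_id=ann.compound_id, cell_line=norm.cell_line,
                     concentration_M=ann.concentration, activity_pct=act,
                     replicate_id=plate_id)
            )
    activities = pd.DataFrame(
        act_rows, columns=["compound_id", "cell_line", "concentration_M",
                           "activity_pct", "replicate_id"]
    ).sort_values(["compound_id", "cell_line", "concentration_M", "replicate_id"],
                  kind="mergesort", ignore_index=True)
    qc = pd.DataFrame(qc_rows, columns=["plate_id", "zprime", "n_neg", "n_pos", "passed"])
    return activities, qc
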