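"""Radiochromic-film surface dosimetry.

EBT-3 film darkens with absorbed dose; scanned in transmission, the
red-channel response is the most sensitive below ~10 Gy. A film piece is
reduced to the mean pixel value of a region of interest, converted to net
optical density against a matched unexposed blank,

    netOD = log10(PV_unexposed / PV_exposed),

and mapped to dose through the standard calibration form

    dose = a·netOD + b·netOD^n,

which is zero at zero netOD by construction. Per-patient skin dose is then
summarised over the three field positions (medial, lateral, central).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

POSITIONS = ("medial", "lateral", "central")


@dataclass
class FilmMeasurement:
    """One film piece: ROI pixel statistics and derived dose."""

    patient_id: str
    position: str
    pv_exposed: float
    pv_unexposed: float
    net_od: float = float("nan")
    dose: float = float("nan")

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}, got {self.position!r}")
        if not (self.pv_exposed > 0 and self.pv_unexposed > 0):
            raise ValueError("pixel values must be positive")
        if math.isnan(self.net_od):
            self.net_od = net_od(self.pv_exposed, self.pv_unexposed)


def net_od(pv_exposed: float, pv_unexposed: float) -> float:
    """Net optical density of the red channel; negative values (exposed
    brighter than blank) are physically suspect but returned unclamped."""
    if not (pv_exposed > 0 and pv_unexposed > 0):
        raise ValueError("pixel values must be positive")
    return math.log10(pv_unexposed / pv_exposed)


@dataclass
class CalibrationCurve:
    """dose = a·netOD + b·netOD^n over the fitted netOD domain."""

    a: float
    b: float
    n: float
    domain: tuple[float, float]
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if not self.n > 1:
            raise ValueError("exponent n must exceed 1")
        self._check_monotone()

    def predict(self, net_od_values) -> np.ndarray:
        x = np.asarray(net_od_values, dtype=float)
        return self.a * x + self.b * np.power(x, self.n)

    def _check_monotone(self, n_grid: int = 512) -> None:
        lo, hi = self.domain
        grid = np.linspace(max(lo, 0.0), hi, n_grid)
        d = np.diff(self.predict(grid))
        if (d < -1e-9).any():
            raise ValueError("calibration curve is not monotone nondecreasing over its domain")


def fit_calibration(
    net_od_values, doses, fix_n: float | None = None
) -> CalibrationCurve:
    """Least-squares fit of dose = a·netOD + b·netOD^n.

    ``fix_n`` pins the exponent (2.5 is a common choice for EBT-3 red
    channel); otherwise n is fitted. Requires >= 4 calibration points (3
    when n is fixed) spanning the use range; doses above 10 Gy are outside
    the red channel's optimal-response region and rejected.
    """
    x = np.asarray(net_od_values, dtype=float)
    y = np.asarray(doses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("netOD and dose vectors must align")
    min_pts = 3 if fix_n is not None else 4
    if x.size < min_pts:
        raise ValueError(f"need >= {min_pts} calibration points, have {x.size}")
    if (x < 0).any():
        raise ValueError("negative netOD in calibration data")
    if (y > 10.0).any():
        raise ValueError("calibration doses above 10 Gy are outside the fitted response region")

    if fix_n is not None:
        # linear in (a, b) once n is pinned
        design = np.column_stack([x, np.power(x, fix_n)])
        (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
        popt = (float(a), float(b), float(fix_n))
    else:
        def model(xx, a, b, n):
            return a * xx + b * np.power(xx, n)

        p0 = (float(y.max() / max(x.max(), 1e-6)), 1.0, 2.5)
        popt_arr, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
        popt = tuple(float(v) for v in popt_arr)
    curve = CalibrationCurve(a=popt[0], b=popt[1], n=popt[2], domain=(float(x.min()), float(x.max())))
    curve.rmse = float(np.sqrt(np.mean((curve.predict(x) - y) ** 2)))
    return curve


def calibrate_measurements(
    measurements: list[FilmMeasurement], curve: CalibrationCurve
) -> list[FilmMeasurement]:
    """Fill the dose field of each measurement from its netOD."""
    for m in measurements:
        m.dose = float(curve.predict(m.net_od))
    return measurements


def read_film_csv(path) -> list[FilmMeasurement]:
    """Read ``patient_id,position,pv_exposed,pv_unexposed`` rows."""
    frame = pd.read_csv(path)
    required = {"patient_id", "position", "pv_exposed", "pv_unexposed"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FilmMeasurement(
            patient_id=str(r.patient_id),
            position=str(r.position),
            pv_exposed=float(r.pv_exposed),
            pv_unexposed=float(r.pv_unexposed),
        )
        for r in frame.itertuples()
    ]


def patient_surface_dose(measurements: list[FilmMeasurement]) -> pd.DataFrame:
    """Per-patient mean ± SD surface dose by position and pooled.

    SD is reported as 0 for a single measurement. The pooled mean feeds the
    dose-versus-toxicity correlation analysis.
    """
    if not measurements:
        raise ValueError("no film measurements")
    frame = pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in measurements],
            "position": [m.position for m in measurements],
            "dose": [m.dose for m in measurements],
        }
    )
    if frame["dose"].isna().any():
        raise ValueError("uncalibrated measurements: run calibrate_measurements first")
    rows = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        row: dict[str, float | str] = {"patient_id": pid}
        for pos in POSITIONS:
            sub = grp.loc[grp.position == pos, "dose"]
            row[f"dose_{pos}_mean_gy"] = float(sub.mean()) if len(sub) else float("nan")
            row[f"dose_{pos}_sd_gy"] = float(sub.std(ddof=1)) if len(sub) > 1 else 0.0
        row["dose_overall_mean_gy"] = float(grp["dose"].mean())
        row["dose_overall_sd_gy"] = float(grp["dose"].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
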