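"""Per-patient intrinsic-radiosensitivity (IRS) indices.

Three indices are computed from the gated γH2AX geometric means GM(D, t):

* DSB induction at dose D:      GM(D, 30 min) − GM(control)
* % residual DSBs at time t:    100 · [GM(D, t) − GM(control)] / [GM(D, 30 min) − GM(control)]
* dose–response slope:          OLS slope of GM(D, 30 min) − GM(control) on D

The control is the unirradiated (0 Gy) tube. Normalisation is subtraction of
the control GM throughout, consistent with the induction index being a
difference; the slope fit keeps an intercept even though the normalised
response is zero at 0 Gy by construction, so that noise in the control tube
is absorbed by the intercept rather than biasing the slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry import GatedStatistic

logger = logging.getLogger(__name__)

#: induction differences smaller than this are treated as an undefined
#: residual denominator rather than divided through
DENOMINATOR_TOL = 1e-9


@dataclass
class PatientGMGrid:
    """Complete dose × timepoint grid of geometric means for one patient."""

    patient_id: str
    gm: dict[float, dict[float, float]]  # gm[dose][timepoint]
    induction_time: float = 0.5
    control_dose: float = 0.0

    @property
    def doses(self) -> list[float]:
        return sorted(self.gm)

    @property
    def timepoints(self) -> list[float]:
        return sorted(next(iter(self.gm.values())))

    def value(self, dose: float, timepoint: float) -> float:
        try:
            return self.gm[dose][timepoint]
        except KeyError:
            raise KeyError(
                f"{self.patient_id}: missing GM cell at dose {dose} Gy, t={timepoint} h"
            ) from None

    @property
    def control(self) -> float:
        """GM of the unirradiated tube at the induction timepoint."""
        return self.value(self.control_dose, self.induction_time)

    def check_complete(self) -> None:
        tps = set(self.timepoints)
        for dose, row in self.gm.items():
            missing = tps - set(row)
            if missing:
                raise ValueError(f"{self.patient_id}: dose {dose} Gy missing timepoints {sorted(missing)}")
            for tp, v in row.items():
                if not (math.isfinite(v) and v > 0):
                    raise ValueError(f"{self.patient_id}: invalid GM {v} at {dose} Gy / {tp} h")


def build_gm_grids(statistics: list[GatedStatistic], induction_time: float = 0.5) -> list[PatientGMGrid]:
    """Assemble per-patient grids from per-sample gated statistics."""
    by_patient: dict[str, dict[float, dict[float, float]]] = {}
    for s in statistics:
        cell = by_patient.setdefault(s.patient_id, {}).setdefault(s.dose, {})
        if s.timepoint in cell:
            raise ValueError(f"duplicate sample for {s.patient_id} at {s.dose} Gy / {s.timepoint} h")
        cell[s.timepoint] = s.geometric_mean
    grids = [
        PatientGMGrid(pid, gm, induction_time=induction_time)
        for pid, gm in sorted(by_patient.items())
    ]
    for g in grids:
        g.check_complete()
    return grids


def dsb_induction(gm_30min: float, gm_control: float) -> float:
    """Background-subtracted induction ΔGM; may legitimately be ≤ 0."""
    if not (gm_30min > 0 and gm_control > 0):
        raise ValueError("geometric means must be positive")
    delta = gm_30min - gm_control
    if delta <= 0:
        logger.warning("non-positive DSB induction (%.4g - %.4g); kept unclamped", gm_30min, gm_control)
    return delta


def residual_pct(
    gm_t: float, gm_30min: float, gm_control: float, denominator_tol: float = DENOMINATOR_TOL
) -> float:
    """Percent of the 30-min induction still present at a later timepoint.

    Returns NaN (flagged undefined) when the induction denominator is not
    positive beyond ``denominator_tol``; such patients are dropped pairwise
    from downstream correlations.
    """
    if not (gm_t > 0 and gm_30min > 0 and gm_control > 0):
        raise ValueError("geometric means must be positive")
    denom = gm_30min - gm_control
    if denom <= denominator_tol:
        logger.warning("undefined residual: induction %.4g below tolerance %.1g", denom, denominator_tol)
        return float("nan")
    return 100.0 * (gm_t - gm_control) / denom


def dose_response_slope(
    doses: np.ndarray, gm_30min_by_dose: np.ndarray, gm_control: float
) -> tuple[float, float]:
    """OLS slope (ΔGM/Gy) and R² of control-subtracted 30-min GM on dose."""
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(gm_30min_by_dose, dtype=float) - gm_control
    if len(np.unique(doses)) < 2:
        raise ValueError("need >= 2 distinct dose levels for a slope")
    if np.ptp(y) == 0:  # flat response; linregress would report r = 0
        return 0.0, 1.0
    fit = stats.linregress(doses, y)
    return float(fit.slope), float(fit.rvalue**2)


@dataclass
class IRSIndexTable:
    """Cohort table of the three IRS indices plus clinical grade.

    ``frame`` columns: patient_id, rtog_grade, dsb_{D}gy per nonzero dose,
    residual{t}h_pct per post-induction timepoint (at ``reporting_dose``),
    slope, slope_r2. Undefined residuals are NaN.
    """

    frame: pd.DataFrame
    reporting_dose: float = 2.0
    n_undefined_residuals: int = 0
    induction_columns: list[str] = field(default_factory=list)
    residual_columns: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")


def compute_index_table(
    grids: list[PatientGMGrid],
    metadata: pd.DataFrame | None = None,
    reporting_dose: float = 2.0,
) -> IRSIndexTable:
    """Compute all indices for every patient.

    ``metadata`` (optional) supplies ``rtog_grade`` keyed by ``patient_id``;
    residual percentages are reported at ``reporting_dose`` (default 2 Gy,
    the highest ex-vivo dose).
    """
    if not grids:
        raise ValueError("no patients")
    grades = (
        metadata.set_index("patient_id")["rtog_grade"].to_dict() if metadata is not None else {}
    )
    t_ind = grids[0].induction_time
    doses = grids[0].doses
    nonzero_doses = [d for d in doses if d != grids[0].control_dose]
    late_times = [t for t in grids[0].timepoints if t != t_ind]
    if reporting_dose not in doses:
        raise ValueError(f"reporting dose {reporting_dose} Gy not among measured doses {doses}")

    ind_cols = [f"dsb_{d:g}gy" for d in nonzero_doses]
    res_cols = [f"residual{t:g}h_pct" for t in late_times]
    n_undef = 0
    rows = []
    for g in grids:
        control = g.control
        row: dict[str, object] = {"patient_id": g.patient_id, "rtog_grade": grades.get(g.patient_id)}
        for d, col in zip(nonzero_doses, ind_cols):
            row[col] = dsb_induction(g.value(d, t_ind), control)
        for t, col in zip(late_times, res_cols):
            r = residual_pct(g.value(reporting_dose, t), g.value(reporting_dose, t_ind), control)
            if math.isnan(r):
                n_undef += 1
            row[col] = r
        gm30 = np.array([g.value(d, t_ind) for d in doses])
        slope, r2 = dose_response_slope(np.array(doses), gm30, control)
        row["slope"] = slope
        row["slope_r2"] = r2
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["patient_id", "rtog_grade", *ind_cols, *res_cols, "slope", "slope_r2"])
    if n_undef:
        logger.warning("%d undefined residual values (near-zero induction)", n_undef)
    return IRSIndexTable(
        frame=frame,
        reporting_dose=reporting_dose,
        n_undefined_residuals=n_undef,
        induction_columns=ind_cols,
        residual_columns=res_cols,
    )


def cohort_mean_dose_response(
    grids: list[PatientGMGrid],
) -> tuple[dict[float, float], float, float, dict[float, float]]:
    """Cohort-mean 30-min GM per dose with an OLS fit across doses.

    Returns (mean GM per dose, fitted slope, R², per-dose SD). The linearity
    of this cohort-average curve (R² near 1) is the first sanity check of
    the dose–response assumption.
    """
    if len(grids) < 2:
        raise ValueError("need >= 2 patients for a cohort mean")
    t_ind = grids[0].induction_time
    doses = grids[0].doses
    if len(doses) < 2:
        raise ValueError("need >= 2 dose levels")
    per_dose = {d: np.array([g.value(d, t_ind) for g in grids]) for d in doses}
    means = {d: float(v.mean()) for d, v in per_dose.items()}
    sds = {d: float(v.std(ddof=1)) for d, v in per_dose.items()}
    x = np.array(doses)
    y = np.array([means[d] for d in doses])
    if np.ptp(y) == 0:
        return means, 0.0, 1.0, sds
    fit = stats.linregress(x, y)
    return means, float(fit.slope), float(fit.rvalue**2), sds


def heatmap_matrix(table: IRSIndexTable) -> pd.DataFrame:
    """Patients × (induction per dose incl. 0 Gy, RTOG grade) matrix for
    heat-map plots.

    The 0 Gy induction column is identically zero (control minus itself) but
    is kept so the matrix spans the full dose axis. Rows ordered by patient
    id; values unscaled; stable across runs.
    """
    out = table.frame.sort_values("patient_id").set_index("patient_id")
    cols = [*table.induction_columns, "rtog_grade"]
    matrix = out[cols].astype(float)
    matrix.insert(0, "dsb_0gy", 0.0)
    return matrix
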