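"""Dose-response analysis: dilution series, viability normalization,
four-parameter-logistic (4PL) fitting, normalized AUC, and curve-shift
comparison.

The sensitivity readout throughout is the area under the viability curve
over a geometric (fold-spaced) concentration series, normalized so that a
completely insensitive sample (flat viability 1) scores 1.  Lower AUC means
more sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .stats_core import TestResult, bh_adjust, student_t_test

__all__ = [
    "DoseSeries",
    "ViabilityCurveData",
    "SigmoidFit",
    "AUCResult",
    "CurveShift",
    "make_dilution_series",
    "normalize_viability",
    "four_param_logistic",
    "fit_sigmoid",
    "normalized_auc",
    "compare_curves",
    "rank_curve_shifts",
]


@dataclass(frozen=True)
class DoseSeries:
    """A descending geometric dilution series in µM."""

    max_concentration: float
    n_points: int
    fold: float = 2.0
    concentrations: tuple = field(default=None)

    def __post_init__(self):
        if self.max_concentration <= 0:
            raise ValueError("max_concentration must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        conc = tuple(
            self.max_concentration / self.fold**k for k in range(self.n_points)
        )
        object.__setattr__(self, "concentrations", conc)

    @property
    def min_concentration(self) -> float:
        return self.concentrations[-1]


def make_dilution_series(
    max_concentration: float, n_points: int, fold: float = 2.0
) -> DoseSeries:
    """Build a descending fold-dilution series: max, max/fold, ..., max/fold^(n-1).

    Examples
    --------
    An 11-point, 2-fold series from 20 µM bottoms out at 0.01953 µM; a
    7-point series from 5 µM bottoms out at 0.07813 µM — the standard
    concentration layouts for GPX4-inhibitor viability assays.
    """
    return DoseSeries(max_concentration, n_points, fold)


@dataclass
class ViabilityCurveData:
    """Replicate viabilities measured along a dilution series.

    ``replicate_viabilities`` has shape (n_points, n_replicates), row k
    matching ``series.concentrations[k]``.  ``normalized`` records whether
    values are relative to the vehicle (e.g. DMSO) condition.
    """

    series: DoseSeries
    replicate_viabilities: np.ndarray
    normalized: bool = True
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.replicate_viabilities, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape[0] != self.series.n_points:
            raise ValueError(
                f"viability rows ({v.shape[0]}) != series points ({self.series.n_points})"
            )
        self.replicate_viabilities = v

    @property
    def n_replicates(self) -> int:
        return self.replicate_viabilities.shape[1]

    def mean_viability(self) -> np.ndarray:
        return self.replicate_viabilities.mean(axis=1)


def normalize_viability(raw_signal, vehicle_signal) -> np.ndarray:
    """Scale raw well signals by the mean vehicle (DMSO) signal.

    Values may exceed 1 (growth stimulation is preserved).
    """
    raw = np.asarray(raw_signal, dtype=float)
    vehicle = np.asarray(vehicle_signal, dtype=float)
    vmean = vehicle.mean()
    if vmean <= 0:
        raise ValueError(f"vehicle mean signal must be positive, got {vmean}")
    return raw / vmean


def four_param_logistic(c, top, bottom, ec50, hill):
    """4PL viability model: v(c) = bottom + (top - bottom) / (1 + (c/ec50)^hill)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


@dataclass(frozen=True)
class SigmoidFit:
    top: float
    bottom: float
    ec50: float
    hill: float
    residual_ss: float
    converged: bool

    def predict(self, concentrations) -> np.ndarray:
        return four_param_logistic(
            concentrations, self.top, self.bottom, self.ec50, self.hill
        )


def fit_sigmoid(curve: ViabilityCurveData) -> SigmoidFit:
    """Least-squares 4PL fit of a viability curve.

    Initialization: top = max observed mean, bottom = min observed mean,
    ec50 = geometric midpoint of the series, hill = 1.  EC50 is bounded to
    [min_conc/4, max_conc*4] to keep the inflection near the tested range.
    Constant curves short-circuit to the degenerate top = bottom fit.  On
    optimizer failure the initial iterate is returned with converged=False.
    """
    conc = np.asarray(curve.series.concentrations, dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("fit_sigmoid requires >= 4 distinct concentrations")
    v = curve.mean_viability()

    if np.allclose(v, v[0], rtol=0, atol=1e-12):
        return SigmoidFit(
            top=float(v[0]),
            bottom=float(v[0]),
            ec50=float(np.sqrt(conc.max() * conc.min())),
            hill=1.0,
            residual_ss=0.0,
            converged=True,
        )

    top0, bottom0 = float(v.max()), float(v.min())
    ec50_0 = float(np.sqrt(conc.max() * conc.min()))
    p0 = (top0, bottom0, ec50_0, 1.0)
    lower = (-0.5, -0.5, conc.min() / 4.0, 0.05)
    upper = (max(2.0, top0 * 2), max(2.0, top0 * 2), conc.max() * 4.0, 20.0)
    try:
        popt, _ = curve_fit(
            four_param_logistic,
            conc,
            v,
            p0=p0,
            bounds=(lower, upper),
            maxfev=20000,
        )
        top, bottom, ec50, hill = (float(x) for x in popt)
        converged = True
    except RuntimeError:
        top, bottom, ec50, hill = p0
        converged = False
    if bottom > top:  # canonical orientation: report top >= bottom
        top, bottom, hill = bottom, top, -hill
    resid = v - four_param_logistic(conc, top, bottom, ec50, hill)
    return SigmoidFit(top, bottom, ec50, hill, float(resid @ resid), converged)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    n_points: int


def _trapezoid_auc(viabilities: np.ndarray) -> float:
    """Trapezoidal mean over the (uniform) log-concentration axis.

    For a fold-spaced series the log-concentration grid is uniform, so the
    trapezoid rule reduces to (v1/2 + v2 + ... + v_{n-1} + vn/2) / (n-1).
    A flat curve at level v therefore yields exactly v.
    """
    v = np.clip(np.asarray(viabilities, dtype=float), 0.0, None)
    n = v.size
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return float((w @ v) / (n - 1))


def normalized_auc(curve: ViabilityCurveData) -> AUCResult:
    """Normalized area under the viability curve.

    Uses per-concentration replicate means; negative viabilities are floored
    at 0 before integration.  Requires a vehicle-normalized curve so that 1
    is the AUC of a fully insensitive sample.
    """
    if not curve.normalized:
        raise ValueError("curve must be vehicle-normalized before AUC; "
                         "call normalize_viability first")
    if curve.series.n_points < 2:
        raise ValueError("normalized_auc requires >= 2 concentrations")
    return AUCResult(_trapezoid_auc(curve.mean_viability()), curve.series.n_points)


@dataclass(frozen=True)
class CurveShift:
    """Result of comparing a candidate viability curve against a control."""

    delta_auc: float
    candidate_auc: float
    control_auc: float
    test: TestResult


def compare_curves(
    candidate: ViabilityCurveData, control: ViabilityCurveData
) -> CurveShift:
    """Test whether a candidate's sensitivity curve is shifted vs a control.

    Replicate j of each curve contributes one AUC (the j-th well at every
    concentration); the shift is the mean AUC difference (candidate -
    control) and the p-value comes from a two-sided Student t-test on the
    replicate-level AUCs.  Adjust across a candidate panel with
    :func:`rank_curve_shifts`.
    """
    if candidate.series.concentrations != control.series.concentrations:
        raise ValueError("candidate and control measured on different dilution series")
    if candidate.n_replicates != control.n_replicates:
        raise ValueError("replicate counts differ between candidate and control")
    if candidate.n_replicates < 2:
        raise ValueError("compare_curves requires >= 2 replicates")
    cand_aucs = [
        _trapezoid_auc(candidate.replicate_viabilities[:, j])
        for j in range(candidate.n_replicates)
    ]
    ctrl_aucs = [
        _trapezoid_auc(control.replicate_viabilities[:, j])
        for j in range(control.n_replicates)
    ]
    if np.allclose(cand_aucs, ctrl_aucs) and np.ptp(cand_aucs) == np.ptp(ctrl_aucs) == 0:
        test = TestResult(0.0, 1.0, "student_t", len(cand_aucs), len(ctrl_aucs))
    else:
        test = student_t_test(cand_aucs, ctrl_aucs)
    return CurveShift(
        delta_auc=float(np.mean(cand_aucs) - np.mean(ctrl_aucs)),
        candidate_auc=float(np.mean(cand_aucs)),
        control_auc=float(np.mean(ctrl_aucs)),
        test=test,
    )


def rank_curve_shifts(candidates, control: ViabilityCurveData):
    """Compare each candidate curve against the control and BH-adjust.

    Returns a list of (label, CurveShift, adj_p) sorted by adjusted p-value
    (ties broken by delta_auc, most protective — largest AUC gain — first
    and most sensitizing — largest AUC loss — last is not imposed; ties are
    broken by |delta_auc| descending).
    """
    shifts = [compare_curves(c, control) for c in candidates]
    adj = bh_adjust([s.test.p_value for s in shifts])
    labeled = [
        (c.label or f"candidate_{i}", s, float(q))
        for i, (c, s, q) in enumerate(zip(candidates, shifts, adj))
    ]
    labeled.sort(key=lambda t: (t[2], -abs(t[1].delta_auc)))
    return labeled
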