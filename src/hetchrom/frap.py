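"""FRAP recovery analysis with full (double) normalization and
dual-exponential kinetics.

A fluorescence-recovery-after-photobleaching experiment records three
regions of interest per frame: the bleached focus, an unbleached reference
focus, and a background region.  Double normalization divides the
background-corrected bleach signal by the background-corrected reference
signal (cancelling shared acquisition photobleaching) and rescales by the
pre-bleach ratio so the pre-bleach plateau is 1.  Full-scale normalization
then anchors the first post-bleach frame at 0, so complete recovery
corresponds to 1.

Averaged recovery curves are fitted to

    F(t) = A1 * (1 - exp(-t / tau1)) + A2 * (1 - exp(-t / tau2))

with non-negative amplitudes and tau1 <= tau2.  The plateau A1 + A2 is the
mobile fraction (reported in percent); the half-maximal recovery time t_1/2
solves F(t) = (A1 + A2) / 2 on the fitted curve.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .errors import (
    AlignmentGridError,
    DegenerateInputError,
    FitError,
    NormalizationError,
)

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FrapTrace:
    """Raw per-frame ROI intensities for one bleached focus."""

    frame_times: np.ndarray  # seconds, strictly increasing
    bleach_roi: np.ndarray
    reference_roi: np.ndarray
    background_roi: np.ndarray
    n_prebleach: int
    n_bleachframes: int

    def __post_init__(self) -> None:
        arrays = (
            self.frame_times,
            self.bleach_roi,
            self.reference_roi,
            self.background_roi,
        )
        n = len(self.frame_times)
        if any(len(a) != n for a in arrays):
            raise ValueError("all per-frame arrays must share one length")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.n_prebleach + self.n_bleachframes >= n:
            raise ValueError("no post-bleach frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        denom = self.reference_roi - self.background_roi
        if np.any(denom <= 0):
            frame = int(np.argmax(denom <= 0))
            raise NormalizationError(
                f"reference - background non-positive at frame {frame}"
            )


@dataclasses.dataclass(frozen=True)
class NormalizedCurve:
    """A post-bleach recovery curve; t = 0 at the first post-bleach frame."""

    t: np.ndarray
    value: np.ndarray
    se: np.ndarray | None = None
    n_traces: int = 1

    def __post_init__(self) -> None:
        if len(self.t) != len(self.value):
            raise ValueError("t and value must share one length")
        if len(self.t) and abs(self.t[0]) > 1e-9:
            raise ValueError("curve must start at t = 0")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite curve values")


@dataclasses.dataclass(frozen=True)
class DualExpFit:
    A1: float
    A2: float
    tau1: float
    tau2: float
    se_A1: float
    se_A2: float
    se_tau1: float
    se_tau2: float
    covariance: np.ndarray  # 4x4, order (A1, A2, tau1, tau2)
    rss: float
    converged: bool


@dataclasses.dataclass(frozen=True)
class KineticSummary:
    mobile_fraction: float  # percent
    immobile_fraction: float  # percent
    t_half: float  # seconds; nan when undefined
    t_half_defined: bool


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------


def double_normalize(trace: FrapTrace) -> NormalizedCurve:
    """Double-normalize a trace and return the post-bleach curve.

    N(t) = [(Ib - Ibg) / (Iref - Ibg)] * [<Iref - Ibg>_pre / <Ib - Ibg>_pre]

    where <.>_pre averages the pre-bleach frames.  The bleach frames
    themselves (saturated/transition frames) are discarded; the returned
    curve starts at the first post-bleach frame (t = 0).
    """
    b = trace.bleach_roi - trace.background_roi
    r = trace.reference_roi - trace.background_roi
    pre = slice(0, trace.n_prebleach)
    pre_b = float(np.mean(b[pre]))
    pre_r = float(np.mean(r[pre]))
    if pre_b <= 0:
        raise NormalizationError("mean pre-bleach bleach-ROI signal non-positive")
    n = (b / r) * (pre_r / pre_b)
    post = slice(trace.n_prebleach + trace.n_bleachframes, None)
    t = trace.frame_times[post] - trace.frame_times[post][0]
    return NormalizedCurve(t=t, value=n[post])


def full_scale_normalize(curve: NormalizedCurve) -> NormalizedCurve:
    """Anchor the curve between bleach depth (0) and pre-bleach level (1).

    F(t) = (N(t) - N0) / (1 - N0) with N0 the first post-bleach value.
    """
    n0 = float(curve.value[0])
    if n0 >= 1:
        raise DegenerateInputError(f"no bleach depth: first frame N = {n0:.3f} >= 1")
    f = (curve.value - n0) / (1.0 - n0)
    se = curve.se / (1.0 - n0) if curve.se is not None else None
    return NormalizedCurve(t=curve.t, value=f, se=se, n_traces=curve.n_traces)


def average_curves(curves: Sequence[NormalizedCurve]) -> NormalizedCurve:
    """Pointwise mean and standard error across curves on a shared grid."""
    if not curves:
        raise DegenerateInputError("no curves to average")
    t0 = curves[0].t
    for c in curves[1:]:
        if len(c.t) != len(t0) or np.any(np.abs(c.t - t0) > 1e-6):
            raise AlignmentGridError("curves do not share a common time grid")
    values = np.vstack([c.value for c in curves])
    mean = values.mean(axis=0)
    n = len(curves)
    se = values.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return NormalizedCurve(t=t0, value=mean, se=se, n_traces=n)


# --------------------------------------------------------------------------
# Dual-exponential fit
# --------------------------------------------------------------------------


def dual_exp(t: np.ndarray, A1: float, tau1: float, A2: float, tau2: float) -> np.ndarray:
    """Recovery model F(t) = A1 (1 - e^{-t/tau1}) + A2 (1 - e^{-t/tau2})."""
    t = np.asarray(t, dtype=float)
    return A1 * (1.0 - np.exp(-t / tau1)) + A2 * (1.0 - np.exp(-t / tau2))


# multi-start tau grids (seconds); amplitude seeds come from the observed
# plateau split 70/30
_TAU_GRID_1 = (0.2, 1.0, 5.0)
_TAU_GRID_2 = (5.0, 20.0, 80.0)
_PLATEAU_CAP = 1.05  # recovery cannot overshoot the pre-bleach level


def _multi_start(resid, x0s, lo, hi):
    """Best (rss, x, n_converged) over a set of starts; plateau (x[0]) at
    its cap marks an unidentifiable extrapolation and is discarded."""
    best = None
    n_ok = 0
    for x0 in x0s:
        sol = least_squares(
            resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=2000,
        )
        if not sol.success:
            continue
        n_ok += 1
        if sol.x[0] > _PLATEAU_CAP - 1e-9:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    return best, n_ok


def fit_dual_exponential(
    curve: NormalizedCurve, fit_depth: bool = False
) -> DualExpFit:
    """Least-squares dual-exponential fit of a normalized recovery curve.

    The fit runs in (plateau, fast fraction, log tau1, log tau2) space for
    conditioning (so amplitudes stay non-negative and the plateau respects
    the physical cap of ~1), from a fixed grid of tau starts, with taus
    bounded to [frame interval / 10, 10 x total duration].  Two numerical
    safeguards address the flat valley in which a near-linear slow
    component (tau2 far beyond the observation window) absorbs noise while
    driving the plateau to its cap:

    * solutions that terminate on the plateau cap are discarded as
      unidentifiable extrapolations;
    * a nested single-exponential fit is preferred unless the second
      component improves the fit significantly (extra-sum-of-squares F
      test at alpha = 0.05); for effectively single-exponential data the
      amplitude split is unidentifiable anyway and the plateau and
      half-time are the quantities under contract.

    With ``fit_depth`` the curve is taken on the double-normalized scale
    and the bleach depth N0 is estimated as a free nuisance parameter,
    N(t) = N0 + (1 - N0) F(t); amplitudes are still reported on the
    full-scale (F) axis.  Otherwise the curve must already be full-scale
    normalized.  Standard errors come from the residual-variance-scaled
    inverse curvature of the objective at the optimum; parameters are
    reported in canonical order tau1 <= tau2 (ties: larger amplitude
    first).
    """
    t, y = curve.t, curve.value
    m = len(t)
    if m < 10:
        raise DegenerateInputError(f"need >= 10 post-bleach points, got {m}")
    dt = float(np.min(np.diff(t)))
    ltau_lo, ltau_hi = math.log(dt / 10.0), math.log(10.0 * float(t[-1]))

    if fit_depth:
        n0_seed = float(y[0])
        plateau_obs = (float(np.mean(y[int(0.9 * m) :])) - n0_seed) / max(
            1.0 - n0_seed, 1e-6
        )
    else:
        n0_seed = 0.0
        plateau_obs = float(np.mean(y[max(1, int(0.9 * m)) :]))
    p_seed = min(max(plateau_obs, 1e-6), _PLATEAU_CAP)

    def scale(model):  # map F-scale model to the fitted data scale
        if fit_depth:
            return lambda p: p[-1] + (1.0 - p[-1]) * model(p) - y
        return lambda p: model(p) - y

    resid1 = scale(lambda p: p[0] * (1.0 - np.exp(-t / math.exp(p[1]))))
    resid2 = scale(
        lambda p: dual_exp(
            t, p[0] * p[1], math.exp(p[2]), p[0] * (1.0 - p[1]), math.exp(p[3])
        )
    )

    extra = ([n0_seed], [-1.0], [0.999]) if fit_depth else ([], [], [])
    taus = sorted(set(_TAU_GRID_1) | set(_TAU_GRID_2))
    x0s1 = [
        [p_seed, min(max(math.log(tau), ltau_lo), ltau_hi)] + extra[0]
        for tau in taus
    ]
    b1, ok1 = _multi_start(
        resid1, x0s1, [0.0, ltau_lo] + extra[1], [_PLATEAU_CAP, ltau_hi] + extra[2]
    )
    x0s2 = [
        [
            p_seed,
            0.7,
            min(max(math.log(t1), ltau_lo), ltau_hi),
            min(max(math.log(t2), ltau_lo), ltau_hi),
        ]
        + extra[0]
        for t1 in _TAU_GRID_1
        for t2 in _TAU_GRID_2
        if t1 < t2
    ]
    b2, ok2 = _multi_start(
        resid2,
        x0s2,
        [0.0, 0.0, ltau_lo, ltau_lo] + extra[1],
        [_PLATEAU_CAP, 1.0, ltau_hi, ltau_hi] + extra[2],
    )
    if b1 is None and b2 is None:
        raise FitError(
            f"recovery fit failed from all starts (m={m}, plateau~{plateau_obs:.3f})"
        )

    n_fitted = 4 + (1 if fit_depth else 0)
    dof = max(m - n_fitted, 1)
    use_dual = False
    if b2 is not None:
        if b1 is None or b2[0] <= 0:
            use_dual = True
        else:
            f_stat = ((b1[0] - b2[0]) / 2.0) / (b2[0] / dof)
            use_dual = f_stat > f_dist.ppf(0.95, 2, dof)

    if use_dual:
        rss, x = b2
        a1, a2 = float(x[0] * x[1]), float(x[0] * (1.0 - x[1]))
        tau1, tau2 = math.exp(x[2]), math.exp(x[3])
        n0 = float(x[4]) if fit_depth else 0.0
    else:
        rss, x = b1
        a1, tau1 = float(x[0]), math.exp(x[1])
        a2, tau2 = 0.0, math.exp(x[1])
        n0 = float(x[2]) if fit_depth else 0.0
    # canonical order: tau1 <= tau2; ties broken by larger amplitude first
    if tau1 > tau2 or (math.isclose(tau1, tau2, rel_tol=1e-9) and a2 > a1):
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1

    cov = _covariance(t, a1, tau1, a2, tau2, n0, fit_depth, rss, dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return DualExpFit(
        A1=a1,
        A2=a2,
        tau1=tau1,
        tau2=tau2,
        se_A1=float(se[0]),
        se_A2=float(se[1]),
        se_tau1=float(se[2]),
        se_tau2=float(se[3]),
        covariance=cov,
        rss=rss,
        converged=(ok1 + ok2) > 0,
    )


def _covariance(
    t: np.ndarray,
    a1: float,
    tau1: float,
    a2: float,
    tau2: float,
    n0: float,
    fit_depth: bool,
    rss: float,
    dof: int,
) -> np.ndarray:
    """Gauss-Newton covariance s^2 (J^T J)^+ for (A1, A2, tau1, tau2); the
    depth nuisance parameter, when fitted, is marginalized over."""
    e1 = np.exp(-t / tau1)
    e2 = np.exp(-t / tau2)
    scale = (1.0 - n0) if fit_depth else 1.0
    cols = [
        scale * (1.0 - e1),
        scale * (1.0 - e2),
        -scale * a1 * t * e1 / tau1**2,
        -scale * a2 * t * e2 / tau2**2,
    ]
    if fit_depth:
        f_model = a1 * (1.0 - e1) + a2 * (1.0 - e2)
        cols.append(1.0 - f_model)
    J = np.column_stack(cols)
    cov = (rss / dof) * np.linalg.pinv(J.T @ J)
    cov = 0.5 * (cov + cov.T)
    return cov[:4, :4]


# --------------------------------------------------------------------------
# Kinetic summary
# --------------------------------------------------------------------------


def kinetic_summary(fit: DualExpFit) -> KineticSummary:
    """Mobile/immobile fractions (percent) and half-maximal recovery time.

    mobile = 100 (A1 + A2), clamped to [0, 100]; immobile = 100 - mobile.
    t_1/2 solves F(t) = (A1 + A2) / 2 by bisection on [0, 10 tau2]; F is
    strictly increasing, so the root is unique.  With zero mobile fraction
    the half-time is undefined and flagged.
    """
    if not fit.converged:
        raise FitError("cannot summarize a non-converged fit")
    plateau = fit.A1 + fit.A2
    mobile = min(max(100.0 * plateau, 0.0), 100.0)
    if plateau <= 0:
        return KineticSummary(mobile, 100.0 - mobile, math.nan, False)
    target = plateau / 2.0
    lo, hi = 0.0, 10.0 * fit.tau2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if dual_exp(np.array([mid]), fit.A1, fit.tau1, fit.A2, fit.tau2)[0] < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    return KineticSummary(mobile, 100.0 - mobile, 0.5 * (lo + hi), True)


# --------------------------------------------------------------------------
# Pipeline and IO
# --------------------------------------------------------------------------


def frap_pipeline(
    traces: Sequence[FrapTrace],
) -> tuple[NormalizedCurve, DualExpFit, KineticSummary]:
    """Normalize every trace, average, fit, summarize.

    Traces are double-normalized and averaged; the recovery model is then
    fitted on the averaged curve with the bleach depth as a free nuisance
    parameter (more robust than anchoring on the single noisy first
    post-bleach frame).  The returned curve is the averaged recovery on
    the full scale (anchored at its first post-bleach frame).
    """
    if not traces:
        raise DegenerateInputError("no traces")
    avg_n = average_curves([double_normalize(tr) for tr in traces])
    fit = fit_dual_exponential(avg_n, fit_depth=True)
    return full_scale_normalize(avg_n), fit, kinetic_summary(fit)


def read_trace_csv(path, n_prebleach: int, n_bleachframes: int) -> FrapTrace:
    """Load one trace CSV with columns time_s, bleach, reference, background."""
    df = pd.read_csv(path)
    return FrapTrace(
        frame_times=df["time_s"].to_numpy(float),
        bleach_roi=df["bleach"].to_numpy(float),
        reference_roi=df["reference"].to_numpy(float),
        background_roi=df["background"].to_numpy(float),
        n_prebleach=n_prebleach,
        n_bleachframes=n_bleachframes,
    )


def write_trace_csv(trace: FrapTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.frame_times,
            "bleach": trace.bleach_roi,
            "reference": trace.reference_roi,
            "background": trace.background_roi,
        }
    ).to_csv(path, index=False)


def curve_frame(curve: NormalizedCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": curve.t,
            "mean": curve.value,
            "se": curve.se if curve.se is not None else np.zeros_like(curve.value),
            "n": curve.n_traces,
        }
    )


def fit_frame(fit: DualExpFit, summary: KineticSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "A1": fit.A1,
                "A2": fit.A2,
                "tau1_s": fit.tau1,
                "tau2_s": fit.tau2,
                "se_A1": fit.se_A1,
                "se_A2": fit.se_A2,
                "se_tau1": fit.se_tau1,
                "se_tau2": fit.se_tau2,
                "rss": fit.rss,
                "mobile_pct": summary.mobile_fraction,
                "immobile_pct": summary.immobile_fraction,
                "t_half_s": summary.t_half,
            }
        ]
    )
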