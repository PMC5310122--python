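"""Growth and fermentation phenotype mathematics.

Growth curves (OD600 vs time) are blank-subtracted, log-transformed to
y = ln(OD_t / OD_0), and fitted with the reparameterised Gompertz model

    y(t) = D * exp(-exp((mu_max * e / D) * (lam - t) + 1))

by damped Gauss-Newton least squares.  The module also provides broad-sense
heritability from segregant vs parental-replicate variances, the 2-sigma
transgression rule, generation counting, fermentation completion time (T100,
density crossing 995 g/L) with a STUCK sentinel, and strain-vs-control
two-sample t-tests with Bonferroni adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STUCK",
    "is_stuck",
    "GrowthCurve",
    "GompertzFit",
    "DensityCurve",
    "FermentationSummary",
    "PhenotypePanel",
    "preprocess_curve",
    "gompertz_y",
    "fit_gompertz",
    "heritability",
    "transgression",
    "TransgressionResult",
    "generations",
    "t100",
    "relative_t100",
    "compare_to_control",
]

#: Sentinel for fermentations that never reach the completion density.
STUCK: float = math.inf


def is_stuck(value: float) -> bool:
    return math.isinf(value)


# ---------------------------------------------------------------------------
# curves


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 vs time (hours), with an optional uninoculated blank series."""

    times: np.ndarray
    od: np.ndarray
    blank: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        od = np.asarray(self.od, dtype=np.float64)
        if t.ndim != 1 or t.shape != od.shape:
            raise ValueError("times and od must be 1-D and of equal length")
        if len(t) < 4:
            raise ValueError("need at least 4 points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD readings must be >= 0")
        blank = self.blank
        if blank is not None:
            blank = np.asarray(blank, dtype=np.float64)
            if blank.shape != t.shape:
                raise ValueError("blank must share the curve's time grid")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        object.__setattr__(self, "blank", blank)


@dataclass(frozen=True)
class DensityCurve:
    """Must density (g/L) vs time (hours) during fermentation."""

    times: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        d = np.asarray(self.density, dtype=np.float64)
        if t.ndim != 1 or t.shape != d.shape or len(t) < 2:
            raise ValueError("need >= 2 aligned (time, density) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "density", d)


@dataclass(frozen=True)
class GompertzFit:
    D: float
    mu_max: float
    lam: float
    sse: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class FermentationSummary:
    t100: float  # hours, or STUCK
    relative_t100: float | None = None  # vs control, or STUCK


@dataclass(frozen=True)
class PhenotypePanel:
    """Segregant trait values plus replicate measurements of both parents."""

    segregants: np.ndarray
    parent_a: np.ndarray
    parent_b: np.ndarray

    def __post_init__(self) -> None:
        seg = np.asarray(self.segregants, dtype=np.float64)
        pa = np.asarray(self.parent_a, dtype=np.float64)
        pb = np.asarray(self.parent_b, dtype=np.float64)
        if seg.size == 0:
            raise ValueError("segregant list must be non-empty")
        if pa.size < 2 or pb.size < 2:
            raise ValueError("need >= 2 replicates per parent")
        object.__setattr__(self, "segregants", seg)
        object.__setattr__(self, "parent_a", pa)
        object.__setattr__(self, "parent_b", pb)

    def pooled_parental_variance(self) -> float:
        """df-weighted pooled sample variance of the two parents' replicates."""
        n1, n2 = len(self.parent_a), len(self.parent_b)
        s1 = self.parent_a.var(ddof=1)
        s2 = self.parent_b.var(ddof=1)
        return ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)


# ---------------------------------------------------------------------------
# preprocessing and the Gompertz model


def preprocess_curve(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """Blank-subtract and log-transform: y_t = ln(od'_t / od'_0), y_0 = 0."""
    od = curve.od if curve.blank is None else curve.od - curve.blank
    bad = np.flatnonzero(od <= 0)
    if bad.size:
        pts = ", ".join(f"t={curve.times[i]:g}" for i in bad[:10])
        raise ValueError(f"non-positive OD after blank subtraction at: {pts}")
    y = np.log(od / od[0])
    y[0] = 0.0
    return curve.times.copy(), y


def gompertz_y(t, D: float, mu_max: float, lam: float):
    """Reparameterised Gompertz: D * exp(-exp((mu_max*e/D)*(lam - t) + 1))."""
    if D <= 0:
        raise ValueError("D must be positive")
    t = np.asarray(t, dtype=np.float64)
    u = (mu_max * math.e / D) * (lam - t) + 1.0
    out = D * np.exp(-np.exp(u))
    return out if out.ndim else float(out)


def _gompertz_jacobian(t: np.ndarray, D: float, mu: float, lam: float) -> np.ndarray:
    u = (mu * math.e / D) * (lam - t) + 1.0
    v = np.exp(u)
    ev = np.exp(-v)
    dD = ev * (1.0 + v * (u - 1.0))
    dmu = -ev * v * math.e * (lam - t)
    dlam = -ev * v * mu * math.e
    return np.column_stack([dD, dmu, dlam])


def fit_gompertz(times, y, max_iter: int = 200, tol: float = 1e-8) -> GompertzFit:
    """Damped Gauss-Newton least-squares fit of the Gompertz model.

    Initialisation: D0 = max(y); mu0 = steepest finite-difference slope;
    lam0 = time intercept of the steepest tangent, floored at 0.  Each step
    is halved (up to 50 times) until the SSE decreases; convergence when the
    relative SSE change drops below ``tol``.
    """
    t = np.asarray(times, dtype=np.float64)
    yo = np.asarray(y, dtype=np.float64)
    if t.shape != yo.shape or t.ndim != 1:
        raise ValueError("times and y must be aligned 1-D arrays")
    if len(t) < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    if np.allclose(yo, yo[0]):
        raise ValueError("degenerate curve: y is constant, nothing to fit")

    slopes = np.diff(yo) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = float(slopes[k])
    if mu0 <= 0:
        raise ValueError("degenerate curve: no positive growth segment")
    d0 = float(max(yo.max(), 1e-6))
    tm = 0.5 * (t[k] + t[k + 1])
    ym = 0.5 * (yo[k] + yo[k + 1])
    lam0 = max(0.0, tm - ym / mu0)

    theta = np.array([d0, mu0, lam0])
    resid = yo - gompertz_y(t, *theta)
    sse = float(resid @ resid)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = _gompertz_jacobian(t, *theta)
        step, *_ = np.linalg.lstsq(J, resid, rcond=None)
        scale = 1.0
        new_theta, new_sse = theta, sse
        for _ in range(51):
            cand = theta + scale * step
            if cand[0] > 0:
                r = yo - gompertz_y(t, *cand)
                s = float(r @ r)
                if s <= sse:
                    new_theta, new_sse, resid = cand, s, r
                    break
            scale *= 0.5
        else:
            break  # no descent direction found: stop, not converged
        theta = new_theta
        if sse - new_sse <= tol * max(sse, 1e-300):
            sse = new_sse
            converged = True
            break
        sse = new_sse
    return GompertzFit(float(theta[0]), float(theta[1]), float(theta[2]), sse, converged, it)


def fit_growth_curve(curve: GrowthCurve, **kwargs) -> GompertzFit:
    """Convenience: preprocess then fit."""
    t, y = preprocess_curve(curve)
    return fit_gompertz(t, y, **kwargs)


# ---------------------------------------------------------------------------
# segregant statistics


def heritability(panel: PhenotypePanel) -> float:
    """Broad-sense heritability, percent: ((Var_seg - Var_env)/Var_seg) * 100.

    Var_env is the pooled parental replicate variance, Var_seg the sample
    variance of segregant values.  Negative estimates are returned as-is
    (with a warning), not clamped.
    """
    if len(panel.segregants) < 2:
        raise ValueError("need >= 2 segregants for a variance")
    var_seg = panel.segregants.var(ddof=1)
    if var_seg == 0:
        raise ValueError("segregant variance is zero; heritability undefined")
    var_env = panel.pooled_parental_variance()
    h2 = (var_seg - var_env) / var_seg * 100.0
    if h2 < 0:
        warnings.warn(f"negative heritability estimate ({h2:.2f}%)", stacklevel=2)
    return float(h2)


@dataclass(frozen=True)
class TransgressionResult:
    n_high: int
    n_low: int
    frac_high: float
    frac_low: float


def transgression(panel: PhenotypePanel) -> TransgressionResult:
    """Segregants beyond the parental range by at least 2 pooled parental SD.

    High: value >= mean(higher parent) + 2*sigma; low: value <= mean(lower
    parent) - 2*sigma (both inclusive).
    """
    sigma = math.sqrt(panel.pooled_parental_variance())
    mean_a, mean_b = panel.parent_a.mean(), panel.parent_b.mean()
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    seg = panel.segregants
    n_high = int(np.sum(seg >= hi + 2 * sigma))
    n_low = int(np.sum(seg <= lo - 2 * sigma))
    n = len(seg)
    return TransgressionResult(n_high, n_low, n_high / n, n_low / n)


def generations(n0: float, nt: float) -> float:
    """Number of doublings between two OD readings: log2(Nt / N0)."""
    if n0 <= 0 or nt <= 0:
        raise ValueError("OD values must be positive")
    return math.log(nt / n0) / math.log(2.0)


# ---------------------------------------------------------------------------
# fermentation endpoints


def t100(curve: DensityCurve, threshold: float = 995.0) -> float:
    """First time the density reaches the completion threshold (<= 995 g/L).

    Linearly interpolated between the bracketing samples; STUCK when the
    series never crosses.  A series already at or below the threshold is
    rejected.
    """
    d = curve.density
    if d[0] <= threshold:
        raise ValueError("density series starts at or below the completion threshold")
    below = np.flatnonzero(d <= threshold)
    if below.size == 0:
        return STUCK
    i = int(below[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    d0, d1 = d[i - 1], d[i]
    if d1 == d0:
        return float(t1)
    return float(t0 + (d0 - threshold) / (d0 - d1) * (t1 - t0))


def relative_t100(strain: FermentationSummary, control: FermentationSummary) -> float:
    """T100 ratio vs control (control normalised to 1); STUCK propagates."""
    if is_stuck(control.t100):
        raise ValueError("control fermentation is stuck; relative T100 undefined")
    if control.t100 <= 0:
        raise ValueError("control T100 must be positive")
    if is_stuck(strain.t100):
        return STUCK
    return strain.t100 / control.t100


# ---------------------------------------------------------------------------
# strain-vs-control testing


def compare_to_control(
    groups: dict[str, np.ndarray | list[float]],
    control_label: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests of each strain against the control.

    Bonferroni: adjusted p = min(1, p * number of non-control strains).
    Returns a DataFrame with columns strain, t, p_raw, p_adj, significant.
    Zero variance in both groups with equal means yields p = 1 by convention.
    """
    if control_label not in groups:
        raise KeyError(f"control {control_label!r} not among groups")
    control = np.asarray(groups[control_label], dtype=np.float64)
    if len(control) < 2:
        raise ValueError("need >= 2 control replicates")
    others = [k for k in groups if k != control_label]
    n_tests = len(others)
    rows = []
    for name in others:
        vals = np.asarray(groups[name], dtype=np.float64)
        if len(vals) < 2:
            raise ValueError(f"need >= 2 replicates for {name!r}")
        if vals.var(ddof=1) == 0 and control.var(ddof=1) == 0:
            t_stat, p = (0.0, 1.0) if vals.mean() == control.mean() else (math.inf, 0.0)
        else:
            t_stat, p = stats.ttest_ind(vals, control, equal_var=equal_var)
        p_adj = min(1.0, float(p) * n_tests)
        rows.append((name, float(t_stat), float(p), p_adj, p_adj <= alpha))
    return pd.DataFrame(rows, columns=["strain", "t", "p_raw", "p_adj", "significant"])
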