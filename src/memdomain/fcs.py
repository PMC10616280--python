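"""Spot-variation z-scan FCS analysis.

The stage mirrors the experimental workflow on giant unilamellar vesicles:

1. Autocorrelation curves are fitted with a 2D lateral diffusion model with
   one or two diffusing populations,
   ``G(tau) = (1/N) * sum_k f_k / (1 + tau/tau_dk)``.
2. Per vesicle, diffusion times measured at >=5 axial offsets are fitted with
   a quadratic in z; the vertex of the parabola is the minimum diffusion time
   tau_d, the value attained when the beam waist crosses the membrane plane.
3. tau_d values from >=5 vesicles at the same waist are combined into a
   weighted mean/s.d., the weight being the number of z points in each fit.
4. The diffusion law ``tau_d = omega^2 / (4 D_eff) + t_0`` is fitted across
   5--6 waists by weighted linear regression.  The intercept t_0 diagnoses
   confinement: t_0 > 0 for dynamic domain partitioning, t_0 < 0 for meshwork
   barriers, t_0 ~ 0 for free diffusion.

Units: lag times in s on curves, diffusion times in ms, waists in um,
diffusion coefficients in um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ACFCurve",
    "ACFFitResult",
    "ZScanSeries",
    "VesicleTau",
    "DiffusionLaw",
    "ACFFitError",
    "ZScanConcaveError",
    "acf_model",
    "fit_acf",
    "select_population_model",
    "fit_zscan",
    "aggregate_vesicles",
    "fit_diffusion_law",
    "classify_confinement",
]

MS_PER_S = 1e3


class ACFFitError(RuntimeError):
    """Nonlinear ACF fit failed to converge or produced an invalid amplitude."""


class ZScanConcaveError(ValueError):
    """z-scan series has no interior minimum (concave/linear fit): the vesicle
    was mispositioned and the series is rejected."""


@dataclass
class ACFCurve:
    """A fluorescence autocorrelation curve G(tau) with acquisition metadata."""

    lags: np.ndarray          # s, strictly increasing, positive
    g: np.ndarray
    vesicle_id: str = ""
    waist: float = np.nan     # um
    z_offset: float = np.nan  # um

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.size == 0:
            raise ValueError("empty lag grid")
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have the same length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")


@dataclass
class ACFFitResult:
    n_populations: int
    n_particles: float
    tau_d: np.ndarray         # ms, ascending
    fractions: np.ndarray     # sum to 1
    residual_sse: float
    se_tau_d: np.ndarray      # ms

    def __post_init__(self):
        self.tau_d = np.atleast_1d(np.asarray(self.tau_d, dtype=float))
        self.fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        self.se_tau_d = np.atleast_1d(np.asarray(self.se_tau_d, dtype=float))
        order = np.argsort(self.tau_d)
        self.tau_d = self.tau_d[order]
        self.fractions = self.fractions[order]
        self.se_tau_d = self.se_tau_d[order]


@dataclass
class ZScanSeries:
    """Diffusion times measured at several axial offsets for one vesicle/waist."""

    z: np.ndarray             # um
    tau_d: np.ndarray         # ms
    waist: float              # um
    vesicle_id: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.tau_d = np.asarray(self.tau_d, dtype=float)
        if self.z.shape != self.tau_d.shape:
            raise ValueError("z and tau_d must have the same length")
        if self.z.size < 5:
            raise ValueError("need >=5 (z, tau_d) pairs per vesicle")
        if np.any(self.tau_d <= 0):
            raise ValueError("tau_d must be positive")


@dataclass
class VesicleTau:
    """Minimum diffusion time of one vesicle with its aggregation weight."""

    tau_min: float            # ms
    weight: int               # number of z points used in the quadratic fit
    waist: float              # um
    z0: float = np.nan        # um, fitted membrane position


@dataclass
class DiffusionLaw:
    d_eff: float              # um^2/s
    t0: float                 # ms
    se_d_eff: float
    se_t0: float
    points: list = field(default_factory=list)  # (waist^2 um^2, mean tau_d ms, sd ms)
    dof: float = np.inf       # residual degrees of freedom of the law fit


# --------------------------------------------------------------------------
# ACF model and fitting
# --------------------------------------------------------------------------

def acf_model(lags_s, n_particles, tau_d_ms, fractions, offset=0.0):
    """2D lateral diffusion autocorrelation with 1--2 populations.

    G(tau) = (1/N) sum_k f_k (1 + tau/tau_dk)^-1 + offset, tau in s,
    tau_d in ms.
    """
    tau = np.asarray(lags_s, dtype=float) * MS_PER_S  # ms
    tau_d = np.atleast_1d(np.asarray(tau_d_ms, dtype=float))
    f = np.atleast_1d(np.asarray(fractions, dtype=float))
    g = np.zeros_like(tau)
    for fk, tk in zip(f, tau_d):
        g += fk / (1.0 + tau / tk)
    return g / n_particles + offset


def _init_guess(curve: ACFCurve):
    g0 = curve.g[0]
    n0 = 1.0 / g0 if g0 > 0 else 1.0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    i = below[0] if below.size else curve.g.size - 1
    tau_half_ms = curve.lags[i] * MS_PER_S
    return max(n0, 1e-3), max(tau_half_ms, 1e-6)


def fit_acf(curve: ACFCurve, n_populations: int) -> ACFFitResult:
    """Nonlinear least-squares fit of the 2D diffusion ACF model.

    Initialization is deterministic: N from 1/G at the first lag, tau_d from
    the lag where G halves; the two-population start splits that tau_d by a
    factor of 10 either way.  Bounded restarts with perturbed starts are
    attempted before reporting failure.
    """
    if curve.lags.size < 10:
        raise ValueError("need >=10 lag points")
    if np.ptp(curve.g) == 0:
        raise ValueError("constant curve cannot be fitted")
    if n_populations not in (1, 2):
        raise ValueError("n_populations must be 1 or 2")

    n0, th = _init_guess(curve)
    x, y = curve.lags, curve.g

    if n_populations == 1:
        def model(t, n, td):
            return acf_model(t, n, [td], [1.0])
        p0s = [(n0, th), (n0, th * 5), (n0, th / 5)]
        bounds = ([1e-9, 1e-9], [np.inf, np.inf])
    else:
        def model(t, n, td1, td2, f1):
            return acf_model(t, n, [td1, td2], [f1, 1.0 - f1])
        p0s = [(n0, th / 10, th * 10, 0.5),
               (n0, th / 3, th * 3, 0.5),
               (n0, th, th * 30, 0.3)]
        bounds = ([1e-9, 1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf, 1.0])

    last_err = None
    for p0 in p0s:
        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000)
            break
        except RuntimeError as err:   # pragma: no cover - rare non-convergence
            last_err = err
    else:   # pragma: no cover
        raise ACFFitError(f"ACF fit did not converge: {last_err}")

    resid = y - model(x, *popt)
    sse = float(np.sum(resid**2))
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    if popt[0] <= 0:   # pragma: no cover - excluded by bounds
        raise ACFFitError("fitted particle number is nonpositive")

    if n_populations == 1:
        return ACFFitResult(1, popt[0], [popt[1]], [1.0], sse, [perr[1]])
    n, td1, td2, f1 = popt
    return ACFFitResult(2, n, [td1, td2], [f1, 1.0 - f1], sse,
                        [perr[1], perr[2]])


def select_population_model(curve: ACFCurve, alpha: float = 0.05,
                            tau_ratio_min: float = 5.0,
                            minor_fraction_min: float = 0.1) -> int:
    """Decide between one and two diffusing populations.

    Returns 2 only if (a) the SSE reduction of the 4-parameter model over the
    2-parameter model passes an extra-sum-of-squares F-test at ``alpha``,
    (b) the fitted diffusion times differ by at least ``tau_ratio_min``, and
    (c) the minor population carries at least ``minor_fraction_min`` of the
    amplitude.  Populations with similar diffusion times merge into a single
    apparent component and are reported as 1.
    """
    fit1 = fit_acf(curve, 1)
    fit2 = fit_acf(curve, 2)
    n = curve.lags.size
    p1, p2 = 2, 4
    if fit2.residual_sse <= 0:
        pval = 0.0
    else:
        fstat = ((fit1.residual_sse - fit2.residual_sse) / (p2 - p1)) / (
            fit2.residual_sse / (n - p2))
        pval = stats.f.sf(max(fstat, 0.0), p2 - p1, n - p2)
    ratio = fit2.tau_d[1] / fit2.tau_d[0]
    minor = float(np.min(fit2.fractions))
    if pval < alpha and ratio >= tau_ratio_min and minor >= minor_fraction_min:
        return 2
    return 1


# --------------------------------------------------------------------------
# z-scan and diffusion law
# --------------------------------------------------------------------------

def fit_zscan(series: ZScanSeries) -> VesicleTau:
    """Quadratic fit of diffusion time vs axial offset; vertex = tau_d minimum.

    The diffusion time is minimal when the focal plane coincides with the
    membrane; a concave or linear trend means the scan missed the membrane
    and the series is rejected.
    """
    z, tau = series.z, series.tau_d
    a, b, c = np.polyfit(z, tau, 2)
    if a <= 0:
        raise ZScanConcaveError(
            f"vesicle {series.vesicle_id!r}: quadratic coefficient {a:.3g} <= 0")
    z0 = -b / (2 * a)
    tau_min = c - b * b / (4 * a)
    if tau_min <= 0:
        raise ZScanConcaveError(
            f"vesicle {series.vesicle_id!r}: fitted minimum {tau_min:.3g} ms <= 0")
    return VesicleTau(tau_min=float(tau_min), weight=int(z.size),
                      waist=series.waist, z0=float(z0))


def aggregate_vesicles(taus: Sequence[VesicleTau]):
    """Weighted mean and s.d. of per-vesicle minimum diffusion times.

    Weights are the number of z points used in each quadratic fit
    (frequency-weight convention).  All entries must share one waist.
    """
    if len(taus) == 0:
        raise ValueError("empty input")
    waists = {round(t.waist, 9) for t in taus}
    if len(waists) > 1:
        raise ValueError(f"mixed waists in aggregation: {sorted(waists)}")
    from .diffusion import weighted_stats
    vals = [t.tau_min for t in taus]
    w = [t.weight for t in taus]
    return weighted_stats(vals, w)


def fit_diffusion_law(points) -> DiffusionLaw:
    """Weighted linear regression of tau_d on omega^2 (the FCS diffusion law).

    ``points`` is a sequence of (waist^2 um^2, mean tau_d ms, sd ms).  Weights
    are 1/sd^2; if any sd is 0 the fit falls back to unweighted.  The slope
    maps to D_eff = 1/(4 slope) (with the ms <-> s conversion) and the
    intercept is t_0; the slope's standard error propagates to D_eff by the
    delta method.
    """
    pts = [(float(a), float(b), float(c)) for a, b, c in points]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    sd = np.array([p[2] for p in pts])
    if np.unique(x).size < 3:
        raise ValueError("need >=3 distinct waist^2 values")
    w = np.ones_like(x) if np.any(sd <= 0) else 1.0 / sd**2

    # weighted normal equations
    sw = w.sum()
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    dof = x.size - 2
    sigma2 = np.sum(w * resid**2) / dof if dof > 0 else 0.0
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / sw + xm**2 / sxx))

    if slope <= 0:
        raise ValueError("nonpositive diffusion-law slope: D_eff undefined")
    # slope in ms/um^2 -> D in um^2/s: tau[ms] = 1e3 * omega^2/(4 D) => D = 1e3/(4 slope)
    d_eff = MS_PER_S / (4.0 * slope)
    se_d = MS_PER_S * se_slope / (4.0 * slope**2)
    return DiffusionLaw(d_eff=float(d_eff), t0=float(intercept),
                        se_d_eff=float(se_d), se_t0=float(se_intercept),
                        points=pts, dof=dof)


def diffusion_law_from_series(series: Sequence[ZScanSeries],
                              min_vesicles: int = 1) -> DiffusionLaw:
    """Full z-scan pipeline: quadratic fits -> weighted aggregation -> law fit.

    Groups the series by waist, extracts each vesicle's minimum diffusion
    time (rejecting concave scans), aggregates per waist with point-count
    weights and fits the diffusion law across waists.
    """
    by_waist = {}
    for s in series:
        by_waist.setdefault(round(s.waist, 9), []).append(s)
    points = []
    for waist in sorted(by_waist):
        taus = []
        for s in by_waist[waist]:
            try:
                taus.append(fit_zscan(s))
            except ZScanConcaveError:
                continue
        if len(taus) < min_vesicles:
            continue
        mean, sd = aggregate_vesicles(taus)
        points.append((waist**2, mean, sd))
    return fit_diffusion_law(points)


def classify_confinement(law: DiffusionLaw, alpha: float = 0.05) -> str:
    """Classify the diffusion mode from the diffusion-law intercept.

    t_0 indistinguishable from 0 -> "free"; significantly positive ->
    "domain_confined" (transient trapping in nanodomains); significantly
    negative -> "meshwork" (diffusion across barrier fences).

    The critical value is Student-t with the law fit's residual degrees of
    freedom (a diffusion law has only 5-6 waist points, so the normal
    quantile would be anti-conservative and break the alpha calibration).
    """
    if law.se_t0 <= 0:
        raise ValueError("se_t0 must be positive")
    dof = getattr(law, "dof", np.inf)
    if np.isfinite(dof) and dof > 0:
        crit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    if abs(law.t0) <= crit * law.se_t0:
        return "free"
    return "domain_confined" if law.t0 > 0 else "meshwork"
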