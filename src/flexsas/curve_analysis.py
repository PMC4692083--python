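"""Experimental-curve analysis: Guinier fits, P(r), extrapolation.

The low-Q expansion ln I(Q) = ln I(0) - Rg^2 Q^2 / 3 gives the radius of
gyration Rg and forward intensity I(0); it is valid to Q.Rg ~ 1.5.  For
elongated particles the cross-sectional expansion
ln[I(Q).Q] = [I(Q).Q]_{Q->0} - Rxs^2 Q^2 / 2 holds in two intermediate-Q
regions (denoted xs-1, steeper, and xs-2, flatter, for immunoglobulins).
The distance distribution function P(r) is obtained by a regularized
indirect Fourier transform of I(Q); its support limit L (Dmax) and peak
positions M1/M2 summarize the real-space shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .curves import ScatteringCurve

__all__ = [
    "GuinierResult",
    "CrossSectionResult",
    "PrResult",
    "guinier_fit",
    "cross_section_fit",
    "pr_transform",
    "extrapolate_to_zero_concentration",
    "difference_curve",
    "DEFAULT_WINDOWS",
]

#: default Q windows (1/nm) per contrast; instrument-specific, override freely
DEFAULT_WINDOWS = {
    "xray": {"rg": (0.13, 0.25), "xs1": (0.28, 0.51), "xs2": (0.56, 1.01)},
    "neutron": {"rg": (0.18, 0.28), "xs1": (0.28, 0.51), "xs2": (0.56, 1.04)},
}


def _weighted_linefit(x, y, w=None):
    """Weighted least-squares line y = a + b x; returns a, b, residual rms."""
    if w is None:
        w = np.ones_like(x)
    sw = np.sqrt(w)
    A = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
    a, b = coef
    resid = y - (a + b * x)
    rms = float(np.sqrt(np.average(resid**2, weights=w)))
    return float(a), float(b), rms


@dataclass
class GuinierResult:
    rg: float                   # nm
    i0: float
    window: tuple[float, float]
    max_qrg: float
    n_points: int
    residual_rms: float
    qrg_limit: float = 1.5

    @property
    def valid(self) -> bool:
        return self.max_qrg <= self.qrg_limit

    def summary(self) -> str:
        flag = "" if self.valid else "  [Q.Rg limit exceeded]"
        return (
            f"Guinier fit: Rg = {self.rg:.3f} nm, I(0) = {self.i0:.4g}, "
            f"window {self.window[0]:.2f}-{self.window[1]:.2f} 1/nm, "
            f"{self.n_points} pts, max Q.Rg = {self.max_qrg:.2f}{flag}"
        )


@dataclass
class CrossSectionResult:
    region: str                 # 'xs-1' | 'xs-2'
    rxs: float                  # nm
    intercept: float            # ln[I(Q).Q] at Q -> 0
    window: tuple[float, float]
    n_points: int
    residual_rms: float

    def summary(self) -> str:
        return (
            f"cross-section fit ({self.region}): Rxs = {self.rxs:.3f} nm, "
            f"window {self.window[0]:.2f}-{self.window[1]:.2f} 1/nm, "
            f"{self.n_points} pts"
        )


def guinier_fit(
    curve: ScatteringCurve,
    window: tuple[float, float] | None = None,
    qrg_limit: float = 1.5,
) -> GuinierResult:
    """Fit ln I vs Q^2 in ``window``; Rg = sqrt(-3 slope), I(0) = exp(a).

    Points with non-positive intensity are dropped with a warning; a
    non-negative slope (low-Q upturn, signalling aggregation) raises.
    Weights are 1/sigma_lnI^2 when the curve carries uncertainties.
    """
    if window is None:
        window = DEFAULT_WINDOWS[curve.contrast]["rg"]
    sub = curve.window(*window)
    keep = sub.i > 0
    if np.count_nonzero(~keep):
        warnings.warn("dropping non-positive intensities in Guinier window")
    q = sub.q[keep]
    i = sub.i[keep]
    if q.size < 3:
        raise ValueError("need >= 3 positive points inside the Guinier window")
    w = None
    if sub.sigma is not None:
        s = sub.sigma[keep]
        with np.errstate(divide="ignore"):
            w = np.where(s > 0, (i / np.where(s > 0, s, 1.0)) ** 2, 0.0)
        if not np.any(w > 0):
            w = None
    a, b, rms = _weighted_linefit(q**2, np.log(i), w)
    if b >= 0:
        raise ValueError(
            "non-negative Guinier slope: low-Q upturn suggests aggregation"
        )
    rg = float(np.sqrt(-3.0 * b))
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(a)),
        window=tuple(window),
        max_qrg=float(q.max() * rg),
        n_points=int(q.size),
        residual_rms=rms,
        qrg_limit=qrg_limit,
    )


def cross_section_fit(
    curve: ScatteringCurve,
    region: str = "xs-1",
    window: tuple[float, float] | None = None,
) -> CrossSectionResult:
    """Fit ln[I(Q).Q] vs Q^2 in ``window``; Rxs = sqrt(-2 slope)."""
    if region not in ("xs-1", "xs-2"):
        raise ValueError("region must be 'xs-1' or 'xs-2'")
    if window is None:
        key = "xs1" if region == "xs-1" else "xs2"
        window = DEFAULT_WINDOWS[curve.contrast][key]
    if window[0] < curve.q.min() - 1e-9 or window[1] > curve.q.max() + 1e-9:
        raise ValueError("window outside the measured Q range")
    sub = curve.window(*window)
    keep = sub.i > 0
    if np.count_nonzero(~keep):
        warnings.warn("dropping non-positive intensities in cross-section window")
    q = sub.q[keep]
    iq = sub.i[keep] * q
    if q.size < 3:
        raise ValueError("need >= 3 positive points inside the window")
    w = None
    if sub.sigma is not None:
        s = sub.sigma[keep]
        with np.errstate(divide="ignore"):
            w = np.where(s > 0, (sub.i[keep] / np.where(s > 0, s, 1.0)) ** 2, 0.0)
        if not np.any(w > 0):
            w = None
    a, b, rms = _weighted_linefit(q**2, np.log(iq), w)
    if b >= 0:
        raise ValueError("non-negative cross-section slope")
    return CrossSectionResult(
        region=region,
        rxs=float(np.sqrt(-2.0 * b)),
        intercept=a,
        window=tuple(window),
        n_points=int(q.size),
        residual_rms=rms,
    )


@dataclass
class PrResult:
    r: np.ndarray               # nm
    pr: np.ndarray              # per-nm density (arbitrary scale)
    dmax: float                 # input support limit, nm
    length: float               # L, smallest r beyond which |P| < 1% max
    rg: float                   # from the second moment of P(r)
    i0: float                   # forward intensity of the fit
    peaks: tuple[float, ...]    # M1 (, M2) positions, nm
    alpha: float                # regularization weight used
    fitted_i: np.ndarray        # forward-transformed fit on the input Q grid
    q: np.ndarray
    detail: dict = field(default_factory=dict)

    @property
    def m1(self) -> float | None:
        return self.peaks[0] if self.peaks else None

    @property
    def m2(self) -> float | None:
        return self.peaks[1] if len(self.peaks) > 1 else None

    def summary(self) -> str:
        pk = ", ".join(f"{p:.2f}" for p in self.peaks)
        return (
            f"P(r): L = {self.length:.2f} nm (dmax {self.dmax:.2f}), "
            f"Rg = {self.rg:.3f} nm, peaks at [{pk}] nm"
        )


def _pr_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    return sinc * (r[1] - r[0])


def _pr_solve(q, i, sigma, r, alpha):
    """Non-negative regularized solve for P(r) with P(0)=P(dmax)=0."""
    A = _pr_design(q, r)
    w = np.ones_like(i) if sigma is None else 1.0 / np.where(sigma > 0, sigma, 1.0)
    # normalize weights so alpha has a data-independent meaning
    w = w / w.mean()
    n = r.size
    D2 = np.zeros((n - 2, n))
    for k in range(n - 2):
        D2[k, k : k + 3] = (1.0, -2.0, 1.0)
    scale = np.abs(w * i).max()
    top = (w[:, None] * A) / scale
    rhs_top = (w * i) / scale
    bot = np.sqrt(alpha) * D2
    # endpoint constraint: drop the first/last basis functions entirely
    M = np.vstack([top, bot])[:, 1:-1]
    rhs = np.concatenate([rhs_top, np.zeros(n - 2)])
    sol, _ = nnls(M, rhs)
    p = np.zeros(n)
    p[1:-1] = sol
    p *= scale
    fitted = A @ p
    chi2 = float(np.sum((w * (i - fitted)) ** 2))
    return p, fitted, chi2


def pr_transform(
    curve: ScatteringCurve,
    dmax: float | None = None,
    grid_size: int = 101,
    alpha: float = 1e-3,
) -> PrResult:
    """Regularized indirect transform of I(Q) to the distance distribution.

    P(r) is expanded on ``grid_size`` points over [0, dmax] and fitted to
    I(Q) by non-negative least squares with a second-difference smoothness
    penalty (weight ``alpha``) and P(0) = P(dmax) = 0.  With ``dmax=None``
    an automatic scan looks for the smallest dmax on a stable chi^2
    plateau and fails if no plateau is found.

    Reported quantities: L (smallest r beyond which |P| stays under 1% of
    the maximum), Rg from the second moment, and up to two peak positions
    (M1, M2).
    """
    q, i = curve.q, curve.i
    sigma = curve.sigma
    if dmax is None:
        # scan: coarse geometric sweep, look for a chi^2 plateau
        guess = 3.5 / q.min()
        cands = np.linspace(0.4 * guess, 2.0 * guess, 13)
        chis = []
        for d in cands:
            r = np.linspace(0.0, d, grid_size)
            _, _, chi2 = _pr_solve(q, i, sigma, r, alpha)
            chis.append(chi2)
        chis = np.asarray(chis)
        best = chis.min()
        ok = np.where(chis <= 1.05 * best)[0]
        if ok.size < 2:
            raise ValueError(
                "dmax auto-scan found no stable plateau; supply dmax manually"
            )
        dmax = float(cands[ok[0]])
    if q.max() * dmax < np.pi * 2:
        raise ValueError("curve does not span enough Q to resolve dmax")
    r = np.linspace(0.0, float(dmax), grid_size)
    p, fitted, chi2 = _pr_solve(q, i, sigma, r, alpha)

    pmax = p.max()
    if pmax <= 0:
        raise ValueError("degenerate P(r): all-zero solution")
    # L: smallest r beyond which |P| stays below 1% of max
    below = np.abs(p) < 0.01 * pmax
    length = float(r[-1])
    for k in range(r.size):
        if below[k:].all() and k > np.argmax(p):
            length = float(r[k])
            break
    dr = r[1] - r[0]
    norm = np.trapezoid(p, r)
    rg = float(np.sqrt(np.trapezoid(p * r**2, r) / (2.0 * norm)))
    i0 = float(4.0 * np.pi * norm) if norm > 0 else 0.0
    idx, props = find_peaks(p, height=0.05 * pmax, prominence=0.02 * pmax)
    order = np.argsort(props["peak_heights"])[::-1][:2]
    peaks = tuple(sorted(float(r[j]) for j in idx[order]))
    return PrResult(
        r=r, pr=p, dmax=float(dmax), length=length, rg=rg, i0=i0,
        peaks=peaks, alpha=alpha, fitted_i=fitted, q=q,
        detail={"chi2": chi2, "dr": float(dr)},
    )


def extrapolate_to_zero_concentration(
    series: list[ScatteringCurve],
    resample: bool = False,
) -> ScatteringCurve:
    """Per-Q linear extrapolation of I(Q)/c to zero concentration.

    Each curve must carry a concentration; I(Q)/c is regressed on c at
    every Q and the intercept is returned (so the output is on the
    per-unit-concentration scale).  Curves must share a Q grid unless
    ``resample`` is set, in which case they are interpolated onto the
    overlap of the first curve's grid.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 concentrations to extrapolate")
    concs = []
    for c in series:
        if c.concentration is None or c.concentration <= 0:
            raise ValueError("every curve needs a positive concentration")
        concs.append(c.concentration)
    concs = np.asarray(concs)
    q0 = series[0].q
    same = all(len(c) == len(series[0]) and np.allclose(c.q, q0) for c in series)
    if not same:
        if not resample:
            raise ValueError("curves have mismatched Q grids; pass resample=True")
        lo = max(c.q.min() for c in series)
        hi = min(c.q.max() for c in series)
        q0 = q0[(q0 >= lo) & (q0 <= hi)]
        series = [c.interpolated(q0) for c in series]
    Y = np.stack([c.i / c.concentration for c in series])  # (ncurve, nq)
    # per-Q line fit y = a + b c by (weighted) normal equations; when every
    # curve carries uncertainties the intercept variance is propagated from
    # them, which is far more stable than a 2-dof residual estimate
    have_sigma = all(c.sigma is not None for c in series)
    if have_sigma:
        S = np.stack([c.sigma / c.concentration for c in series])
        W = 1.0 / np.where(S > 0, S, np.inf) ** 2
        if not np.all(W.sum(axis=0) > 0):
            have_sigma = False
    if not have_sigma:
        W = np.ones_like(Y)
    cvec = concs[:, None]
    A = W.sum(axis=0)
    B = (W * cvec).sum(axis=0)
    C = (W * cvec**2).sum(axis=0)
    D = (W * Y).sum(axis=0)
    E = (W * cvec * Y).sum(axis=0)
    det = A * C - B**2
    a = (C * D - B * E) / det
    b = (A * E - B * D) / det
    if have_sigma:
        var_a = C / det
    else:
        resid = Y - (a[None, :] + np.outer(concs, b))
        dof = max(concs.size - 2, 1)
        s2 = (resid**2).sum(axis=0) / dof
        var_a = s2 * C / det
    sig = np.sqrt(np.maximum(var_a, 0.0))
    return ScatteringCurve(q0, a, sig, contrast=series[0].contrast,
                           concentration=0.0)


def difference_curve(a: ScatteringCurve, b: ScatteringCurve) -> ScatteringCurve:
    """Pointwise a - b after matching b's forward intensity to a's.

    I(0) for the scale match comes from a Guinier fit over the default
    window when possible, else from the mean of the five lowest-Q points.
    Uncertainties combine in quadrature.
    """
    if len(a) != len(b) or not np.allclose(a.q, b.q):
        raise ValueError("curves must share a common Q grid")

    def _i0(c: ScatteringCurve) -> float:
        try:
            return guinier_fit(c).i0
        except ValueError:
            return float(c.i[:5].mean())

    scale = _i0(a) / _i0(b)
    diff = a.i - scale * b.i
    sig = None
    if a.sigma is not None and b.sigma is not None:
        sig = np.hypot(a.sigma, scale * b.sigma)
    return ScatteringCurve(a.q, diff + 0.0, sig, contrast=a.contrast)
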