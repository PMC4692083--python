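"""Theoretical scattering curves from sphere models and R-factor scoring.

The Debye equation adapted to N equal spheres of radius r:

    I(Q)/I(0) = g(Q) [ 1/N + (2/N^2) sum_d n(d) sin(Qd)/(Qd) ]

where g(Q) = [3 (sin Qr - Qr cos Qr)/(Qr)^3]^2 is the squared
single-sphere form factor and n(d) the histogram of inter-sphere
distances (bin width << cube side, default 0.05 nm).  Curves are
normalized to I(0) = 1.

Model-vs-experiment agreement uses the crystallographic-style R factor

    R = sum | |I_expt| - eta |I_theor| | / sum |I_expt| x 100

with each experimental point matched to the theoretical point of closest
Q and the scale factor eta determined by an iterative (golden-section)
search minimizing R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from .curves import ScatteringCurve
from .spheres import SphereModel

__all__ = [
    "FitResult",
    "sphere_form_factor",
    "debye_curve",
    "r_factor",
    "neutron_correction",
    "score_model",
]

#: default X-ray scoring range, 1/nm
DEFAULT_FIT_QMAX = 1.25


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Squared form factor of a uniform sphere, g(0) = 1."""
    x = np.asarray(q, dtype=float) * radius
    out = np.empty_like(x)
    small = np.abs(x) < 1e-2
    xs = x[small]
    # series for the amplitude avoids catastrophic cancellation at small x
    out[small] = (1.0 - xs**2 / 10.0 + xs**4 / 280.0) ** 2
    xn = x[~small]
    out[~small] = (3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn**3) ** 2
    return out


def debye_curve(
    spheres: SphereModel,
    q: np.ndarray,
    bin_width: float | None = 0.02,
) -> ScatteringCurve:
    """I(Q) of an equal-sphere model via the binned Debye sum.

    ``bin_width`` (nm) controls the pair-distance histogram; ``None``
    evaluates the exact O(N^2) double sum (slow beyond a few thousand
    spheres).  The curve is normalized to I(0) = 1.
    """
    q = np.asarray(q, dtype=float)
    n = len(spheres)
    if n < 1:
        raise ValueError("empty sphere model")
    g = sphere_form_factor(q, spheres.radius)
    if n == 1:
        return ScatteringCurve(q, g)
    d = pdist(spheres.centres)
    if bin_width is None:
        qd = np.outer(q, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qd > 0, np.sin(qd) / np.where(qd > 0, qd, 1.0), 1.0)
        s = sinc.sum(axis=1)
    else:
        nbin = max(int(np.ceil(d.max() / bin_width)), 1)
        rng = (0.0, nbin * bin_width)
        hist, edges = np.histogram(d, bins=nbin, range=rng)
        dsum, _ = np.histogram(d, bins=nbin, range=rng, weights=d)
        nz = hist > 0
        # per-bin mean distance: first-order binning error cancels
        mids = dsum[nz] / hist[nz]
        qd = np.outer(q, mids)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qd > 0, np.sin(qd) / np.where(qd > 0, qd, 1.0), 1.0)
        s = sinc @ hist[nz]
    i = g * (1.0 / n + (2.0 / n**2) * s)
    return ScatteringCurve(q, i)


@dataclass
class FitResult:
    model_id: str
    r_factor: float              # percent
    eta: float                   # scale, > 0
    rg: float | None = None      # model Rg, nm
    rxs1: float | None = None    # model Rxs-1, nm
    rxs2: float | None = None    # model Rxs-2, nm
    n_points: int = 0
    hydrated_volume: float | None = None

    def summary(self) -> str:
        parts = [f"model {self.model_id}: R = {self.r_factor:.2f}%",
                 f"eta = {self.eta:.4g}"]
        if self.rg is not None:
            parts.append(f"Rg = {self.rg:.3f} nm")
        if self.rxs1 is not None:
            parts.append(f"Rxs-1 = {self.rxs1:.3f} nm")
        if self.rxs2 is not None:
            parts.append(f"Rxs-2 = {self.rxs2:.3f} nm")
        return ", ".join(parts)


def r_factor(
    expt: ScatteringCurve,
    theor: ScatteringCurve,
    q_max: float = DEFAULT_FIT_QMAX,
    q_min: float | None = None,
    model_id: str = "",
) -> FitResult:
    """R factor between an experimental and a theoretical curve.

    Experimental points inside [q_min, q_max] are matched to the
    theoretical points with nearest Q; eta minimizes the absolute
    deviation sum (golden-section search bracketed around the forward-
    intensity ratio).
    """
    if q_min is None:
        q_min = float(expt.q.min())
    m = (expt.q >= q_min) & (expt.q <= q_max)
    qe, ie = expt.q[m], expt.i[m]
    if qe.size < 10:
        raise ValueError("fewer than 10 experimental points in the fit range")
    if qe.min() < theor.q.min() - 1e-9 or qe.max() > theor.q.max() + 1e-9:
        raise ValueError("theoretical curve does not cover the fit range")
    idx = np.searchsorted(theor.q, qe)
    idx = np.clip(idx, 1, len(theor) - 1)
    left = theor.q[idx - 1]
    right = theor.q[idx]
    idx = np.where(np.abs(qe - left) <= np.abs(right - qe), idx - 1, idx)
    it = theor.i[idx]

    ae = np.abs(ie)
    at = np.abs(it)
    denom = ae.sum()

    def cost(eta):
        return np.abs(ae - eta * at).sum() / denom * 100.0

    eta0 = ae.max() / max(at.max(), 1e-300)
    res = minimize_scalar(
        cost, bounds=(0.5 * eta0, 1.5 * eta0), method="bounded",
        options={"xatol": 1e-12 * max(eta0, 1.0)},
    )
    eta = float(res.x)
    return FitResult(
        model_id=model_id,
        r_factor=float(cost(eta)),
        eta=eta,
        n_points=int(qe.size),
    )


def neutron_correction(
    curve: ScatteringCurve,
    flat_fraction: float = 0.015,
    i0: float | None = None,
) -> ScatteringCurve:
    """Add a flat incoherent background of ``flat_fraction`` x I(0).

    Applied to theoretical neutron curves before scoring, to account for
    the proton content of the sample.  I(0) defaults to the first
    (lowest-Q) intensity.
    """
    if flat_fraction < 0:
        raise ValueError("flat_fraction must be >= 0")
    if i0 is None:
        i0 = float(curve.i[0])
    out = ScatteringCurve(
        curve.q, curve.i + flat_fraction * i0,
        curve.sigma, contrast=curve.contrast,
        concentration=curve.concentration,
    )
    return out


def score_model(
    spheres: SphereModel,
    expt: ScatteringCurve,
    q_max: float = DEFAULT_FIT_QMAX,
    model_id: str = "",
    flat_fraction: float = 0.0,
    windows=None,
) -> FitResult:
    """Debye curve + R factor + model size parameters in one call.

    The model Rg comes from the sphere coordinates (exact second
    moment); Rxs-1/Rxs-2 from cross-sectional Guinier fits to the
    theoretical curve in the standard windows.
    """
    from .curve_analysis import DEFAULT_WINDOWS, cross_section_fit

    theor = debye_curve(spheres, expt.q)
    if flat_fraction > 0:
        theor = neutron_correction(theor, flat_fraction)
    fit = r_factor(expt, theor, q_max=q_max, model_id=model_id)
    fit.rg = spheres.radius_of_gyration()
    win = windows or DEFAULT_WINDOWS[expt.contrast]
    for attr, region, key in (("rxs1", "xs-1", "xs1"), ("rxs2", "xs-2", "xs2")):
        try:
            setattr(fit, attr,
                    cross_section_fit(theor, region, win[key]).rxs)
        except ValueError:
            setattr(fit, attr, None)
    fit.hydrated_volume = spheres.volume if spheres.hydrated else None
    return fit
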