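"""Scattering-curve container and plain-text I/O.

A curve is a set of (Q, I, sigma) triples with optional contrast and
concentration metadata.  Q is in 1/nm throughout the package; files
recorded in 1/A are converted on input when flagged in the header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["ScatteringCurve", "read_curve", "write_curve"]


@dataclass
class ScatteringCurve:
    """One-dimensional scattering curve I(Q).

    Parameters
    ----------
    q : array
        Scattering vector, 1/nm, strictly increasing and positive.
    i : array
        Intensity, arbitrary units.
    sigma : array, optional
        Per-point uncertainty (same units as ``i``).
    contrast : {'xray', 'neutron'}
    concentration : float, optional
        Sample concentration in mg/ml.
    """

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    contrast: str = "xray"
    concentration: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.q.ndim != 1 or self.i.shape != self.q.shape:
            raise ValueError("q and i must be 1-d arrays of equal length")
        if np.any(self.q <= 0):
            raise ValueError("Q values must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")
        if self.contrast not in ("xray", "neutron"):
            raise ValueError(f"unknown contrast {self.contrast!r}")

    def __len__(self) -> int:
        return self.q.size

    def window(self, qmin: float, qmax: float) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= Q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        return replace(
            self,
            q=self.q[m],
            i=self.i[m],
            sigma=None if self.sigma is None else self.sigma[m],
        )

    def scaled(self, factor: float) -> "ScatteringCurve":
        return replace(
            self,
            q=self.q,
            i=self.i * factor,
            sigma=None if self.sigma is None else self.sigma * factor,
        )

    def interpolated(self, q: np.ndarray) -> "ScatteringCurve":
        """Linear re-sampling onto a new Q grid (within the curve's range)."""
        q = np.asarray(q, dtype=float)
        if q.min() < self.q.min() - 1e-12 or q.max() > self.q.max() + 1e-12:
            raise ValueError("target grid extends beyond the measured range")
        i = np.interp(q, self.q, self.i)
        s = None if self.sigma is None else np.interp(q, self.q, self.sigma)
        return replace(self, q=q, i=i, sigma=s)


def read_curve(path: str | Path, contrast: str = "xray",
               concentration: float | None = None) -> ScatteringCurve:
    """Read a 2- or 3-column whitespace/CSV curve file.

    Lines starting with ``#`` are treated as header; a header containing
    the token ``1/A`` (or ``A^-1``) declares angstrom units and Q is
    multiplied by 10.  Non-ascending rows are sorted; duplicated Q values
    are averaged, both with a warning.
    """
    path = Path(path)
    unit_scale = 1.0
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                low = s.lower()
                if "1/a" in low or "a^-1" in low or "angstrom" in low:
                    unit_scale = 10.0
                if "concentration" in low:
                    try:
                        concentration = float(low.split("=")[-1].split()[0])
                    except ValueError:
                        pass
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric data row") from exc
            if len(vals) < 2:
                raise ValueError(f"{path}:{ln}: need at least 2 columns")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0] * unit_scale
    order = np.argsort(q, kind="stable")
    if np.any(np.diff(q) <= 0):
        warnings.warn(f"{path}: Q not strictly ascending; sorting/averaging")
    q = q[order]
    arr = arr[order]
    uq, inv = np.unique(q, return_inverse=True)
    if uq.size != q.size:
        i = np.bincount(inv, weights=arr[:, 1]) / np.bincount(inv)
        sig = None
        if ncol >= 3:
            sig = np.bincount(inv, weights=arr[:, 2]) / np.bincount(inv)
    else:
        i = arr[:, 1]
        sig = arr[:, 2] if ncol >= 3 else None
        uq = q
    return ScatteringCurve(uq, i, sig, contrast=contrast,
                           concentration=concentration)


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3 (or 2) whitespace-separated columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Q(1/nm)  I(Q)  sigma\n")
        fh.write(f"# contrast = {curve.contrast}\n")
        if curve.concentration is not None:
            fh.write(f"# concentration = {curve.concentration} mg/ml\n")
        for k in range(len(curve)):
            if curve.sigma is None:
                fh.write(f"{curve.q[k]:.6e} {curve.i[k]:.6e}\n")
            else:
                fh.write(f"{curve.q[k]:.6e} {curve.i[k]:.6e} "
                         f"{curve.sigma[k]:.6e}\n")
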