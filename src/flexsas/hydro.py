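"""Sedimentation coefficients of sphere models (Kirkwood approximation).

For N equal beads of radius a, the Kirkwood double-sum estimate of the
translational frictional coefficient is

    f = N f_1 / (1 + (a / N) sum_{i != j} 1 / R_ij)

with f_1 = 6 pi eta0 a the single-bead Stokes friction.  The
sedimentation coefficient follows from the Svedberg relation
s = M (1 - vbar rho) / (N_A f), and the frictional ratio compares f with
f_0 = 6 pi eta0 r_0 of the sphere holding the same hydrated volume.
Standard-condition values (s0_20,w) use water at 20 degC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .constants import AVOGADRO, SOLVENTS
from .spheres import SphereModel

__all__ = ["SedimentationResult", "sedimentation_coefficient"]


@dataclass
class SedimentationResult:
    s: float                  # Svedberg (1e-13 s)
    f: float                  # g/s
    f0: float                 # g/s, equal-hydrated-volume sphere
    density: float            # g/ml
    viscosity: float          # poise

    @property
    def frictional_ratio(self) -> float:
        return self.f / self.f0

    def summary(self) -> str:
        return (
            f"s = {self.s:.2f} S, f/f0 = {self.frictional_ratio:.3f} "
            f"(rho = {self.density} g/ml, eta = {self.viscosity} P)"
        )


def surface_spheres(spheres: SphereModel) -> SphereModel:
    """Reduce a filled sphere model to its surface shell.

    A sphere is interior when it has six face-adjacent neighbours
    (within 1.1 cube sides); only surface spheres contribute to the
    hydrodynamic friction.  The Kirkwood sum over a filled body counts
    the many short interior pair distances and underestimates f; over
    the surface shell it converges to the Stokes value for a sphere.
    """
    from scipy.spatial import cKDTree

    if len(spheres) <= 6:
        return spheres
    tree = cKDTree(spheres.centres)
    d_nn, _ = tree.query(spheres.centres, k=2)
    spacing = float(np.median(d_nn[:, 1]))
    neigh = tree.query_ball_point(spheres.centres, 1.1 * spacing)
    nn = np.array([len(v) - 1 for v in neigh])
    keep = nn < 6
    if not keep.any():
        return spheres
    return SphereModel(spheres.centres[keep], spheres.cube_side,
                       hydrated=spheres.hydrated, origin=spheres.origin)


def kirkwood_friction(spheres: SphereModel, viscosity: float) -> float:
    """Kirkwood frictional coefficient, g/s (coordinates nm, eta poise)."""
    n = len(spheres)
    a_cm = spheres.radius * 1e-7          # nm -> cm
    f1 = 6.0 * np.pi * viscosity * a_cm
    if n == 1:
        return f1
    inv = 1.0 / (pdist(spheres.centres) * 1e-7)
    # pdist counts each unordered pair once; the double sum needs both orders
    return n * f1 / (1.0 + (a_cm / n) * 2.0 * inv.sum())


def sedimentation_coefficient(
    spheres: SphereModel,
    mass: float,
    vbar: float,
    solvent: str | dict = "water20",
    use_shell: bool = True,
) -> SedimentationResult:
    """s of a (hydrated) sphere model via Kirkwood + Svedberg.

    Parameters: ``mass`` in Da, ``vbar`` in ml/g; ``solvent`` a preset
    name from :data:`flexsas.constants.SOLVENTS` or a dict with
    ``density`` (g/ml) and ``viscosity`` (poise).  ``use_shell``
    restricts the Kirkwood sum to the surface spheres (see
    :func:`surface_spheres`); the equal-volume reference sphere for f0
    always uses the full model volume.  Raises when the buoyancy term
    1 - vbar rho is not positive.
    """
    if len(spheres) == 0:
        raise ValueError("empty sphere model")
    sol = SOLVENTS[solvent] if isinstance(solvent, str) else solvent
    rho, eta = sol["density"], sol["viscosity"]
    buoy = 1.0 - vbar * rho
    if buoy <= 0:
        raise ValueError("1 - vbar*rho <= 0: particle does not sediment")
    f = kirkwood_friction(surface_spheres(spheres) if use_shell else spheres,
                          eta)
    r0_cm = (3.0 * spheres.volume / (4.0 * np.pi)) ** (1.0 / 3.0) * 1e-7
    f0 = 6.0 * np.pi * eta * r0_cm
    s = mass * buoy / (AVOGADRO * f)      # seconds
    return SedimentationResult(s=s * 1e13, f=f, f0=f0,
                               density=rho, viscosity=eta)
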