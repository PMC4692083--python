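"""Synthetic ground-truth structures and noisy scattering data.

Builds toy antibody-like models -- two "Fab" pseudo-atom bodies joined to
a central "Fc" body by flexible backbone linkers -- and simulates
concentration series of noisy scattering curves with a small
concentration-linear dimer fraction, emulating the weak self-association
seen for serum antibodies.  Every dataset ships with its generating
ground truth so parameter-recovery tests can close the loop.

Pseudo-atoms are laid on a cubic lattice inside each body, so the models
are clash-free by construction and coarse-grain cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ScatteringCurve
from .debye import debye_curve
from .models import AtomisticModel, clash_check
from .peptide import build_backbone
from .spheres import SphereModel

__all__ = ["SyntheticSpec", "GroundTruth", "make_toy_antibody",
           "simulate_curve_series", "Q_GRID_XRAY", "Q_GRID_NEUTRON"]

#: X-ray preset grid: 441 points over 0.13-2.10 1/nm
Q_GRID_XRAY = np.linspace(0.13, 2.10, 441)
#: neutron preset grid: 45 points over 0.18-1.6 1/nm
Q_GRID_NEUTRON = np.linspace(0.18, 1.60, 45)


@dataclass
class SyntheticSpec:
    """Geometry, noise and association parameters of a toy dataset."""

    fab_semiaxes: tuple[float, float, float] = (2.40, 1.80, 1.40)  # nm
    fc_semiaxes: tuple[float, float, float] = (2.10, 1.70, 1.35)   # nm
    linker_residues: int = 21
    linker_phi: float = -60.0      # deg, starting hinge conformation
    linker_psi: float = -50.0
    arm_angle: float = 50.0        # deg, each arm from the vertical
    atom_spacing: float = 0.35     # nm, lattice inside the bodies
    concentrations: tuple[float, ...] = (0.25, 0.51, 0.76, 1.02)   # mg/ml
    dimer_slope: float = 0.03      # dimer mass fraction per mg/ml
    noise_a: float = 0.001         # sigma at Q->0, fraction of I(0)
    noise_triple: float = 3.0      # sigma growth factor across the Q range
    contrast: str = "xray"
    seed: int = 0

    def __post_init__(self):
        fmax = self.dimer_slope * max(self.concentrations)
        if not (0 <= fmax <= 0.2):
            raise ValueError("dimer fraction exceeds 20% over the series")
        if min(self.fab_semiaxes + self.fc_semiaxes) <= 0:
            raise ValueError("body sizes must be positive")


@dataclass
class GroundTruth:
    rg: float                       # monomer Rg, nm
    dmax: float                     # monomer maximum dimension, nm
    rg_dimer: float | None = None
    monomer_curve: ScatteringCurve | None = None
    dimer_curve: ScatteringCurve | None = None
    dimer_fractions: dict = field(default_factory=dict)   # conc -> f_d
    linker_dihedrals: dict = field(default_factory=dict)  # resid -> (phi, psi)


def _lattice_body(centre, semiaxes, spacing, chain, resid, name="PS"):
    """Pseudo-atoms on a cubic lattice inside an ellipsoid."""
    a, b, c = semiaxes
    nx = np.arange(-a, a + 1e-9, spacing)
    ny = np.arange(-b, b + 1e-9, spacing)
    nz = np.arange(-c, c + 1e-9, spacing)
    X, Y, Z = np.meshgrid(nx, ny, nz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = ((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2
              + (pts[:, 2] / c) ** 2) <= 1.0
    pts = pts[inside] - pts[inside].mean(axis=0) + np.asarray(centre)
    n = pts.shape[0]
    return AtomisticModel(
        pts,
        np.array(["C"] * n, dtype=object),
        np.array([name] * n, dtype=object),
        np.full(n, resid, dtype=int),
        np.array(["DUM"] * n, dtype=object),
        np.array([chain] * n, dtype=object),
        np.array(["core"] * n, dtype=object),
    )


def _oriented_linker(n_res, start, direction, chain, start_resid, segment,
                     phi=180.0, psi=180.0):
    """Ideal backbone (uniform phi/psi) with its CA axis along ``direction``."""
    m = build_backbone("G" * n_res, phi=np.full(n_res, phi),
                       psi=np.full(n_res, psi), chain=chain,
                       start_resid=start_resid, segment=segment, with_cb=False)
    ca = m.coords[m.name == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    v = np.cross(axis, d)
    s = np.linalg.norm(v)
    cth = float(axis @ d)
    if s < 1e-12:
        R = np.eye(3) if cth > 0 else -np.eye(3)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - cth) / s**2)
    out = m.copy()
    out.coords = (m.coords - ca[0]) @ R.T + np.asarray(start)
    return out


def make_toy_antibody(spec: SyntheticSpec) -> tuple[AtomisticModel, GroundTruth]:
    """Three-body toy antibody with two tagged flexible linkers.

    Chain layout (single chain "A", residues in order): Fab-1 body,
    linker-1 (tag ``hinge``), Fc body, linker-2 (tag ``hinge``), Fab-2
    body.  With ``linker_residues=0`` the bodies fuse into one rigid
    composite.  Deterministic given the spec.
    """
    sp = spec.atom_spacing
    th = np.deg2rad(spec.arm_angle)
    up1 = np.array([-np.sin(th), np.cos(th), 0.0])
    up2 = np.array([np.sin(th), np.cos(th), 0.0])
    n_res = spec.linker_residues
    if n_res > 1:
        probe = build_backbone("G" * n_res,
                               phi=np.full(n_res, spec.linker_phi),
                               psi=np.full(n_res, spec.linker_psi),
                               with_cb=False)
        ca = probe.coords[probe.name == "CA"]
        linker_span = float(np.linalg.norm(ca[-1] - ca[0]))
    else:
        linker_span = 0.0
    fc_r = max(spec.fc_semiaxes)
    fab_r = max(spec.fab_semiaxes)
    gap = 0.45  # body surface to linker terminus, nm

    parts = []
    resid = 1
    if n_res == 0:
        body = _lattice_body((0.0, 0.0, 0.0),
                             tuple(np.add(spec.fab_semiaxes, 0)), sp, "A", 1)
        truth = GroundTruth(rg=body.radius_of_gyration(),
                            dmax=_max_dim(body.coords))
        return body, truth

    # Fc at the origin; arms radiate upward
    start1 = up1 * (fc_r + gap)
    link1 = _oriented_linker(n_res, start1 + up1 * linker_span, -up1,
                             "A", 0, "hinge",
                             spec.linker_phi, spec.linker_psi)
    fab1_centre = start1 + up1 * (linker_span + gap + fab_r)
    fab1 = _lattice_body(fab1_centre, spec.fab_semiaxes, sp, "A", 0)

    start2 = up2 * (fc_r + gap)
    link2 = _oriented_linker(n_res, start2, up2, "A", 0, "hinge",
                             spec.linker_phi, spec.linker_psi)
    fab2_centre = start2 + up2 * (linker_span + gap + fab_r)
    fab2 = _lattice_body(fab2_centre, spec.fab_semiaxes, sp, "A", 0)
    fc = _lattice_body((0.0, 0.0, 0.0), spec.fc_semiaxes, sp, "A", 0)

    # stitch with increasing residue numbers: Fab1, link1, Fc, link2, Fab2
    def renum(m, r0):
        out = m.copy()
        out.resid = out.resid - out.resid.min() + r0
        return out, int(out.resid.max()) + 1

    fab1, resid = renum(fab1, 1)
    link1, resid = renum(link1, resid)
    fc, resid = renum(fc, resid)
    link2, resid = renum(link2, resid)
    fab2, resid = renum(fab2, resid)
    model = AtomisticModel.concatenate([fab1, link1, fc, link2, fab2])
    if not clash_check(model):
        raise ValueError("toy-antibody bodies overlap at build time")
    dihedrals = {int(r): (spec.linker_phi, spec.linker_psi)
                 for r in np.unique(model.resid[model.segment == "hinge"])}
    truth = GroundTruth(
        rg=model.radius_of_gyration(),
        dmax=_max_dim(model.coords),
        linker_dihedrals=dihedrals,
    )
    return model, truth


def _max_dim(coords: np.ndarray) -> float:
    from scipy.spatial import ConvexHull
    from scipy.spatial.distance import pdist

    if coords.shape[0] > 400:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:
            pass
    return float(pdist(coords).max())


def _model_spheres(model: AtomisticModel, spacing: float) -> SphereModel:
    return SphereModel(model.coords, spacing)


def build_dimer(model: AtomisticModel, step: float = 0.1) -> AtomisticModel:
    """Side-by-side C2 duplicate at the minimal non-clashing separation."""
    width = model.coords[:, 0].max() - model.coords[:, 0].min()
    copy = model.copy()
    copy.chain = np.array(["D"] * len(model), dtype=object)
    shift = width + 0.25
    while True:
        trial = AtomisticModel.concatenate(
            [model, copy.translated((shift, 0.0, 0.0))]
        )
        if clash_check(trial):
            return trial
        shift += step


def simulate_curve_series(
    model: AtomisticModel,
    spec: SyntheticSpec,
) -> tuple[list[ScatteringCurve], GroundTruth]:
    """Noisy concentration series with a concentration-linear dimer blend.

    At concentration c the per-unit-concentration intensity is
    (1 - f_d) I_mono + f_d I_dimer with f_d = slope * c, both curves
    normalized to monomer I(0) = 1 (the dimer scatters forward twice as
    strongly per unit mass).  Gaussian noise sigma(Q) = a + b Q grows by
    ``noise_triple`` across the grid.  Seeded and reproducible.
    """
    q = Q_GRID_XRAY if spec.contrast == "xray" else Q_GRID_NEUTRON
    spheres = _model_spheres(model, spec.atom_spacing)
    mono = debye_curve(spheres, q)
    dimer_model = build_dimer(model)
    dimer = debye_curve(_model_spheres(dimer_model, spec.atom_spacing), q)
    truth = GroundTruth(
        rg=model.radius_of_gyration(),
        dmax=_max_dim(model.coords),
        rg_dimer=dimer_model.radius_of_gyration(),
        monomer_curve=mono,
        dimer_curve=dimer,
    )
    curves = []
    a = spec.noise_a
    b = a * (spec.noise_triple - 1.0) / (q.max() - q.min())
    for j, c in enumerate(spec.concentrations):
        f_d = spec.dimer_slope * c
        truth.dimer_fractions[c] = f_d
        # dimer forward scattering is 2x per unit mass
        i = c * ((1.0 - f_d) * mono.i + 2.0 * f_d * dimer.i)
        sigma = c * (a + b * (q - q.min()))
        rng = np.random.default_rng([spec.seed % (2**31), j])
        noisy = i + rng.normal(0.0, 1.0, q.size) * sigma
        curves.append(
            ScatteringCurve(q, noisy, sigma, contrast=spec.contrast,
                            concentration=c)
        )
    return curves, truth
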