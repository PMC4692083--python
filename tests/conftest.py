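"""Shared fixtures: synthetic datasets and analytic reference curves."""

from __future__ import annotations

import numpy as np
import pytest

import flexsas as fx
from flexsas.debye import sphere_form_factor


def make_lattice_ball(radius=3.66, spacing=0.20):
    """Dense pseudo-atom ball (used as a coarse-graining target)."""
    from flexsas.models import AtomisticModel

    g = np.arange(-radius - 0.2, radius + 0.2, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[(pts**2).sum(axis=1) <= radius**2]
    n = len(pts)
    return AtomisticModel(
        pts,
        np.array(["C"] * n, dtype=object),
        np.array(["PS"] * n, dtype=object),
        np.arange(n),
        np.array(["DUM"] * n, dtype=object),
        np.array(["A"] * n, dtype=object),
        np.array(["core"] * n, dtype=object),
    )


@pytest.fixture(scope="session")
def toy_dataset():
    """Default toy antibody + noisy concentration series (seed 7)."""
    spec = fx.SyntheticSpec(seed=7)
    model, _ = fx.make_toy_antibody(spec)
    curves, truth = fx.simulate_curve_series(model, spec)
    return spec, model, curves, truth


@pytest.fixture(scope="session")
def iga1_composition():
    from flexsas.data import iga1

    return fx.compute_composition(iga1.iga1_chains(), iga1.iga1_glycans())


def exact_sphere_curve(radius=5.0, qmax=2.5, n=400, i0=1.0):
    """Closed-form solid-sphere scattering curve."""
    q = np.linspace(0.02, qmax, n)
    return fx.ScatteringCurve(q, i0 * sphere_form_factor(q, radius))


def exact_cylinder_curve(rc=2.0, length=200.0, qmin=0.02, qmax=1.2, n=500):
    """Numerically orientation-averaged cylinder curve (long rod)."""
    from scipy.special import j1

    q = np.linspace(qmin, qmax, n)
    alpha = np.linspace(1e-4, np.pi / 2, 4000)
    qa = q[:, None]
    arg_l = qa * (length / 2) * np.cos(alpha)[None, :]
    arg_r = qa * rc * np.sin(alpha)[None, :]
    f = (np.sin(arg_l) / arg_l) * (2 * j1(arg_r) / arg_r)
    i = np.trapezoid(f**2 * np.sin(alpha)[None, :], alpha, axis=1)
    return fx.ScatteringCurve(q, i / i[0])
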