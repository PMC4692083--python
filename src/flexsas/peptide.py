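"""Ideal-geometry peptide backbone construction.

Backbones are built from ideal bond lengths/angles (see
:mod:`flexsas.constants`) with trans peptide bonds, by sequential
internal-coordinate (NeRF) placement.  Atoms generated per residue are
N, CA, C and, for non-glycine residues, CB.  Units: nm (internal tables
are in A and converted on output).
"""

from __future__ import annotations

import numpy as np

from .constants import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
)
from .models import AtomisticModel

__all__ = [
    "place_atom",
    "build_backbone",
    "measure_dihedral",
    "trans_ca_ca_distance",
    "hinge_maximum_span",
]

_BOND_CA_CB = 1.530
_ANGLE_N_C_CA_CB = 122.55   # improper dihedral N-C-CA-CB, deg
_ANGLE_C_CA_CB = 110.5


def place_atom(a, b, c, bond, angle, dihedral):
    """Place atom d with |cd| = bond, angle(b,c,d), dihedral(a,b,c,d).

    Angles in degrees, distances in the units of the inputs (NeRF).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.deg2rad(angle)
    tor = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.rad2deg(np.arctan2(m1 @ n2, n1 @ n2)))


def build_backbone(
    sequence: str,
    phi=None,
    psi=None,
    chain: str = "A",
    start_resid: int = 1,
    segment: str = "core",
    with_cb: bool = True,
) -> AtomisticModel:
    """Build an ideal-geometry backbone (N, CA, C [, CB]) in nm.

    ``phi``/``psi`` are per-residue arrays in degrees (default 180, the
    fully extended conformation).  phi of the first residue and psi of
    the last are undefined and ignored.
    """
    n = len(sequence)
    if n < 1:
        raise ValueError("empty sequence")
    phi = np.full(n, 180.0) if phi is None else np.asarray(phi, dtype=float)
    psi = np.full(n, 180.0) if psi is None else np.asarray(psi, dtype=float)
    if phi.shape != (n,) or psi.shape != (n,):
        raise ValueError("phi/psi must have one entry per residue")

    coords = []   # in A during construction
    names = []
    resids = []
    # residue 0 seed atoms
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    def _emit(resi, N, CA, C, aa):
        coords.extend([N, CA, C])
        names.extend(["N", "CA", "C"])
        resids.extend([resi] * 3)
        if with_cb and aa != "G":
            cb = place_atom(N, C, CA, _BOND_CA_CB, _ANGLE_C_CA_CB,
                            _ANGLE_N_C_CA_CB)
            coords.append(cb)
            names.append("CB")
            resids.append(resi)

    _emit(start_resid, N, CA, C, sequence[0])
    prevN, prevCA, prevC = N, CA, C
    for k in range(1, n):
        # next N from psi(k-1); CA via trans omega; C via phi(k)
        Nk = place_atom(prevN, prevCA, prevC, BOND_C_N, ANGLE_CA_C_N, psi[k - 1])
        CAk = place_atom(prevCA, prevC, Nk, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        Ck = place_atom(prevC, Nk, CAk, BOND_CA_C, ANGLE_N_CA_C, phi[k])
        _emit(start_resid + k, Nk, CAk, Ck, sequence[k])
        prevN, prevCA, prevC = Nk, CAk, Ck

    coords = np.asarray(coords) / 10.0   # A -> nm
    na = len(names)
    resnames = np.array(
        [sequence[r - start_resid] for r in resids], dtype=object
    )
    return AtomisticModel(
        coords,
        np.array(["C" if nm != "N" else "N" for nm in names], dtype=object),
        np.array(names, dtype=object),
        np.array(resids, dtype=int),
        resnames,
        np.array([chain] * na, dtype=object),
        np.array([segment] * na, dtype=object),
    )


def trans_ca_ca_distance() -> float:
    """CA-CA distance across one trans peptide bond, nm.

    Fixed by the ideal bond lengths and angles (independent of phi/psi
    for a trans peptide); computed from a two-residue build.
    """
    m = build_backbone("GG", with_cb=False)
    ca = m.coords[m.name == "CA"]
    return float(np.linalg.norm(ca[1] - ca[0]))


def hinge_maximum_span(n_residues: int) -> float:
    """Geometric upper bound on the CA(first)-CA(last) span, nm.

    The CA-CA virtual bond across a trans peptide has fixed length, so a
    segment of n residues can never span more than (n - 1) such bonds
    laid collinearly.  This is the "maximum length" of a flexible
    segment; any realizable set of dihedrals gives a shorter span.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    return (n_residues - 1) * trans_ca_ca_distance()
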