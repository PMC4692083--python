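"""Atomistic model container and rigid-body utilities.

Coordinates are in nm throughout.  Atoms carry element, atom name,
residue id, chain id and a segment tag; the tag marks the flexible parts
(``hinge``, ``tailpiece``, ``N-glycan``, ``O-glycan``) against the rigid
``core``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["AtomisticModel", "kabsch", "clash_check"]

SEGMENT_TAGS = ("core", "hinge", "tailpiece", "N-glycan", "O-glycan")


@dataclass
class AtomisticModel:
    coords: np.ndarray                     # (N, 3) nm
    element: np.ndarray                    # (N,) str
    name: np.ndarray                       # (N,) atom names
    resid: np.ndarray                      # (N,) int
    resname: np.ndarray                    # (N,) str
    chain: np.ndarray                      # (N,) str
    segment: np.ndarray                    # (N,) tag str
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        for attr in ("element", "name", "resname", "chain", "segment"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
            if getattr(self, attr).shape != (n,):
                raise ValueError(f"{attr} must have length {n}")
        self.resid = np.asarray(self.resid, dtype=int)
        if self.resid.shape != (n,):
            raise ValueError("resid must match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "AtomisticModel":
        return AtomisticModel(
            self.coords.copy(), self.element.copy(), self.name.copy(),
            self.resid.copy(), self.resname.copy(), self.chain.copy(),
            self.segment.copy(), list(self.disulfides), dict(self.meta),
        )

    def mask(self, chain=None, resid=None, name=None, segment=None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= np.isin(self.chain, np.atleast_1d(chain))
        if resid is not None:
            m &= np.isin(self.resid, np.atleast_1d(resid))
        if name is not None:
            m &= np.isin(self.name, np.atleast_1d(name))
        if segment is not None:
            m &= np.isin(self.segment, np.atleast_1d(segment))
        return m

    def select(self, **kw) -> "AtomisticModel":
        m = self.mask(**kw)
        return AtomisticModel(
            self.coords[m], self.element[m], self.name[m], self.resid[m],
            self.resname[m], self.chain[m], self.segment[m],
            list(self.disulfides), dict(self.meta),
        )

    def translated(self, shift) -> "AtomisticModel":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, dtype=float)
        return out

    def rotated(self, R, about=None) -> "AtomisticModel":
        out = self.copy()
        about = np.zeros(3) if about is None else np.asarray(about, dtype=float)
        out.coords = (out.coords - about) @ np.asarray(R).T + about
        return out

    @staticmethod
    def concatenate(parts: list["AtomisticModel"]) -> "AtomisticModel":
        return AtomisticModel(
            np.vstack([p.coords for p in parts]),
            np.concatenate([p.element for p in parts]),
            np.concatenate([p.name for p in parts]),
            np.concatenate([p.resid for p in parts]),
            np.concatenate([p.resname for p in parts]),
            np.concatenate([p.chain for p in parts]),
            np.concatenate([p.segment for p in parts]),
            sum((p.disulfides for p in parts), []),
            {},
        )

    def radius_of_gyration(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum(axis=1).mean()))


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns (R, t, rmsd) with x' = x @ R.T + t.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2:
        raise ValueError("point sets must have identical (n, 3) shapes")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    rmsd = float(np.sqrt(((P @ R.T + t - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def clash_check(
    model: AtomisticModel,
    cutoff: float = 0.22,
    return_pairs: bool = False,
):
    """Steric-overlap test between non-bonded heavy atoms.

    A pair clashes when closer than ``cutoff`` (nm) and either on
    different chains or separated by more than one residue on the same
    chain (a proxy for >= 3 covalent bonds along the backbone).  Glycan
    atoms are exempt against their own attachment residue.

    Returns a bool (clash-free) or, with ``return_pairs``, the list of
    offending atom-index pairs.
    """
    if len(model) == 0:
        return (True, []) if return_pairs else True
    tree = cKDTree(model.coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    bad = []
    for i, j in pairs:
        if model.chain[i] == model.chain[j]:
            if abs(int(model.resid[i]) - int(model.resid[j])) <= 1:
                continue
            gi = model.segment[i] in ("N-glycan", "O-glycan")
            gj = model.segment[j] in ("N-glycan", "O-glycan")
            if gi != gj and model.resid[i] == model.resid[j]:
                continue
        bad.append((int(i), int(j)))
    ok = not bad
    return (ok, bad) if return_pairs else ok
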