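"""Monte-Carlo dihedral sampling and combinatorial conformer attachment.

Trial full-length structures are generated by randomizing the backbone
phi/psi angles of tagged flexible segments (each move a uniform draw
within a per-residue maximum step from the previous accepted value),
rotating everything C-terminal of the pivot rigidly, and rejecting
sterically clashing models.  Rigid conformer libraries (e.g. alternative
glycan or tailpiece structures) are attached combinatorially by
least-squares superposition onto anchor atoms, multiplying the ensemble
size by the library size.

Randomness uses independent per-model streams keyed on (seed, model
index), so ensembles are reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import AtomisticModel, clash_check, kabsch

__all__ = [
    "FlexibleSegmentSpec",
    "ConformerLibraryEntry",
    "EnsembleRecord",
    "sample_hinge",
    "attach_conformers",
    "add_o_glycans",
]

DEFAULT_CLASH_CUTOFF = 0.22   # nm, steric minimum between heavy atoms


@dataclass(frozen=True)
class FlexibleSegmentSpec:
    """One flexible segment: residue range plus per-move step limits."""

    chain: str
    resid_start: int
    resid_stop: int            # inclusive
    max_phi_step: float = 10.0  # deg
    max_psi_step: float = 30.0  # deg

    def __post_init__(self):
        if self.max_phi_step < 0 or self.max_psi_step < 0:
            raise ValueError("step limits must be >= 0")
        if self.resid_stop < self.resid_start:
            raise ValueError("empty residue range")


@dataclass
class ConformerLibraryEntry:
    """A rigid fragment plus the anchor atoms used for superposition."""

    label: str
    fragment: AtomisticModel
    anchor_names: tuple[str, ...] = ("N", "CA", "C")
    anchor_resid: int | None = None
    anchor_chain: str | None = None


@dataclass
class EnsembleRecord:
    model_id: str
    moves: list = field(default_factory=list)   # (chain, resid, dphi, dpsi)
    labels: tuple[str, ...] = ()
    clash_free: bool = True


def _axis_rotation(axis_from, axis_to, angle_deg):
    """Rotation matrix for ``angle_deg`` about the axis through two points."""
    axis = np.asarray(axis_to) - np.asarray(axis_from)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _rotate_downstream(model, chain, pivot_idx, axis_a, axis_b, angle):
    """Rotate all same-chain atoms after ``pivot_idx`` about the bond axis."""
    R = _axis_rotation(axis_a, axis_b, angle)
    sel = (model.chain == chain) & (np.arange(len(model)) > pivot_idx)
    model.coords[sel] = (model.coords[sel] - axis_a) @ R.T + axis_a


def _backbone_index(model, chain, resid, name):
    idx = np.where(
        (model.chain == chain) & (model.resid == resid) & (model.name == name)
    )[0]
    if idx.size != 1:
        raise ValueError(f"backbone atom {name} of {chain}:{resid} not unique")
    return int(idx[0])


def apply_dihedral_moves(model: AtomisticModel, moves) -> AtomisticModel:
    """Apply (chain, resid, dphi, dpsi) perturbations C-terminal-ward."""
    out = model.copy()
    for chain, resid, dphi, dpsi in moves:
        iN = _backbone_index(out, chain, resid, "N")
        iCA = _backbone_index(out, chain, resid, "CA")
        iC = _backbone_index(out, chain, resid, "C")
        if dphi:
            _rotate_downstream(out, chain, iCA, out.coords[iN],
                               out.coords[iCA], dphi)
        if dpsi:
            _rotate_downstream(out, chain, iC, out.coords[iCA],
                               out.coords[iC], dpsi)
    return out


def sample_hinge(
    model: AtomisticModel,
    specs: list[FlexibleSegmentSpec],
    n_models: int,
    seed: int = 0,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    policy: str = "redraw",
    max_tries: int = 200,
):
    """Generate an ensemble by a dihedral random walk over flexible segments.

    The sampler is a Markov chain: every residue listed in ``specs``
    receives uniform phi/psi perturbations (within its step limits) from
    the previous accepted model, so conformational diversity accumulates
    along the chain.  Downstream atoms move rigidly; bond lengths and
    angles are untouched.  Clashing models are redrawn
    (``policy='redraw'``) or discarded (``policy='discard'``).  Aborts
    when the acceptance rate over a window falls below 1%.  Draws are
    keyed on (seed, model index), so a given seed reproduces the chain
    exactly.

    Returns (list of AtomisticModel, list of EnsembleRecord).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if policy not in ("redraw", "discard"):
        raise ValueError("policy must be 'redraw' or 'discard'")
    residues = [
        (s.chain, r, s.max_phi_step, s.max_psi_step)
        for s in specs
        for r in range(s.resid_start, s.resid_stop + 1)
    ]
    models, records = [], []
    tries = accepted = 0
    current = model   # Markov chain: each model continues from the last
    for k in range(n_models):
        rng = np.random.default_rng([int(seed) % (2**31), k])
        got = False
        for attempt in range(max_tries):
            tries += 1
            moves = [
                (c, r, float(rng.uniform(-mp, mp)), float(rng.uniform(-ms, ms)))
                for c, r, mp, ms in residues
            ]
            trial = apply_dihedral_moves(current, moves)
            if clash_check(trial, clash_cutoff):
                accepted += 1
                models.append(trial)
                records.append(EnsembleRecord(model_id=f"m{k:06d}",
                                              moves=moves))
                current = trial
                got = True
                break
            if policy == "discard":
                break
            if tries >= 100 and accepted / tries < 0.01:
                raise RuntimeError(
                    f"acceptance rate {accepted}/{tries} fell below 1%; "
                    f"loosen the clash cutoff or reduce step sizes"
                )
        if not got and policy == "redraw":
            raise RuntimeError(
                f"no clash-free model found in {max_tries} tries for m{k:06d}"
            )
    return models, records


def attach_conformers(
    ensemble: list[AtomisticModel],
    records: list[EnsembleRecord],
    library: list[ConformerLibraryEntry],
    max_residual: float = 0.05,
):
    """Cartesian product of an ensemble with a rigid conformer library.

    Each library fragment is least-squares superposed onto the matching
    anchor atoms of every model (atoms matched by chain/resid/name) and
    appended; the output ensemble has len(ensemble) x len(library)
    entries.  Fragments whose anchor superposition residual exceeds
    ``max_residual`` (nm RMSD) are skipped with a warning.
    """
    if not library:
        raise ValueError("empty conformer library")
    out_models, out_records = [], []
    for model, rec in zip(ensemble, records):
        for entry in library:
            frag = entry.fragment
            am = np.zeros(len(frag), dtype=bool)
            for nm in entry.anchor_names:
                m = frag.name == nm
                if entry.anchor_resid is not None:
                    m &= frag.resid == entry.anchor_resid
                am |= m
            if not am.any():
                raise ValueError(f"library entry {entry.label}: no anchor atoms")
            target_idx = []
            ok = True
            for j in np.where(am)[0]:
                cand = np.where(
                    (model.name == frag.name[j])
                    & (model.resid == frag.resid[j])
                    & (
                        model.chain == (entry.anchor_chain or frag.chain[j])
                    )
                )[0]
                if cand.size != 1:
                    ok = False
                    break
                target_idx.append(int(cand[0]))
            if not ok:
                warnings.warn(
                    f"{entry.label}: anchors missing in model {rec.model_id}; skipped"
                )
                continue
            R, t, rmsd = kabsch(frag.coords[am], model.coords[target_idx])
            if rmsd > max_residual:
                warnings.warn(
                    f"{entry.label}: anchor residual {rmsd:.3f} nm "
                    f"> {max_residual}; skipped"
                )
                continue
            placed = frag.copy()
            placed.coords = frag.coords @ R.T + t
            keep = ~am   # anchors already exist in the host
            placed = AtomisticModel(
                placed.coords[keep], placed.element[keep], placed.name[keep],
                placed.resid[keep], placed.resname[keep], placed.chain[keep],
                placed.segment[keep],
            )
            combo = AtomisticModel.concatenate([model, placed])
            out_models.append(combo)
            out_records.append(
                EnsembleRecord(
                    model_id=f"{rec.model_id}:{entry.label}",
                    moves=list(rec.moves),
                    labels=tuple(rec.labels) + (entry.label,),
                    clash_free=rec.clash_free,
                )
            )
    return out_models, out_records


def add_o_glycans(
    model: AtomisticModel,
    sites: list[tuple[str, int]],
    template: AtomisticModel,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    check_clashes: bool = True,
) -> AtomisticModel:
    """Attach an O-glycan template at hinge Ser/Thr sites.

    ``template`` holds the linked residue's backbone + CB (atoms named
    N, CA, C, CB, any resid) plus the sugar atoms (segment 'O-glycan').
    The backbone + CB of the template are superposed on each site and
    only the sugar atoms are added.  Sites must be Ser/Thr with a CB
    present.  Returns a new model; with ``check_clashes`` the grown model
    must stay clash-free.
    """
    anchor_names = ("N", "CA", "C", "CB")
    am = np.isin(template.name, anchor_names) & (template.segment != "O-glycan")
    if am.sum() != 4:
        raise ValueError("template must carry exactly one N/CA/C/CB anchor set")
    sugar = template.segment == "O-glycan"
    if not sugar.any():
        raise ValueError("template has no O-glycan atoms")
    out = model.copy()
    added = []
    next_resid = int(model.resid.max()) + 1
    # anchor template coords ordered by name for a stable correspondence
    t_order = [int(np.where(am & (template.name == nm))[0][0])
               for nm in anchor_names]
    for chain, resid in sites:
        rn = model.resname[(model.chain == chain) & (model.resid == resid)]
        if rn.size == 0:
            raise ValueError(f"site {chain}:{resid} not in model")
        if str(rn[0]).upper() not in ("S", "T", "SER", "THR"):
            raise ValueError(f"site {chain}:{resid} is not Ser/Thr")
        try:
            site_idx = [
                _backbone_index(model, chain, resid, nm) for nm in anchor_names
            ]
        except ValueError as exc:
            raise ValueError(
                f"site {chain}:{resid}: missing backbone/CB atom"
            ) from exc
        R, t, _ = kabsch(template.coords[t_order], model.coords[site_idx])
        sug = template.coords[sugar] @ R.T + t
        ns = int(sugar.sum())
        added.append(
            AtomisticModel(
                sug,
                template.element[sugar].copy(),
                template.name[sugar].copy(),
                np.full(ns, next_resid, dtype=int),
                template.resname[sugar].copy(),
                np.array([chain] * ns, dtype=object),
                np.array(["O-glycan"] * ns, dtype=object),
            )
        )
        next_resid += 1
    if not added:
        return out
    out = AtomisticModel.concatenate([out] + added)
    if check_clashes and not clash_check(out, clash_cutoff):
        warnings.warn("O-glycan decoration introduced steric clashes")
    return out
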