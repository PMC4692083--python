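"""PDB reading/writing (gemmi-backed) and sphere-model files.

PDB files are in angstroms; models are converted to nm on input and
written back in A.  Segment tags (hinge/tailpiece/glycans) are applied
from a configuration mapping of chain -> residue ranges since PDB files
do not carry them.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .models import AtomisticModel
from .spheres import SphereModel

__all__ = ["read_pdb", "write_pdb", "write_sphere_pdb", "write_sphere_xyz",
           "read_sphere_xyz", "apply_segment_tags"]


def read_pdb(path: str | Path, segments: dict | None = None,
             hydrogens: bool = False) -> AtomisticModel:
    """Read the first model of a PDB file into an AtomisticModel (nm).

    Only the first altloc of each atom site is kept; HETATM records
    (glycans, ligands) are included.  ``segments`` optionally maps tags
    to ``{chain: [(start, stop), ...]}`` residue ranges, applied via
    :func:`apply_segment_tags`.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    coords, elem, name, resid, resname, chain = [], [], [], [], [], []
    for ch in model:
        for res in ch:
            seen = set()
            for atom in res:
                if not hydrogens and atom.element.is_hydrogen:
                    continue
                if atom.name in seen:   # keep first altloc only
                    continue
                seen.add(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elem.append(atom.element.name)
                name.append(atom.name)
                resid.append(res.seqid.num)
                resname.append(res.name)
                chain.append(ch.name)
    if not coords:
        raise ValueError(f"{path}: no atoms read")
    m = AtomisticModel(
        np.asarray(coords) / 10.0,
        np.array(elem, dtype=object),
        np.array(name, dtype=object),
        np.array(resid, dtype=int),
        np.array(resname, dtype=object),
        np.array(chain, dtype=object),
        np.array(["core"] * len(coords), dtype=object),
    )
    if segments:
        apply_segment_tags(m, segments)
    return m


def apply_segment_tags(model: AtomisticModel, segments: dict) -> None:
    """Tag residue ranges in place: {tag: {chain: [(start, stop), ...]}}."""
    for tag, chains in segments.items():
        for chain, ranges in chains.items():
            for start, stop in ranges:
                sel = (
                    (model.chain == chain)
                    & (model.resid >= int(start))
                    & (model.resid <= int(stop))
                )
                model.segment[sel] = tag


def write_pdb(model: AtomisticModel, path: str | Path) -> None:
    """Write a model as PDB (coordinates nm -> A, numbering preserved)."""
    with open(path, "w") as fh:
        serial = 0
        for k in range(len(model)):
            serial += 1
            x, y, z = model.coords[k] * 10.0
            nm = str(model.name[k])[:4]
            rn = str(model.resname[k])[:3]
            ch = str(model.chain[k])[:1]
            el = str(model.element[k])[:2]
            fh.write(
                f"ATOM  {serial % 100000:5d} {nm:<4s}{rn:>4s} {ch}"
                f"{int(model.resid[k]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
            )
        fh.write("END\n")


def write_sphere_pdb(spheres: SphereModel, path: str | Path) -> None:
    """Sphere model as dummy-atom PDB (one C1 pseudo-atom per sphere)."""
    with open(path, "w") as fh:
        fh.write(f"REMARK cube_side {spheres.cube_side:.4f} nm "
                 f"hydrated {int(spheres.hydrated)}\n")
        for k, c in enumerate(spheres.centres, 1):
            x, y, z = c * 10.0
            fh.write(
                f"ATOM  {k % 100000:5d}  C1  SER A{k % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_sphere_xyz(spheres: SphereModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(spheres)}\n")
        fh.write(f"cube_side={spheres.cube_side:.6f} "
                 f"hydrated={int(spheres.hydrated)}\n")
        for c in spheres.centres:
            fh.write(f"S {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


def read_sphere_xyz(path: str | Path) -> SphereModel:
    with open(path) as fh:
        n = int(fh.readline())
        meta = dict(
            kv.split("=") for kv in fh.readline().split() if "=" in kv
        )
        centres = []
        for _ in range(n):
            parts = fh.readline().split()
            centres.append([float(v) for v in parts[1:4]])
    return SphereModel(
        np.asarray(centres),
        float(meta.get("cube_side", 0.530)),
        hydrated=bool(int(meta.get("hydrated", 0))),
    )
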