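"""Sequence/glycan composition: mass, volumes, nu-bar and A280.

Computes the physical parameters a scattering or sedimentation analysis
needs from an amino-acid sequence and its attached glycans, using embedded
consensus residue tables (see :mod:`flexsas.constants`):

* molecular mass = sum of residue masses + one water per chain + glycosyl
  residue masses (glycosidic waters already removed from the tables);
* unhydrated (dry) volume from consensus crystallographic residue volumes;
* hydrated volume = dry volume + n_w * v_w, where the bound-water count
  n_w = round(hydration * mass / 18.015) and v_w = 0.0245 nm^3 is the
  electrostricted volume of a bound water;
* partial specific volume nu-bar as the mass-weighted mean of residue
  partial specific volumes;
* A280 on the 1% (w/v), 1 cm basis from Trp/Tyr/cystine content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .constants import (
    BOUND_WATER_VOLUME,
    DEFAULT_HYDRATION,
    EXTINCTION_280,
    RESIDUE_MASS,
    RESIDUE_VBAR,
    RESIDUE_VOLUME,
    SUGAR_MASS,
    SUGAR_VBAR,
    SUGAR_VOLUME,
    WATER_MASS,
)

__all__ = ["GlycanComposition", "CompositionResult", "compute_composition"]


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one attached glycan.

    ``sugars`` maps monosaccharide names (Gal, Man, Glc, Fuc, GlcNAc,
    GalNAc, NeuNAc) to non-negative counts.  ``site`` is a residue
    identifier such as ``"Asn263"``; ``linkage`` is ``"N"`` or ``"O"``.
    """

    sugars: Mapping[str, int]
    site: str = ""
    linkage: str = "N"

    def __post_init__(self):
        for name, n in self.sugars.items():
            if name not in SUGAR_MASS:
                raise ValueError(f"unknown monosaccharide code {name!r}")
            if n < 0:
                raise ValueError("monosaccharide counts must be >= 0")
        if self.linkage not in ("N", "O"):
            raise ValueError("linkage must be 'N' or 'O'")
        if self.linkage == "N" and self.site and not self.site.startswith("Asn"):
            raise ValueError("an N-linked glycan attaches to Asn")
        if self.linkage == "O" and self.site and not (
            self.site.startswith("Ser") or self.site.startswith("Thr")
        ):
            raise ValueError("an O-linked glycan attaches to Ser/Thr")

    @property
    def mass(self) -> float:
        return sum(SUGAR_MASS[s] * n for s, n in self.sugars.items())

    @property
    def volume(self) -> float:
        """Dry volume, A^3."""
        return sum(SUGAR_VOLUME[s] * n for s, n in self.sugars.items())

    @property
    def vbar_mass(self) -> float:
        """Sum of mass * partial specific volume, for mass-weighted nu-bar."""
        return sum(SUGAR_MASS[s] * n * SUGAR_VBAR[s] for s, n in self.sugars.items())


@dataclass
class CompositionResult:
    """Derived physical parameters of a glycoprotein."""

    mass: float                 # Da
    dry_volume: float           # nm^3
    hydrated_volume: float      # nm^3
    vbar: float                 # ml/g
    a280: float                 # 1% (w/v), 1 cm
    bound_waters: int
    extinction_molar: float     # 1/(M cm)
    detail: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"molecular mass       {self.mass:12.0f} Da",
            f"unhydrated volume    {self.dry_volume:12.1f} nm^3",
            f"hydrated volume      {self.hydrated_volume:12.1f} nm^3",
            f"bound waters         {self.bound_waters:12d}",
            f"partial specific vol {self.vbar:12.3f} ml/g",
            f"A280 (1%, 1 cm)      {self.a280:12.2f}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        d = {
            "mass_da": self.mass,
            "dry_volume_nm3": self.dry_volume,
            "hydrated_volume_nm3": self.hydrated_volume,
            "vbar_ml_per_g": self.vbar,
            "a280_1pc_1cm": self.a280,
            "bound_waters": self.bound_waters,
            "extinction_molar": self.extinction_molar,
        }
        return json.dumps(d, indent=2)


def compute_composition(
    chains: Mapping[str, tuple[str, int]] | Mapping[str, str],
    glycans: Iterable[GlycanComposition] = (),
    hydration: float = DEFAULT_HYDRATION,
    water_volume: float = BOUND_WATER_VOLUME,
) -> CompositionResult:
    """Compute mass, volumes, nu-bar and A280 for a glycoprotein.

    Parameters
    ----------
    chains : mapping
        ``{name: (sequence, copy_number)}`` (a bare string implies one
        copy).  Sequences use the 20 standard one-letter codes.
    glycans : iterable of GlycanComposition
        Each entry is one attached glycan (list a glycan once per
        occurrence).
    hydration : float
        g of bound water per g of glycoprotein; 0 disables the shell.
    water_volume : float
        nm^3 per bound water.

    Raises
    ------
    ValueError
        On an unknown residue or monosaccharide code (naming the code),
        or a negative hydration.
    """
    if hydration < 0:
        raise ValueError("hydration must be >= 0")

    mass = 0.0
    vol_a3 = 0.0
    vbar_mass = 0.0
    n_trp = n_tyr = n_cys = 0
    n_residues = 0
    for name, spec in chains.items():
        seq, copies = (spec, 1) if isinstance(spec, str) else spec
        if copies < 0:
            raise ValueError("copy number must be >= 0")
        for aa in seq:
            if aa not in RESIDUE_MASS:
                raise ValueError(f"unknown residue code {aa!r} in chain {name!r}")
        m = sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
        v = sum(RESIDUE_VOLUME[aa] for aa in seq)
        vb = sum(RESIDUE_MASS[aa] * RESIDUE_VBAR[aa] for aa in seq)
        mass += copies * m
        vol_a3 += copies * v
        vbar_mass += copies * vb
        n_trp += copies * seq.count("W")
        n_tyr += copies * seq.count("Y")
        n_cys += copies * seq.count("C")
        n_residues += copies * len(seq)

    n_glycans = 0
    for g in glycans:
        mass += g.mass
        vol_a3 += g.volume
        vbar_mass += g.vbar_mass
        n_glycans += 1

    if mass <= 0:
        raise ValueError("empty composition")

    dry_volume = vol_a3 / 1000.0  # A^3 -> nm^3
    bound_waters = round(hydration * mass / WATER_MASS)
    hydrated_volume = dry_volume + bound_waters * water_volume
    vbar = vbar_mass / mass
    # all cysteines paired -> cystine count = n_cys // 2
    eps = (
        n_trp * EXTINCTION_280["W"]
        + n_tyr * EXTINCTION_280["Y"]
        + (n_cys // 2) * EXTINCTION_280["cystine"]
    )
    a280 = 10.0 * eps / mass
    return CompositionResult(
        mass=mass,
        dry_volume=dry_volume,
        hydrated_volume=hydrated_volume,
        vbar=vbar,
        a280=a280,
        bound_waters=bound_waters,
        extinction_molar=eps,
        detail={
            "n_residues": n_residues,
            "n_glycans": n_glycans,
            "n_trp": n_trp,
            "n_tyr": n_tyr,
            "n_cys": n_cys,
        },
    )
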