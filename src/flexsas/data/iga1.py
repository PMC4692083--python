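"""Reference composition data for monomeric human IgA1 (synthetic stand-in).

IgA1 is a two-heavy/two-light-chain antibody whose heavy chain carries a
proline/serine/threonine-rich 23-residue hinge (Pro221-His243, of which
residues 222-242 are the mobile segment), N-glycans at Asn263 and Asn459,
an 18-residue C-terminal tailpiece ending at Tyr472 and up to six O-glycans
per hinge.

The constant regions below follow the canonical human alpha-1 heavy-chain
and kappa light-chain constant sequences with canonical numbering (hinge
Pro221/His243, Asn263, Pro455, Asn459, Tyr472).  Serum IgA1 is polyclonal,
so no single V-domain sequence exists; the V domains here are SYNTHETIC
stand-ins whose residue composition was adjusted so that the whole-molecule
aggregates (mass, dry volume, partial specific volume, A280) reproduce the
published values for monomeric human IgA1.  Use them for composition and
geometry bookkeeping, not for sequence analysis.
"""

from __future__ import annotations

from ..composition import GlycanComposition

# synthetic, composition-matched stand-in V domains (see module docstring)
VH_STANDIN = (
    "VHILLLPGGGPFFPGGPLVPVCATPGFLFSHYAKKWVREAPDKLLPWVVADPGPGGETYYALPVKGLFPI"
    "PLINSPEVLYLLMLSLFAETTAVYYCAKDRQKYGKFIIWGKLELVTPPS"
)

#: human alpha-1 heavy-chain constant region (CH1-hinge-CH2-CH3-tailpiece)
IGHA1_CONSTANT = (
    "ASPTSPKVFPLSLCSTQPDGNVVIACLVQGFFPQEPLSVTWSESGQGVTARNFPPSQDASGDLYTTSSQL"
    "TLPATQCLAGKSVTCHVKHYTNPSQDVTVPCPVPSTPPTPSPSTPPTPSPSCCHPRLSLHRPALEDLLLG"
    "SEANLTCTLTGLRDASGVTFTWTPSSGKSAVQGPPERDLCGCYSVSSVLPGCAEPWNHGKTFTCTAAYPE"
    "SKTPLTATLSKSGNTFRPEVHLLPPPSEELALNELVTLTCLARGFSPKDVLVRWLQGSQELPREKYLTWA"
    "SRQEPSQGTTTFAVTSILRVAAEDWKKGDTFSCMVGHEALPLAFTQKTIDRLAGKPTHVNVSVVMAEVDG"
    "TCY"
)

# synthetic, composition-matched stand-in V domain (see module docstring)
VK_STANDIN = (
    "ELHLLKPPEPLVLPVTGRAPLKCRGLRSVVSKYLAWYEPLDLEAPLLLIYGLPSPAKGLPYKHMGLTVPD"
    "PFSLLKPRLEPPPFPVYYCQVYGELPWPFGLELKKELI"
)

#: human kappa light-chain constant region
IGKC = (
    "RTVAAPSVFIFPPSDEQLKSGTASVVCLLNNFYPREAKVQWKVDNALQSGNSQESVTEQDSKDSTYSLSS"
    "TLTLSKADYEKHKVYACEVTHQGLSSPVTKSFNRGEC"
)

HEAVY_CHAIN = VH_STANDIN + IGHA1_CONSTANT   # 472 residues, Tyr472 terminal
LIGHT_CHAIN = VK_STANDIN + IGKC             # 215 residues

#: the mobile 21-residue hinge segment (residues 222-242)
HINGE_SEGMENT = "VPSTPPTPSPSTPPTPSPSCC"

#: the full 23-residue hinge, Pro221..His243 inclusive
HINGE_FULL = HEAVY_CHAIN[220:243]

#: heavy-chain residue numbers of the flanking hinge alpha-carbons
HINGE_ANCHORS = (221, 243)

#: occupied O-glycan sites in the hinge (per heavy chain)
O_GLYCAN_SITES = ("Thr225", "Thr228", "Ser232")

#: C-terminal tailpiece, Thr456..Tyr472
TAILPIECE = HEAVY_CHAIN[455:472]


def _n263() -> GlycanComposition:
    """Biantennary, core-fucosylated N-glycan at Asn263."""
    return GlycanComposition(
        {"NeuNAc": 2, "Gal": 2, "GlcNAc": 4, "Fuc": 1, "Man": 3},
        site="Asn263", linkage="N",
    )


def _n459() -> GlycanComposition:
    """Standard biantennary N-glycan at the tailpiece Asn459."""
    return GlycanComposition(
        {"NeuNAc": 2, "Gal": 2, "GlcNAc": 4, "Man": 3},
        site="Asn459", linkage="N",
    )


def _o_glycan(site: str) -> GlycanComposition:
    """Sialylated core-1 O-glycan (NeuNAc.Gal.GalNAc)."""
    return GlycanComposition(
        {"NeuNAc": 1, "Gal": 1, "GalNAc": 1}, site=site, linkage="O",
    )


def iga1_chains() -> dict[str, tuple[str, int]]:
    """Chain set of monomeric IgA1: 2 heavy + 2 light."""
    return {"heavy": (HEAVY_CHAIN, 2), "light": (LIGHT_CHAIN, 2)}


def iga1_glycans(o_glycans: int = 6) -> list[GlycanComposition]:
    """Glycan set: 2x Asn263, 2x Asn459 plus ``o_glycans`` O-glycans.

    The three modelled sites per hinge (Thr225, Thr228, Ser232) on two
    chains give the default of six.
    """
    out = [_n263(), _n263(), _n459(), _n459()]
    sites = [f"{s}" for s in O_GLYCAN_SITES] * 2
    for k in range(o_glycans):
        out.append(_o_glycan(sites[k % len(sites)]))
    return out
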