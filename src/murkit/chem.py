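"""Compositional algebra for UDP-linked muropeptide precursors.

The cytoplasmic stage of peptidoglycan biosynthesis builds a ladder of
nucleotide-linked intermediates: UDP-GlcNAc is converted (MurA/MurB) to
UDP-MurNAc, and the Mur ligases MurC-MurF then append the stem-peptide
residues one condensation at a time, ending at the UDP-MurNAc-pentapeptide
(L-Ala, D-Glu, meso-DAP or L-Lys, D-Ala-D-Ala).  Every species in the ladder
is therefore a chain of building blocks joined by bonds that each release
one water, so its neutral elemental composition is the element-wise sum of
the free-molecule block formulas minus one H2O per inter-block bond.

This module provides that algebra: an :class:`ElementalComposition` over
C/H/N/O/P, a library of :class:`BuildingBlock` free-molecule formulas,
condensation (:func:`compose`), monoisotopic masses from an embedded
atomic-mass table (:func:`monoisotopic_mass`), and the pathway-ordered
ladder constructor (:func:`build_ladder`).

Stereochemistry (L-/D- labels, meso-DAP vs its diastereoisomers) is carried
as metadata only; it never changes a mass, since isomers are indistinguishable
by mass spectrometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "WATER_MASS",
    "ElementalComposition",
    "BuildingBlock",
    "BUILDING_BLOCKS",
    "PrecursorSpecies",
    "compose",
    "monoisotopic_mass",
    "build_ladder",
    "ladder_table",
    "write_ladder",
]

ELEMENTS = ("C", "H", "N", "O", "P")

#: Monoisotopic atomic masses (Da) of the most abundant isotope, 12C = 12 exactly.
#: Embedded so that no external lookup happens at run time.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
}


class UnknownBlockError(KeyError):
    """Raised when a building-block token is not in the library."""


@dataclass(frozen=True)
class ElementalComposition:
    """Non-negative atom counts over C, H, N, O, P.

    Supports element-wise addition and subtraction; subtraction below zero
    raises ``ValueError`` (a molecule cannot owe atoms).
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = {el: getattr(self, el) - getattr(other, el) for el in ELEMENTS}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"subtraction yields negative counts: {counts}")
        return ElementalComposition(**counts)

    def hill_formula(self) -> str:
        """Molecular formula in Hill order (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H", "N", "O", "P"):
            n = getattr(self, el)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


WATER = ElementalComposition(H=2, O=1)
WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]  # 18.0106 Da

BlockClass = Literal["nucleotide", "sugar", "amino-acid", "dipeptide", "enol-ether"]


@dataclass(frozen=True)
class BuildingBlock:
    """A free-molecule building block of the precursor ladder."""

    name: str
    composition: ElementalComposition
    block_class: str

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.composition)


def _blocks(*items: tuple[str, dict, str]) -> dict[str, BuildingBlock]:
    return {
        name: BuildingBlock(name, ElementalComposition(**comp), cls)
        for name, comp, cls in items
    }


#: Free-molecule formulas.  Condensed with loss of one water per inter-block
#: bond these reproduce the neutral masses behind every printed ion of the
#: five-intermediate ladder.
BUILDING_BLOCKS: dict[str, BuildingBlock] = _blocks(
    ("UDP", dict(C=9, H=14, N=2, O=12, P=2), "nucleotide"),
    ("GlcNAc", dict(C=8, H=15, N=1, O=6), "sugar"),
    ("MurNAc", dict(C=11, H=19, N=1, O=8), "sugar"),
    # enolpyruvyl donor, modelled as free enol-pyruvic acid so the uniform
    # one-water-per-bond rule gives the MurA product formula
    ("enolpyruvate", dict(C=3, H=4, O=3), "enol-ether"),
    ("Ala", dict(C=3, H=7, N=1, O=2), "amino-acid"),
    ("Glu", dict(C=5, H=9, N=1, O=4), "amino-acid"),
    ("meso-DAP", dict(C=7, H=14, N=2, O=4), "amino-acid"),
    ("Lys", dict(C=6, H=14, N=2, O=2), "amino-acid"),
    ("Ala-Ala", dict(C=6, H=12, N=2, O=3), "dipeptide"),
)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da: sum of count(e) * monoisotopic atomic mass(e)."""
    return sum(getattr(comp, el) * ATOMIC_MASS[el] for el in ELEMENTS)


def _resolve(block: "str | BuildingBlock") -> BuildingBlock:
    if isinstance(block, BuildingBlock):
        return block
    try:
        return BUILDING_BLOCKS[block]
    except KeyError:
        raise UnknownBlockError(
            f"unknown building block {block!r}; known: {sorted(BUILDING_BLOCKS)}"
        ) from None


def compose(blocks: Sequence["str | BuildingBlock"]) -> ElementalComposition:
    """Condense an ordered block list into one neutral composition.

    The result is the element-wise sum of the free-molecule formulas minus
    (n - 1) waters for n blocks; an empty list gives the empty composition.
    """
    resolved = [_resolve(b) for b in blocks]
    total = ElementalComposition()
    for b in resolved:
        total = total + b.composition
    if len(resolved) > 1:
        for _ in range(len(resolved) - 1):
            total = total - WATER
    return total


@dataclass(frozen=True)
class PrecursorSpecies:
    """A UDP-linked precursor: ordered blocks, neutral composition and mass M."""

    identifier: str
    blocks: tuple[str, ...]
    composition: ElementalComposition = field(compare=False)
    mass: float = field(compare=False)
    pathway_index: int = 0
    third_residue: "str | None" = None

    @classmethod
    def from_blocks(
        cls,
        identifier: str,
        blocks: Sequence[str],
        pathway_index: int = 0,
        third_residue: "str | None" = None,
    ) -> "PrecursorSpecies":
        comp = compose(blocks)
        return cls(
            identifier=identifier,
            blocks=tuple(blocks),
            composition=comp,
            mass=monoisotopic_mass(comp),
            pathway_index=pathway_index,
            third_residue=third_residue,
        )

    @property
    def contains_lys(self) -> bool:
        return "Lys" in self.blocks


_THIRD = {"DAP": "meso-DAP", "Lys": "Lys"}


def build_ladder(
    third_residue: str = "DAP",
    include_murnac: bool = False,
    include_enolpyruvyl: bool = False,
) -> list[PrecursorSpecies]:
    """Pathway-ordered precursor ladder for one stem-peptide variant.

    Parameters
    ----------
    third_residue : "DAP" or "Lys"
        Amino acid appended by MurE at stem position 3: meso-DAP (typical of
        Gram-negative walls, cyanobacteria and the moss chloroplast pathway)
        or L-Lys (typical of Gram-positive bacteria).
    include_enolpyruvyl, include_murnac
        Optionally include the MurA product (UDP-GlcNAc-enolpyruvate) and the
        MurB product (UDP-MurNAc), which precede the ligase ladder.

    Returns
    -------
    list of PrecursorSpecies, masses strictly increasing with pathway index.
    """
    if third_residue not in _THIRD:
        raise ValueError(f"third_residue must be 'DAP' or 'Lys', got {third_residue!r}")
    third = _THIRD[third_residue]
    tag = third_residue

    specs: list[tuple[str, list[str], "str | None"]] = [
        ("UDP-GlcNAc", ["UDP", "GlcNAc"], None)
    ]
    if include_enolpyruvyl:
        specs.append(
            ("UDP-GlcNAc-enolpyruvate", ["UDP", "GlcNAc", "enolpyruvate"], None)
        )
    if include_murnac:
        specs.append(("UDP-MurNAc", ["UDP", "MurNAc"], None))
    specs += [
        ("UDP-MurNAc-Ala", ["UDP", "MurNAc", "Ala"], None),
        ("UDP-MurNAc-Ala-Glu", ["UDP", "MurNAc", "Ala", "Glu"], None),
        (f"UDP-MurNAc-tripeptide-{tag}", ["UDP", "MurNAc", "Ala", "Glu", third], tag),
        (
            f"UDP-MurNAc-pentapeptide-{tag}",
            ["UDP", "MurNAc", "Ala", "Glu", third, "Ala-Ala"],
            tag,
        ),
    ]
    return [
        PrecursorSpecies.from_blocks(name, blocks, pathway_index=i, third_residue=tr)
        for i, (name, blocks, tr) in enumerate(specs)
    ]


def ladder_table(ladder: Iterable[PrecursorSpecies]) -> pd.DataFrame:
    """Tabulate a ladder: identifier, Hill formula, neutral monoisotopic mass."""
    rows = [
        {
            "identifier": sp.identifier,
            "formula": sp.composition.hill_formula(),
            "monoisotopic_mass": round(sp.mass, 4),
            "pathway_index": sp.pathway_index,
        }
        for sp in ladder
    ]
    return pd.DataFrame(rows)


def write_ladder(ladder: Iterable[PrecursorSpecies], path, sep: str = "\t") -> None:
    ladder_table(ladder).to_csv(path, sep=sep, index=False)
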