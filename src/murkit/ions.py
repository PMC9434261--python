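"""Negative-mode ion enumeration and ppm-tolerant peak matching.

Nanospray TOF spectra of UDP-linked precursors in negative mode show, for a
neutral species of monoisotopic mass M, a family of ions: multiply
deprotonated species (m-z)/z for charge z, and sodium-for-hydrogen exchange
("sodiated") satellites (m + k Na - z)/z in which k acidic protons are
replaced by Na+, each exchange shifting m/z by +21.9819/z.

The ionization convention subtracts one hydrogen-ATOM mass (1.0078250 Da)
per charge, neglecting the electron mass; a ``proton`` convention
(1.00727646 Da per charge) is available as a config switch.

Matching assigns each observed peak to the candidate ion minimizing the
absolute ppm error, if any ion lies within the configured tolerance.  A
precursor counts as identified when it has at least ``min_ions`` matched
ions, and (by default) at least one of them is a sodium-free deprotonated
ion: sodium-adduct satellites corroborate an identification but cannot
establish one on their own.  The base-ion requirement matters because two
Na-for-H exchanges (+43.9639 Da) almost compensate a CO2 difference
(43.9898 Da), so heavily sodiated ions of a Lys-containing species fall
within a few tens of ppm of DAP-species ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import ATOMIC_MASS, PrecursorSpecies

__all__ = [
    "HYDROGEN_ATOM_MASS",
    "PROTON_MASS",
    "SODIUM_MINUS_H",
    "IonSpecies",
    "Peak",
    "MatchResult",
    "MatchConfig",
    "IdentificationReport",
    "mz_of",
    "ion_label",
    "enumerate_ions",
    "match_peaks",
    "identify_intermediates",
]

HYDROGEN_ATOM_MASS = ATOMIC_MASS["H"]  # 1.0078250 Da
PROTON_MASS = 1.007276466621
SODIUM_MINUS_H = ATOMIC_MASS["Na"] - ATOMIC_MASS["H"]  # 21.9819443 Da


def mz_of(M: float, z: int, k: int = 0, convention: str = "atom") -> float:
    """Theoretical negative-mode m/z for charge ``z`` and ``k`` Na exchanges.

    m/z = (M - z*m_H + k*(m_Na - m_H)) / z, with m_H the hydrogen-atom mass
    under the default ``atom`` convention (electron mass neglected), or the
    bare proton mass under ``proton``.
    """
    if z not in (1, 2, 3):
        raise ValueError(f"charge z must be 1, 2 or 3, got {z}")
    if k < 0:
        raise ValueError(f"Na exchange count k must be >= 0, got {k}")
    if convention == "atom":
        m_h = HYDROGEN_ATOM_MASS
    elif convention == "proton":
        m_h = PROTON_MASS
    else:
        raise ValueError(f"convention must be 'atom' or 'proton', got {convention!r}")
    return (M - z * m_h + k * SODIUM_MINUS_H) / z


def ion_label(z: int, k: int) -> str:
    """Label in the field's notation, e.g. ``(m-2)/2`` or ``(m+2Na-1)/1``."""
    if k == 0:
        return f"(m-{z})/{z}"
    na = "Na" if k == 1 else f"{k}Na"
    return f"(m+{na}-{z})/{z}"


@dataclass(frozen=True)
class IonSpecies:
    """One theoretical ion of a precursor: charge z, k Na exchanges, m/z."""

    parent: PrecursorSpecies
    z: int
    k: int
    mz: float
    label: str

    @property
    def contains_lys(self) -> bool:
        return self.parent.contains_lys


@dataclass(frozen=True)
class Peak:
    """An observed peak: m/z plus optional intensity and fraction metadata."""

    mz: float
    intensity: "float | None" = None
    treatment: "str | None" = None
    fraction: "str | None" = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")


@dataclass(frozen=True)
class MatchResult:
    """A peak assigned to an ion, with signed ppm error."""

    peak: Peak
    ion: IonSpecies
    ppm_error: float


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters.

    tolerance_ppm
        Acceptance window; 30 ppm accepts every printed identification of
        the reference peak table while the nearest decoys stay far outside.
    z_range, k_range
        Inclusive charge and Na-exchange ranges enumerated per species.
    min_ions
        Matched-ion count needed to call a precursor identified.
    require_base_ion
        If True (default), an identification additionally needs at least one
        matched sodium-free (k=0) ion; adducts then only corroborate.
    convention
        Hydrogen mass convention for ionization, 'atom' or 'proton'.
    """

    tolerance_ppm: float = 30.0
    z_range: tuple[int, int] = (1, 3)
    k_range: tuple[int, int] = (0, 3)
    min_ions: int = 1
    require_base_ion: bool = True
    convention: str = "atom"

    def __post_init__(self) -> None:
        if self.tolerance_ppm < 0:
            raise ValueError("tolerance_ppm must be >= 0")
        if self.min_ions < 1:
            raise ValueError("min_ions must be >= 1")


def enumerate_ions(
    ladder: Sequence[PrecursorSpecies], cfg: "MatchConfig | None" = None
) -> list[IonSpecies]:
    """All (species x z x k) ions within the config ranges, sorted by m/z.

    Species appearing more than once in ``ladder`` (e.g. the shared early
    intermediates of the DAP and Lys variants) are deduplicated.
    """
    if not ladder:
        raise ValueError("ladder must be non-empty")
    cfg = cfg or MatchConfig()
    seen: set[str] = set()
    ions: list[IonSpecies] = []
    for sp in ladder:
        if sp.identifier in seen:
            continue
        seen.add(sp.identifier)
        for z in range(cfg.z_range[0], cfg.z_range[1] + 1):
            for k in range(cfg.k_range[0], cfg.k_range[1] + 1):
                ions.append(
                    IonSpecies(
                        parent=sp,
                        z=z,
                        k=k,
                        mz=mz_of(sp.mass, z, k, cfg.convention),
                        label=ion_label(z, k),
                    )
                )
    ions.sort(key=lambda i: i.mz)
    return ions


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class IdentificationReport:
    """Peak assignments plus per-precursor evidence aggregation."""

    matches: list[MatchResult]
    unassigned: list[Peak]
    config: MatchConfig
    ladder: list[PrecursorSpecies] = field(default_factory=list)

    def matches_for(self, identifier: str) -> list[MatchResult]:
        return [m for m in self.matches if m.ion.parent.identifier == identifier]

    def identified(self) -> list[PrecursorSpecies]:
        """Precursors meeting the evidence rule, in pathway order."""
        out = []
        for sp in sorted(
            {m.ion.parent for m in self.matches}, key=lambda s: (s.pathway_index, s.identifier)
        ):
            ms = self.matches_for(sp.identifier)
            if len(ms) < self.config.min_ions:
                continue
            if self.config.require_base_ion and not any(m.ion.k == 0 for m in ms):
                continue
            out.append(sp)
        return out


def match_peaks(
    peaks: Sequence[Peak],
    ions: Sequence[IonSpecies],
    cfg: "MatchConfig | None" = None,
) -> IdentificationReport:
    """Assign each peak to the nearest-ppm ion within tolerance.

    Each peak is matched independently and lands on at most one ion.  Ties
    in |ppm| break deterministically to the lower charge, then lower k.
    """
    cfg = cfg or MatchConfig()
    if not ions:
        raise ValueError("ion list must be non-empty")
    matches: list[MatchResult] = []
    unassigned: list[Peak] = []
    for peak in peaks:
        best: "IonSpecies | None" = None
        best_ppm = 0.0
        for ion in ions:
            err = ppm_error(peak.mz, ion.mz)
            if abs(err) > cfg.tolerance_ppm:
                continue
            if (
                best is None
                or abs(err) < abs(best_ppm) - 1e-12
                or (abs(abs(err) - abs(best_ppm)) <= 1e-12 and (ion.z, ion.k) < (best.z, best.k))
            ):
                best, best_ppm = ion, err
        if best is None:
            unassigned.append(peak)
        else:
            matches.append(MatchResult(peak=peak, ion=best, ppm_error=best_ppm))
    ladder = sorted(
        {i.parent for i in ions}, key=lambda s: (s.pathway_index, s.identifier)
    )
    return IdentificationReport(
        matches=matches, unassigned=list(unassigned), config=cfg, ladder=ladder
    )


def identify_intermediates(report: IdentificationReport) -> dict[str, list[str]]:
    """Identified precursors in pathway order with their supporting ion labels."""
    return {
        sp.identifier: sorted(
            {m.ion.label for m in report.matches_for(sp.identifier)},
            key=lambda lab: lab,
        )
        for sp in report.identified()
    }
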