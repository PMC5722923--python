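"""Peptide sequence model, elemental composition and mass/isotope arithmetic.

The NiSOD model peptides studied here are short Ni-hook mimics
(HCDLPCG-NH2 and variants) whose identity is confirmed by exact
monoisotopic mass and, for degradation products, by simulated isotope
envelopes.  This module provides the mass engine: an element-count
container with strict non-negativity, residue/terminus/modification
bookkeeping, adduct m/z arithmetic under the charged-adduct (proton)
convention, and isotope-pattern simulation by iterated convolution of
per-element isotope distributions.

Element masses and isotope abundances come from the NIST table shipped
with :mod:`pyteomics` (``pyteomics.mass.nist_mass``), the single source
of truth for all mass arithmetic in this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "SODIUM_ION_MASS",
    "ElementalComposition",
    "Modification",
    "MODIFICATIONS",
    "Peptide",
    "parse_peptide",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_mz",
    "IsotopePattern",
    "isotope_pattern",
]

#: Mass of a bare proton (charged adduct, electron-corrected), Da.
PROTON_MASS = 1.00727646688
#: Mass of the Na+ cation (Na atom minus one electron), Da.
SODIUM_ION_MASS = 22.98922070
_ELECTRON_MASS = 0.00054857990907

#: Monoisotopic mass of each supported element, Da (most abundant isotope).
ELEMENT_MASS: dict[str, float] = {
    el: _pmass.nist_mass[el][0][0]
    for el in ("H", "C", "N", "O", "S", "P", "Se", "Ni", "Na")
}


def _element_isotopes(element: str) -> list[tuple[float, float]]:
    """(mass, abundance) pairs for the naturally occurring isotopes."""
    table = _pmass.nist_mass[element]
    iso = [(m, ab) for key, (m, ab) in table.items() if key != 0 and ab > 0]
    iso.sort()
    return iso


class ElementalComposition(Mapping[str, int]):
    """Immutable element → count mapping with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    count below zero raises ``ValueError`` (a physical composition cannot
    owe atoms).  Scalar multiplication scales all counts.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if el not in ELEMENT_MASS:
                raise KeyError(f"element {el!r} has no mass-table entry")
        self._counts = {el: n for el, n in sorted(merged.items()) if n > 0}

    # Mapping interface ------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el) -> bool:
        return el in self._counts

    # Arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction would leave {out[el]} atoms of {el}"
                )
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, (int, np.integer)) or k < 0:
            raise ValueError("composition can only be scaled by a non-negative int")
        return ElementalComposition({el: n * int(k) for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    # Rendering --------------------------------------------------------
    def hill_formula(self) -> str:
        """Hill-order formula string, e.g. ``C30H47N11O10S2``."""
        parts = []
        order = [el for el in ("C", "H") if el in self._counts]
        order += sorted(el for el in self._counts if el not in ("C", "H"))
        for el in order:
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalComposition({self.hill_formula() or 'empty'})"


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Sum of most-abundant-isotope masses, Da."""
    return float(sum(ELEMENT_MASS[el] * n for el, n in comp.items()))


# --------------------------------------------------------------------------
# Residues, termini and modifications
# --------------------------------------------------------------------------

#: Residue (dehydrated amino acid) compositions, standard 20, from pyteomics.
RESIDUE_COMPOSITION: dict[str, ElementalComposition] = {
    aa: ElementalComposition(dict(comp))
    for aa, comp in _pmass.std_aa_comp.items()
    if len(aa) == 1 and aa.isalpha() and aa.isupper()
}

_WATER = ElementalComposition(H=2, O=1)
# free acid C-terminus: +H2O; amide: replace the terminal OH by NH2 (-O +N +H net)
_AMIDE_DELTA = ElementalComposition(N=1, H=3)  # residues + NH3 for -NH2 terminus


@dataclass(frozen=True)
class Modification:
    """A named elemental modification with a site restriction.

    ``site`` is one of ``"n_term"`` (any N-terminus) or ``"his1"``
    (requires His at position 1, e.g. imidazole Nε substitutions).
    """

    name: str
    tag: str
    delta: ElementalComposition
    site: str  # "n_term" | "his1"


#: Built-in modification vocabulary (tag → record); extensible at run time.
MODIFICATIONS: dict[str, Modification] = {
    m.tag: m
    for m in (
        Modification("N-terminal acetyl", "ac", ElementalComposition(C=2, H=2, O=1), "n_term"),
        Modification("His Nε-methyl", "meH", ElementalComposition(C=1, H=2), "his1"),
        Modification("His Nε-tosyl", "tosH", ElementalComposition(C=7, H=6, O=2, S=1), "his1"),
    )
}


@dataclass(frozen=True)
class Peptide:
    """A linear peptide: one-letter sequence, terminal state, modifications."""

    sequence: str
    c_term: str = "free-acid"  # "free-acid" | "amide"
    mods: tuple[str, ...] = ()  # modification tags, applied in order

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        for aa in self.sequence:
            if aa not in RESIDUE_COMPOSITION:
                raise ValueError(f"unknown residue letter {aa!r}")
        if self.c_term not in ("free-acid", "amide"):
            raise ValueError(f"unknown C-terminus {self.c_term!r}")
        for tag in self.mods:
            mod = MODIFICATIONS.get(tag)
            if mod is None:
                raise ValueError(f"unknown modification tag {tag!r}")
            if mod.site == "his1" and self.sequence[0] != "H":
                raise ValueError(
                    f"modification {tag!r} requires His at position 1 "
                    f"(sequence starts with {self.sequence[0]!r})"
                )

    def composition(self) -> ElementalComposition:
        comp = ElementalComposition()
        for aa in self.sequence:
            comp = comp + RESIDUE_COMPOSITION[aa]
        comp = comp + (_WATER if self.c_term == "free-acid" else _AMIDE_DELTA)
        for tag in self.mods:
            comp = comp + MODIFICATIONS[tag].delta
        return comp

    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition())

    def format(self) -> str:
        """Round-trippable spec string, e.g. ``"{ac-}HCDLPCG-NH2"``."""
        mods = "".join("{%s-}" % tag for tag in self.mods)
        suffix = "-NH2" if self.c_term == "amide" else ""
        return f"{mods}{self.sequence}{suffix}"

    def __str__(self) -> str:
        return self.format()


_SPEC_RE = re.compile(
    r"^(?P<mods>(?:\{[A-Za-z0-9]+-\})*)(?P<seq>[A-Za-z]+?)(?P<amide>-NH2)?$"
)


def parse_peptide(spec: str) -> Peptide:
    """Parse a modification-annotated sequence string.

    Grammar: ``[{modtag-}]SEQUENCE[-NH2]`` — e.g. ``"HCDLPCG-NH2"``,
    ``"{meH-}HCDLPCG-NH2"``, ``"{ac-}HCDLPCG-NH2"``.  The default
    C-terminus is the free acid.
    """
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise ValueError(f"cannot parse peptide spec {spec!r}")
    tags = tuple(re.findall(r"\{([A-Za-z0-9]+)-\}", m.group("mods")))
    return Peptide(
        sequence=m.group("seq").upper(),
        c_term="amide" if m.group("amide") else "free-acid",
        mods=tags,
    )


# --------------------------------------------------------------------------
# Adduct m/z arithmetic
# --------------------------------------------------------------------------

_ADDUCT_ION_MASS = {"H": PROTON_MASS, "Na": SODIUM_ION_MASS}


def adduct_mz(neutral_mass: float, adduct: str = "H", z: int = 1) -> float:
    """m/z of ``[M + zX]^z+`` using charged-adduct masses.

    ``adduct`` is ``"H"`` or ``"Na"`` (all charges carried by the same
    ion), or a mixed spec like ``"HNa"`` listing one carrier per charge.
    The calc. [M+H]+ values of TOF instruments follow this electron-
    corrected proton convention (proton = 1.0072765 Da), not the H-atom
    mass.
    """
    if z < 1:
        raise ValueError("charge z must be >= 1")
    carriers = _parse_adduct(adduct, z)
    return (neutral_mass + sum(_ADDUCT_ION_MASS[c] for c in carriers)) / z


def neutral_from_mz(mz: float, adduct: str = "H", z: int = 1) -> float:
    """Inverse of :func:`adduct_mz`: recover the neutral monoisotopic mass."""
    if z < 1:
        raise ValueError("charge z must be >= 1")
    carriers = _parse_adduct(adduct, z)
    return mz * z - sum(_ADDUCT_ION_MASS[c] for c in carriers)


def _parse_adduct(adduct: str, z: int) -> list[str]:
    carriers = re.findall(r"Na|H", adduct)
    if not carriers or "".join(carriers) != adduct:
        raise ValueError(f"unknown adduct spec {adduct!r}")
    if len(carriers) == 1:
        carriers = carriers * z
    if len(carriers) != z:
        raise ValueError(f"adduct {adduct!r} supplies {len(carriers)} charges, need {z}")
    return carriers


# --------------------------------------------------------------------------
# Isotope patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopePattern:
    """Simulated isotope envelope: (m/z, relative abundance) pairs.

    Abundances are normalized to sum to 1; m/z strictly increasing.
    """

    mz: np.ndarray
    abundance: np.ndarray
    charge: int
    bin_width: float

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        ab = np.asarray(self.abundance, dtype=float)
        if mz.shape != ab.shape or mz.ndim != 1:
            raise ValueError("mz and abundance must be matching 1-d arrays")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z must be strictly increasing")
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 after normalization")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "abundance", ab)

    @property
    def base_peak_mz(self) -> float:
        return float(self.mz[np.argmax(self.abundance)])


def _convolve_sparse(
    a: dict[int, float], b: dict[int, float], prune: float
) -> dict[int, float]:
    out: dict[int, float] = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            v = va * vb
            if v > 0:
                k = ka + kb
                out[k] = out.get(k, 0.0) + v
    if out:
        top = max(out.values())
        out = {k: v for k, v in out.items() if v >= top * prune}
    return out


def isotope_pattern(
    comp: ElementalComposition,
    z: int = 1,
    bin_width: float = 0.01,
    abundance_floor: float = 1e-4,
    adduct: str = "H",
) -> IsotopePattern:
    """Isotope envelope of a composition by iterated convolution.

    Per-element isotope distributions (NIST abundances) are raised to the
    atom count by repeated squaring and convolved across elements on a
    fixed mass grid of width ``bin_width`` (default 0.01 Da — envelope
    resolution, no fine structure).  Peaks below ``abundance_floor``
    relative to the base peak are dropped and the result renormalized to
    sum to 1.  For ``z >= 1`` the m/z axis is ``(mass + z*adduct)/z``;
    ``z = 0`` gives the neutral-mass pattern.
    """
    if len(comp) == 0:
        raise ValueError("composition is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if z < 0:
        raise ValueError("charge z must be >= 0")

    prune = min(abundance_floor, 1e-8)  # keep intermediate tails
    # work on integer bins of width bin_width in *neutral mass* space
    dist: dict[int, float] = {0: 1.0}
    offset = 0.0  # accumulated exact mass of per-bin reference
    for el, n in comp.items():
        isotopes = _element_isotopes(el)
        mono_mass = isotopes[0][0]
        # element distribution relative to its lightest isotope
        base = {
            int(round((m - mono_mass) / bin_width)): ab for m, ab in isotopes
        }
        # merge duplicate bins (possible for coarse bin_width)
        el_dist: dict[int, float] = {}
        for k, v in base.items():
            el_dist[k] = el_dist.get(k, 0.0) + v
        # el_dist ** n by binary exponentiation
        power = el_dist
        acc: dict[int, float] | None = None
        m_left = n
        while m_left:
            if m_left & 1:
                acc = power if acc is None else _convolve_sparse(acc, power, prune)
            m_left >>= 1
            if m_left:
                power = _convolve_sparse(power, power, prune)
        dist = _convolve_sparse(dist, acc, prune)
        offset += mono_mass * n

    if z == 0:
        adduct_mass, div = 0.0, 1
    else:
        carriers = _parse_adduct(adduct, z)
        adduct_mass, div = sum(_ADDUCT_ION_MASS[c] for c in carriers), z
    bins = np.array(sorted(dist))
    ab = np.array([dist[k] for k in bins])
    ab = ab / ab.max()
    keep = ab >= abundance_floor
    bins, ab = bins[keep], ab[keep]
    ab = ab / ab.sum()
    mz = (offset + bins * bin_width + adduct_mass) / div
    return IsotopePattern(mz=mz, abundance=ab, charge=z, bin_width=bin_width)
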