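"""Oxidative degradation species of two-cysteine NiSOD model peptides.

Treatment of the Ni(II)-peptides with superoxide destroys the complex
and oxidizes the peptide at sulfur: disulfide-bridged dimers, trimers
and tetramers form, with variable numbers of additional oxygen atoms on
the cysteine sulfurs (sulfenate/sulfinate/sulfonate and cystine-S-oxide
placements are mass-isomeric and not distinguished).  This module
enumerates those species combinatorially and annotates observed peak
lists by exact mass (ppm tolerance) and isotope-envelope similarity.

Composition bookkeeping: an n-mer connected by d disulfides with k added
oxygens has composition ``n*base - 2d*H + k*O`` (each S-S bond removes
two hydrogens); a connected n-mer needs at least n-1 bridges and the two
cysteines per monomer cap d at n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .peptide import (
    ElementalComposition,
    IsotopePattern,
    Peptide,
    adduct_mz,
    isotope_pattern,
    monoisotopic_mass,
)

__all__ = [
    "NI_ADDUCT_DELTA",
    "DegradationSpecies",
    "species_composition",
    "enumerate_species",
    "PeakList",
    "Assignment",
    "assign_peaks",
    "isotope_score",
]

#: Default elemental delta for one bound Ni: replace two protons by Ni(II).
NI_ADDUCT_DELTA: tuple[ElementalComposition, ElementalComposition] = (
    ElementalComposition(Ni=1),  # added
    ElementalComposition(H=2),  # removed
)


@dataclass(frozen=True)
class DegradationSpecies:
    """One candidate degradation product of a single base peptide.

    n      oligomer order (>= 1)
    d      number of disulfide bridges (n-1 <= d <= n for connected n-mers;
           d = n allows one intramolecular ring on top of the chain)
    k      added oxygen atoms (sulfur oxygenation), 0 <= k <= k_max
    ni     number of Ni adducts retained by the ion
    adduct charge-carrier spec ("H", "Na", or mixed like "HNa")
    z      charge state
    """

    base: Peptide
    n: int = 1
    d: int = 0
    k: int = 0
    ni: int = 0
    adduct: str = "H"
    z: int = 1

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("oligomer order n must be >= 1")
        if self.d < 0 or self.k < 0 or self.ni < 0:
            raise ValueError("d, k, ni must be non-negative")
        if self.d > self.n:
            raise ValueError(
                f"d={self.d} disulfides exceed the {2*self.n} cysteines "
                f"of an n={self.n} oligomer of a two-Cys peptide"
            )
        if self.n > 1 and self.d < self.n - 1:
            raise ValueError(f"a connected {self.n}-mer needs >= {self.n-1} disulfides")
        if self.z < 1:
            raise ValueError("charge z must be >= 1")

    @property
    def label(self) -> str:
        parts = [f"{self.n}mer", f"{self.d}SS"]
        if self.k:
            parts.append(f"+{self.k}O")
        if self.ni:
            parts.append(f"+{self.ni}Ni")
        carrier = self.adduct if self.adduct in ("H", "Na") else f"({self.adduct})"
        parts.append(f"[M+{self.z}{carrier}]{self.z}+" if self.z > 1 else f"[M+{carrier}]+")
        return " ".join(parts)


def species_composition(
    s: DegradationSpecies,
    ni_delta: tuple[ElementalComposition, ElementalComposition] = NI_ADDUCT_DELTA,
) -> ElementalComposition:
    """Neutral elemental composition: ``n*base - 2d*H + k*O`` plus Ni delta."""
    comp = s.n * s.base.composition()
    comp = comp - ElementalComposition(H=2 * s.d)
    comp = comp + ElementalComposition(O=s.k)
    if s.ni:
        add, remove = ni_delta
        comp = (comp + s.ni * add) - (s.ni * remove)
    return comp


def species_mass(s: DegradationSpecies, **kw) -> float:
    """Neutral monoisotopic mass, Da."""
    return monoisotopic_mass(species_composition(s, **kw))


def species_mz(s: DegradationSpecies, **kw) -> float:
    """Theoretical m/z of the species ion."""
    return adduct_mz(species_mass(s, **kw), s.adduct, s.z)


def enumerate_species(
    base: Peptide,
    n_max: int = 4,
    k_max: int = 7,
    d_options: str | dict[int, Sequence[int]] = "connected",
    metal_options: Sequence[int] = (0,),
    charges: Sequence[int] = (1, 2, 3),
    adducts: Sequence[str] = ("H", "Na"),
) -> list[DegradationSpecies]:
    """Exhaustive candidate list over the Cartesian product of parameters.

    ``d_options`` is ``"connected"`` (default: d in {n-1, n}, i.e. chain
    plus optionally one intramolecular ring; for n=1 that is {0, 1}) or a
    mapping n → iterable of allowed d.  No duplicates are produced.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    out: list[DegradationSpecies] = []
    seen: set = set()
    for n in range(1, n_max + 1):
        if d_options == "connected":
            ds: Sequence[int] = (n - 1, n)
        else:
            ds = tuple(d_options.get(n, ()))
        for d in ds:
            for k in range(0, k_max + 1):
                for ni in metal_options:
                    for adduct in adducts:
                        for z in charges:
                            sp = DegradationSpecies(
                                base=base, n=n, d=d, k=k, ni=ni, adduct=adduct, z=z
                            )
                            key = (n, d, k, ni, adduct, z)
                            if key not in seen:
                                seen.add(key)
                                out.append(sp)
    return out


# --------------------------------------------------------------------------
# Peak lists and assignment
# --------------------------------------------------------------------------


@dataclass
class PeakList:
    """Centroided peaks: m/z, intensity, optional per-peak isotope envelope."""

    mz: np.ndarray
    intensity: np.ndarray
    envelopes: list[tuple[np.ndarray, np.ndarray] | None] | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-d arrays")
        if len(self.mz) and np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if len(self.intensity) and np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.envelopes is not None and len(self.envelopes) != len(self.mz):
            raise ValueError("one envelope entry (or None) per peak required")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Assignment:
    """One candidate species matched to one observed peak."""

    peak_index: int
    species: DegradationSpecies
    theoretical_mz: float
    ppm_error: float  # signed, observed relative to theoretical
    isotope_similarity: float | None = None  # cosine score in [0, 1], if envelope given


def isotope_score(
    observed_mz: np.ndarray,
    observed_intensity: np.ndarray,
    simulated: IsotopePattern,
    bin_width: float = 0.05,
) -> float:
    """Cosine similarity of two envelopes on a shared m/z grid.

    Both envelopes are binned at ``bin_width`` (Da) and compared as
    intensity vectors; identical normalized envelopes score 1, envelopes
    with no overlapping bins score 0.
    """
    obs_mz = np.asarray(observed_mz, dtype=float)
    obs_int = np.asarray(observed_intensity, dtype=float)
    if obs_mz.size == 0 or simulated.mz.size == 0:
        raise ValueError("envelopes must be non-empty")
    lo = min(obs_mz.min(), simulated.mz.min())
    nbins = int(np.ceil((max(obs_mz.max(), simulated.mz.max()) - lo) / bin_width)) + 1
    a = np.zeros(nbins)
    b = np.zeros(nbins)
    np.add.at(a, ((obs_mz - lo) / bin_width).round().astype(int), obs_int)
    np.add.at(b, ((simulated.mz - lo) / bin_width).round().astype(int), simulated.abundance)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def assign_peaks(
    peaks: PeakList,
    candidates: Sequence[DegradationSpecies],
    tol_ppm: float = 5.0,
    score_bin_width: float = 0.05,
    isotope_bin_width: float = 0.01,
) -> list[list[Assignment]]:
    """Match each peak to all candidates within ``tol_ppm``.

    Returns one (possibly empty) list of assignments per peak, ranked by
    isotope similarity (descending, when envelopes are available) then by
    absolute ppm error.  The result is deterministic and independent of
    the input peak ordering.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    theo = np.array([species_mz(s) for s in candidates])
    order = np.argsort(theo, kind="stable")
    theo_sorted = theo[order]

    results: list[list[Assignment]] = []
    for i, mz in enumerate(peaks.mz):
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(theo_sorted, mz - tol, side="left")
        hi = np.searchsorted(theo_sorted, mz + tol, side="right")
        matches: list[Assignment] = []
        for j in order[lo:hi]:
            s = candidates[j]
            ppm = (mz - theo[j]) / theo[j] * 1e6
            score = None
            if peaks.envelopes is not None and peaks.envelopes[i] is not None:
                env_mz, env_int = peaks.envelopes[i]
                sim = isotope_pattern(
                    species_composition(s), z=s.z,
                    bin_width=isotope_bin_width, adduct=s.adduct,
                )
                score = isotope_score(env_mz, env_int, sim, bin_width=score_bin_width)
            matches.append(
                Assignment(
                    peak_index=i,
                    species=s,
                    theoretical_mz=float(theo[j]),
                    ppm_error=float(ppm),
                    isotope_similarity=score,
                )
            )
        matches.sort(
            key=lambda a: (
                -(a.isotope_similarity if a.isotope_similarity is not None else 0.0),
                abs(a.ppm_error),
                a.theoretical_mz,
            )
        )
        results.append(matches)
    return results
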