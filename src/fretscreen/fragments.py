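"""Theoretical b/y fragment ions, tolerance peak matching, and ladder reading.

MALDI CID of the library peptides yields predominantly singly charged b and y
ions, so that is the default ion model: ``b_i`` is the N-terminal fragment of
``i`` residues (plus any N-terminal acyl group), ``y_j`` the C-terminal
fragment of ``j`` residues (plus water and any C-terminal amide).  For singly
charged pairs of an unmodified-terminus peptide the complementarity identity
``mz(b_i) + mz(y_{n−i}) = M + 2·proton`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import PROTON_MASS, WATER, Peptide, Registry, ResidueSpec, formula_mass, parse_peptide

__all__ = [
    "FragmentIon",
    "Spectrum",
    "MatchResult",
    "LadderStep",
    "theoretical_fragments",
    "match_peaks",
    "ladder_read",
]


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int  # 1..n-1
    charge: int
    mz: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}" + ("" if self.charge == 1 else f"^{self.charge}+")


@dataclass
class Spectrum:
    """A centroided peak list with an optional precursor.

    Peaks are kept sorted by m/z; intensities must be finite and nonnegative.
    """

    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int = 1
    title: str = ""

    def __post_init__(self):
        mz = np.asarray(self.peaks_mz, dtype=float)
        inten = np.asarray(self.peaks_intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("peak m/z and intensity arrays must be 1-D and equal length")
        if np.any(~np.isfinite(mz)) or np.any(~np.isfinite(inten)):
            raise ValueError("peaks contain non-finite values")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(mz, kind="stable")
        self.peaks_mz = mz[order]
        self.peaks_intensity = inten[order]

    def __len__(self) -> int:
        return len(self.peaks_mz)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.peaks_intensity.max()) if len(self) else 0.0


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    peak_index: int
    ppm_error: float


@dataclass
class MatchResult:
    matched: list[PeakMatch]
    n_theoretical: int

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def coverage(self) -> float:
        return self.n_matched / self.n_theoretical if self.n_theoretical else 0.0

    @property
    def mean_abs_ppm(self) -> float:
        if not self.matched:
            return float("nan")
        return float(np.mean([abs(m.ppm_error) for m in self.matched]))


def theoretical_fragments(
    peptide: Peptide | str,
    series: Iterable[str] = ("b", "y"),
    charge: int = 1,
    registry: Registry | None = None,
) -> list[FragmentIon]:
    """All b/y ions of a peptide at the given charge, sorted by m/z.

    Side-chain modifications travel with their residue; the N-terminal acyl is
    part of every b ion and the C-terminal amide part of every y ion.
    """
    if isinstance(peptide, str):
        peptide = parse_peptide(peptide, registry)
    n = len(peptide)
    if n < 2:
        raise ValueError("fragmentation requires at least 2 residues")
    series = tuple(series)
    for s in series:
        if s not in ("b", "y"):
            raise ValueError(f"unsupported ion series {s!r}")
    masses = np.array([r.monoisotopic_mass for r in peptide.residues])
    acyl = peptide.n_terminal_acyl.delta_mass if peptide.n_terminal_acyl else 0.0
    cterm = formula_mass(WATER) + (
        formula_mass(peptide.amide_delta) if peptide.c_terminal_amide else 0.0
    )
    ions: list[FragmentIon] = []
    if "b" in series:
        prefix = np.cumsum(masses[:-1]) + acyl
        ions += [
            FragmentIon("b", i + 1, charge, (m + charge * PROTON_MASS) / charge)
            for i, m in enumerate(prefix)
        ]
    if "y" in series:
        suffix = np.cumsum(masses[::-1][:-1]) + cterm
        ions += [
            FragmentIon("y", j + 1, charge, (m + charge * PROTON_MASS) / charge)
            for j, m in enumerate(suffix)
        ]
    return sorted(ions, key=lambda f: f.mz)


def match_peaks(theoretical: Sequence[FragmentIon], spectrum: Spectrum, tol_ppm: float = 10.0) -> MatchResult:
    """Greedy one-to-one matching of theoretical ions to experimental peaks.

    All (ion, peak) pairs within ``tol_ppm`` are ranked by absolute ppm error;
    pairs are accepted in that order, each ion and each peak at most once, so
    the result is deterministic and independent of input peak order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not theoretical:
        raise ValueError("empty theoretical ion list")
    if len(spectrum) == 0:
        return MatchResult([], n_theoretical=len(theoretical))

    mz = spectrum.peaks_mz
    candidates: list[tuple[float, int, int]] = []  # (|ppm|, ion idx, peak idx)
    for i, ion in enumerate(theoretical):
        tol_da = ion.mz * tol_ppm * 1e-6
        lo = np.searchsorted(mz, ion.mz - tol_da, side="left")
        hi = np.searchsorted(mz, ion.mz + tol_da, side="right")
        for j in range(lo, hi):
            ppm = (mz[j] - ion.mz) / ion.mz * 1e6
            candidates.append((abs(ppm), i, j))
    candidates.sort()

    used_ion: set[int] = set()
    used_peak: set[int] = set()
    matched: list[PeakMatch] = []
    for _, i, j in candidates:
        if i in used_ion or j in used_peak:
            continue
        used_ion.add(i)
        used_peak.add(j)
        ion = theoretical[i]
        matched.append(PeakMatch(ion, j, (mz[j] - ion.mz) / ion.mz * 1e6))
    matched.sort(key=lambda m: m.ion.mz)
    return MatchResult(matched, n_theoretical=len(theoretical))


@dataclass(frozen=True)
class LadderStep:
    """A mass difference between two peaks explained by one residue."""

    lower_index: int
    upper_index: int
    delta_mz: float
    tokens: tuple[str, ...]  # all residues within tolerance
    ambiguous: bool


def ladder_read(
    spectrum: Spectrum,
    alphabet: Sequence[ResidueSpec],
    tol_da: float = 0.01,
    adjacent_only: bool = True,
) -> list[LadderStep]:
    """Assign residues to mass differences between peaks (de novo ladder reading).

    With ``adjacent_only`` each consecutive peak pair is examined; otherwise all
    ordered pairs.  A step lists every alphabet residue whose mass lies within
    ``tol_da`` of the difference and is flagged ambiguous when there are
    several (isobaric residues at loose tolerance, e.g. K vs Q).  Reading a
    complete y-ion ladder yields the internal sequence C→N; the two terminal
    residues are not recoverable from differences alone.
    """
    if not alphabet:
        raise ValueError("empty residue alphabet")
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    mz = spectrum.peaks_mz
    steps: list[LadderStep] = []
    pairs = (
        [(i, i + 1) for i in range(len(mz) - 1)]
        if adjacent_only
        else [(i, j) for i in range(len(mz)) for j in range(i + 1, len(mz))]
    )
    for i, j in pairs:
        delta = mz[j] - mz[i]
        hits = tuple(
            sorted({r.token for r in alphabet if abs(r.monoisotopic_mass - delta) <= tol_da})
        )
        if hits:
            steps.append(LadderStep(i, j, float(delta), hits, ambiguous=len(hits) > 1))
    return steps
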