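"""Library-constrained hit decoding: score precursor-consistent members, rank, flag ties.

The decoder mirrors the screening workflow for one-bead-one-compound FRET
libraries: the quasi-molecular ion constrains the candidate set to the library
members matching the precursor mass, each candidate's theoretical b/y ions are
matched against the tandem spectrum, and candidates are ranked by an
intensity-weighted match score.  Because a positional library is small and
closed, score margin — not a decoy FDR — is the operative control: near-ties
are flagged ambiguous rather than forced to a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .chem import Peptide, Registry
from .fragments import MatchResult, Spectrum, match_peaks, theoretical_fragments
from .library import PositionalLibrary, candidates_for_precursor

__all__ = ["CandidateScore", "score_candidate", "identify_hit", "PRECURSOR_INTERPRETATIONS"]

# Precursor readings tried in order: the intact [M+H]+ first, then the
# single-oxygen-loss ion seen for nitro-tyrosine-containing peptides.
PRECURSOR_INTERPRETATIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("[M+H]+", ()),
    ("[M-O+H]+", ("O",)),
)


def _default_weight(intensity: float, max_intensity: float) -> float:
    """1 + relative intensity: counts the match, rewards intense peaks."""
    if max_intensity <= 0:
        return 1.0
    return 1.0 + intensity / max_intensity


@dataclass
class CandidateScore:
    peptide: Peptide
    score: float
    n_matched: int
    coverage: float
    mean_abs_ppm: float
    rank: int = 0
    ambiguous: bool = False
    precursor_interpretation: str = ""

    @property
    def sequence(self) -> str:
        return self.peptide.sequence()


def score_candidate(
    peptide: Peptide,
    spectrum: Spectrum,
    tol_ppm: float = 10.0,
    weight: Callable[[float, float], float] | None = None,
    registry: Registry | None = None,
) -> CandidateScore:
    """Intensity-weighted fragment-match score of one candidate.

    score = Σ over matched b/y ions of ``weight(I_peak, I_max)`` with the
    default weight ``1 + I/I_max``; zero iff nothing matches.  On an all-zero
    intensity spectrum every weight degrades to 1 per match.  The score is
    invariant to uniform intensity rescaling.
    """
    weight = weight or _default_weight
    theo = theoretical_fragments(peptide, ("b", "y"), charge=1, registry=registry)
    result: MatchResult = match_peaks(theo, spectrum, tol_ppm=tol_ppm)
    imax = spectrum.base_peak_intensity
    score = sum(weight(float(spectrum.peaks_intensity[m.peak_index]), imax) for m in result.matched)
    return CandidateScore(
        peptide=peptide,
        score=float(score),
        n_matched=result.n_matched,
        coverage=result.coverage,
        mean_abs_ppm=result.mean_abs_ppm,
    )


def identify_hit(
    spectrum: Spectrum,
    library: PositionalLibrary,
    tol_precursor_ppm: float = 5.0,
    tol_fragment_ppm: float = 10.0,
    losses: Sequence[tuple[str, tuple[str, ...]]] = PRECURSOR_INTERPRETATIONS,
    ambiguity_rel: float = 0.01,
    weight: Callable[[float, float], float] | None = None,
    registry: Registry | None = None,
    candidate_fn: Callable[..., list[Peptide]] | None = None,
) -> list[CandidateScore]:
    """Rank every precursor-consistent library member against a spectrum.

    Precursor interpretations are tried in order ([M+H]+ then [M−O+H]+ by
    default) and all consistent candidates pooled, each tagged with the
    interpretation that admitted it.  Candidates are sorted by descending
    score, ties broken by lower mean |ppm| error; any candidate whose score is
    within ``ambiguity_rel`` (relative) of the next-ranked one — or that ties
    exactly — is flagged ambiguous.  Returns the full ranked table; empty if
    no member matches the precursor.
    """
    if spectrum.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    gen = candidate_fn or candidates_for_precursor

    scored: list[CandidateScore] = []
    seen: set[str] = set()
    for name, loss in losses:
        for pep in gen(
            library,
            spectrum.precursor_mz,
            charge=spectrum.precursor_charge,
            tol_ppm=tol_precursor_ppm,
            losses=loss,
            registry=registry,
        ):
            seq = pep.sequence()
            if seq in seen:
                continue
            seen.add(seq)
            cs = score_candidate(pep, spectrum, tol_ppm=tol_fragment_ppm, weight=weight, registry=registry)
            cs.precursor_interpretation = name
            scored.append(cs)

    def sort_key(c: CandidateScore):
        ppm = c.mean_abs_ppm if np.isfinite(c.mean_abs_ppm) else np.inf
        return (-c.score, ppm, c.sequence)

    scored.sort(key=sort_key)
    # dense ranks with exact score ties sharing a rank
    rank = 0
    last_score: float | None = None
    for i, c in enumerate(scored):
        if last_score is None or c.score != last_score:
            rank = i + 1
            last_score = c.score
        c.rank = rank
    for i, c in enumerate(scored):
        if c.score == 0.0:  # no fragment evidence at all
            c.ambiguous = True
            continue
        neighbors = []
        if i > 0:
            neighbors.append(scored[i - 1])
        if i + 1 < len(scored):
            neighbors.append(scored[i + 1])
        denom = max(c.score, *(n.score for n in neighbors), 0.0) if neighbors else c.score
        for n in neighbors:
            if denom == 0.0 or abs(c.score - n.score) <= ambiguity_rel * denom:
                c.ambiguous = True
                break
    return scored
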