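"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its config (seed included): tandem
spectra of planted library members with partial fragment coverage, ppm-scale
mass error and chemical-noise peaks; fluorogenic substrate-depletion progress
curves; tight-binding titration series; and cleavage-annotated substrate
tables.  Noise models are deliberately simple — Gaussian ppm mass error,
log-normal intensities, uniform noise m/z — which matches the character of
MALDI CID peak lists without attempting instrument physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .chem import Peptide, Registry, mz as ion_mz, parse_peptide
from .fragments import Spectrum, theoretical_fragments
from .kinetics import ProgressCurve, TitrationSeries, morrison_activity
from .profiling import SubstrateRecord

__all__ = [
    "SpectrumSimConfig",
    "KineticsSimConfig",
    "simulate_spectrum",
    "simulate_progress",
    "simulate_titration",
    "simulate_substrate_table",
]


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Parameters of a simulated MALDI CID spectrum of one library member."""

    peptide: str  # bracketed notation of the planted member
    coverage: float = 0.7  # fraction of theoretical b/y ions present
    ppm_sd: float = 5.0  # Gaussian mass-error s.d.
    n_noise_peaks: int = 20
    mz_range: tuple[float, float] = (150.0, 2500.0)
    intensity_mu: float = 7.0  # log-normal log-mean of fragment intensities
    intensity_sigma: float = 1.0
    noise_intensity_scale: float = 0.3  # noise intensity relative to fragments
    precursor_loss: str | None = None  # e.g. "O" for the −O precursor
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must lie in (0, 1]")
        if self.ppm_sd < 0:
            raise ValueError("ppm_sd must be nonnegative")


def simulate_spectrum(cfg: SpectrumSimConfig, registry: Registry | None = None) -> Spectrum:
    """Simulate the tandem spectrum of a planted peptide.

    Theoretical singly charged b/y ions are subsampled to ``coverage``,
    perturbed by Gaussian ppm error, given log-normal intensities, and mixed
    with uniform chemical-noise peaks; the precursor is [M+H]+ or, with
    ``precursor_loss="O"``, the oxygen-loss ion.  With coverage 1, zero ppm
    error and zero noise peaks the peak m/z list equals the theoretical one.
    """
    rng = np.random.default_rng(cfg.seed)
    pep = parse_peptide(cfg.peptide, registry)
    ions = theoretical_fragments(pep, ("b", "y"), charge=1, registry=registry)
    n_keep = max(1, int(round(cfg.coverage * len(ions))))
    if n_keep < len(ions):
        keep = rng.choice(len(ions), size=n_keep, replace=False)
        ions = [ions[i] for i in sorted(keep)]

    frag_mz = np.array([f.mz for f in ions])
    if cfg.ppm_sd > 0:
        frag_mz = frag_mz * (1.0 + rng.normal(0.0, cfg.ppm_sd * 1e-6, size=len(frag_mz)))
    frag_int = rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma, size=len(frag_mz))

    noise_mz = rng.uniform(*cfg.mz_range, size=cfg.n_noise_peaks)
    noise_int = (
        rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma, size=cfg.n_noise_peaks)
        * cfg.noise_intensity_scale
    )

    losses = (cfg.precursor_loss,) if cfg.precursor_loss else ()
    precursor = ion_mz(pep, charge=1, neutral_losses=losses, registry=registry)
    return Spectrum(
        peaks_mz=np.concatenate([frag_mz, noise_mz]),
        peaks_intensity=np.concatenate([frag_int, noise_int]),
        precursor_mz=precursor,
        precursor_charge=1,
        title=f"sim:{cfg.peptide}",
    )


@dataclass(frozen=True)
class KineticsSimConfig:
    """Parameters of a simulated fluorogenic cleavage assay."""

    kcat_s: float
    km_uM: float
    enzyme_uM: float
    substrate_uM: tuple[float, ...] = tuple(200.0 / 2**i for i in range(8))
    gradient_rfu_per_uM: float = 50.0
    read_interval_s: float = 20.0
    horizon_s: float = 3600.0
    noise_sd_rfu: float = 0.0
    inner_filter_alpha: float = 0.0  # per-μM exponential quench coefficient
    background_rfu: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.kcat_s, self.km_uM, self.enzyme_uM) <= 0:
            raise ValueError("kcat, Km and [E] must be positive")
        if any(s <= 0 for s in self.substrate_uM):
            raise ValueError("substrate concentrations must be positive")


def inner_filter_factor(substrate_uM: float | np.ndarray, alpha: float) -> np.ndarray:
    """Exponential quench model: factor(S) = exp(−α·S), factor(0) = 1."""
    return np.exp(-alpha * np.asarray(substrate_uM, dtype=float))


def simulate_progress(cfg: KineticsSimConfig) -> list[ProgressCurve]:
    """Integrate substrate depletion and read out fluorescence per well.

    dS/dt = −kcat·E·S/(Km+S); RFU(t) = gradient · P(t) · factor(S0) + noise
    with P = S0 − S, so the apparent rate at concentration S0 is quenched by
    the inner-filter factor exactly as in a plate assay.  Returns one
    background-subtracted curve per substrate concentration.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.horizon_s + cfg.read_interval_s / 2, cfg.read_interval_s)
    curves: list[ProgressCurve] = []
    for s0 in cfg.substrate_uM:
        sol = solve_ivp(
            lambda t, s: -cfg.kcat_s * cfg.enzyme_uM * s / (cfg.km_uM + s),
            (0.0, float(times[-1])),
            [float(s0)],
            t_eval=times,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed at S0 = {s0} μM: {sol.message}")
        product = s0 - sol.y[0]
        rfu = cfg.gradient_rfu_per_uM * product * inner_filter_factor(s0, cfg.inner_filter_alpha)
        rfu = rfu + cfg.background_rfu
        if cfg.noise_sd_rfu > 0:
            rfu = rfu + rng.normal(0.0, cfg.noise_sd_rfu, size=rfu.shape)
        rfu = rfu - cfg.background_rfu  # background subtraction as in the assay
        curves.append(
            ProgressCurve(times=times, rfu=rfu, enzyme_nM=cfg.enzyme_uM * 1e3, substrate_uM=s0)
        )
    return curves


def simulate_titration(
    enzyme_nM: float,
    ki_app_nM: float,
    inhibitor_nM: Sequence[float],
    noise_sd_percent: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Percent activity from the Morrison expression plus Gaussian noise."""
    if enzyme_nM <= 0:
        raise ValueError("enzyme concentration must be positive")
    rng = np.random.default_rng(seed)
    I = np.asarray(inhibitor_nM, dtype=float)
    a = morrison_activity(I, enzyme_nM, ki_app_nM)
    if noise_sd_percent > 0:
        a = a + rng.normal(0.0, noise_sd_percent, size=a.shape)
    return TitrationSeries(inhibitor_nM=I, percent_activity=a)


def simulate_substrate_table(
    position_probs: Mapping[str, Mapping[str, float]],
    n: int = 500,
    seed: int = 0,
) -> list[SubstrateRecord]:
    """Draw cleavage-annotated substrate records from per-position residue distributions.

    ``position_probs`` maps P-position labels (e.g. ``"P1"``, ``"P2'"``) to
    residue→probability mappings; each must sum to 1.  Residues are drawn
    independently per position; the cleavage index equals the number of
    unprimed positions so every record covers the full window.
    """
    from .profiling import parse_position

    rng = np.random.default_rng(seed)
    offsets = sorted(parse_position(lbl) for lbl in position_probs)
    if len(offsets) != len(position_probs):
        raise ValueError("duplicate position labels")
    by_offset = {parse_position(lbl): probs for lbl, probs in position_probs.items()}
    for lbl, probs in position_probs.items():
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities at {lbl} sum to {total}, not 1")
    n_unprimed = sum(1 for o in offsets if o < 0)
    records = []
    for _ in range(n):
        seq = []
        for off in offsets:
            probs = by_offset[off]
            tokens = sorted(probs)
            seq.append(rng.choice(tokens, p=[probs[t] for t in tokens]))
        records.append(SubstrateRecord("".join(seq), cleavage_index=n_unprimed, source="simulated"))
    return records
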