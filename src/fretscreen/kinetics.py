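"""Protease cleavage kinetics for FRET substrate assays.

Covers the full quantitative chain from raw plate-reader fluorescence to
catalytic constants:

* fluorophore calibration (RFU per μM) and RFU→concentration conversion,
* initial rates from the linear part of progress curves,
* inner-filter-effect correction factors from spiked-fluorophore readings,
* Michaelis–Menten fits (v = Vmax·S/(Km+S), kcat = Vmax/[E]),
* Morrison tight-binding titration and active-site concentration,
* selectivity fold tables, detection calls against a ΔRFU threshold, and
  bead ΔFI arithmetic.

Concentrations are carried in μM internally unless a function's signature
says otherwise (enzyme and inhibitor concentrations in titrations are nM,
matching how these assays are reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from lmfit import Model
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ProgressCurve",
    "TitrationSeries",
    "KineticFit",
    "InnerFilterTable",
    "RateFit",
    "fit_calibration",
    "initial_rate",
    "convert_rate",
    "inner_filter_factors",
    "michaelis_menten",
    "fit_michaelis_menten",
    "morrison_activity",
    "fit_tight_binding",
    "TightBindingFit",
    "selectivity_table",
    "detection_call",
    "bead_delta_fi",
    "CalibrationError",
    "FitConvergenceError",
]


class CalibrationError(ValueError):
    """Calibration series unusable (non-positive gradient, too few points)."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the starting values tried."""

    def __init__(self, message: str, start_values: Mapping[str, float]):
        super().__init__(f"{message} (starting values: {dict(start_values)})")
        self.start_values = dict(start_values)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorophore calibration: RFU = gradient·[F] + intercept."""

    gradient: float  # RFU per μM
    intercept: float  # RFU
    r_squared: float

    def rfu_to_uM(self, rfu: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(rfu) - self.intercept) / self.gradient


@dataclass
class ProgressCurve:
    """A background-subtracted time course of fluorescence."""

    times: np.ndarray  # s, strictly increasing
    rfu: np.ndarray
    enzyme_nM: float | None = None
    substrate_uM: float | None = None
    replicate: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times.shape != self.rfu.shape or self.times.ndim != 1:
            raise ValueError("times and rfu must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TitrationSeries:
    """Percent activity as a function of inhibitor concentration."""

    inhibitor_nM: np.ndarray
    percent_activity: np.ndarray

    def __post_init__(self):
        self.inhibitor_nM = np.asarray(self.inhibitor_nM, dtype=float)
        self.percent_activity = np.asarray(self.percent_activity, dtype=float)
        if self.inhibitor_nM.shape != self.percent_activity.shape:
            raise ValueError("inhibitor and activity arrays must be equal length")
        if np.any(self.inhibitor_nM < 0):
            raise ValueError("inhibitor concentrations must be nonnegative")


@dataclass
class KineticFit:
    """Michaelis–Menten result with derived constants and standard errors."""

    vmax_uM_s: float
    km_uM: float
    kcat_s: float
    kcat_over_km_M_s: float
    vmax_se: float = float("nan")
    km_se: float = float("nan")
    kcat_se: float = float("nan")
    kcat_over_km_se: float = float("nan")
    enzyme_uM: float = float("nan")
    correction_applied: bool = False


@dataclass
class InnerFilterTable:
    """Per-concentration inner-filter correction factors, factor(0 μM) = 1."""

    substrate_uM: np.ndarray
    factor: np.ndarray

    def __post_init__(self):
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.factor = np.asarray(self.factor, dtype=float)
        if np.any(self.factor <= 0) or np.any(self.factor > 1 + 1e-9):
            raise ValueError("correction factors must lie in (0, 1]")
        if np.any(np.diff(self.factor[np.argsort(self.substrate_uM)]) > 1e-9):
            warnings.warn("inner-filter factors increase with concentration", stacklevel=2)

    def factor_at(self, substrate_uM: float) -> float:
        idx = np.argmin(np.abs(self.substrate_uM - substrate_uM))
        return float(self.factor[idx])

    def correct_rates(self, substrate_uM: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """Divide raw rates by the factor of the nearest tabulated concentration."""
        return np.array([r / self.factor_at(s) for s, r in zip(substrate_uM, rates)])


def fit_calibration(concs_uM: Sequence[float], rfu: Sequence[float]) -> CalibrationCurve:
    """Ordinary least-squares fluorophore calibration line.

    Requires ≥ 3 distinct concentrations and a positive gradient; the gradient
    (RFU μM⁻¹) converts rates from RFU s⁻¹ to μM s⁻¹ downstream.
    """
    c = np.asarray(concs_uM, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if len(np.unique(c)) < 3:
        raise CalibrationError("need at least 3 distinct concentrations")
    res = stats.linregress(c, y)
    if res.slope <= 0:
        raise CalibrationError(f"non-positive calibration gradient ({res.slope:.3g} RFU/μM)")
    return CalibrationCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclass
class RateFit:
    """Initial-rate estimate from the linear leading window of a progress curve."""

    slope: float  # RFU/s
    intercept: float
    r_squared: float
    window: tuple[int, int]  # [start, stop) indices
    quality_warning: bool = False


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r² — with r² := 1 for an exactly flat trace."""
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def initial_rate(curve: ProgressCurve, min_points: int = 5, r2_threshold: float = 0.995) -> RateFit:
    """Slope of the longest leading window (≥ ``min_points``) with r² ≥ threshold.

    Falls back to the first ``min_points`` points with ``quality_warning`` set
    when no leading window meets the linearity criterion.
    """
    if len(curve) < min_points:
        raise ValueError(f"progress curve needs at least {min_points} points")
    t, y = curve.times, curve.rfu
    best: RateFit | None = None
    for stop in range(len(t), min_points - 1, -1):
        slope, intercept, r2 = _linfit(t[:stop], y[:stop])
        if r2 >= r2_threshold:
            best = RateFit(slope, intercept, r2, (0, stop))
            break
    if best is None:
        slope, intercept, r2 = _linfit(t[:min_points], y[:min_points])
        best = RateFit(slope, intercept, r2, (0, min_points), quality_warning=True)
        warnings.warn(
            f"no leading window of ≥{min_points} points reached r² ≥ {r2_threshold}; "
            "using the first points",
            stacklevel=2,
        )
    return best


def convert_rate(rate_rfu_per_s: float, calibration: CalibrationCurve, enzyme_conc: float) -> float:
    """Per-enzyme rate: (RFU/s) ÷ [E] ÷ gradient.

    Units follow the inputs: with the gradient in RFU μM⁻¹ and [E] in μM the
    result is μM s⁻¹ μM⁻¹ (equivalently nM s⁻¹ nM⁻¹ with nM units —
    the per-enzyme rate is scale-free as long as the two agree).
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    if calibration.gradient <= 0:
        raise CalibrationError("calibration gradient must be positive")
    return rate_rfu_per_s / enzyme_conc / calibration.gradient


def inner_filter_factors(
    substrate_uM: Sequence[float],
    rfu_with_spike: Sequence[float],
    rfu_without_spike: Sequence[float],
    blank_with_spike: float = 0.0,
    blank_without_spike: float = 0.0,
) -> InnerFilterTable:
    """Correction factors from spiked-fluorophore end-point readings.

    At each substrate concentration the net fluorophore signal is
    ``RFU_F(S) = (reading with spiked fluorophore − its blank) −
    (reading without − its blank)``; the factor is ``RFU_F(S)/RFU_F(0)``.
    The series must include S = 0 μM.  Dividing a raw rate by its factor
    undoes the quench, so corrected rates are never smaller than raw ones.
    """
    s = np.asarray(substrate_uM, dtype=float)
    net = (np.asarray(rfu_with_spike, dtype=float) - blank_with_spike) - (
        np.asarray(rfu_without_spike, dtype=float) - blank_without_spike
    )
    zero = np.flatnonzero(s == 0.0)
    if len(zero) == 0:
        raise ValueError("series must include a 0 μM substrate reading")
    ref = float(net[zero].mean())
    if ref <= 0:
        raise ValueError("fluorophore signal at 0 μM substrate is non-positive")
    factor = np.clip(net / ref, None, 1.0)
    if np.any(factor <= 0):
        raise ValueError("non-positive inner-filter factor (signal lost entirely)")
    order = np.argsort(s)
    return InnerFilterTable(s[order], factor[order])


def michaelis_menten(S, vmax, km):
    """v = Vmax·S / (Km + S)."""
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


def fit_michaelis_menten(
    substrate_uM: Sequence[float],
    rates_uM_s: Sequence[float],
    enzyme_uM: float,
    correction: InnerFilterTable | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> KineticFit:
    """Nonlinear least-squares Michaelis–Menten fit with derived kcat and kcat/Km.

    Rates are corrected by ``correction`` first when given.  The fit starts
    from Vmax = 1.2·max(v), Km = median(S) and falls back to seeded random
    multi-starts on failure.  Standard errors come from the fit covariance;
    kcat = Vmax/[E] and kcat/Km (M⁻¹ s⁻¹) propagate them to first order.
    """
    S = np.asarray(substrate_uM, dtype=float)
    v = np.asarray(rates_uM_s, dtype=float)
    if len(S) < 5:
        raise ValueError("need rates at ≥ 5 substrate concentrations")
    if np.any(v < 0):
        raise ValueError("negative rates")
    if enzyme_uM <= 0:
        raise ValueError("enzyme concentration must be positive")
    corrected = correction is not None
    if correction is not None:
        v = correction.correct_rates(S, v)

    model = Model(michaelis_menten)
    start = {"vmax": float(v.max() * 1.2), "km": float(np.median(S))}
    rng = np.random.default_rng(seed)
    attempts = [start] + [
        {"vmax": float(v.max() * rng.uniform(0.8, 3.0)), "km": float(rng.uniform(S.min(), S.max()))}
        for _ in range(n_restarts)
    ]
    result = None
    for sv in attempts:
        params = model.make_params(vmax=dict(value=sv["vmax"], min=0), km=dict(value=sv["km"], min=0))
        try:
            fit = model.fit(v, params, S=S)
        except Exception:
            continue
        if fit.success and (result is None or fit.chisqr < result.chisqr):
            result = fit
    if result is None:
        raise FitConvergenceError("Michaelis–Menten fit did not converge", start)

    vmax = float(result.params["vmax"].value)
    km = float(result.params["km"].value)
    vmax_se = float(result.params["vmax"].stderr or np.nan)
    km_se = float(result.params["km"].stderr or np.nan)
    kcat = vmax / enzyme_uM
    kcat_se = vmax_se / enzyme_uM
    eff = kcat / (km * 1e-6)  # Km μM → M
    with np.errstate(invalid="ignore", divide="ignore"):
        eff_se = eff * np.sqrt((kcat_se / kcat) ** 2 + (km_se / km) ** 2)
    return KineticFit(
        vmax_uM_s=vmax,
        km_uM=km,
        kcat_s=kcat,
        kcat_over_km_M_s=eff,
        vmax_se=vmax_se,
        km_se=km_se,
        kcat_se=kcat_se,
        kcat_over_km_se=float(eff_se),
        enzyme_uM=enzyme_uM,
        correction_applied=corrected,
    )


def morrison_activity(I, E, Ki):
    """Morrison tight-binding percent activity.

    a = 100 · (E − I − Ki + sqrt((I + Ki − E)² + 4·Ki·E)) / (2E), all
    concentrations in the same unit (nM here).  At I = 0 this is 100%;
    as Ki → 0 it falls linearly to 0 at I = E, which is why the linear limb
    extrapolates to the active-enzyme concentration.
    """
    I = np.asarray(I, dtype=float)
    return 100.0 * (E - I - Ki + np.sqrt((I + Ki - E) ** 2 + 4.0 * Ki * E)) / (2.0 * E)


@dataclass
class TightBindingFit:
    ki_app_nM: float
    enzyme_fit_nM: float  # from the full Morrison fit
    enzyme_active_nM: float  # x-intercept of the 20–80% linear limb
    ki_se: float = float("nan")
    enzyme_se: float = float("nan")
    n_linear_points: int = 0


def fit_tight_binding(
    series: TitrationSeries,
    enzyme_guess_nM: float,
    linear_band: tuple[float, float] = (20.0, 80.0),
) -> TightBindingFit:
    """Fit the Morrison equation and extract the active-enzyme concentration.

    Two estimates of [E] are returned: the nonlinear Morrison fit parameter,
    and the graphical one — a straight line through points with activity in
    ``linear_band`` (percent) extrapolated to the abscissa, which is how
    active-site titrations are read out in practice.
    """
    I = series.inhibitor_nM
    a = series.percent_activity
    if len(I) < 6:
        raise ValueError("need ≥ 6 inhibitor concentrations")
    if np.all(a > 90.0):
        raise ValueError("no inhibition observed (all activities > 90%)")

    model = Model(morrison_activity)
    params = model.make_params(
        E=dict(value=float(enzyme_guess_nM), min=1e-6),
        Ki=dict(value=float(enzyme_guess_nM) / 100.0, min=1e-9),
    )
    fit = model.fit(a, params, I=I)
    if not fit.success:
        raise FitConvergenceError(
            "Morrison fit did not converge", {"E": enzyme_guess_nM, "Ki": enzyme_guess_nM / 100}
        )

    lo, hi = linear_band
    mask = (a >= lo) & (a <= hi)
    if mask.sum() >= 2:
        res = stats.linregress(I[mask], a[mask])
        e_active = float(-res.intercept / res.slope)
    else:
        e_active = float(fit.params["E"].value)
        warnings.warn(
            f"fewer than 2 titration points inside the {lo}–{hi}% band; "
            "reporting the Morrison [E] as the active concentration",
            stacklevel=2,
        )
    return TightBindingFit(
        ki_app_nM=float(fit.params["Ki"].value),
        enzyme_fit_nM=float(fit.params["E"].value),
        enzyme_active_nM=e_active,
        ki_se=float(fit.params["Ki"].stderr or np.nan),
        enzyme_se=float(fit.params["E"].stderr or np.nan),
        n_linear_points=int(mask.sum()),
    )


def selectivity_table(
    per_enzyme_rates: Mapping[str, float],
    reference: str,
    detection_bound: float = 1e-12,
) -> dict[str, dict[str, float | str]]:
    """Fold preference of the reference enzyme over each other enzyme.

    Returns per enzyme: its rate, ``fold`` = rate(reference)/rate(enzyme)
    (``inf`` with a ``"> x-fold"`` note when the rate is below the detection
    bound) and ``percent_of_reference``.
    """
    if reference not in per_enzyme_rates:
        raise KeyError(f"reference enzyme {reference!r} missing")
    ref_rate = per_enzyme_rates[reference]
    if ref_rate <= 0:
        raise ValueError("reference rate must be positive")
    table: dict[str, dict[str, float | str]] = {}
    for enzyme, rate in per_enzyme_rates.items():
        entry: dict[str, float | str] = {
            "rate": float(rate),
            "percent_of_reference": 100.0 * rate / ref_rate,
        }
        if rate <= detection_bound:
            entry["fold"] = float("inf")
            entry["note"] = f"> {ref_rate / detection_bound:.3g}-fold (rate below detection bound)"
        else:
            entry["fold"] = float(ref_rate / rate)
        table[enzyme] = entry
    return table


def detection_call(
    times_s: Sequence[float],
    rfu: Sequence[float],
    threshold: float,
    horizon_s: float,
) -> tuple[bool, float | None]:
    """Whether ΔRFU = RFU(t) − RFU(0) crosses ``threshold`` within the horizon.

    Returns (detected, first-crossing time); the crossing time is linearly
    interpolated between the bracketing samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(times_s, dtype=float)
    delta = np.asarray(rfu, dtype=float) - float(np.asarray(rfu, dtype=float)[0])
    within = t <= horizon_s
    t, delta = t[within], delta[within]
    above = np.flatnonzero(delta >= threshold)
    if len(above) == 0:
        return False, None
    k = above[0]
    if k == 0:
        return True, float(t[0])
    t0, t1 = t[k - 1], t[k]
    d0, d1 = delta[k - 1], delta[k]
    cross = t0 + (threshold - d0) * (t1 - t0) / (d1 - d0)
    return True, float(cross)


def bead_delta_fi(fi: Sequence[float], background: Sequence[float]) -> np.ndarray:
    """ΔFI(t) = (FI(t) − BG(t)) − (FI(0) − BG(0)) for bead fluorescence series."""
    fi = np.asarray(fi, dtype=float)
    bg = np.asarray(background, dtype=float)
    if fi.shape != bg.shape:
        raise ValueError("FI and background series must be equal length")
    net = fi - bg
    return net - net[0]
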