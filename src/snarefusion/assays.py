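"""Stochastic simulation of the in vitro fusion assays and recovery of
rates and activation energies from the simulated traces.

The bulk lipid-mixing assay mixes dye-quenched v-SNARE vesicles with an
excess of unlabelled t-SNARE vesicles; each labelled vesicle undergoes
Poisson collisions at a fixed rate and fuses at most once, with a small
per-collision probability. Fluorescence dequenching then reports the
fused fraction. At p ≪ 1 the first-fusion time of each vesicle is
exponential with rate = collision rate × per-collision probability; an
exact per-collision Bernoulli mode is kept for cross-validation at small
sizes.

The inverse chain mirrors the analysis applied to the real assay:
fit the ensemble trace for the fusion rate, convert to collisions per
fusion, accumulate SNARE contact time, and invert the Kramers relation
for the initiation barrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .units import InvalidParameterError

__all__ = [
    "AssaySpec",
    "FluorescenceTrace",
    "FitError",
    "RateEstimate",
    "simulate_first_fusion_times",
    "simulate_lipid_mixing_trace",
    "simulate_content_release_trace",
    "estimate_fusion_rate",
    "estimate_initiation_energy",
    "simulate_pore_current",
]


class FitError(RuntimeError):
    """Trace cannot support a rate fit (flat, degenerate, or non-monotone)."""


@dataclass(frozen=True)
class AssaySpec:
    """Conditions of one simulated bulk fluorescence assay.

    collision_rate (s⁻¹): per-vesicle vSUV–tSUV collision rate, ≈ 300
    under standard conditions. per_collision_fusion_probability: ~1e-6
    (one fusion per 10⁶–10⁷ collisions). dequench_gain: plateau signal of
    full fusion relative to the detergent reference (1.0). noise_sd:
    additive Gaussian noise on the normalised fluorescence.
    """

    collision_rate: float = 300.0
    per_collision_fusion_probability: float = 1e-6
    n_vesicles: int = 1000
    duration: float = 14400.0
    time_step: float = 10.0
    dequench_gain: float = 1.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_collision_fusion_probability <= 1.0:
            raise InvalidParameterError("fusion probability must be in [0, 1]")
        if self.n_vesicles < 1:
            raise InvalidParameterError("n_vesicles must be >= 1")
        if not self.duration > self.time_step > 0:
            raise InvalidParameterError("need duration > time_step > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.collision_rate < 0:
            raise InvalidParameterError("collision_rate must be >= 0")


@dataclass(frozen=True)
class FluorescenceTrace:
    """Normalised fluorescence time course of a bulk assay.

    signal is scaled to the detergent reference (0 = initial, 1 = fully
    dequenched); fused_fraction is the underlying noiseless fraction of
    vesicles fused by each time point (non-decreasing).
    """

    times: np.ndarray
    signal: np.ndarray
    fused_fraction: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.signal) == len(self.fused_fraction)):
            raise InvalidParameterError("trace arrays must have equal length")


@dataclass(frozen=True)
class RateEstimate:
    rate: float  # s⁻¹
    ci_low: float
    ci_high: float


def _effective_rate(spec: AssaySpec) -> float:
    return spec.collision_rate * spec.per_collision_fusion_probability


def simulate_first_fusion_times(
    spec: AssaySpec, exact_bernoulli: bool = False
) -> np.ndarray:
    """Per-vesicle first-fusion times (s), exponential at rate ν·p.

    With a zero effective rate every vesicle is censored at the assay
    duration (+inf is returned). ``exact_bernoulli=True`` draws the number
    of collisions to first success geometrically and multiplies by the
    mean inter-collision time — identical in distribution to the
    exponential law at p ≪ 1, used as a cross-check at small sizes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rate = _effective_rate(spec)
    if rate == 0.0:
        return np.full(spec.n_vesicles, np.inf)
    if exact_bernoulli:
        n_coll = rng.geometric(spec.per_collision_fusion_probability, spec.n_vesicles)
        # the sum of n exponential inter-collision gaps is Gamma(n, 1/rate)
        return rng.gamma(n_coll, 1.0 / spec.collision_rate)
    return rng.exponential(1.0 / rate, spec.n_vesicles)


def _time_grid(spec: AssaySpec) -> np.ndarray:
    n = int(math.floor(spec.duration / spec.time_step)) + 1
    return np.arange(n) * spec.time_step


def simulate_lipid_mixing_trace(spec: AssaySpec) -> FluorescenceTrace:
    """Bulk dequenching time course of the lipid-mixing assay.

    fused_fraction(t) is the empirical fraction of vesicles fused by t;
    signal = dequench_gain × fused_fraction + Gaussian noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    times = _time_grid(spec)
    fusion_times = simulate_first_fusion_times(spec)
    fused = np.searchsorted(np.sort(fusion_times), times, side="right") / spec.n_vesicles
    signal = spec.dequench_gain * fused
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, len(times))
    return FluorescenceTrace(times=times, signal=signal, fused_fraction=fused)


def simulate_content_release_trace(
    spec: AssaySpec,
    efflux_time_s: float,
    transient_fraction: float,
    transient_open_time_s: float,
) -> FluorescenceTrace:
    """Bulk content-release time course with transient (flickering) pores.

    Each fusion event releases its full content with probability
    (1 − transient_fraction); otherwise the pore reseals after
    ``transient_open_time_s`` and only the fraction 1 − exp(−t_open/τ_efflux)
    escapes. Release is instantaneous on the trace's time grid because the
    efflux time (ms) is far below the sampling step (s). The trace is the
    population mean of per-vesicle released fractions.
    """
    if not 0.0 <= transient_fraction <= 1.0:
        raise InvalidParameterError("transient_fraction must be in [0, 1]")
    if not efflux_time_s > 0 or transient_open_time_s < 0:
        raise InvalidParameterError("efflux_time > 0 and open_time >= 0 required")
    rng = np.random.default_rng(spec.rng_seed)
    times = _time_grid(spec)
    fusion_times = simulate_first_fusion_times(spec)
    partial = 1.0 - math.exp(-transient_open_time_s / efflux_time_s)
    is_transient = rng.random(spec.n_vesicles) < transient_fraction
    amounts = np.where(is_transient, partial, 1.0)
    order = np.argsort(fusion_times)
    sorted_times = fusion_times[order]
    cum_release = np.concatenate([[0.0], np.cumsum(amounts[order])])
    idx = np.searchsorted(sorted_times, times, side="right")
    released = cum_release[idx] / spec.n_vesicles
    fused = idx / spec.n_vesicles
    signal = spec.dequench_gain * released
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, len(times))
    return FluorescenceTrace(times=times, signal=signal, fused_fraction=fused)


def estimate_fusion_rate(
    trace: FluorescenceTrace,
    n_bootstrap: int = 200,
    ci_level: float = 0.95,
    rng_seed: int = 0,
    n_vesicles: int | None = None,
) -> RateEstimate:
    """Fusion rate from a saturating exponential fit A·(1 − e^(−kt)).

    Least squares on the normalised signal. The confidence interval is a
    seeded bootstrap (percentile method): when ``n_vesicles`` is given, a
    parametric bootstrap that redraws that many exponential first-fusion
    times per replicate — the dominant error in a bulk trace is the
    finite-ensemble sampling of the fused-fraction curve, which is
    autocorrelated and invisible to residual resampling — plus Gaussian
    noise at the residual scale; otherwise a plain residual bootstrap
    (appropriate when instrument noise dominates). Raises FitError on a
    flat or degenerate trace.
    """
    if len(trace.times) < 10:
        raise FitError("trace must have at least 10 points")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.signal, dtype=float)
    span = float(np.max(y) - np.min(y))
    if not np.isfinite(span) or span <= 1e-12:
        raise FitError("flat trace: no fusion signal to fit")

    def model(tt, amplitude, k):
        return amplitude * (1.0 - np.exp(-k * tt))

    t_scale = max(float(t[-1]), 1.0)
    p0 = (max(float(y[-1]), 1e-6), 1.0 / t_scale)
    bounds = ((1e-12, 1e-15), (10.0, np.inf))
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    amp, k = popt
    if not (np.isfinite(k) and k > 0):
        raise FitError("fit produced a non-positive rate")

    rng = np.random.default_rng(rng_seed)
    residuals = y - model(t, *popt)
    noise_sd = float(np.std(residuals))
    ks = []
    for _ in range(n_bootstrap):
        if n_vesicles is not None:
            t_star = rng.exponential(1.0 / k, n_vesicles)
            frac = np.searchsorted(np.sort(t_star), t, side="right") / n_vesicles
            y_star = amp * frac + rng.normal(0.0, noise_sd, len(t))
        else:
            y_star = model(t, *popt) + rng.choice(residuals, size=len(t), replace=True)
        try:
            popt_star, _ = curve_fit(
                model, t, y_star, p0=popt, bounds=bounds, maxfev=5000
            )
            ks.append(popt_star[1])
        except (RuntimeError, ValueError):
            continue
    if ks:
        alpha = 0.5 * (1.0 - ci_level)
        lo, hi = np.quantile(ks, [alpha, 1.0 - alpha])
    else:  # pragma: no cover - bootstrap pathologically failing
        lo = hi = k
    return RateEstimate(rate=float(k), ci_low=float(lo), ci_high=float(hi))


def estimate_initiation_energy(
    recovered_rate_per_s: float,
    collision_rate_per_s: float,
    per_collision_dwell_s: float,
    snares_per_contact: float,
    prefactor_time_s: float,
) -> float:
    """SNAREpin initiation barrier (kBT) from a recovered fusion rate.

    collisions per fusion = collision rate / fusion rate; cumulated SNARE
    contact time = collisions × dwell × SNAREs per contact; the barrier is
    the Kramers inversion Ea = ln(contact time / τ0). The standard chain
    (10⁶–10⁷ collisions, 10 μs dwell, 10 v-SNAREs, τ0 = 0.1–10 ns)
    brackets Ea between 23 and 30 kBT.
    """
    if not (
        recovered_rate_per_s > 0
        and collision_rate_per_s > 0
        and per_collision_dwell_s > 0
        and snares_per_contact > 0
        and prefactor_time_s > 0
    ):
        raise InvalidParameterError("all rates and times must be > 0")
    if recovered_rate_per_s > collision_rate_per_s:
        raise InvalidParameterError(
            "recovered fusion rate cannot exceed the collision rate"
        )
    collisions = collision_rate_per_s / recovered_rate_per_s
    contact = collisions * per_collision_dwell_s * snares_per_contact
    return math.log(contact / prefactor_time_s)


def simulate_pore_current(
    open_conductance_ps: float,
    open_time_s: float,
    voltage_mv: float,
    sample_rate_hz: float,
    noise_sd_pa: float = 0.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular single-pore current trace (times s, current pA).

    Closed baseline, an open segment of mean current g·V, then closed
    again; Gaussian current noise throughout. 167 pS at 30 mV gives
    ≈ 5 pA of open-pore current.
    """
    if not (
        open_conductance_ps > 0
        and open_time_s > 0
        and voltage_mv >= 0
        and sample_rate_hz > 0
    ):
        raise InvalidParameterError("conductance, times, sample rate must be > 0")
    if noise_sd_pa < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    pad = 0.25 * open_time_s
    total = open_time_s + 2 * pad
    n = max(int(round(total * sample_rate_hz)), 4)
    times = np.arange(n) / sample_rate_hz
    open_mask = (times >= pad) & (times < pad + open_time_s)
    i_open = open_conductance_ps * 1e-12 * voltage_mv * 1e-3 * 1e12  # pA
    current = np.where(open_mask, i_open, 0.0)
    if noise_sd_pa > 0:
        current = current + rng.normal(0.0, noise_sd_pa, n)
    return times, current
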