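"""Simulated feedback loop that keeps the cuff stimulation detectable and separated.

The physical system inflates/deflates a finger cuff under a pressure ceiling
derived from the subject's noninvasive blood pressure, and uses the
frequency and strength of the two PPG components as feedback: the
stimulation frequency must stay away from the pulse and its harmonics, and
the stimulation-band SNR must stay above target.  This module reproduces
that loop in software against the synthetic finger model.

Policy numbers (step sizes, SNR target, hysteresis margins) are tunable;
the physical loop is described only qualitatively, so the defaults here are
engineering choices: frequency moves upward in 0.2 Hz steps (wrapping below
the maximum), amplitude rises in steps of 10 % of the pressure ceiling and
never exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .decompose import (
    BandSpec,
    ComponentSignals,
    PowerSpectrum,
    compute_power_spectrum,
    locate_component_peaks,
    separate_components,
)
from .errors import ConfigError, InvalidInputError, SeparationInfeasibleError
from .pipeline import PipelineConfig
from .simulate import SimulationConfig, simulate_ppg


@dataclass(frozen=True)
class StimulationState:
    """Current stimulation drive: frequency, cuff-pressure surrogate, enable flag."""

    frequency: float                 # Hz
    amplitude: float                 # pressure surrogate units
    enabled: bool = True
    pressure_threshold: float = 60.0  # NIBP-derived ceiling, same surrogate units

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ConfigError("stimulation frequency must be > 0")
        if not (0.0 <= self.amplitude <= self.pressure_threshold):
            raise ConfigError("amplitude must lie in [0, pressure_threshold]")


@dataclass(frozen=True)
class FeedbackMetrics:
    """What the controller sees: band SNRs and harmonic separation."""

    pulse_freq: float        # Hz
    stim_snr: float          # dB; -inf when the stimulation band is absent
    pulse_snr: float         # dB
    separation: float        # Hz distance from stim frequency to nearest pulse harmonic

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise InvalidInputError("separation must be >= 0")


@dataclass(frozen=True)
class ControlPolicy:
    """Rule-based controller parameters."""

    min_separation: float = 0.5      # Hz required distance from pulse harmonics
    target_stim_snr: float = 10.0    # dB
    freq_step: float = 0.2           # Hz upward move per candidate
    amplitude_step_fraction: float = 0.1  # of pressure_threshold per adjustment
    separation_margin: float = 0.1   # Hz hysteresis when choosing a new frequency
    n_harmonics: int = 3             # pulse harmonics considered for avoidance
    min_freq: float = 0.5            # Hz wrap-around floor
    max_freq: float = 8.0            # Hz ceiling (well under Nyquist)
    pressure_to_path: float = 5.0e-4 # venous path amplitude per surrogate pressure unit


def harmonic_separation(stim_freq: float, pulse_freq: float, n_harmonics: int = 3) -> float:
    """Distance (Hz) from the stimulation frequency to the nearest pulse harmonic."""
    if pulse_freq <= 0:
        return stim_freq
    return min(abs(stim_freq - k * pulse_freq) for k in range(1, n_harmonics + 1))


def compute_feedback_metrics(
    components: Optional[ComponentSignals],
    spectrum: PowerSpectrum,
    state: StimulationState,
    *,
    pulse_search: BandSpec = BandSpec(center=1.5, half_width=1.0),
    band_half_width: float = 0.3,
    prominence_ratio: float = 3.0,
    n_harmonics: int = 3,
) -> FeedbackMetrics:
    """Band-power SNRs and harmonic separation from the measured spectrum.

    The noise floor is the median spectral power outside the pulse and
    stimulation bands.  SNR is mean in-band power over that floor, in dB.
    When the stimulation is disabled or its band holds no prominent peak the
    stimulation SNR is −inf — a valid observation for the controller, not an
    error.  ``components`` may be None when band separation itself failed.
    """
    f = spectrum.frequency
    power = spectrum.total
    floor_df = f[1] - f[0] if len(f) > 1 else 1.0

    pulse_mask = (f >= pulse_search.lo) & (f <= pulse_search.hi)
    if not np.any(pulse_mask):
        raise ConfigError("pulse search band is empty")
    idx = np.flatnonzero(pulse_mask)
    pulse_freq = float(f[idx[np.argmax(power[idx])]])

    stim_lo = max(state.frequency - band_half_width, floor_df)
    stim_hi = state.frequency + band_half_width
    stim_mask = (f >= stim_lo) & (f <= stim_hi)

    out_mask = ~pulse_mask & ~stim_mask & (f > 0.2)
    floor = float(np.median(power[out_mask])) if np.any(out_mask) else float(np.median(power))
    floor = max(floor, np.finfo(float).tiny)

    def _snr_db(mask: np.ndarray, require_peak: bool) -> float:
        if not np.any(mask):
            return -np.inf
        band = power[mask]
        if require_peak and band.max() < prominence_ratio * floor:
            return -np.inf
        return float(10.0 * np.log10(band.mean() / floor))

    pulse_snr = _snr_db(pulse_mask, require_peak=False)
    if not state.enabled or state.amplitude == 0.0:
        stim_snr = -np.inf
    else:
        stim_snr = _snr_db(stim_mask, require_peak=True)

    return FeedbackMetrics(
        pulse_freq=pulse_freq,
        stim_snr=stim_snr,
        pulse_snr=pulse_snr,
        separation=harmonic_separation(state.frequency, pulse_freq, n_harmonics),
    )


def adjust_stimulation(
    state: StimulationState,
    metrics: FeedbackMetrics,
    policy: ControlPolicy = ControlPolicy(),
) -> tuple[StimulationState, tuple[str, ...]]:
    """One rule-based update of the stimulation state.

    * separation below target → move the frequency upward in ``freq_step``
      increments (wrapping below ``max_freq`` to ``min_freq``) until it
      clears every considered pulse harmonic by
      ``min_separation + separation_margin``;
    * stimulation SNR below target → raise the amplitude by one step of
      ``amplitude_step_fraction × pressure_threshold``, capped at the
      pressure ceiling (a "saturated" warning when already there);
    * both satisfied → the state is returned unchanged (fixed point).

    Returns the new state and a tuple of warning strings.
    """
    if not state.enabled:
        return state, ()
    warnings: list[str] = []
    new_freq = state.frequency
    if metrics.separation < policy.min_separation:
        target = policy.min_separation + policy.separation_margin
        candidate = state.frequency
        span = policy.max_freq - policy.min_freq
        max_iter = int(np.ceil(span / policy.freq_step)) + 2
        found = False
        for _ in range(max_iter):
            candidate += policy.freq_step
            if candidate > policy.max_freq:
                candidate = policy.min_freq
            if harmonic_separation(candidate, metrics.pulse_freq, policy.n_harmonics) >= target:
                found = True
                break
        if found:
            new_freq = candidate
        else:
            warnings.append("no-feasible-frequency")

    new_amp = state.amplitude
    if np.isneginf(metrics.stim_snr) or metrics.stim_snr < policy.target_stim_snr:
        step = policy.amplitude_step_fraction * state.pressure_threshold
        if state.amplitude >= state.pressure_threshold:
            warnings.append("amplitude-saturated")
        else:
            new_amp = min(state.amplitude + step, state.pressure_threshold)

    if new_freq == state.frequency and new_amp == state.amplitude:
        return state, tuple(warnings)
    return replace(state, frequency=new_freq, amplitude=new_amp), tuple(warnings)


def closed_loop_run(
    subject: SimulationConfig,
    controller: ControlPolicy = ControlPolicy(),
    n_steps: int = 5,
    seed: int = 0,
    initial_state: Optional[StimulationState] = None,
    step_duration: float = 12.0,
) -> pd.DataFrame:
    """Alternate simulate → decompose → metrics → adjust for ``n_steps`` steps.

    Each step simulates a short recording of the subject under the current
    stimulation drive (the pressure surrogate maps linearly to venous path
    amplitude through ``controller.pressure_to_path``), measures feedback
    metrics, and applies one controller update.  Seeded and reproducible:
    step k uses the derived seed ``(seed·1009 + k) mod 2^31``.

    Returns a step-by-step trace with the state before/after and the
    measured metrics.
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    state = initial_state or StimulationState(
        frequency=subject.stim_rate, amplitude=30.0, pressure_threshold=60.0
    )
    records = []
    pipe_defaults = PipelineConfig()
    for step in range(n_steps):
        import warnings as _w

        cfg = replace(
            subject,
            stim_rate=state.frequency,
            venous_stim_amp=controller.pressure_to_path * state.amplitude
            if state.enabled
            else 0.0,
            duration=step_duration,
            seed=(seed * 1009 + step) % 2**31,
        )
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # colliding drive is an expected transient
            ppg = simulate_ppg(cfg)
        spectrum = compute_power_spectrum(ppg)
        try:
            located = locate_component_peaks(
                spectrum, pipe_defaults.pulse_search, pipe_defaults.stim_search
            )
            comps = separate_components(ppg, located.pulse_freq, state.frequency)
        except (SeparationInfeasibleError, ConfigError, InvalidInputError):
            comps = None
        metrics = compute_feedback_metrics(
            comps, spectrum, state, n_harmonics=controller.n_harmonics
        )
        new_state, warns = adjust_stimulation(state, metrics, controller)
        records.append(
            {
                "step": step,
                "frequency": state.frequency,
                "amplitude": state.amplitude,
                "pulse_freq": metrics.pulse_freq,
                "stim_snr": metrics.stim_snr,
                "pulse_snr": metrics.pulse_snr,
                "separation": metrics.separation,
                "new_frequency": new_state.frequency,
                "new_amplitude": new_state.amplitude,
                "warnings": ";".join(warns),
            }
        )
        state = new_state
    return pd.DataFrame(records)
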