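"""Three-step venous oximetry: SpO2, Mixed_SpO2, and SvO2 per analysis window.

Step 1 removes the stimulation signal and computes ordinary pulse-band SpO2.
Step 2 applies the identical ratio-of-ratios computation to the
stimulation-band component, whose blood-volume oscillation samples both the
cuff-compressed veins and the co-compressed arteries; the resulting
saturation is a mixture, Mixed_SpO2.  Step 3 inverts the mixture model

    Mixed_SpO2 = w·SpO2 + (1−w)·SvO2,     w = 0.5 by default,

to SvO2 = (Mixed − w·SpO2)/(1−w) — for the default equal-weight mixture,
SvO2 = 2·Mixed_SpO2 − SpO2.  Oxygen consumption is reported as the
arteriovenous saturation difference SaO2 − SvO2 (percentage points), using
SpO2 as the arterial estimate.

Per-cycle R values use the exact log form ln(I_peak/I_trough) with the
peak/trough intensities reconstructed as DC ± AC/2; the window estimate is
the median over cycles for robustness.  Estimates outside [0, 100] % are
flagged, never silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .decompose import (
    BandSpec,
    ComponentSignals,
    PeakLocation,
    compute_power_spectrum,
    detect_cycle_extrema,
    extract_ac_dc,
    locate_component_peaks,
    separate_components,
)
from .errors import (
    ConfigError,
    InsufficientDataError,
    InvalidInputError,
    SeparationInfeasibleError,
    VenoximError,
)
from .optics import DEFAULT_COEFFICIENTS, OpticalCoefficients, _invert_r
from .simulate import DualWavelengthPPG


@dataclass(frozen=True)
class CalibrationMap:
    """Optional empirical linear calibration S = a − b·R (fractional saturation).

    Fitted against reference saturations (e.g. co-oximetry) in place of the
    theoretical coefficient-based inversion.
    """

    a: float
    b: float

    def __call__(self, r):
        return self.a - self.b * np.asarray(r, dtype=float)

    @classmethod
    def fit(cls, r_values: Sequence[float], s_reference: Sequence[float]) -> "CalibrationMap":
        r = np.asarray(r_values, dtype=float)
        s = np.asarray(s_reference, dtype=float)
        if len(r) != len(s) or len(r) < 2:
            raise InvalidInputError("need >= 2 paired (R, reference) points")
        slope, intercept = np.polyfit(r, s, 1)
        return cls(a=float(intercept), b=float(-slope))


@dataclass(frozen=True)
class PipelineConfig:
    """Windowing, search bands and mixture model for the extraction pipeline."""

    window_s: float = 10.0
    hop_s: float = 5.0
    arterial_weight: float = 0.5        # w in Mixed = w·SpO2 + (1−w)·SvO2
    pulse_search: BandSpec = BandSpec(center=1.5, half_width=1.0)   # 0.5–2.5 Hz
    stim_search: BandSpec = BandSpec(center=6.0, half_width=3.4)    # 2.6–9.4 Hz
    pulse_freq: Optional[float] = None  # known-drive overrides (else located)
    stim_freq: Optional[float] = None
    coefficients: OpticalCoefficients = DEFAULT_COEFFICIENTS
    calibration: Optional[CalibrationMap] = None
    range_slack: float = 0.05           # fractional slack before out-of-range flagging
    min_cycles: int = 3                 # cycles needed for a trusted window value

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ConfigError("window_s and hop_s must be > 0")
        if not (0.0 <= self.arterial_weight < 1.0):
            raise ConfigError("arterial_weight must lie in [0, 1)")
        if self.pulse_search.overlaps(self.stim_search):
            raise ConfigError("pulse and stimulation search bands must be disjoint")


@dataclass(frozen=True)
class OximetryResult:
    """Windowed saturation estimates with per-window quality flags.

    ``svo2 = (mixed_spo2 − w·spo2)/(1−w)`` holds wherever all three are
    reported; for the default w = 0.5 this is exactly 2·mixed − spo2.
    Out-of-range values are flagged through ``quality['in_range']``.
    """

    window_times: np.ndarray
    spo2: np.ndarray
    mixed_spo2: np.ndarray
    svo2: np.ndarray
    oxygen_consumption: np.ndarray
    quality: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "window_time": self.window_times,
                "spo2": self.spo2,
                "mixed_spo2": self.mixed_spo2,
                "svo2": self.svo2,
                "o2_consumption": self.oxygen_consumption,
            }
        )
        return pd.concat([df, self.quality.reset_index(drop=True)], axis=1)


class SvO2Estimate(NamedTuple):
    value: float
    in_range: bool


class ConsumptionEstimate(NamedTuple):
    value: float
    plausible: bool


def _window_saturation(
    ac_red, dc_red, ac_ir, dc_ir,
    coefs: OpticalCoefficients,
    calibration: Optional[CalibrationMap],
) -> float:
    """Median per-cycle saturation (percent) from paired AC/DC cycles."""
    ac_red = np.asarray(ac_red, dtype=float)
    ac_ir = np.asarray(ac_ir, dtype=float)
    dc_red = np.asarray(dc_red, dtype=float)
    dc_ir = np.asarray(dc_ir, dtype=float)
    if not (len(ac_red) == len(dc_red) == len(ac_ir) == len(dc_ir)):
        raise InvalidInputError("AC/DC arrays must be aligned across wavelengths")
    if len(ac_red) == 0:
        raise InsufficientDataError("no valid cycles")
    # Exact log-form R per cycle from reconstructed peak/trough intensities.
    ip_r, it_r = dc_red + ac_red / 2.0, dc_red - ac_red / 2.0
    ip_i, it_i = dc_ir + ac_ir / 2.0, dc_ir - ac_ir / 2.0
    ok = (it_r > 0) & (it_i > 0) & (ip_r > 0) & (ip_i > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.log(ip_r / it_r)
        den = np.log(ip_i / it_i)
        r = np.where(ok & (den != 0), num / np.where(den != 0, den, 1.0), np.nan)
    if calibration is not None:
        s = calibration(r)
    else:
        s = _invert_r(r, coefs)
    s = np.asarray(s, dtype=float)
    s = s[np.isfinite(s)]
    if len(s) == 0:
        raise InsufficientDataError("no finite per-cycle saturations")
    return float(np.median(s)) * 100.0


def compute_spo2(
    ac_red, dc_red, ac_ir, dc_ir,
    coefs: OpticalCoefficients = DEFAULT_COEFFICIENTS,
    calibration: Optional[CalibrationMap] = None,
) -> float:
    """Arterial SpO2 (percent) from pulse-band per-cycle AC/DC pairs.

    R is formed per cycle and mapped to saturation through the theoretical
    inversion (or the supplied empirical calibration); the window value is
    the median over cycles.
    """
    return _window_saturation(ac_red, dc_red, ac_ir, dc_ir, coefs, calibration)


def compute_mixed_spo2(
    ac_red, dc_red, ac_ir, dc_ir,
    coefs: OpticalCoefficients = DEFAULT_COEFFICIENTS,
    calibration: Optional[CalibrationMap] = None,
) -> float:
    """Mixed arterial/venous saturation (percent) from stimulation-band AC/DC pairs.

    Identical computation to :func:`compute_spo2`, applied to the
    cuff-stimulated component.
    """
    return _window_saturation(ac_red, dc_red, ac_ir, dc_ir, coefs, calibration)


def svo2_from_mixed(
    spo2: float, mixed: float, arterial_weight: float = 0.5
) -> SvO2Estimate:
    """Invert the mixture model to SvO2 (percent); flags out-of-range results.

    For the default equal-weight mixture this is exactly 2·mixed − spo2.
    """
    if not (np.isfinite(spo2) and np.isfinite(mixed)):
        raise InvalidInputError("spo2 and mixed must be finite")
    if not (0.0 <= arterial_weight < 1.0):
        raise InvalidInputError("arterial_weight must lie in [0, 1)")
    if arterial_weight == 0.5:
        value = 2.0 * mixed - spo2
    else:
        value = (mixed - arterial_weight * spo2) / (1.0 - arterial_weight)
    return SvO2Estimate(value=value, in_range=0.0 <= value <= 100.0)


def oxygen_consumption(sao2: float, svo2: float) -> ConsumptionEstimate:
    """Arteriovenous saturation difference SaO2 − SvO2 (percentage points).

    Negative values (venous above arterial) are physiologically implausible
    and flagged, not suppressed.
    """
    if not (np.isfinite(sao2) and np.isfinite(svo2)):
        raise InvalidInputError("sao2 and svo2 must be finite")
    value = sao2 - svo2
    return ConsumptionEstimate(value=value, plausible=value >= 0.0)


def run_pipeline(ppg: DualWavelengthPPG, config: PipelineConfig = PipelineConfig()) -> OximetryResult:
    """Full extraction chain: decompose → per-window cycles → AC/DC → saturations.

    The trace is decomposed once (the two fundamentals are located on the
    full-record spectrum unless fixed in the config), then windowed.  Windows
    in which a step fails (too few cycles, no prominent stimulation peak)
    carry NaN for the affected quantities and a False quality flag; errors
    never abort the whole record — in particular, disabling the stimulation
    degrades SvO2 to fully-flagged NaN while SpO2 is still produced.
    """
    time = np.asarray(ppg.time)
    n = len(ppg)
    spectrum = compute_power_spectrum(ppg, window_s=config.window_s)
    located = locate_component_peaks(spectrum, config.pulse_search, config.stim_search)
    pulse_freq = config.pulse_freq if config.pulse_freq is not None else located.pulse_freq
    stim_freq = config.stim_freq if config.stim_freq is not None else located.stim_freq
    stim_available = located.stim_prominent or (config.stim_freq is not None)

    fs = float(1.0 / np.median(np.diff(time)))
    separation_ok = True
    components: Optional[ComponentSignals] = None
    try:
        components = separate_components(ppg, pulse_freq, stim_freq)
    except SeparationInfeasibleError:
        separation_ok = False
        if stim_available:
            # Pulse-only fallback: keep SpO2 alive with a stimulation band
            # parked far from the pulse (its output will be flagged).
            stim_available = False
    if components is None:
        fallback_stim = min(4.0 * pulse_freq + 1.0, 0.45 * fs)
        components = separate_components(ppg, pulse_freq, fallback_stim)

    guard = components.edge_guard
    rows = []
    quality_rows = []
    win = int(round(config.window_s * fs))
    hop = int(round(config.hop_s * fs))
    if win < 2 or win > n:
        raise ConfigError("window length must fit inside the trace")

    for start in range(0, n - win + 1, hop):
        stop = start + win
        t_mid = float(time[start] + 0.5 * (time[stop - 1] - time[start]))
        lo = max(start, guard)
        hi = min(stop, n - guard)

        def _band_value(comp_red, comp_ir, dc_red, dc_ir, freq) -> tuple[float, int]:
            if hi - lo < max(2, int(2.0 * fs / freq)):
                raise InsufficientDataError("window shorter than two cycles after edge guard")
            pairs = detect_cycle_extrema(comp_ir[lo:hi], freq, fs)
            ac_i, dc_i = extract_ac_dc(comp_ir[lo:hi], dc_ir[lo:hi], pairs)
            ac_r, dc_r = extract_ac_dc(comp_red[lo:hi], dc_red[lo:hi], pairs)
            value = _window_saturation(
                ac_r, dc_r, ac_i, dc_i, config.coefficients, config.calibration
            )
            return value, len(pairs)

        spo2 = np.nan
        mixed = np.nan
        svo2 = np.nan
        consumption = np.nan
        n_pulse = n_stim = 0
        pulse_ok = False
        try:
            spo2, n_pulse = _band_value(
                components.pulse_red, components.pulse_ir,
                components.dc_red, components.dc_ir, pulse_freq,
            )
            pulse_ok = True
        except VenoximError:
            pass

        stim_ok = False
        if stim_available and separation_ok:
            try:
                mixed, n_stim = _band_value(
                    components.stim_red, components.stim_ir,
                    components.dc_red, components.dc_ir, stim_freq,
                )
                stim_ok = True
            except VenoximError:
                pass

        if pulse_ok and stim_ok:
            est = svo2_from_mixed(spo2, mixed, config.arterial_weight)
            svo2 = est.value
            consumption = oxygen_consumption(spo2, svo2).value

        slack = config.range_slack * 100.0
        values = [v for v in (spo2, mixed, svo2) if np.isfinite(v)]
        in_range = bool(values) and all(-slack <= v <= 100.0 + slack for v in values)
        rows.append((t_mid, spo2, mixed, svo2, consumption))
        quality_rows.append(
            {
                "separation_ok": separation_ok and stim_available,
                "snr_ok": stim_ok and n_stim >= config.min_cycles,
                "in_range": in_range,
                "n_pulse_cycles": n_pulse,
                "n_stim_cycles": n_stim,
            }
        )

    if not rows:
        raise InsufficientDataError("trace shorter than one analysis window")
    arr = np.array(rows, dtype=float)
    return OximetryResult(
        window_times=arr[:, 0],
        spo2=arr[:, 1],
        mixed_spo2=arr[:, 2],
        svo2=arr[:, 3],
        oxygen_consumption=arr[:, 4],
        quality=pd.DataFrame(quality_rows),
        meta={
            "pulse_freq": pulse_freq,
            "stim_freq": stim_freq,
            "located": located._asdict(),
            "separation_ok": separation_ok,
            "stim_available": stim_available,
            "arterial_weight": config.arterial_weight,
        },
    )
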