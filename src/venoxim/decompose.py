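"""Frequency-domain separation of pulse and stimulation components.

The cardiac pulse and the cuff stimulation occupy disjoint spectral bands
(the stimulation rate is controlled to keep them apart), so an ordinary
linear-phase FIR band-pass per band separates the two, and a moving mean
supplies the slowly varying DC baseline.  The per-cycle AC (peak-to-trough)
and DC values extracted here feed the ratio-of-ratios oximetry stage.

Numerical choices:

* Band half-widths default to 0.4× the band's fundamental, capped at 0.75×
  the distance to the nearest harmonic of the *other* component, because the
  cuff drive and the pulse both carry harmonics that must stay out of band.
* Filters are windowed-sinc (Hamming) band-passes of odd order; the
  transition width equals the band half-width, and the order follows from
  it.  The same filter is applied to both wavelength channels, so passband
  ripple cancels exactly in the red/infrared ratio.
* Filtering is zero-lag: symmetric FIR applied via reflection-padded
  convolution, so components stay time-aligned with the input.  Cycles
  within half a filter length of the trace ends are unreliable and callers
  should discard them (``ComponentSignals.edge_guard``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import (
    ConfigError,
    InsufficientDataError,
    InvalidInputError,
    ResampleRequiredError,
    SeparationInfeasibleError,
)
from .simulate import DualWavelengthPPG


@dataclass(frozen=True)
class BandSpec:
    """A frequency band given by its center and half-width (Hz)."""

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise InvalidInputError("band center must be > 0")
        if not (0 < self.half_width < self.center):
            raise InvalidInputError("band half_width must satisfy 0 < half_width < center")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width

    def overlaps(self, other: "BandSpec") -> bool:
        return self.lo < other.hi and other.lo < self.hi

    def contains(self, freq: float) -> bool:
        return self.lo <= freq <= self.hi


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density per wavelength channel."""

    frequency: np.ndarray
    power_red: np.ndarray
    power_ir: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency)
        if np.any(np.diff(f) <= 0) or f[0] < 0:
            raise InvalidInputError("frequency grid must be monotone from 0")
        if np.any(np.asarray(self.power_red) < 0) or np.any(np.asarray(self.power_ir) < 0):
            raise InvalidInputError("power must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.power_red + self.power_ir

    @property
    def resolution(self) -> float:
        return float(self.frequency[1] - self.frequency[0])


@dataclass(frozen=True)
class ComponentSignals:
    """Band-separated pulse/stimulation components plus DC baselines, time-aligned."""

    time: np.ndarray
    pulse_red: np.ndarray
    pulse_ir: np.ndarray
    stim_red: np.ndarray
    stim_ir: np.ndarray
    dc_red: np.ndarray
    dc_ir: np.ndarray
    pulse_band: BandSpec
    stim_band: BandSpec
    edge_guard: int = 0
    meta: dict = field(default_factory=dict)


class PeakLocation(NamedTuple):
    """Located spectral peaks and their prominence flags."""

    pulse_freq: float
    stim_freq: float
    pulse_prominent: bool
    stim_prominent: bool

    @property
    def separated(self) -> bool:
        return self.pulse_prominent and self.stim_prominent


class CyclePair(NamedTuple):
    peak: int
    trough: int


# ------------------------------------------------------------------ spectrum
def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if len(dt) < 1:
        raise InsufficientDataError("need at least 2 samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ResampleRequiredError("time base is not uniform; resample first")
    return 1.0 / dt[0]


def compute_power_spectrum(
    ppg: DualWavelengthPPG, window_s: float = 10.0, overlap: float = 0.5
) -> PowerSpectrum:
    """Welch power spectral density of both channels, mean-removed, Hann-tapered.

    Segment length defaults to 10 s (bounded by the trace length) with 50 %
    overlap, trading frequency resolution against variance for time series of
    around a minute.
    """
    fs = _check_uniform(np.asarray(ppg.time))
    n = len(ppg)
    nperseg = min(n, max(16, int(round(window_s * fs))))
    kwargs = dict(
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap * nperseg),
        detrend="constant",
    )
    f, p_red = sps.welch(np.asarray(ppg.i_red, dtype=float), **kwargs)
    _, p_ir = sps.welch(np.asarray(ppg.i_ir, dtype=float), **kwargs)
    return PowerSpectrum(frequency=f, power_red=p_red, power_ir=p_ir)


def locate_component_peaks(
    spectrum: PowerSpectrum,
    pulse_search: BandSpec,
    stim_search: BandSpec,
    *,
    prominence_ratio: float = 5.0,
    absolute_floor: float = 1e-4,
    harmonic_exclusion: float = 0.25,
    n_harmonics: int = 7,
) -> PeakLocation:
    """Locate the pulse and stimulation peaks within their search bands.

    The pulse peak is the argmax of the summed-channel power in
    ``pulse_search``.  Before locating the stimulation peak, narrow zones of
    ``harmonic_exclusion`` Hz around each pulse harmonic are masked out of
    ``stim_search`` so that pulse harmonics are never mistaken for the cuff
    drive.  A peak is flagged prominent when it exceeds
    ``prominence_ratio`` × the median in-band power *and*
    ``absolute_floor`` × the global spectral maximum; otherwise that
    component is reported as not reliably present.  Ties break to the lowest
    frequency.
    """
    if pulse_search.overlaps(stim_search):
        raise InvalidInputError("pulse and stimulation search bands must be disjoint")
    f = spectrum.frequency
    power = spectrum.total
    global_max = float(power.max())

    def _peak(mask: np.ndarray) -> tuple[float, bool]:
        if not np.any(mask):
            raise ConfigError("search band is empty after masking")
        idx = np.flatnonzero(mask)
        best = idx[np.argmax(power[idx])]  # argmax returns first max: lowest frequency
        band_median = float(np.median(power[idx]))
        prominent = (
            power[best] >= prominence_ratio * max(band_median, np.finfo(float).tiny)
            and power[best] >= absolute_floor * global_max
        )
        return float(f[best]), bool(prominent)

    pulse_mask = (f >= pulse_search.lo) & (f <= pulse_search.hi)
    pulse_freq, pulse_prominent = _peak(pulse_mask)

    stim_mask = (f >= stim_search.lo) & (f <= stim_search.hi)
    if pulse_prominent:
        for k in range(1, n_harmonics + 1):
            stim_mask &= np.abs(f - k * pulse_freq) > harmonic_exclusion
    stim_freq, stim_prominent = _peak(stim_mask)
    return PeakLocation(pulse_freq, stim_freq, pulse_prominent, stim_prominent)


# ------------------------------------------------------------------ filtering
def design_component_bands(
    pulse_freq: float,
    stim_freq: float,
    *,
    band_fraction: float = 0.4,
    harmonic_guard: float = 0.75,
    n_harmonics: int = 4,
    min_half_width: float = 0.05,
) -> tuple[BandSpec, BandSpec]:
    """Choose pulse and stimulation extraction bands around the two fundamentals.

    Each half-width is ``band_fraction`` × the fundamental, capped at
    ``harmonic_guard`` × the distance to the nearest harmonic (k = 1..n) of
    the other component.  Raises :class:`SeparationInfeasibleError` when the
    frequencies are too close for usable bands — the controller's cue to move
    the stimulation frequency.
    """
    if pulse_freq <= 0 or stim_freq <= 0:
        raise InvalidInputError("frequencies must be > 0")

    def _dist_to_harmonics(freq: float, base: float) -> float:
        return min(abs(freq - k * base) for k in range(1, n_harmonics + 1))

    hw_stim = min(band_fraction * stim_freq,
                  harmonic_guard * _dist_to_harmonics(stim_freq, pulse_freq))
    hw_pulse = min(band_fraction * pulse_freq,
                   harmonic_guard * _dist_to_harmonics(pulse_freq, stim_freq))
    if hw_stim < min_half_width or hw_pulse < min_half_width:
        raise SeparationInfeasibleError(
            f"pulse {pulse_freq:.3g} Hz and stimulation {stim_freq:.3g} Hz are too "
            "close (or harmonically colliding) for band separation"
        )
    pulse_band = BandSpec(pulse_freq, hw_pulse)
    stim_band = BandSpec(stim_freq, hw_stim)
    if pulse_band.overlaps(stim_band):
        raise SeparationInfeasibleError("pulse and stimulation bands overlap")
    return pulse_band, stim_band


def _fir_bandpass(band: BandSpec, fs: float, n_samples: int) -> np.ndarray:
    """Odd-order Hamming windowed-sinc band-pass with transition ≈ the half-width."""
    transition = band.half_width
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps = min(numtaps, 2 * n_samples - 3)  # reflection padding bound
    numtaps = max(numtaps, 21)
    if numtaps % 2 == 0:
        numtaps += 1
    hi = min(band.hi, 0.49 * fs)
    return sps.firwin(numtaps, [band.lo, hi], pass_zero=False, fs=fs, window="hamming")


def _apply_zero_lag(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Linear-phase FIR with group delay compensated via reflection padding."""
    half = len(taps) // 2
    xp = np.pad(x, half, mode="reflect")
    return np.convolve(xp, taps, mode="valid")


def separate_components(
    ppg: DualWavelengthPPG,
    pulse_freq: float,
    stim_freq: float,
    *,
    pulse_band: Optional[BandSpec] = None,
    stim_band: Optional[BandSpec] = None,
    dc_periods: float = 2.0,
) -> ComponentSignals:
    """Split the trace into pulse-band, stimulation-band and DC parts per channel.

    DC is a moving mean over ``dc_periods`` periods of the slower component
    (a uniform window spanning whole periods nulls that fundamental).  The
    reconstruction pulse + stim + DC approximates the input within the
    modeled bands; out-of-band harmonics of the cuff drive are deliberately
    discarded.
    """
    fs = _check_uniform(np.asarray(ppg.time))
    n = len(ppg)
    if pulse_band is None or stim_band is None:
        designed = design_component_bands(pulse_freq, stim_freq)
        pulse_band = pulse_band or designed[0]
        stim_band = stim_band or designed[1]
    if pulse_band.overlaps(stim_band):
        raise SeparationInfeasibleError("pulse and stimulation bands overlap")

    taps_pulse = _fir_bandpass(pulse_band, fs, n)
    taps_stim = _fir_bandpass(stim_band, fs, n)
    dc_win = max(3, int(round(dc_periods * fs / min(pulse_freq, stim_freq))))

    out = {}
    for name, trace in (("red", ppg.i_red), ("ir", ppg.i_ir)):
        x = np.asarray(trace, dtype=float)
        x0 = x - x.mean()
        out[f"pulse_{name}"] = _apply_zero_lag(x0, taps_pulse)
        out[f"stim_{name}"] = _apply_zero_lag(x0, taps_stim)
        out[f"dc_{name}"] = uniform_filter1d(x, size=dc_win, mode="reflect")

    edge_guard = max(len(taps_pulse), len(taps_stim)) // 2
    return ComponentSignals(
        time=np.asarray(ppg.time),
        pulse_band=pulse_band,
        stim_band=stim_band,
        edge_guard=edge_guard,
        meta={"fs": fs, "numtaps": (len(taps_pulse), len(taps_stim)), "dc_window": dc_win},
        **out,
    )


# ------------------------------------------------------------------ cycles
def detect_cycle_extrema(
    component: np.ndarray, freq: float, fs: float
) -> list[CyclePair]:
    """One (peak, trough) index pair per cycle of a band-limited component.

    Extrema are found with a minimum spacing of 0.6 periods; each peak is
    paired with the nearest following trough.  Pairs are ordered in time.
    """
    x = np.asarray(component, dtype=float)
    if freq <= 0 or fs <= 0:
        raise InvalidInputError("freq and fs must be > 0")
    distance = max(1, int(round(0.6 * fs / freq)))
    peaks, _ = sps.find_peaks(x, distance=distance)
    troughs, _ = sps.find_peaks(-x, distance=distance)
    pairs: list[CyclePair] = []
    j = 0
    for p in peaks:
        while j < len(troughs) and troughs[j] <= p:
            j += 1
        if j < len(troughs):
            pairs.append(CyclePair(peak=int(p), trough=int(troughs[j])))
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"found {len(pairs)} cycle(s); need at least 2 full cycles"
        )
    return pairs


def detect_stimulation_peaks(
    stim_component: np.ndarray, stim_freq: float, fs: float
) -> list[CyclePair]:
    """Peak/trough pairs of the stimulation component, one per cuff cycle."""
    return detect_cycle_extrema(stim_component, stim_freq, fs)


def extract_ac_dc(
    component: np.ndarray,
    dc: np.ndarray,
    pairs: Sequence[CyclePair],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle AC (peak-to-trough difference) and DC (baseline at cycle midpoint).

    The same index pairs may be applied to both wavelength channels — the two
    channels are modulated by the same waveform, so their extrema coincide in
    time and using shared indices avoids a noise-driven extremum-selection
    bias between channels.
    """
    component = np.asarray(component, dtype=float)
    dc = np.asarray(dc, dtype=float)
    if len(component) != len(dc):
        raise InvalidInputError("component and dc must share the time base")
    if len(pairs) == 0:
        raise InsufficientDataError("no cycle pairs supplied")
    ac = np.array([component[p.peak] - component[p.trough] for p in pairs])
    dcv = np.array([dc[(p.peak + p.trough) // 2] for p in pairs])
    if np.any(dcv <= 0):
        raise InvalidInputError("non-positive DC baseline: invalid signal")
    return ac, dcv
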