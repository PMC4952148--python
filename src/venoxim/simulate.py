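"""Synthetic dual-wavelength PPG generator for cuff-stimulated venous oximetry.

The model is a finger illuminated in transmission whose optical path
comprises three compartments:

* static tissue, a fixed absorbance offset per wavelength;
* an arterial compartment whose optical path pulsates at the cardiac rate
  with saturation SaO2;
* a venous compartment whose optical path is periodically compressed by an
  air cuff at a stimulation rate distinct from the pulse rate, with
  saturation SvO2.

Transmitted intensity per wavelength is

    I(λ,t) = I0 · exp(−[A_static(λ) + μ(λ, SaO2)·l_a(t) + μ(λ, SvO2)·l_v(t)]) + noise

with μ(λ, s) = s·ε_HbO2(λ) + (1−s)·ε_Hb(λ).  The arterial path carries an
asymmetric raised-cosine beat; the venous path carries a smoothed
rectangular inflation/deflation profile (finite rise time), so the
stimulation drive has harmonic content that the decomposition stage must
reject.  The cuff also compresses arterial vessels, so a configurable
fraction of the stimulation waveform leaks into the arterial path
(``arterial_stim_coupling``); at the default coupling of 1 the
stimulation-band signal is an equal arterial/venous mixture, which is the
mixture model the downstream Mixed_SpO2 → SvO2 inversion assumes.

Noise is additive white Gaussian on intensity with standard deviation
``noise_sd`` relative to the clean mean intensity of each channel.  Every
stochastic run requires an explicit seed; identical seeds give bit-identical
traces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidInputError
from .optics import DEFAULT_COEFFICIENTS, IR, RED, OpticalCoefficients, _sat_value


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario description for one simulated recording.

    Path quantities are in consistent (concentration·length) units matching
    the reciprocal units of the extinction coefficients; with the default
    coefficient set (mM⁻¹·cm⁻¹) they read as cm·mM.  The defaults give
    pulse-band intensity modulations of roughly 1–4 % and a stimulation-band
    modulation of a few percent, typical of transmission finger PPG.
    """

    sampling_rate: float = 100.0      # Hz
    duration: float = 60.0            # s
    pulse_rate: float = 1.2           # Hz (72 bpm)
    stim_rate: float = 4.0            # Hz cuff inflation/deflation rate
    sao2: float = 0.98                # arterial saturation (fraction)
    svo2: float = 0.75                # venous saturation (fraction)
    static_absorbance_red: float = 0.45
    static_absorbance_ir: float = 0.35
    arterial_path_mean: float = 0.20
    arterial_path_amp: float = 0.03
    venous_path_mean: float = 0.25
    venous_stim_amp: float = 0.02
    arterial_stim_coupling: float = 1.0   # cuff squeezes arteries and veins alike
    noise_sd: float = 0.002           # relative to clean mean intensity
    incident_intensity: float = 1.0
    seed: Optional[int] = None
    clip_negative: bool = True        # clip (with warning) vs raise on negative intensity
    coefficients: OpticalCoefficients = DEFAULT_COEFFICIENTS

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * max(self.pulse_rate, self.stim_rate):
            raise ConfigError(
                f"sampling_rate {self.sampling_rate} Hz violates Nyquist for "
                f"pulse {self.pulse_rate} / stim {self.stim_rate} Hz"
            )
        if self.stim_rate == self.pulse_rate:
            # Permitted (the feedback controller must be able to experience and
            # escape a frequency collision) but spectrally unseparable.
            warnings.warn(
                "stim_rate equals pulse_rate: components cannot be separated",
                stacklevel=2,
            )
        if self.duration <= 0 or self.pulse_rate <= 0 or self.stim_rate <= 0:
            raise ConfigError("duration, pulse_rate and stim_rate must be > 0")
        for name in ("arterial_path_mean", "arterial_path_amp",
                     "venous_path_mean", "venous_stim_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.arterial_path_amp >= self.arterial_path_mean > 0 and self.arterial_path_amp > 0:
            raise ConfigError("arterial_path_amp must be smaller than arterial_path_mean")
        if self.venous_stim_amp >= self.venous_path_mean > 0 and self.venous_stim_amp > 0:
            raise ConfigError("venous_stim_amp must be smaller than venous_path_mean")
        if self.arterial_stim_coupling < 0:
            raise ConfigError("arterial_stim_coupling must be >= 0")
        if not (0.0 <= self.sao2 <= 1.0 and 0.0 <= self.svo2 <= 1.0):
            raise ConfigError("sao2 and svo2 must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ConfigError("a seed is required for any stochastic run (noise_sd > 0)")
        if self.incident_intensity <= 0:
            raise ConfigError("incident_intensity must be > 0")

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = self.coefficients.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        coefs = d.pop("coefficients", None)
        if coefs is not None and not isinstance(coefs, OpticalCoefficients):
            coefs = OpticalCoefficients(**coefs)
        return cls(**d, **({"coefficients": coefs} if coefs is not None else {}))

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a scenario from YAML or JSON (chosen by file extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class DualWavelengthPPG:
    """Sampled transmitted-intensity traces at 660 and 940 nm on a uniform time base."""

    time: np.ndarray
    i_red: np.ndarray
    i_ir: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, r, i = map(np.asarray, (self.time, self.i_red, self.i_ir))
        if not (len(t) == len(r) == len(i)):
            raise InvalidInputError("time, i_red and i_ir must have equal lengths")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("time must be strictly increasing")
        if np.any(r <= 0) or np.any(i <= 0):
            raise InvalidInputError("intensities must be strictly positive")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "i660": self.i_red, "i940": self.i_ir})


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered list of (level, replicate, repeat) sampling events."""

    levels: Sequence[float]
    samples_per_level: int
    repeats: int
    points: Sequence[tuple]

    def __len__(self) -> int:
        return len(self.points)


# ------------------------------------------------------------------ waveforms
def pulse_waveform(phase, rise: float = 0.15, fall: float = 0.30):
    """Asymmetric cardiac beat template on phase in [0, 1): value in [0, 1].

    Raised-cosine systolic upstroke of width ``rise`` followed by a slower
    raised-cosine decay of width ``fall``; diastole is flat.  The template is
    C1-smooth so its harmonics roll off quickly.
    """
    x = np.asarray(phase, dtype=float) % 1.0
    up = 0.5 * (1.0 - np.cos(np.pi * x / rise))
    down = 0.5 * (1.0 + np.cos(np.pi * (x - rise) / fall))
    return np.where(x < rise, up, np.where(x < rise + fall, down, 0.0))


def cuff_waveform(phase, duty: float = 0.5, rise: float = 0.10):
    """Smoothed rectangular cuff inflation profile on phase in [0, 1): value in [0, 1].

    Plateau of width ``duty`` with raised-cosine edges of width ``rise`` —
    the finite-rise-time analogue of periodic inflation/deflation.  Odd
    harmonics are present by construction.
    """
    x = np.asarray(phase, dtype=float) % 1.0
    up = 0.5 * (1.0 - np.cos(np.pi * x / rise))
    down = 0.5 * (1.0 + np.cos(np.pi * (x - duty) / rise))
    return np.where(
        x < rise, up,
        np.where(x < duty, 1.0, np.where(x < duty + rise, down, 0.0)),
    )


# ------------------------------------------------------------------ synthesis
def _synthesize(
    t: np.ndarray,
    sao2: np.ndarray,
    svo2: np.ndarray,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator],
) -> DualWavelengthPPG:
    """Core forward model shared by constant-saturation and protocol runs."""
    coefs = cfg.coefficients
    pulse = pulse_waveform(t * cfg.pulse_rate)
    stim = cuff_waveform(t * cfg.stim_rate)

    l_a = (cfg.arterial_path_mean
           + cfg.arterial_path_amp * pulse
           + cfg.arterial_stim_coupling * cfg.venous_stim_amp * stim)
    l_v = cfg.venous_path_mean + cfg.venous_stim_amp * stim

    channels = {}
    truth_absorbance = {}
    for wl, static in ((RED, cfg.static_absorbance_red), (IR, cfg.static_absorbance_ir)):
        a_art = coefs.effective(sao2, wl) * l_a
        a_ven = coefs.effective(svo2, wl) * l_v
        absorbance = static + a_art + a_ven
        clean = cfg.incident_intensity * np.exp(-absorbance)
        sig = clean
        if cfg.noise_sd > 0:
            sig = clean + rng.normal(0.0, cfg.noise_sd * clean.mean(), size=clean.shape)
            bad = sig <= 0
            if np.any(bad):
                if cfg.clip_negative:
                    warnings.warn(
                        f"{int(bad.sum())} non-positive samples clipped after noise",
                        stacklevel=2,
                    )
                    sig = np.where(bad, np.finfo(float).tiny, sig)
                else:
                    raise InvalidInputError("noise drove intensity non-positive")
        channels[wl] = sig
        truth_absorbance[wl] = {"static": static, "arterial": a_art, "venous": a_ven}

    meta = {
        "config": cfg.to_dict(),
        "truth": {
            "sao2": np.broadcast_to(sao2, t.shape).copy(),
            "svo2": np.broadcast_to(svo2, t.shape).copy(),
            "l_arterial": l_a,
            "l_venous": l_v,
            "absorbance": truth_absorbance,
        },
    }
    return DualWavelengthPPG(time=t, i_red=channels[RED], i_ir=channels[IR], meta=meta)


def simulate_ppg(config: SimulationConfig) -> DualWavelengthPPG:
    """Simulate one recording at constant arterial and venous saturations.

    The returned trace carries ground truth (per-sample saturations and
    compartment paths) in ``meta['truth']`` for recovery testing.
    """
    n = int(round(config.duration * config.sampling_rate))
    if n < 2:
        raise ConfigError("duration × sampling_rate must give at least 2 samples")
    t = np.arange(n) / config.sampling_rate
    rng = np.random.default_rng(config.seed) if config.noise_sd > 0 else None
    sao2 = np.full(n, _sat_value(config.sao2))
    svo2 = np.full(n, _sat_value(config.svo2))
    return _synthesize(t, sao2, svo2, config, rng)


def hypoxia_protocol(
    levels: Sequence,
    dwell: float,
    config: SimulationConfig,
    svo2_levels: Optional[Sequence] = None,
) -> tuple[DualWavelengthPPG, pd.DataFrame]:
    """Step the arterial saturation through ``levels``, dwelling ``dwell`` s at each.

    The venous saturation steps in parallel: explicitly via ``svo2_levels``,
    or by default offset below each arterial level by the configured
    arterial–venous gap ``config.sao2 − config.svo2``.  Returns the trace and
    a per-sample ground-truth table (time, level index, sao2, svo2).
    """
    levels = [_sat_value(v) for v in levels]
    if not levels:
        raise ConfigError("hypoxia protocol needs at least one level")
    if dwell <= 0:
        raise ConfigError("dwell must be > 0")
    if any(not 0.0 <= v <= 1.0 for v in levels):
        raise ConfigError("levels must lie in [0, 1]")
    if svo2_levels is None:
        gap = _sat_value(config.sao2) - _sat_value(config.svo2)
        svo2_levels = [min(max(v - gap, 0.0), 1.0) for v in levels]
    else:
        svo2_levels = [_sat_value(v) for v in svo2_levels]
        if len(svo2_levels) != len(levels):
            raise ConfigError("svo2_levels must match levels in length")

    cfg = replace(config, duration=dwell * len(levels))
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    idx = np.minimum((t / dwell).astype(int), len(levels) - 1)
    sao2 = np.asarray(levels, dtype=float)[idx]
    svo2 = np.asarray(svo2_levels, dtype=float)[idx]
    rng = np.random.default_rng(cfg.seed) if cfg.noise_sd > 0 else None
    ppg = _synthesize(t, sao2, svo2, cfg, rng)
    truth = pd.DataFrame({"time": t, "level": idx, "sao2": sao2, "svo2": svo2})
    return ppg, truth


def build_sampling_schedule(
    levels: int, samples_per_level: int, repeats: int
) -> SamplingSchedule:
    """Ordered sampling schedule: ``levels × samples_per_level × repeats`` events.

    Mirrors a stepped desaturation protocol in which several samples are drawn
    at each saturation level and the whole sweep is repeated.
    """
    if levels < 1 or samples_per_level < 1 or repeats < 1:
        raise ConfigError("levels, samples_per_level and repeats must all be >= 1")
    points = [
        (level, replicate, repeat)
        for repeat in range(repeats)
        for level in range(levels)
        for replicate in range(samples_per_level)
    ]
    return SamplingSchedule(
        levels=list(range(levels)),
        samples_per_level=samples_per_level,
        repeats=repeats,
        points=points,
    )


# ------------------------------------------------------------------ file I/O
def write_ppg_csv(ppg: DualWavelengthPPG, path, truth_path=None) -> None:
    """Write a trace as CSV (columns time, i660, i940); optional truth sidecar JSON."""
    ppg.to_frame().to_csv(path, index=False)
    if truth_path is not None:
        truth = ppg.meta.get("truth", {})
        payload = {
            "config": ppg.meta.get("config"),
            "sao2": np.asarray(truth.get("sao2", [])).tolist(),
            "svo2": np.asarray(truth.get("svo2", [])).tolist(),
        }
        Path(truth_path).write_text(json.dumps(payload))


def read_ppg_csv(path) -> DualWavelengthPPG:
    """Read a trace from CSV with columns time, i660, i940."""
    df = pd.read_csv(path)
    required = {"time", "i660", "i940"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
    return DualWavelengthPPG(
        time=df["time"].to_numpy(dtype=float),
        i_red=df["i660"].to_numpy(dtype=float),
        i_ir=df["i940"].to_numpy(dtype=float),
        meta={"source": str(path)},
    )
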