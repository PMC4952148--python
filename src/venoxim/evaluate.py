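"""Agreement statistics between noninvasive estimates and reference values.

Designed for paired series in the roles the validation protocol uses:
a reference (invasive co-oximetry, or simulated ground truth) against the
noninvasive estimate.  Provides RMSE, Pearson correlation, a difference
analysis with a ±band membership summary (no outlier exclusion, ever), a
Bland–Altman-style limits-of-agreement summary, and a paired oxygen
consumption comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConstantSeriesError, InvalidInputError
from .pipeline import OximetryResult


@dataclass(frozen=True)
class PairedSeries:
    """Paired reference/estimate saturation values (percent)."""

    reference: np.ndarray
    estimate: np.ndarray
    labels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        est = np.asarray(self.estimate, dtype=float)
        if len(ref) != len(est):
            raise AlignmentError("reference and estimate must have equal lengths")
        if len(ref) < 1:
            raise InvalidInputError("paired series must be non-empty")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "estimate", est)
        if self.labels is not None and len(self.labels) != len(ref):
            raise AlignmentError("labels must match the series length")

    def __len__(self) -> int:
        return len(self.reference)

    @property
    def differences(self) -> np.ndarray:
        return self.estimate - self.reference


def rmse(pairs: PairedSeries) -> float:
    """Root mean square error of estimate − reference."""
    d = pairs.differences
    return float(np.sqrt(np.mean(d * d)))


def pearson_correlation(pairs: PairedSeries) -> float:
    """Product-moment correlation between estimate and reference series."""
    if len(pairs) < 2:
        raise InvalidInputError("correlation needs at least 2 pairs")
    if np.ptp(pairs.reference) == 0 or np.ptp(pairs.estimate) == 0:
        raise ConstantSeriesError("correlation is undefined for a constant series")
    return float(stats.pearsonr(pairs.reference, pairs.estimate).statistic)


@dataclass(frozen=True)
class DifferenceSummary:
    """Per-pair differences with band membership and Bland–Altman limits.

    Every input pair is represented; no outlier is ever excluded.
    """

    differences: np.ndarray
    within_band: np.ndarray
    band: float
    mean: float
    sd: float
    loa_lower: float           # mean − 1.96·sd
    loa_upper: float           # mean + 1.96·sd
    min: float
    max: float
    fraction_within: float
    n: int = field(default=0)


def difference_analysis(pairs: PairedSeries, band: float = 10.0) -> DifferenceSummary:
    """Differences estimate − reference with ±``band`` membership and summary."""
    d = pairs.differences
    within = np.abs(d) <= band
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    mean = float(np.mean(d))
    return DifferenceSummary(
        differences=d,
        within_band=within,
        band=band,
        mean=mean,
        sd=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        min=float(d.min()),
        max=float(d.max()),
        fraction_within=float(np.mean(within)),
        n=len(d),
    )


def consumption_comparison(
    noninvasive: OximetryResult,
    reference_sao2: Sequence[float],
    reference_svo2: Sequence[float],
) -> pd.DataFrame:
    """Per-window oxygen consumption (SaO2 − SvO2) of both sources, aligned.

    The noninvasive source uses the pipeline's windowed estimates; the
    reference arrays must align with the result windows.  Returns a table
    with both consumptions and their disagreement per window.
    """
    ref_a = np.asarray(reference_sao2, dtype=float)
    ref_v = np.asarray(reference_svo2, dtype=float)
    n = len(noninvasive.window_times)
    if len(ref_a) != n or len(ref_v) != n:
        raise AlignmentError(
            f"reference arrays (len {len(ref_a)}/{len(ref_v)}) must align with "
            f"{n} result windows"
        )
    est = noninvasive.oxygen_consumption
    ref = ref_a - ref_v
    return pd.DataFrame(
        {
            "window_time": noninvasive.window_times,
            "consumption_noninvasive": est,
            "consumption_reference": ref,
            "disagreement": est - ref,
        }
    )
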