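"""Mean Difference Value (MDV) statistic, quality gate and classifier.

The MDV summarises a DEP spectrum as the difference between the mean
response over a low-frequency band (default: the 9 lowest-frequency
valid points) and a high-frequency band (the 9 highest).  Cancer-arm
spectra sit lower below the crossover and higher above it, so their
MDV is smaller; a sample is called cancerous when its MDV falls below a
threshold.  Samples whose spectrum has exceptionally low standard
deviation across frequency carry no real DEP curve (too few cells) and
are excluded before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .processing import ProcessedSample

__all__ = [
    "MDVConfig",
    "MDVResult",
    "spectrum_sd",
    "exclusion_filter",
    "compute_mdv",
    "classify",
]

BAND_MODES = ("by_frequency", "by_value")

EXCLUDED = "excluded"


@dataclass(frozen=True)
class MDVConfig:
    """Band sizes, decision threshold and exclusion cut.

    ``band_mode='by_frequency'`` (default) reads the low/high bands as
    the lowest/highest *frequencies*; ``'by_value'`` as the smallest/
    largest *values*.  ``sign='low_minus_high'`` fixes the orientation
    MDV = low_mean - high_mean; flip with ``'high_minus_low'``.
    """

    n_low: int = 9
    n_high: int = 9
    threshold: float = 0.65
    sd_min: float = 0.4
    band_mode: str = "by_frequency"
    sign: str = "low_minus_high"

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("band sizes must be >= 1")
        if self.band_mode not in BAND_MODES:
            raise ValueError(f"band_mode must be one of {BAND_MODES}")
        if self.sign not in ("low_minus_high", "high_minus_low"):
            raise ValueError("sign must be low_minus_high or high_minus_low")
        if self.sd_min < 0:
            raise ValueError("sd_min must be >= 0")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class MDVResult:
    sample_id: str
    arm: Optional[str]
    low_mean: float
    high_mean: float
    mdv: float
    spectrum_sd: float
    excluded: bool
    predicted: str  # "cancer", "control" or "excluded"


def spectrum_sd(sample: ProcessedSample) -> float:
    """Sample SD (n-1 denominator) of the valid median-spectrum values."""
    vals = sample.median_spectrum.valid_values
    if vals.size < 2:
        raise ValueError(
            f"sample {sample.sample_id}: need >= 2 valid points for spectrum SD"
        )
    return float(np.std(vals, ddof=1))


def exclusion_filter(sample: ProcessedSample, config: MDVConfig) -> bool:
    """True when the sample's spectrum SD is below ``sd_min`` (strict).

    Low cell counts leave no real DEP curve, hence no wide spread
    between the low and high plateaux: the spectrum SD collapses to the
    noise floor.
    """
    return spectrum_sd(sample) < config.sd_min


def _band_indices(
    values: np.ndarray, freqs: np.ndarray, config: MDVConfig
) -> tuple[np.ndarray, np.ndarray]:
    if config.band_mode == "by_frequency":
        order = np.argsort(freqs, kind="stable")
    else:
        order = np.argsort(values, kind="stable")
    return order[: config.n_low], order[-config.n_high:]


def compute_mdv(
    sample: ProcessedSample,
    config: MDVConfig = MDVConfig(),
    apply_exclusion: bool = True,
    allow_overlap: bool = False,
) -> MDVResult:
    """Compute band means, MDV, spectrum SD and the predicted label.

    Only valid (unmasked) points participate.  With ``apply_exclusion``
    the SD gate runs first and an excluded sample's prediction is
    ``"excluded"``; otherwise every sample is classified.  By default
    fewer valid points than ``n_low + n_high`` is an error; with
    ``allow_overlap`` the two bands may share mid-band points (each band
    alone still needs enough valid points), which keeps samples with
    several dead connections scorable.
    """
    spec = sample.median_spectrum
    vals = spec.valid_values
    freqs = spec.valid_frequencies
    needed = (
        max(config.n_low, config.n_high)
        if allow_overlap
        else config.n_low + config.n_high
    )
    if vals.size < needed:
        raise ValueError(
            f"sample {sample.sample_id}: {vals.size} valid points < "
            f"required {needed}"
        )
    low_idx, high_idx = _band_indices(vals, freqs, config)
    low_mean = float(vals[low_idx].mean())
    high_mean = float(vals[high_idx].mean())
    mdv = low_mean - high_mean
    if config.sign == "high_minus_low":
        mdv = -mdv
    sd = spectrum_sd(sample)
    excluded = apply_exclusion and sd < config.sd_min
    result = MDVResult(
        sample_id=sample.sample_id,
        arm=sample.arm,
        low_mean=low_mean,
        high_mean=high_mean,
        mdv=mdv,
        spectrum_sd=sd,
        excluded=excluded,
        predicted=EXCLUDED,
    )
    return classify(result, config)


def classify(result: MDVResult, config: MDVConfig) -> MDVResult:
    """Threshold rule: cancer iff MDV < threshold (strict), else control.

    Excluded samples pass through untouched with label ``"excluded"``.
    """
    if result.excluded:
        return replace(result, predicted=EXCLUDED)
    label = "cancer" if result.mdv < config.threshold else "control"
    return replace(result, predicted=label)
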