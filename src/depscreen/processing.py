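"""Raw-spectrum processing: repeat medians, dead-point masking, arm means.

The per-sample summary curve is the median across technical repeats
(robust to the heavy noise of clinical spectra); dead-connection
frequency points are masked automatically by a relative-magnitude rule;
arm-level mean spectra and rolling-average trendlines support the
exploratory comparison of the two arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SampleRecord
from .shell_model import FrequencyGrid, Spectrum

__all__ = [
    "ProcessedSample",
    "median_across_repeats",
    "detect_dead_points",
    "rolling_average",
    "arm_mean_spectrum",
    "process_sample",
    "DEFAULT_DEAD_THRESHOLD",
]

#: Default near-zero cut (DEP-response units) for dead-connection detection.
DEFAULT_DEAD_THRESHOLD = 0.02


@dataclass
class ProcessedSample:
    """Per-sample median spectrum with the dead-point mask applied."""

    sample_id: str
    arm: str
    median_spectrum: Spectrum
    n_repeats_used: int


def median_across_repeats(record: SampleRecord) -> ProcessedSample:
    """Per-frequency median over technical repeats.

    Even repeat counts use the midpoint of the two central values (the
    numpy convention).  The mask starts all-valid; dead-point masking is
    a separate step (:func:`detect_dead_points`).
    """
    if not record.repeats:
        raise ValueError(f"sample {record.sample_id}: no repeats")
    mat = record.repeat_matrix()
    med = np.median(mat, axis=0)
    return ProcessedSample(
        sample_id=record.sample_id,
        arm=record.arm,
        median_spectrum=Spectrum(grid=record.grid, values=med),
        n_repeats_used=mat.shape[0],
    )


def detect_dead_points(
    record: SampleRecord, dead_threshold: float = DEFAULT_DEAD_THRESHOLD
) -> np.ndarray:
    """Flag dead-connection frequency points in a raw sample.

    A point is flagged when its median absolute reading across repeats
    falls below ``dead_threshold`` while the spectrum's overall median
    absolute level is at least twice that — i.e. the point is a
    near-zero outlier relative to a real curve.  A uniformly near-zero
    spectrum (a low-cell sample) fails the guard and gets no mask: such
    samples are handled by the SD-based exclusion filter, not here.

    Returns the boolean mask of *dead* points; the data are not
    modified.
    """
    mat = np.abs(record.repeat_matrix())
    point_level = np.median(mat, axis=0)
    overall_level = np.median(point_level)
    if overall_level < 2.0 * dead_threshold:
        return np.zeros(point_level.size, dtype=bool)
    return point_level < dead_threshold


def rolling_average(spectrum: Spectrum, window: int = 2) -> np.ndarray:
    """Moving mean over consecutive valid points (trendline only).

    Output has ``n_valid - window + 1`` points.  Used for plotting arm
    trends; never feeds the MDV statistic.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = spectrum.valid_values
    if window > vals.size:
        raise ValueError(f"window {window} exceeds {vals.size} valid points")
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def arm_mean_spectrum(samples: list[ProcessedSample], arm: str) -> Spectrum:
    """Per-frequency mean of an arm's median spectra.

    Points masked in a sample are omitted from that frequency's mean; a
    frequency masked in every sample is masked in the output.
    """
    members = [s for s in samples if s.arm == arm]
    if not members:
        raise ValueError(f"no samples in arm {arm!r}")
    grid = members[0].median_spectrum.grid
    values = np.vstack([s.median_spectrum.values for s in members])
    masks = np.vstack([s.median_spectrum.mask for s in members])
    counts = masks.sum(axis=0)
    out_mask = counts > 0
    sums = np.where(masks, values, 0.0).sum(axis=0)
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=out_mask)
    return Spectrum(grid=grid, values=mean, mask=out_mask)


def process_sample(
    record: SampleRecord, dead_threshold: float = DEFAULT_DEAD_THRESHOLD
) -> ProcessedSample:
    """Median across repeats with dead points masked."""
    processed = median_across_repeats(record)
    dead = detect_dead_points(record, dead_threshold)
    processed.median_spectrum.mask = ~dead
    return processed
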