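"""Synthetic cohort generator emulating a two-arm DEP screening study.

The generator reproduces the statistical structure the downstream
analysis assumes: two arms (cancer / control) of 8 urine samples each,
whose cells differ in membrane conductance and cytoplasm conductivity;
3-5 technical repeats per sample on a 20-point log-spaced frequency grid
from 10 kHz to 45 MHz; additive Gaussian instrument noise; occasional
dead-connection frequency points (near-zero readings across repeats);
and low-cell samples whose spectra are pure noise with no underlying
DEP curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .shell_model import (
    CellShellParams,
    DielectricMedium,
    FrequencyGrid,
    Spectrum,
    re_cm,
)

__all__ = [
    "ArmPopulation",
    "CohortConfig",
    "SampleRecord",
    "CohortDataset",
    "default_medium",
    "default_grid",
    "default_arms",
    "sample_cell_params",
    "simulate_sample",
    "simulate_cohort",
    "write_cohort",
]

ARM_LABELS = ("cancer", "control")


def default_medium() -> DielectricMedium:
    """Low-conductivity iso-osmotic DEP buffer (43 mS/m, eps_r 78)."""
    return DielectricMedium(rel_permittivity=78.0, conductivity=0.043)


def default_grid() -> FrequencyGrid:
    """20 log-spaced points spanning 10 kHz - 45 MHz."""
    return FrequencyGrid.log_spaced(1e4, 45e6, 20)


@dataclass(frozen=True)
class ArmPopulation:
    """Cell-parameter distribution for one study arm.

    Individual cell parameters are drawn log-normally around ``mean``
    with a common coefficient of variation ``cv`` (log-normal keeps every
    parameter positive).  ``cv`` may also be a per-parameter mapping.
    """

    label: str
    mean: CellShellParams
    cv: float | dict[str, float] = 0.15

    def __post_init__(self) -> None:
        if self.label not in ARM_LABELS:
            raise ValueError(f"label must be one of {ARM_LABELS}")

    def cv_for(self, name: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(name, 0.0))
        return float(self.cv)


def default_arms() -> tuple[ArmPopulation, ArmPopulation]:
    """(cancer, control) populations reproducing the two-state contrast.

    Control cells carry a high membrane conductance (2000 S/m^2) and a
    moderate cytoplasm conductivity (0.25 S/m); cancer cells the reverse
    (200 S/m^2, 0.5 S/m).  This makes the cancer spectrum more negative
    below its crossover (~90 kHz) and more positive at the top of the
    band, the contrast the classifier exploits.
    """
    control = ArmPopulation(
        label="control",
        mean=CellShellParams(
            radius=10e-6,
            membrane_capacitance=0.01,
            membrane_conductance=2000.0,
            cytoplasm_rel_permittivity=60.0,
            cytoplasm_conductivity=0.25,
        ),
    )
    cancer = ArmPopulation(
        label="cancer",
        mean=replace(
            control.mean, membrane_conductance=200.0, cytoplasm_conductivity=0.5
        ),
    )
    return cancer, control


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for :func:`simulate_cohort`.

    Defaults mirror the pilot-study structure: 8 + 8 samples, 3-5
    technical repeats, 20-point 10 kHz - 45 MHz grid, additive noise of
    SD 0.05 (in DEP-response units), one-in-twenty dead frequency
    points, and three low-cell samples injected into the cancer arm.
    ``gain`` is the instrument scale factor applied to Re[CM].
    """

    n_cancer: int = 8
    n_control: int = 8
    repeats_min: int = 3
    repeats_max: int = 5
    grid: FrequencyGrid = field(default_factory=default_grid)
    noise_sd: float = 0.05
    dead_point_probability: float = 0.05
    low_cell_probability: float = 0.0
    n_low_cell_cancer: int = 3
    gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 1 or self.n_control < 1:
            raise ValueError("arm sizes must be >= 1")
        if not (1 <= self.repeats_min <= self.repeats_max):
            raise ValueError("need 1 <= repeats_min <= repeats_max")
        for name in ("dead_point_probability", "low_cell_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.n_low_cell_cancer <= self.n_cancer:
            raise ValueError("n_low_cell_cancer must be in [0, n_cancer]")


@dataclass
class SampleRecord:
    """One participant's sample: repeats of its DEP spectrum plus metadata.

    ``metadata`` carries optional sex/age plus, for simulated samples,
    the ground truth (``low_cell`` flag and injected ``dead_points``
    indices) used by validation tests; the on-disk manifest stores only
    sex and age.
    """

    sample_id: str
    arm: str
    repeats: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARM_LABELS:
            raise ValueError(f"arm must be one of {ARM_LABELS}")
        if not self.repeats:
            raise ValueError("at least one repeat required")
        n = len(self.repeats[0].grid)
        if any(len(r.grid) != n for r in self.repeats):
            raise ValueError("all repeats must share one frequency grid")

    @property
    def grid(self) -> FrequencyGrid:
        return self.repeats[0].grid

    def repeat_matrix(self) -> np.ndarray:
        """Repeats stacked as an (n_repeats, n_freq) array."""
        return np.vstack([r.values for r in self.repeats])


@dataclass
class CohortDataset:
    samples: list[SampleRecord]
    grid: FrequencyGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def arm(self, label: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.arm == label]


def sample_cell_params(arm: ArmPopulation, rng: np.random.Generator) -> CellShellParams:
    """Draw one cell-parameter set from the arm's log-normal distributions.

    Log-normal with mean m and coefficient of variation c uses
    sigma^2 = ln(1 + c^2), mu = ln m - sigma^2/2, so the arithmetic mean
    equals m and the CV equals c.  CV = 0 returns the mean exactly.
    """
    drawn = {}
    for name, m in arm.mean.as_dict().items():
        c = arm.cv_for(name)
        if c == 0.0 or m == 0.0:
            drawn[name] = m
            continue
        s2 = np.log1p(c * c)
        mu = np.log(m) - 0.5 * s2
        drawn[name] = float(rng.lognormal(mean=mu, sigma=np.sqrt(s2)))
    return CellShellParams(**drawn)


def simulate_sample(
    params: CellShellParams,
    medium: DielectricMedium,
    config: CohortConfig,
    arm_label: str,
    rng: np.random.Generator,
    sample_id: str = "S00",
    force_low_cell: Optional[bool] = None,
) -> SampleRecord:
    """Simulate one sample's technical repeats.

    Each repeat is ``gain * Re[CM](f) + N(0, noise_sd)``.  A low-cell
    sample (forced, or drawn with ``low_cell_probability``) has no
    underlying curve: repeats are pure noise.  Each grid point
    independently becomes a dead connection with
    ``dead_point_probability``; dead points read near zero
    (``N(0, noise_sd/10)``) in every repeat, emulating a failed well
    electrode that affects the whole acquisition.
    """
    n = len(config.grid)
    n_repeats = int(rng.integers(config.repeats_min, config.repeats_max + 1))
    if force_low_cell is None:
        low_cell = bool(rng.random() < config.low_cell_probability)
    else:
        low_cell = bool(force_low_cell)
    dead = rng.random(n) < config.dead_point_probability

    if low_cell:
        base = np.zeros(n)
    else:
        base = config.gain * re_cm(params, medium, config.grid.frequencies)

    repeats = []
    for _ in range(n_repeats):
        values = base + rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else base.copy()
        if dead.any():
            values[dead] = rng.normal(0.0, config.noise_sd / 10.0, int(dead.sum()))
        repeats.append(Spectrum(grid=config.grid, values=values))

    return SampleRecord(
        sample_id=sample_id,
        arm=arm_label,
        repeats=repeats,
        metadata={
            "low_cell": low_cell,
            "dead_points": np.nonzero(dead)[0].tolist(),
            "cell_params": params.as_dict(),
        },
    )


# sex ratios and age distributions mirror the pilot cohort make-up
_DEMOGRAPHICS = {
    "cancer": {"male_fraction": 6 / 8, "age_mean": 73.0, "age_sd": 10.0},
    "control": {"male_fraction": 7 / 8, "age_mean": 52.0, "age_sd": 17.0},
}


def simulate_cohort(
    config: CohortConfig,
    arms: Optional[tuple[ArmPopulation, ArmPopulation]] = None,
    medium: Optional[DielectricMedium] = None,
) -> CohortDataset:
    """Simulate a full two-arm cohort, reproducible from ``config.seed``.

    The first ``config.n_low_cell_cancer`` cancer samples are forced to
    be low-cell (the deterministic analogue of the pilot study's three
    failed samples); further low-cell samples may arise stochastically
    via ``low_cell_probability``.
    """
    if arms is None:
        arms = default_arms()
    if medium is None:
        medium = default_medium()
    cancer_pop, control_pop = arms
    if {cancer_pop.label, control_pop.label} != set(ARM_LABELS):
        raise ValueError("arms must be one cancer and one control population")
    if cancer_pop.label != "cancer":
        cancer_pop, control_pop = control_pop, cancer_pop

    rng = np.random.default_rng(config.seed)
    samples: list[SampleRecord] = []
    for i in range(config.n_cancer):
        params = sample_cell_params(cancer_pop, rng)
        rec = simulate_sample(
            params,
            medium,
            config,
            "cancer",
            rng,
            sample_id=f"C{i + 1:02d}",
            force_low_cell=True if i < config.n_low_cell_cancer else None,
        )
        samples.append(rec)
    for i in range(config.n_control):
        params = sample_cell_params(control_pop, rng)
        rec = simulate_sample(
            params,
            medium,
            config,
            "control",
            rng,
            sample_id=f"H{i + 1:02d}",
        )
        samples.append(rec)

    for rec in samples:
        demo = _DEMOGRAPHICS[rec.arm]
        rec.metadata["sex"] = "M" if rng.random() < demo["male_fraction"] else "F"
        rec.metadata["age"] = int(
            np.clip(round(rng.normal(demo["age_mean"], demo["age_sd"])), 20, 95)
        )

    provenance = {
        "seed": config.seed,
        "n_cancer": config.n_cancer,
        "n_control": config.n_control,
        "noise_sd": config.noise_sd,
        "gain": config.gain,
        "dead_point_probability": config.dead_point_probability,
        "low_cell_probability": config.low_cell_probability,
        "n_low_cell_cancer": config.n_low_cell_cancer,
    }
    return CohortDataset(samples=samples, grid=config.grid, provenance=provenance)


def write_cohort(dataset: CohortDataset, directory: str | Path) -> Path:
    """Write one spectrum CSV per sample plus a cohort manifest.

    Per-sample files use the ``frequency_hz,repeat_1..repeat_k`` dialect;
    the manifest lists ``sample_id,arm,file,sex,age``.  Returns the
    manifest path.  The written tree round-trips losslessly through
    :func:`depscreen.io.read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    try:
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "arm", "file", "sex", "age"])
            for rec in dataset.samples:
                fname = f"{rec.sample_id}.csv"
                writer.writerow(
                    [
                        rec.sample_id,
                        rec.arm,
                        fname,
                        rec.metadata.get("sex", ""),
                        rec.metadata.get("age", ""),
                    ]
                )
                _write_sample_csv(rec, directory / fname)
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return manifest_path


def _write_sample_csv(rec: SampleRecord, path: Path) -> None:
    mat = rec.repeat_matrix()
    header = ["frequency_hz"] + [f"repeat_{k + 1}" for k in range(mat.shape[0])]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for j, f in enumerate(rec.grid.frequencies):
            writer.writerow([_fmt_freq(f)] + [repr(float(v)) for v in mat[:, j]])


def _fmt_freq(f: float) -> str:
    return str(int(f)) if float(f).is_integer() else repr(float(f))
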