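"""Single-shell dielectric model of a cell and its DEP response.

A cell is idealised as a conductive cytoplasm sphere wrapped in a thin,
poorly conducting membrane characterised by its specific capacitance
C_mem (F/m^2) and specific conductance G_mem (S/m^2).  The frequency
response of the cell in a suspending medium is summarised by the real
part of the Clausius-Mossotti (CM) factor,

    Re[CM](f) = Re[(e*_p - e*_m) / (e*_p + 2 e*_m)],

bounded in [-0.5, 1] for a sphere, where e*_p and e*_m are the complex
permittivities of the (effective homogeneous) particle and the medium.
The sign of Re[CM] sets the direction of the dielectrophoretic force;
the frequency where it changes sign is the crossover frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "EPSILON_0",
    "DielectricMedium",
    "CellShellParams",
    "FrequencyGrid",
    "Spectrum",
    "CrossoverResult",
    "ShellFitResult",
    "complex_permittivity",
    "single_shell_effective_permittivity",
    "re_cm",
    "dep_spectrum",
    "crossover_frequency",
    "closed_form_crossover",
    "fit_shell_params",
]

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.854e-12

#: Names of the free parameters accepted by :func:`fit_shell_params`.
FITTABLE_PARAMS = (
    "radius",
    "membrane_capacitance",
    "membrane_conductance",
    "cytoplasm_rel_permittivity",
    "cytoplasm_conductivity",
    "gain",
)


class NoCrossoverError(ValueError):
    """Re[CM] does not change sign on the requested frequency bracket."""


@dataclass(frozen=True)
class DielectricMedium:
    """Suspending medium: relative permittivity and conductivity (S/m)."""

    rel_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if self.rel_permittivity <= 0:
            raise ValueError("rel_permittivity must be > 0")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")


@dataclass(frozen=True)
class CellShellParams:
    """Dielectric description of one cell.

    Parameters
    ----------
    radius
        Cell radius in metres.
    membrane_capacitance
        Membrane specific capacitance in F/m^2.
    membrane_conductance
        Membrane specific conductance in S/m^2 (may be 0).
    cytoplasm_rel_permittivity
        Relative permittivity of the cytoplasm interior.
    cytoplasm_conductivity
        Cytoplasm conductivity in S/m.
    """

    radius: float
    membrane_capacitance: float
    membrane_conductance: float
    cytoplasm_rel_permittivity: float
    cytoplasm_conductivity: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.membrane_capacitance <= 0:
            raise ValueError("membrane_capacitance must be > 0")
        if self.membrane_conductance < 0:
            raise ValueError("membrane_conductance must be >= 0")
        if self.cytoplasm_rel_permittivity <= 0:
            raise ValueError("cytoplasm_rel_permittivity must be > 0")
        if self.cytoplasm_conductivity <= 0:
            raise ValueError("cytoplasm_conductivity must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "radius": self.radius,
            "membrane_capacitance": self.membrane_capacitance,
            "membrane_conductance": self.membrane_conductance,
            "cytoplasm_rel_permittivity": self.cytoplasm_rel_permittivity,
            "cytoplasm_conductivity": self.cytoplasm_conductivity,
        }


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies (Hz)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if np.any(freqs <= 0):
            raise ValueError("all frequencies must be > 0")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freqs)

    def __len__(self) -> int:
        return self.frequencies.size

    @classmethod
    def log_spaced(cls, f_min: float, f_max: float, n_points: int) -> "FrequencyGrid":
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n_points))


@dataclass
class Spectrum:
    """One DEP response curve on a frequency grid with a validity mask."""

    grid: FrequencyGrid
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.grid), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.values) == len(self.grid) == len(self.mask)):
            raise ValueError("grid, values and mask must have equal length")

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def valid_frequencies(self) -> np.ndarray:
        return self.frequencies[self.mask]

    def n_valid(self) -> int:
        return int(self.mask.sum())


def complex_permittivity(
    rel_permittivity: float, conductivity: float, frequency
) -> complex:
    """Complex relative permittivity ``eps - j*sigma/(omega*eps0)``.

    Vectorised over ``frequency``; every frequency must be positive.
    """
    freq = np.asarray(frequency, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be > 0")
    omega = 2.0 * np.pi * freq
    out = rel_permittivity - 1j * conductivity / (omega * EPSILON_0)
    return complex(out) if np.isscalar(frequency) else out


def single_shell_effective_permittivity(cell: CellShellParams, frequency):
    """Effective complex relative permittivity of a thin-shelled sphere.

    The membrane shell enters through its complex specific capacitance
    ``C*_mem = C_mem - j*G_mem/omega`` (F/m^2); the thin-shell limit of the
    two-layer shelled-sphere mixing formula combines it in series with the
    cytoplasm:

        e*_p = (r * C*_mem / eps0) * e*_cyt / (r * C*_mem / eps0 + e*_cyt)
    """
    freq = np.asarray(frequency, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be > 0")
    omega = 2.0 * np.pi * freq
    c_mem = cell.membrane_capacitance - 1j * cell.membrane_conductance / omega
    shell_term = cell.radius * c_mem / EPSILON_0  # dimensionless (relative units)
    eps_cyt = complex_permittivity(
        cell.cytoplasm_rel_permittivity, cell.cytoplasm_conductivity, freq
    )
    out = shell_term * eps_cyt / (shell_term + eps_cyt)
    return complex(out) if np.isscalar(frequency) else out


def re_cm(cell: CellShellParams, medium: DielectricMedium, frequency):
    """Real part of the Clausius-Mossotti factor; bounded in [-0.5, 1]."""
    eps_p = single_shell_effective_permittivity(cell, frequency)
    eps_m = complex_permittivity(
        medium.rel_permittivity, medium.conductivity, frequency
    )
    cm = (eps_p - eps_m) / (eps_p + 2.0 * eps_m)
    out = np.real(cm)
    return float(out) if np.isscalar(frequency) else out


def dep_spectrum(
    cell: CellShellParams, medium: DielectricMedium, grid: FrequencyGrid
) -> Spectrum:
    """Noise-free DEP spectrum: Re[CM] evaluated pointwise on ``grid``."""
    values = re_cm(cell, medium, grid.frequencies)
    return Spectrum(grid=grid, values=values)


def closed_form_crossover(cell: CellShellParams, medium: DielectricMedium) -> float:
    """Thin-shell, insulating-membrane approximation of the crossover (Hz).

    ``f_xo = sqrt(2) * sigma_medium / (2*pi*r*C_mem)``; accurate when the
    membrane conductance is negligible and the cytoplasm is much more
    conductive than the medium.
    """
    return float(
        np.sqrt(2.0)
        * medium.conductivity
        / (2.0 * np.pi * cell.radius * cell.membrane_capacitance)
    )


@dataclass(frozen=True)
class CrossoverResult:
    """Lowest-frequency sign change of Re[CM] on a bracket."""

    frequency: float
    additional_crossovers: bool

    def __float__(self) -> float:
        return self.frequency


def crossover_frequency(
    cell: CellShellParams,
    medium: DielectricMedium,
    bracket: tuple[float, float],
    n_scan: int = 400,
) -> CrossoverResult:
    """Locate where Re[CM] changes sign inside ``bracket``.

    The bracket is scanned on a log grid for sign changes; the
    lowest-frequency one is refined by Brent's method to relative
    tolerance 1e-9.  If more than one sign change exists the result is
    flagged via ``additional_crossovers``.

    Raises
    ------
    NoCrossoverError
        If Re[CM] does not change sign anywhere on the bracket.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    freqs = np.logspace(np.log10(lo), np.log10(hi), n_scan)
    vals = re_cm(cell, medium, freqs)
    signs = np.sign(vals)
    # treat exact zeros as belonging to the preceding sign
    change = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    if change.size == 0:
        raise NoCrossoverError(
            f"Re[CM] does not change sign on [{lo:.3g}, {hi:.3g}] Hz"
        )
    i = change[0]
    root = optimize.brentq(
        lambda f: re_cm(cell, medium, f),
        freqs[i],
        freqs[i + 1],
        rtol=1e-9,
    )
    return CrossoverResult(frequency=float(root), additional_crossovers=change.size > 1)


@dataclass
class ShellFitResult:
    """Outcome of a least-squares fit of the single-shell model."""

    params: CellShellParams
    gain: float
    residual_norm: float
    converged: bool
    n_points: int
    message: str = ""


def fit_shell_params(
    spectrum: Spectrum,
    medium: DielectricMedium,
    initial: CellShellParams,
    free_params: Iterable[str] = ("membrane_capacitance", "cytoplasm_conductivity"),
    gain: float = 1.0,
) -> ShellFitResult:
    """Fit shell parameters to an observed DEP spectrum.

    Minimises ``sum((observed - gain * Re[CM])^2)`` over the named free
    parameters using bounded least squares; the optimisation runs in
    log-space so every parameter stays strictly positive.  Include
    ``"gain"`` in ``free_params`` to fit the instrument scale factor as
    well; otherwise it is held at ``gain``.  Masked points are ignored.
    """
    free = list(free_params)
    unknown = set(free) - set(FITTABLE_PARAMS)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    fit_gain = "gain" in free
    free_cell = [p for p in free if p != "gain"]

    freqs = spectrum.valid_frequencies
    obs = spectrum.valid_values
    if freqs.size < len(free):
        raise ValueError(
            f"need at least {len(free)} valid points, have {freqs.size}"
        )

    base = initial.as_dict()
    # membrane_conductance may legitimately be 0; floor it for log-space
    floor = 1e-12
    x0 = [np.log(max(base[p], floor)) for p in free_cell]
    if fit_gain:
        x0.append(np.log(max(gain, floor)))

    def build(x: np.ndarray) -> tuple[CellShellParams, float]:
        values = dict(base)
        for name, xi in zip(free_cell, x):
            values[name] = float(np.exp(xi))
        g = float(np.exp(x[-1])) if fit_gain else gain
        return CellShellParams(**values), g

    def residuals(x: np.ndarray) -> np.ndarray:
        cell, g = build(x)
        return g * re_cm(cell, medium, freqs) - obs

    result = optimize.least_squares(residuals, np.asarray(x0), method="lm")
    cell, g = build(result.x)
    return ShellFitResult(
        params=cell,
        gain=g,
        residual_norm=float(np.linalg.norm(result.fun)),
        converged=bool(result.success),
        n_points=int(freqs.size),
        message=result.message,
    )
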