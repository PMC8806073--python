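"""Processing of vibrational line spectra into continuous Raman/ROA spectra.

A quantum-chemical (harmonic) calculation of one solute snapshot yields a
stick spectrum: mode wavenumbers with paired Raman and ROA scattering
intensities.  The processing protocol applied here is

1. rescale the harmonic wavenumbers with a smooth two-plateau scaling
   function (corrects systematic harmonic/basis-set error, which differs
   below and above the fingerprint region),
2. multiply the intensities by the Stokes Boltzmann temperature factor
   ``[1 - exp(-h c nu / k_B T)]^-1`` (thermal population of vibrational
   states at the experimental temperature),
3. convolve the sticks with a unit-area Lorentzian of fixed full width at
   half maximum onto a uniform wavenumber grid,
4. average the resulting continuous spectra pointwise over the snapshot
   ensemble of a conformer.

Defaults follow the protocol constants used throughout the package:
scaling ``(a, b, c, d) = (0.982, 1.00, 15, 1210)``, ``T = 300 K``,
``Gamma = 7.5 cm^-1``, grid 200-1800 cm^-1 at 1 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, NamedTuple, Sequence

import numpy as np
from scipy import constants

__all__ = [
    "HC_OVER_KB_CM_K",
    "VibMode",
    "LineSpectrum",
    "WavenumberGrid",
    "ContinuousSpectrum",
    "SpectrumPair",
    "ScalingParams",
    "scale_frequencies",
    "boltzmann_factor",
    "temperature_correct",
    "broaden",
    "ensemble_average",
    "cid",
    "DEFAULT_GRID",
]

#: h*c/k_B in cm*K (second radiation constant); converts a wavenumber in
#: cm^-1 into a temperature scale.
HC_OVER_KB_CM_K: float = constants.h * constants.c * 100.0 / constants.k


class VibMode(NamedTuple):
    """One vibrational mode: wavenumber (cm^-1) with Raman and ROA intensity."""

    wavenumber: float
    raman: float
    roa: float


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber grid [start, stop] with spacing ``step`` (cm^-1)."""

    start: float = 200.0
    stop: float = 1800.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start must lie below stop, got [{self.start}, {self.stop}]")
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def points(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


DEFAULT_GRID = WavenumberGrid(200.0, 1800.0, 1.0)


@dataclass(frozen=True)
class ContinuousSpectrum:
    """Continuous spectrum on a uniform grid; ``channel`` is 'raman' or 'roa'.

    ``mask`` marks valid points; invalid points (e.g. CID at vanishing Raman
    intensity) carry NaN values and ``mask = False``.
    """

    grid: WavenumberGrid
    values: np.ndarray
    channel: str = "raman"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_points,):
            raise ValueError(
                f"values shape {values.shape} does not match grid ({self.grid.n_points} points)"
            )
        if self.channel not in ("raman", "roa", "cid"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            object.__setattr__(self, "mask", mask)
            if mask.shape != values.shape:
                raise ValueError("mask shape does not match values")
            if not np.all(np.isfinite(values[mask])):
                raise ValueError("non-finite values at unmasked points")
        elif not np.all(np.isfinite(values)):
            raise ValueError("spectrum values must be finite")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.points


@dataclass(frozen=True)
class SpectrumPair:
    """Raman and ROA continuous spectra sharing one wavenumber grid."""

    raman: ContinuousSpectrum
    roa: ContinuousSpectrum

    def __post_init__(self) -> None:
        if self.raman.grid != self.roa.grid:
            raise ValueError("Raman and ROA spectra must share one grid")

    @property
    def grid(self) -> WavenumberGrid:
        return self.raman.grid


@dataclass(frozen=True)
class LineSpectrum:
    """Stick spectrum of one snapshot: sorted wavenumbers with intensities."""

    wavenumbers: np.ndarray
    raman: np.ndarray
    roa: np.ndarray
    snapshot_id: str = "0"
    conformer_label: str = ""

    def __post_init__(self) -> None:
        nu = np.atleast_1d(np.asarray(self.wavenumbers, dtype=float))
        raman = np.atleast_1d(np.asarray(self.raman, dtype=float))
        roa = np.atleast_1d(np.asarray(self.roa, dtype=float))
        if not (nu.shape == raman.shape == roa.shape):
            raise ValueError("wavenumbers, raman and roa must have equal length")
        if nu.size and np.any(nu <= 0):
            raise ValueError("wavenumbers must be positive")
        if not (np.all(np.isfinite(raman)) and np.all(np.isfinite(roa))):
            raise ValueError("intensities must be finite")
        order = np.argsort(nu, kind="stable")
        object.__setattr__(self, "wavenumbers", nu[order])
        object.__setattr__(self, "raman", raman[order])
        object.__setattr__(self, "roa", roa[order])

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def modes(self) -> Iterator[VibMode]:
        for nu, ram, roa in zip(self.wavenumbers, self.raman, self.roa):
            yield VibMode(float(nu), float(ram), float(roa))


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of the two-plateau frequency scaling function.

    The scale factor interpolates logistically between ``b`` (below the
    transition center ``d``) and ``a`` (above it) over a width ``c``:

        phi(nu) = a + (b - a) / (1 + exp((nu - d) / c))

    The functional form can be swapped via ``scale_frequencies(func=...)``
    without touching callers.
    """

    a: float = 0.982
    b: float = 1.00
    c: float = 15.0
    d: float = 1210.0

    def __post_init__(self) -> None:
        for name in ("a", "b"):
            v = getattr(self, name)
            if not 0.9 < v < 1.1:
                raise ValueError(f"scale factor {name}={v} outside the physical band (0.9, 1.1)")
        if self.c <= 0:
            raise ValueError("transition width c must be positive")

    def factor(self, wavenumber: np.ndarray | float) -> np.ndarray | float:
        nu = np.asarray(wavenumber, dtype=float)
        # clip the exponent so the plateaus are exact in floating point
        z = np.clip((nu - self.d) / self.c, -500.0, 500.0)
        return self.a + (self.b - self.a) / (1.0 + np.exp(z))


def scale_frequencies(
    spectrum: LineSpectrum,
    params: ScalingParams = ScalingParams(),
    func: Callable[[np.ndarray, ScalingParams], np.ndarray] | None = None,
) -> LineSpectrum:
    """Rescale each mode wavenumber by the scaling function; intensities unchanged.

    ``func(nu, params)`` may replace the default logistic form.
    """
    nu = spectrum.wavenumbers
    phi = func(nu, params) if func is not None else params.factor(nu)
    scaled = nu * np.asarray(phi, dtype=float)
    if scaled.size and np.any(scaled <= 0):
        raise ValueError("scaling produced non-positive wavenumbers")
    return replace(spectrum, wavenumbers=scaled, raman=spectrum.raman, roa=spectrum.roa)


def boltzmann_factor(wavenumber: np.ndarray | float, temperature: float) -> np.ndarray | float:
    """Stokes Raman temperature factor ``1 / (1 - exp(-h c nu / k_B T))``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    nu = np.asarray(wavenumber, dtype=float)
    return 1.0 / (1.0 - np.exp(-HC_OVER_KB_CM_K * nu / temperature))


def temperature_correct(spectrum: LineSpectrum, temperature: float = 300.0) -> LineSpectrum:
    """Multiply Raman and ROA intensities by the Boltzmann occupation factor."""
    f = boltzmann_factor(spectrum.wavenumbers, temperature)
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers,
        raman=spectrum.raman * f,
        roa=spectrum.roa * f,
    )


def _lorentzian_matrix(grid_points: np.ndarray, centers: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzians, shape (n_centers, n_grid); peak 2/(pi*Gamma)."""
    half = fwhm / 2.0
    d = grid_points[None, :] - centers[:, None]
    return (half / np.pi) / (d * d + half * half)


def broaden(spectrum: LineSpectrum, grid: WavenumberGrid = DEFAULT_GRID, fwhm: float = 7.5) -> SpectrumPair:
    """Convolve a stick spectrum with unit-area Lorentzians onto ``grid``.

    Each channel becomes ``sum_k I_k * L(nu; nu_k, Gamma)``; the integrated
    broadened intensity equals the summed stick intensity whenever the grid
    extends far enough beyond the modes.  An empty mode list yields zeros.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    pts = grid.points
    if len(spectrum) == 0:
        zeros = np.zeros(grid.n_points)
        return SpectrumPair(
            ContinuousSpectrum(grid, zeros, "raman"),
            ContinuousSpectrum(grid, zeros.copy(), "roa"),
        )
    L = _lorentzian_matrix(pts, spectrum.wavenumbers, fwhm)
    return SpectrumPair(
        ContinuousSpectrum(grid, spectrum.raman @ L, "raman"),
        ContinuousSpectrum(grid, spectrum.roa @ L, "roa"),
    )


def ensemble_average(pairs: Sequence[SpectrumPair]) -> SpectrumPair:
    """Pointwise arithmetic mean of spectrum pairs sharing one grid."""
    if len(pairs) == 0:
        raise ValueError("cannot average an empty ensemble")
    grid = pairs[0].grid
    for p in pairs[1:]:
        if p.grid != grid:
            raise ValueError("all spectrum pairs must share one grid")
    raman = np.mean([p.raman.values for p in pairs], axis=0)
    roa = np.mean([p.roa.values for p in pairs], axis=0)
    return SpectrumPair(
        ContinuousSpectrum(grid, raman, "raman"),
        ContinuousSpectrum(grid, roa, "roa"),
    )


def cid(pair: SpectrumPair, floor: float = 1e-6) -> ContinuousSpectrum:
    """Circular intensity difference I_ROA / I_Raman, masked at weak Raman signal.

    Points where ``|I_Raman| < floor * max|I_Raman|`` are flagged invalid
    (NaN, mask False) instead of divided.
    """
    raman = pair.raman.values
    roa = pair.roa.values
    scale = np.max(np.abs(raman)) if raman.size else 0.0
    valid = np.abs(raman) >= floor * scale if scale > 0 else np.zeros_like(raman, dtype=bool)
    out = np.full_like(raman, np.nan)
    np.divide(roa, raman, out=out, where=valid)
    return ContinuousSpectrum(pair.grid, out, "cid", mask=valid)
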