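"""Seeded synthetic-data generators for every input class of the pipeline.

These generators stand in for the expensive external engines: random
conformer stick spectra emulate QM ensemble output, noisy weighted
mixtures emulate measured spectra of systems with known composition,
von Mises dihedral ensembles emulate (biased) MD torsion sampling, and
the inverse Cremer-Pople construction produces ring geometries at chosen
puckering coordinates.  All generators are pure functions of their
arguments including the seed.

They make no attempt at physically realistic normal modes; their purpose
is identifiability: distinct conformers get distinct spectra, ROA
intensities are signed and roughly three orders of magnitude below Raman
(the typical circular-intensity-difference scale), and noise is
multiplicative (experimental Raman noise roughly scales with signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import ConformerSpectra, compose
from .spectra import (
    DEFAULT_GRID,
    ContinuousSpectrum,
    LineSpectrum,
    SpectrumPair,
    WavenumberGrid,
    broaden,
    ensemble_average,
)

__all__ = [
    "SynthSpec",
    "gen_conformer_modes",
    "gen_conformer_spectra",
    "gen_mixture",
    "gen_dihedral_ensemble",
    "gen_ring",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic conformer ensemble.

    ``roa_scale`` is relative to ``raman_scale``; the default 1e-3 mimics
    the circular-intensity-difference magnitude of real saccharide spectra.
    ``n_snapshots`` > 1 adds per-snapshot wavenumber jitter, emulating the
    spread of a structural ensemble.
    """

    n_conformers: int = 4
    n_modes: int = 60
    wavenumber_range: tuple[float, float] = (220.0, 1780.0)
    raman_scale: float = 1.0
    roa_scale: float = 1e-3
    noise_level: float = 0.0
    seed: int = 0
    n_snapshots: int = 1
    jitter: float = 3.0

    def __post_init__(self) -> None:
        if self.n_conformers < 1 or self.n_modes < 1 or self.n_snapshots < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


def gen_conformer_modes(spec: SynthSpec) -> dict[str, list[LineSpectrum]]:
    """Random stick spectra per conformer: label -> list of snapshots.

    Wavenumbers are uniform over the range, Raman intensities log-normal
    (positive), ROA intensities normal (signed) at ``roa_scale`` relative
    magnitude.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.wavenumber_range
    out: dict[str, list[LineSpectrum]] = {}
    for ci in range(spec.n_conformers):
        label = f"c{ci + 1}"
        base_nu = np.sort(rng.uniform(lo, hi, size=spec.n_modes))
        raman = spec.raman_scale * rng.lognormal(mean=0.0, sigma=0.8, size=spec.n_modes)
        roa = spec.raman_scale * spec.roa_scale * rng.normal(size=spec.n_modes)
        snaps = []
        for si in range(spec.n_snapshots):
            nu = base_nu if spec.n_snapshots == 1 else np.clip(
                base_nu + rng.normal(scale=spec.jitter, size=spec.n_modes), 1.0, None
            )
            snaps.append(
                LineSpectrum(
                    wavenumbers=nu,
                    raman=raman,
                    roa=roa,
                    snapshot_id=str(si),
                    conformer_label=label,
                )
            )
        out[label] = snaps
    return out


def gen_conformer_spectra(
    spec: SynthSpec,
    grid: WavenumberGrid = DEFAULT_GRID,
    fwhm: float = 7.5,
) -> ConformerSpectra:
    """Broadened, ensemble-averaged synthetic conformer spectra on ``grid``."""
    tables = gen_conformer_modes(spec)
    pairs = {
        label: ensemble_average([broaden(s, grid, fwhm) for s in snaps])
        for label, snaps in tables.items()
    }
    return ConformerSpectra.from_dict(pairs)


def gen_mixture(
    conformers: ConformerSpectra,
    true_weights: np.ndarray,
    noise_level: float = 0.0,
    seed: int = 0,
) -> tuple[SpectrumPair, dict]:
    """Noisy weighted mixture of conformer spectra plus its truth record.

    Noise is multiplicative Gaussian per grid point: I -> I * (1 + eps),
    eps ~ N(0, noise_level).  Weights must lie on the unit simplex.
    """
    w = np.asarray(true_weights, dtype=float)
    if w.shape != (len(conformers),):
        raise ValueError("true_weights length must match the number of conformers")
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("true_weights must be non-negative and sum to 1")
    pair = compose(w, conformers)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        raman = pair.raman.values * (1.0 + rng.normal(scale=noise_level, size=pair.grid.n_points))
        roa = pair.roa.values * (1.0 + rng.normal(scale=noise_level, size=pair.grid.n_points))
        pair = SpectrumPair(
            ContinuousSpectrum(pair.grid, raman, "raman"),
            ContinuousSpectrum(pair.grid, roa, "roa"),
        )
    truth = {
        "labels": list(conformers.labels),
        "weights": [float(x) for x in w],
        "noise_level": float(noise_level),
        "seed": int(seed),
    }
    return pair, truth


def gen_dihedral_ensemble(
    center: float, kappa: float, n: int, seed: int = 0
) -> np.ndarray:
    """von Mises dihedral samples around ``center`` (radians), wrapped to (-pi, pi].

    ``kappa`` is the concentration; kappa = 0 is circular-uniform and large
    kappa collapses onto the center (emulating a harmonically restrained
    biased-MD torsion).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    samples = rng.vonmises(mu=center, kappa=kappa, size=n) if kappa > 0 else rng.uniform(
        -np.pi, np.pi, size=n
    )
    wrapped = -np.remainder(-samples + np.pi, 2 * np.pi) + np.pi
    return wrapped


def gen_ring(
    Q: float, theta: float, phi: float, bond_length: float = 1.54
) -> np.ndarray:
    """Six ring-atom coordinates at prescribed Cremer-Pople (Q, theta, phi).

    Inverse construction: a regular hexagon of circumradius ``bond_length``
    in the xy-plane (traversed clockwise seen from +z, so the Cremer-Pople
    normal points along +z) plus the out-of-plane displacements

        z_j = sqrt(1/3) q2 cos(phi + 4 pi j / 6) + sqrt(1/6) q3 (-1)^j

    with q2 = Q sin(theta), q3 = Q cos(theta).  ``cremer_pople`` recovers
    (Q, theta, phi) from the result to numerical precision.
    """
    if Q < 0:
        raise ValueError("Q must be non-negative")
    j = np.arange(6)
    a = -2.0 * np.pi * j / 6.0
    xy = bond_length * np.column_stack([np.cos(a), np.sin(a)])
    q2 = Q * np.sin(theta)
    q3 = Q * np.cos(theta)
    z = np.sqrt(1.0 / 3.0) * q2 * np.cos(phi + 4.0 * np.pi * j / 6.0) + np.sqrt(
        1.0 / 6.0
    ) * q3 * (-1.0) ** j
    return np.column_stack([xy, z])
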