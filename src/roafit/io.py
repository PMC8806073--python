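"""File formats and run configuration.

Formats:

* mode tables — TSV with header ``conformer  snapshot  wavenumber_cm1
  raman  roa``, one row per vibrational mode;
* continuous spectra — two-column text (wavenumber, intensity),
  whitespace- or comma-delimited, ``#`` comments;
* coordinates — XYZ (possibly concatenated frames) or multi-model PDB,
  read through MDAnalysis;
* J tables — TSV ``conformer  observable  j_sim_hz``; observations — TSV
  ``observable  j_exp_hz  sigma_hz``;
* run configuration — YAML aggregating the protocol constants.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .nmr import CouplingObservable
from .spectra import (
    DEFAULT_GRID,
    ContinuousSpectrum,
    LineSpectrum,
    ScalingParams,
    WavenumberGrid,
)

__all__ = [
    "read_mode_table",
    "write_mode_table",
    "read_spectrum",
    "write_spectrum",
    "read_coordinate_frames",
    "write_xyz_frames",
    "read_j_table",
    "read_observations",
    "RunConfig",
]

MODE_TABLE_COLUMNS = ["conformer", "snapshot", "wavenumber_cm1", "raman", "roa"]


def read_mode_table(path: str | Path) -> dict[str, list[LineSpectrum]]:
    """Read a TSV mode table into conformer-grouped, sorted line spectra."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"conformer": str, "snapshot": str})
    except Exception as exc:  # noqa: BLE001 - surface parse problems with the file name
        raise ValueError(f"cannot parse mode table {path}: {exc}") from exc
    missing = set(MODE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mode table {path} lacks columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"mode table {path} has no data rows", stacklevel=2)
        return {}
    bad = df[MODE_TABLE_COLUMNS[2:]].isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise ValueError(f"malformed row at line {int(bad.idxmax()) + 2} of {path}")
    out: dict[str, list[LineSpectrum]] = {}
    for (conf, snap), g in df.groupby(["conformer", "snapshot"], sort=True):
        out.setdefault(str(conf), []).append(
            LineSpectrum(
                wavenumbers=g["wavenumber_cm1"].to_numpy(float),
                raman=g["raman"].to_numpy(float),
                roa=g["roa"].to_numpy(float),
                snapshot_id=str(snap),
                conformer_label=str(conf),
            )
        )
    for conf, snaps in out.items():
        ids = [s.snapshot_id for s in snaps]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate snapshot ids within conformer {conf!r} in {path}")
    return out


def write_mode_table(path: str | Path, spectra: dict[str, list[LineSpectrum]]) -> None:
    rows = []
    for conf in spectra:
        for snap in spectra[conf]:
            for mode in snap.modes:
                rows.append((conf, snap.snapshot_id, mode.wavenumber, mode.raman, mode.roa))
    pd.DataFrame(rows, columns=MODE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def _load_two_columns(path: str | Path) -> np.ndarray:
    text = Path(path).read_text()
    body = "\n".join(
        line.replace(",", " ") for line in text.splitlines() if not line.lstrip().startswith("#")
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-input warning; handled below
            data = np.loadtxt(_io.StringIO(body), ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse spectrum file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"spectrum file {path} contains no data")
    if data.shape[1] < 2:
        raise ValueError(f"spectrum file {path} needs two columns (wavenumber, intensity)")
    return data[:, :2]


def read_spectrum(
    path: str | Path,
    grid: WavenumberGrid = DEFAULT_GRID,
    channel: str = "raman",
) -> ContinuousSpectrum:
    """Read a two-column spectrum and resample it onto ``grid`` linearly.

    Input points outside the grid are dropped; where the grid extends
    beyond the data a warning is issued and edge values are held.
    """
    data = _load_two_columns(path)
    order = np.argsort(data[:, 0], kind="stable")
    x, y = data[order, 0], data[order, 1]
    pts = grid.points
    if x[0] > pts[0] + 1e-9 or x[-1] < pts[-1] - 1e-9:
        warnings.warn(
            f"{path}: data range [{x[0]:g}, {x[-1]:g}] does not cover the grid "
            f"[{pts[0]:g}, {pts[-1]:g}]; edge values held",
            stacklevel=2,
        )
    return ContinuousSpectrum(grid, np.interp(pts, x, y), channel)


def write_spectrum(path: str | Path, spectrum: ContinuousSpectrum, header: str = "") -> None:
    lines = [f"# {h}" for h in header.splitlines() if h]
    lines.append("# wavenumber_cm1 intensity")
    for nu, v in zip(spectrum.wavenumbers, spectrum.values):
        lines.append(f"{nu:.6g} {v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinates


def read_coordinate_frames(
    path: str | Path, indices: Sequence[int] | None = None
) -> Iterator[np.ndarray]:
    """Yield per-frame coordinate arrays (Angstrom) from XYZ or multi-model PDB.

    ``indices`` selects atoms (0-based) from each frame.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        u = mda.Universe(str(path))
    sel = np.asarray(indices, dtype=int) if indices is not None else None
    for _ in u.trajectory:
        pos = u.atoms.positions.astype(float)
        yield pos[sel] if sel is not None else pos


def write_xyz_frames(
    path: str | Path, frames: Sequence[np.ndarray], symbols: Sequence[str] | None = None
) -> None:
    """Write frames as concatenated XYZ blocks (plain text)."""
    lines: list[str] = []
    for fi, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=float)
        syms = symbols if symbols is not None else ["C"] * len(frame)
        lines.append(str(len(frame)))
        lines.append(f"frame {fi}")
        for s, (x, y, z) in zip(syms, frame):
            lines.append(f"{s} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# NMR tables


def read_j_table(path: str | Path) -> pd.DataFrame:
    """Read a conformer J table (TSV: conformer, observable, j_sim_hz) into a
    conformer x observable DataFrame (Hz)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"conformer": str, "observable": str})
    need = {"conformer", "observable", "j_sim_hz"}
    if not need <= set(df.columns):
        raise ValueError(f"J table {path} needs columns {sorted(need)}")
    table = df.pivot(index="conformer", columns="observable", values="j_sim_hz")
    if table.isna().any().any():
        raise ValueError(f"J table {path} is incomplete (missing conformer/observable pairs)")
    return table


def read_observations(path: str | Path) -> list[CouplingObservable]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"observable": str})
    need = {"observable", "j_exp_hz"}
    if not need <= set(df.columns):
        raise ValueError(f"observations file {path} needs columns {sorted(need)}")
    sigmas = df["sigma_hz"] if "sigma_hz" in df.columns else pd.Series(0.2, index=df.index)
    return [
        CouplingObservable(name=str(r.observable), j_exp=float(r.j_exp_hz), sigma=float(s))
        for (_, r), s in zip(df.iterrows(), sigmas)
    ]


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Aggregated protocol constants and file locations for a pipeline run."""

    grid: WavenumberGrid = DEFAULT_GRID
    fwhm: float = 7.5
    temperature: float = 300.0
    scaling: ScalingParams = field(default_factory=ScalingParams)
    window: WavenumberGrid | None = None
    threshold: float = 0.99
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    nmr_delta: float = 0.2
    nmr_mode: str = "rms"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.window is not None:
            if self.window.start < self.grid.start - 1e-9 or self.window.stop > self.grid.stop + 1e-9:
                raise ValueError("window must lie within the grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "grid" in raw:
            kwargs["grid"] = WavenumberGrid(**raw["grid"])
        if "window" in raw and raw["window"] is not None:
            g = kwargs.get("grid", DEFAULT_GRID)
            w = dict(raw["window"])
            w.setdefault("step", g.step)
            kwargs["window"] = WavenumberGrid(**w)
        if "scaling" in raw:
            kwargs["scaling"] = ScalingParams(**raw["scaling"])
        for key in ("fwhm", "temperature", "threshold", "seed", "paths", "nmr_delta", "nmr_mode"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return {
            "grid": {"start": self.grid.start, "stop": self.grid.stop, "step": self.grid.step},
            "fwhm": self.fwhm,
            "temperature": self.temperature,
            "scaling": {
                "a": self.scaling.a,
                "b": self.scaling.b,
                "c": self.scaling.c,
                "d": self.scaling.d,
            },
            "window": None
            if self.window is None
            else {"start": self.window.start, "stop": self.window.stop, "step": self.window.step},
            "threshold": self.threshold,
            "seed": self.seed,
            "paths": dict(self.paths),
            "nmr_delta": self.nmr_delta,
            "nmr_mode": self.nmr_mode,
        }
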