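"""End-to-end workflow: process mode tables, fit weights, report.

``run_pipeline`` executes the full protocol — per-snapshot frequency
scaling, temperature correction and Lorentzian broadening; per-conformer
ensemble averaging; joint Raman/ROA weight fitting with uncertainty
profiling; optionally an NMR J-coupling fit — and returns a structured,
JSON-serializable report that records every protocol constant used.
Identical configuration and inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .io import RunConfig, read_j_table, read_mode_table, read_observations, read_spectrum
from .nmr import JCouplingFitter
from .similarity import ConformerSpectra, SpectralDecomposer
from .spectra import (
    LineSpectrum,
    SpectrumPair,
    broaden,
    ensemble_average,
    scale_frequencies,
    temperature_correct,
)

__all__ = ["process_conformers", "run_pipeline", "write_report"]

log = logging.getLogger("roafit")


def process_conformers(
    mode_tables: dict[str, list[LineSpectrum]], config: RunConfig
) -> ConformerSpectra:
    """Scale, temperature-correct, broaden and ensemble-average per conformer."""
    if not mode_tables:
        raise ValueError("no conformer mode tables to process")
    pairs: dict[str, SpectrumPair] = {}
    for label in sorted(mode_tables):
        processed = []
        for snap in mode_tables[label]:
            s = scale_frequencies(snap, config.scaling)
            s = temperature_correct(s, config.temperature)
            processed.append(broaden(s, config.grid, config.fwhm))
        pairs[label] = ensemble_average(processed)
    return ConformerSpectra.from_dict(pairs)


def run_pipeline(config: RunConfig) -> dict:
    """Run process -> ensemble-average -> fit -> uncertainty (-> nmr-fit).

    Required ``config.paths`` keys: ``modes`` (TSV mode table), ``exp_raman``
    and ``exp_roa`` (two-column spectra).  Optional: ``j_table`` and
    ``observations`` for the NMR fit, ``report`` to write the JSON report.
    """
    paths = config.paths
    for key in ("modes", "exp_raman", "exp_roa"):
        if key not in paths:
            raise ValueError(f"configuration error: missing path {key!r}")
    log.info("protocol constants: %s", json.dumps(config.as_dict(), sort_keys=True))

    try:
        tables = read_mode_table(paths["modes"])
    except Exception as exc:
        raise RuntimeError(f"[process] {exc}") from exc
    try:
        conformers = process_conformers(tables, config)
    except Exception as exc:
        raise RuntimeError(f"[ensemble] {exc}") from exc
    try:
        experiment = SpectrumPair(
            read_spectrum(paths["exp_raman"], config.grid, "raman"),
            read_spectrum(paths["exp_roa"], config.grid, "roa"),
        )
    except Exception as exc:
        raise RuntimeError(f"[experiment] {exc}") from exc
    try:
        decomposer = SpectralDecomposer(
            window=config.window,
            threshold=config.threshold,
            random_state=config.seed,
        ).fit(conformers, experiment)
    except Exception as exc:
        raise RuntimeError(f"[fit] {exc}") from exc

    report = {
        "config": config.as_dict(),
        "fit": decomposer.solution_.as_dict(),
    }

    if "j_table" in paths or "observations" in paths:
        if not ("j_table" in paths and "observations" in paths):
            raise RuntimeError("[nmr] both j_table and observations paths are required")
        try:
            fitter = JCouplingFitter(
                delta=config.nmr_delta, mode=config.nmr_mode, random_state=config.seed
            ).fit(read_j_table(paths["j_table"]), read_observations(paths["observations"]))
            report["nmr"] = fitter.as_dict()
        except Exception as exc:
            raise RuntimeError(f"[nmr] {exc}") from exc

    if "report" in paths:
        write_report(paths["report"], report)
    return report


def write_report(path: str | Path, report: dict) -> None:
    """Serialize a report deterministically (sorted keys, fixed layout)."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
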