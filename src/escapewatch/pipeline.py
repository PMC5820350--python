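"""Pipeline orchestration: synth -> scan -> fit -> report.

Executes the stages named in a :class:`~escapewatch.config.RunConfig` in
order, logging seeds and parameters, and writes a machine-readable
``report.json`` joining fitted parameters, predicted half-life and
per-feature frequency tables.  Reruns with the same config and seeds
produce byte-identical tables; stage failures halt the run with partial
outputs preserved.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .config import RunConfig
from .fitting import fit_stability
from .growth import estimate_growth
from .interface_io import write_fastq, write_tsv
from .isscan.scan import scan_insertions
from .isscan.coverage import me_fraction
from .isscan.variants import call_variants
from .popmodel import ModelParams, half_life, producer_fraction

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Run the configured stages; returns the artifact directory."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages), "parameters": config.to_dict()}
    params = ModelParams(config.load, config.escape_rate, config.ref_growth)
    meta = {"seed": config.seed}
    series = None
    grid = np.asarray(config.generations, dtype=float)

    for stage in config.stages:
        logger.info("running stage %s", stage)
        if stage == "model":
            table = pd.DataFrame(
                {
                    "generation": grid,
                    "producer_fraction": producer_fraction(params, grid),
                }
            )
            table["nonproducer_fraction"] = 1.0 - table["producer_fraction"]
            write_tsv(table, out / "model_predictions.tsv", params=meta)
            report["half_life_generations"] = half_life(params)
        elif stage == "series":
            series = synth.simulate_stability_series(
                params,
                grid,
                noise_sd=config.noise_sd,
                n_reps=config.n_reps,
                seed=config.seed,
                observable_kind=config.observable_kind,
            )
            series.to_tsv(out / "stability_series.tsv")
        elif stage == "fit":
            if series is None:
                raise RuntimeError("fit stage requires the series stage first")
            fit = fit_stability(series, free=tuple(config.free_parameters), seed=config.seed)
            report["fit"] = {
                "estimates": fit.estimates,
                "ci95": fit.ci95,
                "rss": fit.rss,
                "converged": fit.converged,
                "flags": list(fit.flags),
            }
            report["fitted_half_life_generations"] = half_life(fit.params)
        elif stage == "reads" or stage == "scan":
            ref = synth.make_reference(seed=config.seed)
            catalog = synth.make_catalog(seed=config.seed + 1)
            spectrum = synth.default_spectrum(
                ref, catalog, load=config.load, k_total=config.escape_rate
            )
            # inflate frequencies to the configured timepoint's truth
            truth = synth.simulate_spectrum_frequencies(spectrum, [config.timepoint]).at(
                config.timepoint
            )
            reads, ledger = synth.simulate_reads(
                ref,
                truth,
                catalog,
                spectrum,
                depth=config.depth,
                read_len=config.read_len,
                error_rate=config.error_rate,
                seed=config.seed,
            )
            (out / "reads_truth.json").write_text(json.dumps(ledger, indent=2))
            if stage == "reads":
                write_fastq(
                    ((n, s, "I" * len(s)) for n, s in zip(reads.names, reads.seqs)),
                    out / "reads.fastq",
                )
                continue
            freqs, events, unassigned = scan_insertions(
                reads, ref, catalog, min_support=config.min_support
            )
            rows = [
                {
                    "feature": f"{fr.event.subgroup}@{fr.event.position}",
                    "position": fr.event.position,
                    "subgroup": fr.event.subgroup,
                    "orientation": fr.event.orientation,
                    "tsd_length": fr.event.tsd_length,
                    "junction_support": fr.junction_support,
                    "reference_support": fr.reference_support,
                    "frequency": fr.frequency,
                }
                for fr in freqs
            ]
            write_tsv(pd.DataFrame(rows), out / "insertion_frequencies.tsv", params=meta)
            mef = me_fraction(reads, ref, catalog)
            calls = call_variants(reads, ref, error_rate=config.error_rate)
            report["scan"] = {
                "n_events": len(events),
                "n_unassigned_clusters": len(unassigned),
                "me_fraction": mef.fraction,
                "n_variant_calls": len(calls),
                "features": {r["feature"]: r["frequency"] for r in rows},
            }
        elif stage == "growth":
            od = synth.simulate_od(
                config.growth_rate, noise_sd=config.od_noise_sd, seed=config.seed
            )
            est = estimate_growth(od)
            report["growth"] = {
                "mean_rate_per_h": est.mean_rate,
                "n_points_used": est.n_points_used,
            }
        else:  # pragma: no cover - guarded by validate()
            raise ValueError(f"unknown stage {stage!r}")

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return out
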