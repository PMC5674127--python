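"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes: simulate inputs (optional) -> differential
expression per comparison -> growth-rate/temperature cascade -> COG
enrichment -> LGT screen -> genome statistics (coding density, ANI), and
writes every intermediate table plus a machine-readable run report whose
counts mirror the cascade narrative (responsive per comparison, up/down,
|r| > 0.7, rate-significant, LRT-rejected, transferred, K / K+M).

All outputs are reproducible from (inputs, config, seed); every file
carries a header with the tool version, config hash and seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .cascade import CascadeConfig, cascade_summary, classify_cascade
from .cog import enrichment_table
from .de import ResponsivenessCriteria, de_all_comparisons, responsive_union, updown_summary
from .errors import ConfigError, ThermotxError
from .genome import AniConfig, GenomeAnnotation, ani_two_way, genome_coding_stats
from .growth import fit_ratkowsky, rates_from_curves, RatkowskyParams
from .lgt import run_lgt_screen
from .synthetic import (
    SimulationConfig,
    simulate_annotated_genome,
    simulate_expression_experiment,
    simulate_growth_curves,
    simulate_homology_hits,
)

log = logging.getLogger("thermotx")

_KNOWN_KEYS = {
    "seed", "outdir", "simulate", "de", "cascade", "lgt", "ani", "genome",
    "growth", "inputs",
}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    ``simulate`` toggles the synthetic front end; otherwise ``inputs``
    must point at counts/samples/genes files.  Unknown keys in the source
    mapping are configuration errors.
    """

    seed: int = 0
    outdir: str = "thermotx_out"
    simulate: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    cascade: dict = field(default_factory=dict)
    lgt: dict = field(default_factory=dict)
    ani: dict = field(default_factory=dict)
    genome: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": self.outdir, "simulate": self.simulate,
            "de": self.de, "cascade": self.cascade, "lgt": self.lgt,
            "ani": self.ani, "genome": self.genome, "growth": self.growth,
            "inputs": self.inputs,
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk).

    A stage failure aborts the run with the stage name while the outputs
    of completed stages remain on disk.
    """
    t0 = time.time()
    hashed = {k: v for k, v in config.as_dict().items() if k != "outdir"}
    cfg_hash = io.config_hash(hashed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    report: dict = {"seed": seed, "config_hash": cfg_hash, "stages": {}}

    stage = "simulate"
    try:
        if config.inputs:
            experiment = io.read_experiment(
                config.inputs["counts"], config.inputs["samples"],
                config.inputs["genes"],
            )
            truth = None
        else:
            sim_kwargs = dict(config.simulate)
            class_mix = sim_kwargs.pop("class_mix", None)
            effect = sim_kwargs.pop("effect_log2", 2.0)
            slope = sim_kwargs.pop("rate_slope_log2", 8.0)
            sim = SimulationConfig(seed=seed, **sim_kwargs)
            experiment, truth = simulate_expression_experiment(
                sim, class_mix=class_mix, effect_log2=effect,
                rate_slope_log2=slope,
            )
            io.write_experiment(experiment, outdir / "inputs", seed, cfg_hash)
            io.write_table(truth, outdir / "inputs" / "truth.tsv", seed, cfg_hash)
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "growth"
        growth_cfg = dict(config.growth)
        params = RatkowskyParams(**growth_cfg.get(
            "ratkowsky", {"b": 0.02, "c": 0.3, "t_min": 20.0, "t_max": 80.0}
        ))
        curves = simulate_growth_curves(
            params,
            temperatures=growth_cfg.get("temperatures", (30.0, 40.0, 55.0, 65.0, 70.0, 77.0)),
            noise_sd=growth_cfg.get("noise_sd", 0.05),
            seed=seed,
        )
        io.write_growth_curves(curves, outdir / "growth_curves.csv", seed, cfg_hash)
        rates = rates_from_curves(curves, min_window=growth_cfg.get("min_window", 8))
        fitted, diag = fit_ratkowsky(rates, seed=seed)
        io.write_json(
            {
                "b": fitted.b, "c": fitted.c, "t_min": fitted.t_min,
                "t_max": fitted.t_max, **diag,
            },
            outdir / "ratkowsky.json", seed, cfg_hash,
        )
        report["stages"]["growth"] = {
            "t_min": fitted.t_min, "t_max": fitted.t_max,
            "converged": diag["converged"],
        }

        stage = "de"
        criteria = ResponsivenessCriteria(**{
            k: v for k, v in config.de.items() if k != "min_reads_per"
        })
        de_tables = de_all_comparisons(
            experiment, criteria=criteria,
            min_reads_per=config.de.get("min_reads_per", "condition"),
        )
        for t, tab in de_tables.items():
            io.write_table(tab, outdir / f"de_{t:g}v65.tsv", seed, cfg_hash)
        summary = updown_summary(de_tables)
        io.write_table(summary, outdir / "de_summary.tsv", seed, cfg_hash, index=False)
        responsive = responsive_union(de_tables)
        report["stages"]["de"] = {
            "responsive_union": int(len(responsive)),
            "per_comparison": summary.to_dict(orient="records"),
        }
        log.info("stage de done: %d responsive genes", len(responsive))

        stage = "cascade"
        cas_cfg = CascadeConfig(**config.cascade)
        cascade = classify_cascade(responsive, experiment, cas_cfg)
        io.write_table(cascade, outdir / "cascade.tsv", seed, cfg_hash)
        report["stages"]["cascade"] = cascade_summary(cascade, cas_cfg)

        stage = "enrichment"
        for t, tab in de_tables.items():
            resp_t = tab.index[tab["responsive"]]
            enr = enrichment_table(resp_t, experiment.genes["cog_categories"])
            io.write_table(enr, outdir / f"enrichment_{t:g}v65.tsv", seed, cfg_hash)
        report["stages"]["enrichment"] = {"comparisons": len(de_tables)}

        stage = "lgt"
        lgt_cfg = dict(config.lgt)
        hits, lgt_truth = simulate_homology_hits(
            n_genes=lgt_cfg.get("n_genes", 1000),
            transfer_fraction=lgt_cfg.get("transfer_fraction", 0.3),
            seed=seed,
        )
        result = run_lgt_screen(hits)
        io.write_table(result.scores, outdir / "lgt_scores.tsv", seed, cfg_hash)
        io.write_json(
            {
                "close_cutoff": result.close_cutoff,
                "distal_cutoff": result.distal_cutoff,
                "close_peak": result.close_diag.peak,
                "close_minimum": result.close_diag.minimum,
                "distal_peak": result.distal_diag.peak,
                "distal_minimum": result.distal_diag.minimum,
            },
            outdir / "lgt_cutoffs.json", seed, cfg_hash,
        )
        rec = result.scores["recentness"]
        report["stages"]["lgt"] = {
            "transferred": int(result.scores["transferred"].sum()),
            "K": int((rec == "K").sum()),
            "K+M": int((rec == "K+M").sum()),
        }

        stage = "genome"
        gen_cfg = dict(config.genome)
        seq_a, seq_b, feats = simulate_annotated_genome(
            length=gen_cfg.get("length", 60000),
            coding_fraction=gen_cfg.get("coding_fraction", 0.885),
            divergence=gen_cfg.get("divergence", 0.01),
            seed=seed,
        )
        annotation = GenomeAnnotation(length=len(seq_a), features=tuple(feats))
        coding = genome_coding_stats(annotation)
        ani = ani_two_way(seq_a, seq_b, AniConfig(**config.ani))
        io.write_json({**coding, **ani}, outdir / "genome_compare.json", seed, cfg_hash)
        report["stages"]["genome"] = {
            "noncoding_to_coding_ratio": coding["noncoding_to_coding_ratio"],
            "ani_mean": ani["ani_mean"],
        }
    except ThermotxError as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        io.write_json(report, outdir / "report.json", seed, cfg_hash)
        raise

    log.info("pipeline finished in %.1fs", time.time() - t0)
    io.write_json(report, outdir / "report.json", seed, cfg_hash)
    return report
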