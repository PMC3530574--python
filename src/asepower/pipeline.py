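"""End-to-end pipeline: simulate, quantify, scan, correct, permute, summarize.

Configuration is one YAML file with a ``simulation`` block mirroring
:class:`~asepower.simulate.SimulationConfig` and an optional ``analysis``
block (flank, group filters, informative-SNP minimum, aggregator,
permutations). All artifacts are plain text (VCF/BED/TSV/JSON) with
provenance headers carrying the seed and the per-scan test count ``m``.
Re-running with the same config and seed reproduces every artifact.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .association import run_scan
from .containers import Cohort
from .correction import add_corrections
from .permutation import null_calibration
from .power import compare_power
from .quantify import region_sd_qc, transcript_ase
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

_ANALYSIS_DEFAULTS = {
    "flank": 100_000,
    "min_informative": 5,
    "ase_min_group": 4,
    "gte_min_group": 3,
    "aggregator": "mean",
    "normalize": True,
    "alpha": 0.05,
    "n_permutations": 100,
    "sample_sizes": None,  # default: full cohort only
    "n_runs": 10,
}


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig
    analysis: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        sim_raw = raw.get("simulation", {})
        if not isinstance(sim_raw, dict):
            raise ValueError("config field 'simulation' must be a mapping")
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = sorted(set(sim_raw) - known)
        if bad:
            raise ValueError(f"unknown simulation field(s): {bad}")
        for key in ("maf_range", "transcript_length", "dye_bias_coeffs"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
        ana_raw = raw.get("analysis", {})
        if not isinstance(ana_raw, dict):
            raise ValueError("config field 'analysis' must be a mapping")
        bad = sorted(set(ana_raw) - set(_ANALYSIS_DEFAULTS))
        if bad:
            raise ValueError(f"unknown analysis field(s): {bad}")
        analysis = {**_ANALYSIS_DEFAULTS, **ana_raw}
        if analysis["aggregator"] not in ("mean", "median"):
            raise ValueError("analysis.aggregator must be 'mean' or 'median'")
        return cls(simulation=sim, analysis=analysis)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def _write_records(rec: pd.DataFrame, path: Path, seed: int) -> None:
    aio.write_matrix(
        rec.set_index("snp"), path,
        provenance={"m": rec.attrs.get("m", len(rec)), "seed": seed},
    )


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run simulate → quantify → scan ×2 → correct → permute → power.

    Returns a manifest dict (also written as ``report.json``) with the
    artifact paths, per-scan test counts and headline ratios. ``seed``
    overrides the simulation seed from the config.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if seed is not None:
        sim = dataclasses.replace(sim, seed=seed)
    ana = config.analysis

    logger.info("simulating cohort (n=%d, transcripts=%d, seed=%d)",
                sim.n_samples, sim.n_transcripts, sim.seed)
    cohort = simulate_cohort(sim)
    aio.write_vcf(cohort.genotypes, out / "genotypes.vcf")
    aio.write_bed(cohort.transcripts, out / "transcripts.bed")
    aio.write_signals(cohort.gdna, out / "gdna_signals.tsv",
                      provenance={"seed": sim.seed, "assay": "gDNA"})
    aio.write_signals(cohort.cdna, out / "cdna_signals.tsv",
                      provenance={"seed": sim.seed, "assay": "cDNA"})
    aio.write_matrix(cohort.expression, out / "expression.tsv",
                     provenance={"seed": sim.seed})
    aio.write_covariates(cohort.covariates, out / "covariates.tsv")
    if cohort.truth is not None:
        cohort.truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)

    tase = transcript_ase(
        cohort, min_informative=ana["min_informative"],
        aggregator=ana["aggregator"], normalize=ana["normalize"],
    )
    aio.write_matrix(tase.values, out / "transcript_ase.tsv",
                     provenance={"min_informative": ana["min_informative"],
                                 "aggregator": ana["aggregator"]})
    _, qc = region_sd_qc(cohort, normalize=ana["normalize"],
                         min_informative=ana["min_informative"])
    qc.to_csv(out / "region_qc.tsv", sep="\t")

    manifest: dict = {"seed": sim.seed, "n_samples": sim.n_samples,
                      "scans": {}, "artifacts": {}}
    scans = {}
    for method, mg in (("ase", ana["ase_min_group"]), ("gte", ana["gte_min_group"])):
        kwargs = dict(flank=ana["flank"], min_group=mg,
                      min_informative=ana["min_informative"],
                      aggregator=ana["aggregator"], normalize=ana["normalize"])
        rec = run_scan(cohort, method, ase=tase if method == "ase" else None,
                       **kwargs)
        rec = add_corrections(rec)
        path = out / f"associations_{method}.tsv"
        _write_records(rec, path, sim.seed)
        scans[method] = rec
        manifest["scans"][method] = {"m": rec.attrs["m"], "n_records": len(rec)}
        manifest["artifacts"][f"associations_{method}"] = str(path)

        perm = null_calibration(
            cohort, method, n_permutations=ana["n_permutations"],
            seed=sim.seed, flank=ana["flank"], min_group=mg,
            min_informative=ana["min_informative"],
            aggregator=ana["aggregator"], normalize=ana["normalize"],
        )
        null_summary = {
            "n_permutations": perm.n_permutations,
            "pooled_tests": int(perm.pvalues.size),
            "ks_stat": perm.ks_stat,
            "ks_pvalue": perm.ks_pvalue,
            "frac_below_05": perm.frac_below_05,
        }
        with open(out / f"null_{method}.json", "w") as fh:
            json.dump(null_summary, fh, indent=2)
        perm.qq.to_csv(out / f"null_qq_{method}.tsv", sep="\t", index=False)
        manifest["scans"][method]["null"] = null_summary

    sizes = ana["sample_sizes"] or [sim.n_samples]
    summary = compare_power(
        cohort, sample_sizes=tuple(int(s) for s in sizes),
        n_runs=ana["n_runs"], seed=sim.seed, flank=ana["flank"],
        min_informative=ana["min_informative"], aggregator=ana["aggregator"],
        normalize=ana["normalize"],
    )
    summary.table.to_csv(out / "power_summary.tsv", sep="\t", index=False)
    ratios = {}
    for n in sizes:
        for thr in ("bonferroni_0.05", "fdr_0.05"):
            r = summary.ratio(int(n), thr, "snps")
            ratios[f"n{n}_{thr}"] = None if not np.isfinite(r) else r
    manifest["ase_gte_snp_ratios"] = ratios
    manifest["artifacts"]["power_summary"] = str(out / "power_summary.tsv")

    with open(out / "report.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
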