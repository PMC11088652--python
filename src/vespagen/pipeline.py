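"""End-to-end pipeline orchestration with a YAML config and a run manifest.

Stage order mirrors the analysis workflow: genotype/quality filters, then
three SNP-set branches maintained side by side — the physical-window LD-pruned
and locus-subsampled set feeding relatedness and kin-pruning, the SNP-count
LD-pruned set feeding PCA, and the LD-unpruned set feeding ROH/fROH — plus a
separate mitogenome branch. Every stage parameter defaults to the standard
analysis value; a manifest (parameters, per-stage sample/site counts, sha256
of every artifact) is written so identical configs yield identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import genotypes, ld, mito, pca, relatedness, roh, simulate
from .errors import ConfigError, DataError, VespagenError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Fully serializable pipeline configuration."""

    output_dir: str = "vespagen_out"
    seed: int = 0
    # either a simulate block...
    simulate: Optional[dict[str, Any]] = None
    # ...or input paths
    vcf: Optional[str] = None
    metadata: Optional[str] = None
    mito_fasta: Optional[str] = None
    mito_depth: Optional[str] = None
    # stage toggles
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "gatk_filter": False,
            "filter": True,
            "ld": True,
            "relatedness": True,
            "kin_prune": True,
            "roh": True,
            "pca": True,
            "mitotype": True,
        }
    )
    # stage parameters (defaults = the standard analysis values)
    filter_params: dict[str, Any] = field(
        default_factory=lambda: {"min_gq": 20, "max_missing_frac": 0.10, "min_depth": 3}
    )
    ld_kb_params: dict[str, Any] = field(
        default_factory=lambda: {"window_kb": 200, "r2_max": 0.1}
    )
    ld_snp_params: dict[str, Any] = field(
        default_factory=lambda: {"window_snps": 50, "step_snps": 5, "r2_max": 0.8}
    )
    subsample_step: int = 90
    relatedness_cutoff: float = 0.33
    roh_params: dict[str, Any] = field(default_factory=dict)
    roh_lengths_kb: list[float] = field(default_factory=lambda: [500, 1000, 2000])
    pca_k: int = 10
    pca_plot: bool = False
    mito_params: dict[str, Any] = field(
        default_factory=lambda: {"min_depth": 100, "max_n_frac": 0.004}
    )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, val in d.items():
            default = getattr(base, key)
            if isinstance(default, dict) and isinstance(val, dict) and key != "simulate":
                default.update(val)
            else:
                setattr(base, key, val)
        return base

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return str(path)


def fixture_config(output_dir: str, seed: int = 0, **simulate_overrides: Any) -> PipelineConfig:
    """The bundled small-fixture configuration: simulated inputs end to end.

    The locus-subsampling step is set to 1 because the fixture has ~5k SNPs
    rather than the >100k of a whole-genome panel.
    """
    sim = {"seed": seed, "autozygosity_targets": [0.05, 0.2, 0.5]}
    sim.update(simulate_overrides)
    return PipelineConfig(
        output_dir=output_dir, seed=seed, simulate=sim, subsample_step=1
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": {}, "outputs": {}}

    def record(stage: str, **counts: Any) -> None:
        manifest["stages"][stage] = counts

    def artifact(name: str, path: Path) -> None:
        manifest["outputs"][name] = _sha256(path)

    def run_stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except VespagenError as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc

    # ---- inputs -------------------------------------------------------
    aln = None
    if config.simulate is not None:
        sim_cfg = simulate.SimConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        gm, meta, truth = run_stage("simulate", simulate.simulate_panel, sim_cfg)
        aln, mito_truth = run_stage("simulate", simulate.simulate_mito, sim_cfg)
        truth.mito_haplotype = mito_truth.mito_haplotype
        vcf_path = out / "simulated.vcf"
        genotypes.write_vcf(gm, str(vcf_path))
        meta_path = out / "simulated_meta.tsv"
        genotypes.write_metadata(meta, str(meta_path))
        mito.write_fasta(aln, str(out / "simulated_mito.fasta"))
        mito.write_depth(aln, str(out / "simulated_mito_depth.tsv"))
        for p in simulate.write_truth(truth, str(out / "simulated")):
            artifact(Path(p).name, Path(p))
        for name in ("simulated.vcf", "simulated_meta.tsv", "simulated_mito.fasta",
                     "simulated_mito_depth.tsv"):
            artifact(name, out / name)
        record("simulate", n_samples=gm.n_samples, n_sites=gm.n_sites,
               n_mito_samples=aln.n_samples)
    else:
        if config.vcf is None or config.metadata is None:
            raise ConfigError("config needs either a simulate block or vcf+metadata paths")
        gm = run_stage("load", genotypes.read_vcf, config.vcf)
        meta = run_stage("load", genotypes.read_metadata, config.metadata)
        if config.mito_fasta:
            aln = run_stage("load", mito.read_fasta, config.mito_fasta)
            if config.mito_depth:
                aln = mito.read_depth(config.mito_depth, aln)
        record("load", n_samples=gm.n_samples, n_sites=gm.n_sites)
    genotypes.check_metadata(gm, meta)

    # ---- site/genotype filters ---------------------------------------
    if config.stages.get("gatk_filter"):
        gm = run_stage("gatk_filter", genotypes.gatk_hard_filter, gm)
        record("gatk_filter", n_sites=gm.n_sites)
    if config.stages.get("filter"):
        gm = run_stage("filter", genotypes.filter_genotypes, gm, **config.filter_params)
        record("filter", n_samples=gm.n_samples, n_sites=gm.n_sites)
    gm_roh = gm  # LD-unpruned branch for ROH

    # ---- LD pruning (two dialects) -----------------------------------
    gm_rel = gm_pca = gm
    if config.stages.get("ld"):
        pr_kb = run_stage("ld", ld.prune_kb_window, gm, **config.ld_kb_params)
        gm_rel = pr_kb.apply(gm)
        pr_kb.write_sites(gm, str(out / "kept_sites_kb_window.txt"))
        artifact("kept_sites_kb_window.txt", out / "kept_sites_kb_window.txt")
        pr_snp = run_stage("ld", ld.prune_snp_window, gm, **config.ld_snp_params)
        gm_pca = pr_snp.apply(gm)
        pr_snp.write_sites(gm, str(out / "kept_sites_snp_window.txt"))
        artifact("kept_sites_snp_window.txt", out / "kept_sites_snp_window.txt")
        record("ld", kb_window_kept=gm_rel.n_sites, snp_window_kept=gm_pca.n_sites)
    gm_rel = genotypes.site_subsample(gm_rel, config.subsample_step)

    # ---- relatedness + kin pruning -----------------------------------
    rel = None
    if config.stages.get("relatedness"):
        rel = run_stage("relatedness", relatedness.relatedness_matrix, gm_rel, meta)
        rel.write(str(out / "relatedness_matrix.tsv"))
        rel.per_population_mean.to_csv(out / "relatedness_summary.tsv", sep="\t", index=False)
        artifact("relatedness_matrix.tsv", out / "relatedness_matrix.tsv")
        artifact("relatedness_summary.tsv", out / "relatedness_summary.tsv")
        record("relatedness", n_females=len(rel.sample_ids), n_sites=gm_rel.n_sites)
    if config.stages.get("kin_prune"):
        if rel is None:
            raise ConfigError("kin_prune requires the relatedness stage")
        unrel = run_stage("kin_prune", relatedness.prune_related, rel,
                          config.relatedness_cutoff)
        unrel.write(str(out / "unrelated_samples.txt"))
        artifact("unrelated_samples.txt", out / "unrelated_samples.txt")
        record("kin_prune", n_retained=len(unrel.retained), n_removed=len(unrel.removed))

    # ---- ROH / fROH ---------------------------------------------------
    if config.stages.get("roh"):
        params = roh.ROHParams(**config.roh_params)
        frames = [
            run_stage("roh", roh.froh_profile, gm_roh, meta,
                      config.roh_lengths_kb, mode, params)
            for mode in ("pooled", "within_population")
        ]
        froh_table = pd.concat(frames, ignore_index=True)
        froh_table.to_csv(out / "froh.tsv", sep="\t", index=False)
        artifact("froh.tsv", out / "froh.tsv")
        seg_frames = []
        females = [s for s in gm_roh.sample_ids
                   if meta.set_index("sample_id").loc[s, "sex"] == "female"]
        for s in females:
            segs = roh.detect_roh(gm_roh.calls[gm_roh.sample_index(s)],
                                  gm_roh.chrom, gm_roh.pos, params)
            seg_frames.append(roh.segments_frame(s, segs))
        pd.concat(seg_frames, ignore_index=True).to_csv(
            out / "roh_segments.tsv", sep="\t", index=False
        )
        artifact("roh_segments.tsv", out / "roh_segments.tsv")
        record("roh", n_females=len(females), n_sites=gm_roh.n_sites,
               n_rows=len(froh_table))

    # ---- PCA ----------------------------------------------------------
    if config.stages.get("pca"):
        k = min(config.pca_k, gm_pca.n_samples - 1, gm_pca.n_sites)
        res = run_stage("pca", pca.run_pca, gm_pca, k)
        res.write(str(out / "pca_scores.tsv"))
        artifact("pca_scores.tsv", out / "pca_scores.tsv")
        if config.pca_plot:
            pca.plot_pca(res, meta, str(out / "pca.png"))
        record("pca", n_samples=gm_pca.n_samples, n_sites=gm_pca.n_sites, k=k)

    # ---- mitotype branch ---------------------------------------------
    if config.stages.get("mitotype") and aln is not None:
        trimmed, census, table = run_stage(
            "mitotype", mito.mitotype_pipeline, aln, **config.mito_params
        )
        table.to_frame().to_csv(out / "mitotypes.tsv", sep="\t", index=False)
        artifact("mitotypes.tsv", out / "mitotypes.tsv")
        record(
            "mitotype",
            n_samples=trimmed.n_samples,
            alignment_length=trimmed.length,
            n_mitotypes=table.n_mitotypes,
            n_parsimony_informative=census.n_parsimony_informative,
            n_singleton=census.n_singleton,
            n_constant=census.n_constant,
        )

    config.to_yaml(str(out / "config_used.yaml"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
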