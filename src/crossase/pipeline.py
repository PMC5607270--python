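"""End-to-end orchestration: simulate -> genotypes -> mask -> ASE ->
imprinting -> dosage, with plain-file stage outputs and a JSON report.

Stage order mirrors the analysis workflow: parental DNA calls are
filtered and intersected into informative loci, the reference is
N-masked, RNA observations are filtered and tested for allelic
imbalance, genes are classified for parent-of-origin effects over the
reciprocal crosses, and the expression matrix yields Z-dosage summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import dosage as dosage_mod
from . import genotypes as geno_mod
from . import imprinting as imp_mod
from . import io as io_mod
from .simulate import (SimConfig, make_sample_sheet, simulate_expression_matrix,
                       simulate_f1_counts, simulate_parental_vcfs)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "genotype", "mask", "ase", "imprint", "dosage")


@dataclass
class RunConfig:
    """Serializable run configuration: paths, thresholds and stage toggles."""

    outdir: str = "crossase_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    # input paths; defaulted to the simulate stage's outputs
    fayoumi_vcf: str | None = None
    leghorn_vcf: str | None = None
    reference_fasta: str | None = None
    genes_bed: str | None = None
    counts_tsv: str | None = None
    fpkm_tsv: str | None = None
    gene_map_tsv: str | None = None
    sample_sheet_tsv: str | None = None

    parental_min_dp: int = 10
    parental_error_frac: float = 0.01
    min_qd: float = 2.0
    max_fs: float = 30.0
    cluster_size: int = 3
    cluster_window: int = 35
    min_dp: int = 10
    min_gq: int = 30
    error_frac: float = 0.01
    alpha: float = 0.1
    min_samples_per_cross: int = 2
    fpkm_threshold: float = 0.1
    normalization: str = "median-autosomal"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def sim_config(self) -> SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.seed)
        return SimConfig.from_dict(params)


def _path(config: RunConfig, attr: str, default_name: str) -> str:
    explicit = getattr(config, attr)
    return explicit if explicit else os.path.join(config.outdir, default_name)


def run_simulate(config: RunConfig) -> dict:
    sim = config.sim_config()
    parental = simulate_parental_vcfs(sim)
    obs = simulate_f1_counts(sim, parental.truth)
    fpkm, gene_map, expr_sheet = simulate_expression_matrix(sim)
    sheet = make_sample_sheet(sim)

    out = config.outdir
    contig_lengths = {c: len(s) for c, s in parental.reference.items()}
    io_mod.write_parental_vcf(parental.fayoumi, contig_lengths,
                              os.path.join(out, "fayoumi.vcf"), "FAYOUMI")
    io_mod.write_parental_vcf(parental.leghorn, contig_lengths,
                              os.path.join(out, "leghorn.vcf"), "LEGHORN")
    io_mod.write_fasta(parental.reference, os.path.join(out, "reference.fa"))
    io_mod.write_bed(parental.genes, os.path.join(out, "genes.bed"))
    io_mod.write_tsv(obs, os.path.join(out, "counts.tsv"))
    fpkm.rename_axis("gene_id").reset_index().to_csv(
        os.path.join(out, "fpkm.tsv"), sep="\t", index=False)
    io_mod.write_tsv(gene_map, os.path.join(out, "gene_map.tsv"))
    io_mod.write_tsv(expr_sheet, os.path.join(out, "samples_expression.tsv"))
    io_mod.write_tsv(sheet, os.path.join(out, "samples.tsv"))
    io_mod.write_tsv(parental.truth, os.path.join(out, "truth.tsv"))
    return {"n_loci": int(len(parental.truth)),
            "n_observations": int(len(obs)),
            "n_genes": int(len(gene_map))}


def run_genotype(config: RunConfig) -> dict:
    fay = io_mod.read_parental_vcf(_path(config, "fayoumi_vcf", "fayoumi.vcf"))
    leg = io_mod.read_parental_vcf(_path(config, "leghorn_vcf", "leghorn.vcf"))
    genes = io_mod.read_bed(_path(config, "genes_bed", "genes.bed"))

    stats = {"n_fayoumi_raw": len(fay), "n_leghorn_raw": len(leg)}
    fay = geno_mod.reassign_het_to_hom(
        geno_mod.filter_parental_calls(fay, config.parental_min_dp),
        config.parental_error_frac)
    leg = geno_mod.reassign_het_to_hom(
        geno_mod.filter_parental_calls(leg, config.parental_min_dp),
        config.parental_error_frac)
    stats["n_fayoumi_filtered"] = len(fay)
    stats["n_leghorn_filtered"] = len(leg)

    informative = geno_mod.find_informative_loci(fay, leg, genes)
    io_mod.write_tsv(informative,
                     os.path.join(config.outdir, "informative_loci.tsv"))
    # all parental SNP sites (both lines, any genotype) feed the mask
    sites = pd.concat([fay[["chrom", "pos"]], leg[["chrom", "pos"]]])
    sites = sites.drop_duplicates().sort_values(["chrom", "pos"])
    io_mod.write_tsv(sites, os.path.join(config.outdir, "mask_sites.tsv"))
    stats["n_informative"] = len(informative)
    stats["n_mask_sites"] = len(sites)
    return stats


def run_mask(config: RunConfig) -> dict:
    ref = io_mod.read_fasta(_path(config, "reference_fasta", "reference.fa"))
    sites_df = io_mod.read_tsv(os.path.join(config.outdir, "mask_sites.tsv"))
    sites = list(zip(sites_df["chrom"], sites_df["pos"]))
    masked = geno_mod.mask_reference(ref, sites)
    io_mod.write_fasta(masked, os.path.join(config.outdir, "reference_masked.fa"))
    return {"n_masked_sites": len(sites)}


def run_ase(config: RunConfig) -> dict:
    obs = io_mod.read_tsv(_path(config, "counts_tsv", "counts.tsv"))
    informative = io_mod.read_tsv(
        os.path.join(config.outdir, "informative_loci.tsv"),
        dtype={"chrom": str, "gene_ids": str})
    informative["gene_ids"] = informative["gene_ids"].fillna("")

    filtered = ase_mod.filter_rna_variants(
        obs, min_qd=config.min_qd, max_fs=config.max_fs,
        cluster_size=config.cluster_size, cluster_window=config.cluster_window,
        min_dp=config.min_dp, min_gq=config.min_gq)
    cleaned = ase_mod.reassign_count_errors(filtered, config.error_frac)
    testable = ase_mod.define_testable(cleaned, informative)
    calls = ase_mod.call_ase(testable, config.alpha)
    meta = ase_mod.call_ase_meta(calls, config.alpha)
    combined = ase_mod.combined_ase_loci(calls, meta)

    io_mod.write_tsv(calls, os.path.join(config.outdir, "ase_calls.tsv"))
    io_mod.write_tsv(meta, os.path.join(config.outdir, "ase_meta.tsv"))
    io_mod.write_tsv(combined, os.path.join(config.outdir, "ase_combined.tsv"))

    expressed = ase_mod.declare_expressed_genes(testable)
    ase_genes = ase_mod.ase_gene_sets(combined)
    stats = {
        "n_observations": len(obs),
        "n_after_filters": len(filtered),
        "n_testable": len(testable),
        "n_ase_calls": int(calls["is_ase"].sum()),
        "ase_snps_by_tissue": {
            t: int(g[["chrom", "pos"]].drop_duplicates().shape[0])
            for t, g in combined.groupby("tissue")},
        "ase_genes_by_tissue": {t: len(s) for t, s in ase_genes.items()},
        "expressed_genes_by_tissue": {t: len(s) for t, s in expressed.items()},
    }
    tissues = sorted(ase_genes)
    if len(tissues) == 2:
        shared, a_only, b_only = ase_mod.tissue_specific_ase(
            ase_genes[tissues[0]], ase_genes[tissues[1]])
        stats["tissue_specific"] = {
            "shared": len(shared),
            f"{tissues[0]}_only": len(a_only),
            f"{tissues[1]}_only": len(b_only)}

    if {"ref_count_original", "alt_count_original"} <= set(obs.columns):
        keys = ["sample", "chrom", "pos"]
        orig = cleaned[keys].copy()
        orig["ref_count"] = cleaned["ref_count_original"]
        orig["alt_count"] = cleaned["alt_count_original"]
        masked_counts = cleaned[keys + ["ref_count", "alt_count"]]
        bias = ase_mod.reference_bias_report(orig, masked_counts)
        io_mod.write_tsv(bias["table"],
                         os.path.join(config.outdir, "bias_table.tsv"))
        ase_mod.plot_reference_bias(
            bias["table"], os.path.join(config.outdir, "bias_hist.png"))
        stats["reference_bias"] = {
            k: bias[k] for k in ("mean_ref_ratio_original",
                                 "mean_ref_ratio_masked",
                                 "mean_ref_ratio_averaged")}
    return stats


def run_imprint(config: RunConfig) -> dict:
    calls = io_mod.read_tsv(os.path.join(config.outdir, "ase_calls.tsv"),
                            dtype={"chrom": str, "gene_ids": str})
    calls["gene_ids"] = calls["gene_ids"].fillna("")
    ratios = imp_mod.to_parental_counts(calls)
    result = imp_mod.classify_imprinting(
        ratios, min_samples_per_cross=config.min_samples_per_cross)
    io_mod.write_tsv(result, os.path.join(config.outdir, "imprinting.tsv"))
    nuclear_ratios = ratios.loc[ratios["chrom"] != "MT"]
    summary = imp_mod.genomewide_parental_summary(ratios, nuclear_ratios)
    io_mod.write_tsv(summary["per_chromosome"],
                     os.path.join(config.outdir, "parental_ratio_by_chrom.tsv"))
    # split the mitochondrial positive control from nuclear genes
    genes_path = _path(config, "genes_bed", "genes.bed")
    if os.path.exists(genes_path):
        gene_chrom = io_mod.read_bed(genes_path).set_index("gene_id")["chrom"]
        result["chrom"] = result["gene"].map(gene_chrom)
    else:
        result["chrom"] = ""
    imprinted = result["status"].str.startswith("imprinted")
    nuclear = result["chrom"] != "MT"
    status_counts = result["status"].value_counts().to_dict()
    return {
        "status_counts": {k: int(v) for k, v in status_counts.items()},
        "n_imprinted": int(imprinted.sum()),
        "n_imprinted_nuclear": int((imprinted & nuclear).sum()),
        "n_imprinted_mito": int((imprinted & ~nuclear).sum()),
        "genomewide_median_paternal_ratio": summary["genomewide_median"],
        "pct_paternal_preference_mean": summary.get(
            "pct_paternal_preference_mean"),
    }


def run_dosage(config: RunConfig) -> dict:
    fpkm = io_mod.read_tsv(_path(config, "fpkm_tsv", "fpkm.tsv")).set_index("gene_id")
    gene_map = io_mod.read_tsv(
        _path(config, "gene_map_tsv", "gene_map.tsv")).set_index("gene_id")
    sheet_path = _path(config, "sample_sheet_tsv", "samples_expression.tsv")
    if not os.path.exists(sheet_path):
        sheet_path = _path(config, "sample_sheet_tsv", "samples.tsv")
    sheet = io_mod.read_tsv(sheet_path).set_index("sample")

    deltas = pd.Series({
        s: dosage_mod.delta_z_a(fpkm, gene_map["chrom"], s,
                                config.fpkm_threshold)
        for s in fpkm.columns})
    per_tissue = dosage_mod.tissue_mean_delta(deltas, sheet["tissue"])
    delta_df = deltas.rename("delta_z_a").rename_axis("sample").reset_index()
    delta_df["ratio"] = 2.0 ** delta_df["delta_z_a"]
    io_mod.write_tsv(delta_df, os.path.join(config.outdir, "dosage_per_sample.tsv"))
    io_mod.write_tsv(per_tissue.rename_axis("tissue").reset_index(),
                     os.path.join(config.outdir, "dosage_per_tissue.tsv"))
    stats = {"per_tissue": {
        t: {"mean_delta": float(r.mean_delta), "ratio": float(r.ratio)}
        for t, r in per_tissue.iterrows()}}
    if set(sheet["sex"].unique()) >= {"M", "F"}:
        auto_r, z_r = dosage_mod.male_female_ratio(
            fpkm, gene_map["chrom"], sheet["sex"], config.fpkm_threshold,
            config.normalization)
        stats["male_female"] = {"autosomal_ratio": auto_r, "z_ratio": z_r}
    return stats


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "genotype": run_genotype,
    "mask": run_mask,
    "ase": run_ase,
    "imprint": run_imprint,
    "dosage": run_dosage,
}

_STAGE_INPUTS = {
    "mask": ["mask_sites.tsv"],
    "ase": ["informative_loci.tsv"],
    "imprint": ["ase_calls.tsv"],
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns and writes
    a summary report carrying the configuration hash."""
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "config_used.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    report = {"config_hash": config.config_hash(), "stages": {}}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        for dep in _STAGE_INPUTS.get(stage, []):
            if not os.path.exists(os.path.join(config.outdir, dep)):
                raise FileNotFoundError(
                    f"stage '{stage}' needs {dep}; run its upstream stage first")
        logger.info("running stage %s", stage)
        report["stages"][stage] = _STAGE_FUNCS[stage](config)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
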