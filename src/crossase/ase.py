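"""Allele-specific expression calling from RNA allelic read counts.

The analysis unit is a (sample, locus) observation of reference and
alternative allele read counts at a predicted-heterozygous (informative)
locus.  Observations pass a variant-quality cascade (QD, strand bias,
SNP clusters, depth, genotype quality), sub-error allele counts are
zeroed, and allelic balance is tested per sample with an exact binomial
test (BH-corrected within sample).  Monoallelic expression at a testable
locus is ASE by definition.  Evidence is pooled across replicates that
prefer the same allele with Fisher's combined probability test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, binom_test_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "filter_rna_variants",
    "cluster_sites",
    "reassign_count_errors",
    "define_testable",
    "call_ase_within_sample",
    "call_ase",
    "call_ase_meta",
    "combined_ase_loci",
    "declare_expressed_genes",
    "ase_gene_sets",
    "tissue_specific_ase",
    "reference_bias_report",
    "plot_reference_bias",
]


def cluster_sites(positions_by_chrom: dict, cluster_size: int = 3,
                  window: int = 35) -> set:
    """Sites belonging to a SNP cluster: any ``cluster_size`` sites whose
    span (inclusive, in bp) fits within ``window``.

    Returns the set of (chrom, pos) to exclude; every member of a
    qualifying window is removed.
    """
    bad = set()
    for chrom, positions in positions_by_chrom.items():
        pos = np.sort(np.unique(np.asarray(list(positions), dtype=np.int64)))
        if len(pos) < cluster_size:
            continue
        span = pos[cluster_size - 1:] - pos[:len(pos) - cluster_size + 1] + 1
        for i in np.nonzero(span <= window)[0]:
            for p in pos[i:i + cluster_size]:
                bad.add((chrom, int(p)))
    return bad


def filter_rna_variants(obs: pd.DataFrame, *, min_qd: float = 2.0,
                        max_fs: float = 30.0, cluster_size: int = 3,
                        cluster_window: int = 35, min_dp: int = 10,
                        min_gq: int = 30) -> pd.DataFrame:
    """Quality cascade for RNA variant observations.

    Site level (cohort-wide): remove sites with QD < ``min_qd`` or
    FS > ``max_fs``, and all members of SNP clusters (``cluster_size``
    sites within ``cluster_window`` bp).  Observation level: remove rows
    with DP < ``min_dp`` or GQ < ``min_gq`` (boundary values are kept).
    Missing annotations are treated conservatively (removed).
    """
    qd = pd.to_numeric(obs["QD"], errors="coerce")
    fs = pd.to_numeric(obs["FS"], errors="coerce")
    site_bad = qd.isna() | fs.isna() | (qd < min_qd) | (fs > max_fs)
    bad_sites = set(map(tuple, obs.loc[site_bad, ["chrom", "pos"]]
                        .drop_duplicates().itertuples(index=False)))

    sites = obs[["chrom", "pos"]].drop_duplicates()
    by_chrom = {c: g["pos"].to_numpy() for c, g in sites.groupby("chrom")}
    bad_sites |= cluster_sites(by_chrom, cluster_size, cluster_window)

    key = list(zip(obs["chrom"], obs["pos"]))
    keep_site = np.fromiter((k not in bad_sites for k in key),
                            dtype=bool, count=len(obs))
    dp = pd.to_numeric(obs["DP"], errors="coerce")
    gq = pd.to_numeric(obs["GQ"], errors="coerce")
    keep_row = dp.notna() & gq.notna() & (dp >= min_dp) & (gq >= min_gq)
    out = obs.loc[keep_site & keep_row.to_numpy()].copy()
    logger.info("RNA filter: %d/%d observations retained (%d sites excluded)",
                len(out), len(obs), len(bad_sites))
    return out


def reassign_count_errors(obs: pd.DataFrame, error_frac: float = 0.01,
                          count_cols=("ref_count", "alt_count")) -> pd.DataFrame:
    """Zero out allele counts below ``DP * error_frac`` (sequencing error).

    Strict inequality: a count equal to the threshold is kept.  An
    observation whose counts are both zeroed is flagged unusable via the
    added ``usable`` column.
    """
    out = obs.copy()
    dp = out["DP"].to_numpy(dtype=float)
    threshold = dp * error_frac
    for col in count_cols:
        counts = out[col].to_numpy(dtype=float)
        out[col] = np.where(counts < threshold, 0, counts).astype(np.int64)
    out["usable"] = (out[count_cols[0]] + out[count_cols[1]]) > 0
    return out


def define_testable(obs: pd.DataFrame, informative: pd.DataFrame) -> pd.DataFrame:
    """Observations at informative loci, with line-labelled allele counts.

    A locus is testable for a sample when the predicted F1 genotype is
    heterozygous (the locus is informative) and the site survived the RNA
    filters.  Adds ``fayoumi_count``/``leghorn_count`` by mapping the
    ref/alt counts through the informative locus' allele assignment, plus
    ``gene_ids`` when present.  Observations whose recorded alleles
    contradict the informative table are excluded with a log message.
    """
    cols = ["chrom", "pos", "ref", "alt", "fayoumi_allele", "leghorn_allele"]
    if "gene_ids" in informative.columns:
        cols.append("gene_ids")
    merged = obs.merge(informative[cols], on=["chrom", "pos"], how="inner",
                       suffixes=("", "_inf"))
    if "ref_inf" in merged.columns:
        consistent = ((merged["ref"] == merged["ref_inf"])
                      & (merged["alt"] == merged["alt_inf"]))
        n_bad = int((~consistent).sum())
        if n_bad:
            logger.warning("excluding %d observations with allele mismatch", n_bad)
        merged = merged.loc[consistent].drop(columns=["ref_inf", "alt_inf"])
    fay_is_ref = (merged["fayoumi_allele"] == merged["ref"]).to_numpy()
    ref_c = merged["ref_count"].to_numpy()
    alt_c = merged["alt_count"].to_numpy()
    merged["fayoumi_count"] = np.where(fay_is_ref, ref_c, alt_c)
    merged["leghorn_count"] = np.where(fay_is_ref, alt_c, ref_c)
    return merged


def call_ase_within_sample(testable: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """ASE calls for the testable observations of a single sample.

    Monoallelic observations (one allele count zero after error
    reassignment) are ASE without a test.  Biallelic observations get an
    exact two-sided binomial p-value against 0.5, BH-adjusted across all
    biallelic testable loci of the sample; ASE when the adjusted p is at
    or below ``alpha``.  Ties (equal counts) have no preferred allele and
    are never ASE.
    """
    out = testable.copy()
    if len(out) == 0:
        return _empty_calls(out)
    fay = out["fayoumi_count"].to_numpy(dtype=np.int64)
    leg = out["leghorn_count"].to_numpy(dtype=np.int64)
    total = fay + leg
    usable = total > 0
    if not usable.all():
        out = out.loc[usable].copy()
        fay, leg, total = fay[usable], leg[usable], total[usable]
    if len(out) == 0:
        return _empty_calls(out)

    mono = (fay == 0) | (leg == 0)
    tied = fay == leg
    out["monoallelic"] = mono
    out["preferred_allele"] = np.select(
        [tied, fay > leg], ["tied", "fayoumi"], default="leghorn")
    pref_count = np.maximum(fay, leg)
    out["allelic_ratio"] = pref_count / total
    ref_c = out["ref_count"].to_numpy()
    alt_c = out["alt_count"].to_numpy()
    out["preferred_refalt"] = np.select(
        [tied, ref_c > alt_c], ["tied", "reference"], default="alternative")

    p = np.full(len(out), np.nan)
    bi = ~mono
    if bi.any():
        p[bi] = binom_test_two_sided(fay[bi], total[bi])
    out["p_value"] = p
    p_adj = np.full(len(out), np.nan)
    if bi.any():
        p_adj[bi] = bh_adjust(p[bi])
    out["p_adjusted"] = p_adj
    out["is_ase"] = mono | (np.nan_to_num(p_adj, nan=1.0) <= alpha)
    out.loc[out["preferred_allele"] == "tied", "is_ase"] = False
    return out


def _empty_calls(df: pd.DataFrame) -> pd.DataFrame:
    for col, dtype in [("monoallelic", bool), ("preferred_allele", object),
                       ("allelic_ratio", float), ("preferred_refalt", object),
                       ("p_value", float), ("p_adjusted", float),
                       ("is_ase", bool)]:
        df[col] = pd.Series(dtype=dtype)
    return df


def call_ase(testable: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Within-sample ASE calls for every sample in a testable table."""
    parts = [call_ase_within_sample(g, alpha)
             for _, g in testable.groupby("sample", sort=True)]
    if not parts:
        return _empty_calls(testable.copy())
    return pd.concat(parts, ignore_index=True)


def call_ase_meta(calls: pd.DataFrame, alpha: float = 0.1,
                  min_samples: int = 2) -> pd.DataFrame:
    """Meta-analysis of ASE across replicates of a tissue.

    Per locus, samples sharing the same preferred allele (at least
    ``min_samples``) form a group; the raw binomial p-values of the
    group's biallelic members are combined with Fisher's method and the
    combined p-values are BH-adjusted across loci within the tissue.
    A group whose members are all monoallelic is declared ASE outright
    (no p-value exists to combine).
    """
    usable = calls.loc[calls["preferred_allele"].isin(["fayoumi", "leghorn"])].copy()
    if len(usable) == 0:
        return pd.DataFrame(columns=[
            "tissue", "chrom", "pos", "gene_ids", "preferred_allele",
            "n_samples", "sample_ids", "chi_square", "dof", "combined_p",
            "combined_p_adjusted", "is_ase"])
    keys = ["tissue", "chrom", "pos", "preferred_allele"]
    # monoallelic rows (NaN p) count toward group support but contribute
    # nothing to the Fisher statistic
    usable["_logp"] = np.where(
        usable["p_value"].notna(),
        np.log(usable["p_value"].clip(lower=np.finfo(float).tiny)), 0.0)
    grouped = usable.groupby(keys, sort=True).agg(
        n_samples=("sample", "size"), **{
            "sample_ids": ("sample", lambda s: ",".join(sorted(s))),
            "sum_logp": ("_logp", "sum"),
            "n_p": ("p_value", "count"),
            **({"gene_ids": ("gene_ids", "first")}
               if "gene_ids" in usable.columns else {}),
        }).reset_index()
    meta = grouped.loc[grouped["n_samples"] >= min_samples].copy()
    has_p = meta["n_p"] > 0
    meta["chi_square"] = np.where(has_p, -2.0 * meta["sum_logp"], np.nan)
    meta["dof"] = np.where(has_p, 2 * meta["n_p"], 0).astype(int)
    meta["combined_p"] = np.where(
        has_p, sps.chi2.sf(meta["chi_square"], np.maximum(meta["dof"], 1)), np.nan)
    meta["combined_p_adjusted"] = np.nan
    meta["is_ase"] = False
    for _, idx in meta.groupby("tissue").groups.items():
        sub = meta.loc[idx]
        with_p = sub.index[sub["n_p"] > 0]
        if len(with_p):
            meta.loc[with_p, "combined_p_adjusted"] = bh_adjust(
                meta.loc[with_p, "combined_p"].to_numpy())
    meta["is_ase"] = ((meta["n_p"] == 0)
                      | (meta["combined_p_adjusted"].fillna(1.0) <= alpha))
    return meta.drop(columns=["sum_logp"]).reset_index(drop=True)


def combined_ase_loci(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Union of within-sample and meta-analysis ASE loci per tissue."""
    cols = ["tissue", "chrom", "pos"]
    frames = []
    within = calls.loc[calls["is_ase"], cols
                       + (["gene_ids"] if "gene_ids" in calls.columns else [])]
    frames.append(within.drop_duplicates(subset=cols))
    if len(meta):
        m = meta.loc[meta["is_ase"], cols
                     + (["gene_ids"] if "gene_ids" in meta.columns else [])]
        frames.append(m.drop_duplicates(subset=cols))
    out = pd.concat(frames, ignore_index=True).drop_duplicates(subset=cols)
    return out.sort_values(cols, kind="stable").reset_index(drop=True)


def declare_expressed_genes(obs: pd.DataFrame, min_samples: int = 2) -> dict:
    """Genes expressed per tissue: a gene is expressed when at least one
    of its SNPs is observed in ``min_samples`` or more samples of the
    tissue (the rule is per SNP, not summed over SNPs)."""
    expressed: dict[str, set] = {}
    with_genes = obs.loc[obs.get("gene_ids", pd.Series(dtype=object)).fillna("") != ""]
    counts = (with_genes.groupby(["tissue", "chrom", "pos"])
              .agg(n=("sample", "nunique"), gene_ids=("gene_ids", "first"))
              .reset_index())
    hits = counts.loc[counts["n"] >= min_samples]
    for tissue, g in hits.groupby("tissue"):
        genes: set = set()
        for ids in g["gene_ids"]:
            genes.update(ids.split(","))
        expressed[tissue] = genes - {""}
    for tissue in obs["tissue"].unique():
        expressed.setdefault(tissue, set())
    return expressed


def ase_gene_sets(combined: pd.DataFrame) -> dict:
    """Genes containing at least one ASE SNP, per tissue."""
    out: dict[str, set] = {}
    for tissue, g in combined.groupby("tissue"):
        genes: set = set()
        for ids in g.get("gene_ids", pd.Series(dtype=object)).fillna(""):
            genes.update(ids.split(","))
        out[tissue] = genes - {""}
    return out


def tissue_specific_ase(genes_a: set, genes_b: set):
    """Partition two tissue ASE gene sets into (shared, a_only, b_only)."""
    shared = genes_a & genes_b
    return shared, genes_a - shared, genes_b - shared


def reference_bias_report(counts_original: pd.DataFrame,
                          counts_masked: pd.DataFrame) -> dict:
    """Reference-bias diagnostics comparing original vs N-masked alignments.

    Both tables carry (sample, chrom, pos, ref_count, alt_count).  Reports
    the mean reference-allele ratio under each alignment and under the
    count-averaging strategy (per-observation mean of the two count pairs,
    then ratio).  Observations present in only one table are excluded from
    averaging and counted.
    """
    keys = [k for k in ("sample", "chrom", "pos") if k in counts_original.columns
            and k in counts_masked.columns]
    merged = counts_original.merge(counts_masked, on=keys, how="outer",
                                   suffixes=("_orig", "_mask"), indicator=True)
    n_unmatched = int((merged["_merge"] != "both").sum())
    both = merged.loc[merged["_merge"] == "both"].copy()

    def mean_ratio(ref, alt):
        total = ref + alt
        ok = total > 0
        return float((ref[ok] / total[ok]).mean()) if ok.any() else np.nan

    ref_o = both["ref_count_orig"].to_numpy(dtype=float)
    alt_o = both["alt_count_orig"].to_numpy(dtype=float)
    ref_m = both["ref_count_mask"].to_numpy(dtype=float)
    alt_m = both["alt_count_mask"].to_numpy(dtype=float)
    both["ref_count_avg"] = (ref_o + ref_m) / 2.0
    both["alt_count_avg"] = (alt_o + alt_m) / 2.0
    return {
        "mean_ref_ratio_original": mean_ratio(ref_o, alt_o),
        "mean_ref_ratio_masked": mean_ratio(ref_m, alt_m),
        "mean_ref_ratio_averaged": mean_ratio(
            both["ref_count_avg"].to_numpy(), both["alt_count_avg"].to_numpy()),
        "n_shared": len(both),
        "n_unmatched": n_unmatched,
        "table": both.drop(columns=["_merge"]),
    }


def plot_reference_bias(bias_table: pd.DataFrame, path) -> None:
    """Histogram of per-observation reference-allele ratios under the
    original and N-masked alignments (the distributions whose right shift
    reveals alignment reference bias)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for prefix, label in (("orig", "original reference"),
                          ("mask", "masked reference")):
        ref = bias_table[f"ref_count_{prefix}"].to_numpy(dtype=float)
        alt = bias_table[f"alt_count_{prefix}"].to_numpy(dtype=float)
        total = ref + alt
        ok = total > 0
        ax.hist(ref[ok] / total[ok], bins=50, range=(0, 1), alpha=0.5,
                label=label, density=True)
    ax.axvline(0.5, color="k", lw=0.8, ls="--")
    ax.set_xlabel("reference-allele ratio")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
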