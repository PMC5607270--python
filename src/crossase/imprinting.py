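"""Parent-of-origin analysis over reciprocal crosses.

Reciprocal crosses disentangle parent-of-origin effects (imprinting) from
line-of-origin effects (cis regulation): an imprinted gene prefers the
allele inherited from one parent in *both* cross directions, so the
preferred line flips between FL (Fayoumi sire x Leghorn dam) and LF
samples, whereas a cis effect keeps preferring the same line's allele
regardless of direction.  Mitochondrial loci, maternally inherited, act
as a built-in positive control for the maternal pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "parental_origin_of_line",
    "to_parental_counts",
    "classify_imprinting",
    "genomewide_parental_summary",
]

_CROSSES = ("FL", "LF")


def parental_origin_of_line(line: str, cross: str) -> str:
    """Which parent contributed a line's allele in a given cross.

    Cross names are sire-first: in FL the Fayoumi allele is paternal.
    """
    if cross not in _CROSSES:
        raise ValueError(f"not an F1 cross: {cross!r}")
    if line not in ("fayoumi", "leghorn"):
        raise ValueError(f"unknown line: {line!r}")
    paternal_line = "fayoumi" if cross == "FL" else "leghorn"
    return "paternal" if line == paternal_line else "maternal"


def to_parental_counts(obs: pd.DataFrame) -> pd.DataFrame:
    """Map line-labelled allele counts to parental-origin counts.

    ``obs`` needs ``cross`` (FL/LF), ``fayoumi_count`` and
    ``leghorn_count``; parental-line (non-F1) samples are rejected.
    Adds ``paternal_count``, ``maternal_count`` and ``paternal_ratio``
    (paternal / total; NaN at zero total).
    """
    bad = ~obs["cross"].isin(_CROSSES)
    if bad.any():
        raise ValueError(
            f"non-F1 samples cannot be decomposed by parent: "
            f"{sorted(obs.loc[bad, 'sample'].unique())[:5]}")
    out = obs.copy()
    fay_paternal = (out["cross"] == "FL").to_numpy()
    fay = out["fayoumi_count"].to_numpy(dtype=float)
    leg = out["leghorn_count"].to_numpy(dtype=float)
    out["paternal_count"] = np.where(fay_paternal, fay, leg).astype(np.int64)
    out["maternal_count"] = np.where(fay_paternal, leg, fay).astype(np.int64)
    total = out["paternal_count"] + out["maternal_count"]
    with np.errstate(invalid="ignore"):
        out["paternal_ratio"] = np.where(
            total > 0, out["paternal_count"] / total, np.nan)
    return out


def classify_imprinting(calls: pd.DataFrame, min_samples_per_cross: int = 2,
                        gene_col: str = "gene_ids") -> pd.DataFrame:
    """Classify genes by parent-of-origin pattern from per-sample ASE calls.

    ``calls`` are within-sample ASE calls (one row per sample x SNP)
    carrying ``is_ase``, ``preferred_allele`` (line labels or 'tied'),
    ``cross``, ``tissue`` and gene annotation.  Per (tissue, gene):

    * ``imprinted_paternal`` / ``imprinted_maternal`` — at least
      ``min_samples_per_cross`` distinct samples with a detected ASE SNP
      in each cross direction, and every supporting (sample, SNP) call
      prefers the same parental origin;
    * ``line_effect`` — support in both crosses but the preferred *line*
      is unanimous instead (origin flips with direction);
    * ``not_imprinted`` — anything else, including genes whose support is
      contradictory or confined to one cross direction.

    A supporting call with a tied preferred allele breaks unanimity.
    """
    ase = calls.loc[calls["is_ase"]].copy()
    ase[gene_col] = ase[gene_col].fillna("")
    ase = ase.loc[ase[gene_col] != ""]
    ase = ase.assign(gene=ase[gene_col].str.split(",")).explode("gene")

    rows = []
    for (tissue, gene), g in ase.groupby(["tissue", "gene"], sort=True):
        support_fl = g.loc[g["cross"] == "FL", "sample"].nunique()
        support_lf = g.loc[g["cross"] == "LF", "sample"].nunique()
        origins = {
            parental_origin_of_line(line, cross) if line != "tied" else "tied"
            for line, cross in zip(g["preferred_allele"], g["cross"])
        }
        lines = set(g["preferred_allele"])
        enough = (support_fl >= min_samples_per_cross
                  and support_lf >= min_samples_per_cross)
        if enough and len(origins) == 1 and "tied" not in origins:
            status = f"imprinted_{origins.pop()}"
        elif enough and len(lines) == 1 and "tied" not in lines:
            status = "line_effect"
        else:
            status = "not_imprinted"
        rows.append((tissue, gene, status, support_fl, support_lf,
                     g["pos"].nunique()))
    return pd.DataFrame(rows, columns=[
        "tissue", "gene", "status", "n_samples_FL", "n_samples_LF", "n_snps"])


def genomewide_parental_summary(ratios: pd.DataFrame,
                                ase_calls: pd.DataFrame | None = None) -> dict:
    """Distributional summaries of the paternal expression ratio.

    Returns per-chromosome quantiles of ``paternal_ratio`` over all
    testable observations, the genome-wide median, and (when within-sample
    ASE calls with parental counts are supplied) the per-sample fraction
    of ASE loci preferring the paternal allele.
    """
    ok = ratios.loc[ratios["paternal_ratio"].notna()]
    per_chrom = (ok.groupby("chrom")["paternal_ratio"]
                 .quantile([0.25, 0.5, 0.75]).unstack()
                 .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
                 .reset_index())
    out = {
        "per_chromosome": per_chrom,
        "genomewide_median": float(ok["paternal_ratio"].median()),
    }
    if ase_calls is not None:
        sub = ase_calls.loc[ase_calls["is_ase"]
                            & ase_calls["paternal_ratio"].notna()
                            & (ase_calls["paternal_count"]
                               != ase_calls["maternal_count"])]
        frac = (sub.assign(pat=sub["paternal_ratio"] > 0.5)
                .groupby("sample")["pat"].mean() * 100.0)
        out["pct_paternal_preference_by_sample"] = frac
        out["pct_paternal_preference_mean"] = (
            float(frac.mean()) if len(frac) else np.nan)
    return out
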