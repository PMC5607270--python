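"""Z-chromosome dosage compensation from FPKM expression matrices.

Birds are ZZ (male) / ZW (female).  Dosage compensation is quantified as
delta_ZA = mean log2 FPKM of Z-linked genes minus mean log2 FPKM of
autosomal genes within a sample (genes with FPKM > 0.1), and as the
male-to-female expression ratio of Z-linked versus autosomal genes after
between-sample normalisation.  2**delta_ZA is the Z-to-A expression
ratio; 0 (ratio 1) means full compensation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "fpkm_from_counts",
    "delta_z_a",
    "z_to_a_ratio",
    "tissue_mean_delta",
    "male_female_ratio",
]

# sex chromosome W and the mitochondrion belong to neither expression class
_EXCLUDED_CHROMS = ("W", "MT")


def fpkm_from_counts(counts: pd.DataFrame, gene_lengths: pd.Series,
                     mapped_totals: pd.Series) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (gene length [bp] * mapped reads in sample).

    ``counts`` is genes x samples; ``gene_lengths`` indexed by gene,
    ``mapped_totals`` by sample.
    """
    lengths = gene_lengths.reindex(counts.index)
    totals = mapped_totals.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive mapped-read total")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def _classes(gene_chrom: pd.Series):
    chrom = gene_chrom.astype(str)
    is_z = chrom == "Z"
    is_auto = ~is_z & ~chrom.isin(_EXCLUDED_CHROMS)
    return is_z, is_auto


def delta_z_a(fpkm: pd.DataFrame, gene_chrom: pd.Series, sample: str,
              threshold: float = 0.1) -> float:
    """delta_ZA for one sample: mean log2 FPKM of Z genes minus mean log2
    FPKM of autosomal genes, over genes with FPKM strictly above
    ``threshold``."""
    if sample not in fpkm.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    x = fpkm[sample]
    chrom = gene_chrom.reindex(fpkm.index)
    if chrom.isna().any():
        raise ValueError("every gene needs a chromosome assignment")
    is_z, is_auto = _classes(chrom)
    expressed = x > threshold
    z_vals = x[is_z.to_numpy() & expressed.to_numpy()]
    a_vals = x[is_auto.to_numpy() & expressed.to_numpy()]
    if len(z_vals) == 0 or len(a_vals) == 0:
        raise ValueError(
            f"sample {sample!r}: no expressed genes in one class "
            f"(Z: {len(z_vals)}, autosomal: {len(a_vals)})")
    return float(np.log2(z_vals).mean() - np.log2(a_vals).mean())


def z_to_a_ratio(delta: float) -> float:
    """Z-to-autosome expression ratio implied by a delta_ZA value."""
    return float(2.0 ** delta)


def tissue_mean_delta(deltas: pd.Series, tissue_of_sample: pd.Series) -> pd.DataFrame:
    """Average per-sample delta_ZA within tissues.

    Returns a tissue-indexed frame with ``mean_delta``, ``ratio``
    (= 2**mean_delta) and ``n_samples``.
    """
    tissues = tissue_of_sample.reindex(deltas.index)
    grouped = deltas.groupby(tissues)
    out = pd.DataFrame({
        "mean_delta": grouped.mean(),
        "n_samples": grouped.size(),
    })
    out["ratio"] = 2.0 ** out["mean_delta"]
    return out


def male_female_ratio(fpkm: pd.DataFrame, gene_chrom: pd.Series,
                      sex_of_sample: pd.Series, threshold: float = 0.1,
                      normalization: str = "median-autosomal"):
    """Male-to-female expression ratio for autosomal and Z-linked genes.

    Samples are first normalised so their autosomal expression is
    comparable (``median-autosomal``: scale each sample so its median
    autosomal log2 FPKM above ``threshold`` matches the cross-sample
    median; ``none``: no scaling).  The ratio per class is
    2**(mean log2 male - mean log2 female) over expressed genes.

    Returns ``(autosomal_ratio, z_ratio)``.
    """
    sex = sex_of_sample.reindex(fpkm.columns)
    males = sex.index[sex == "M"]
    females = sex.index[sex == "F"]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("need at least one sample of each sex")
    chrom = gene_chrom.reindex(fpkm.index)
    is_z, is_auto = _classes(chrom)

    mat = fpkm.copy()
    if normalization == "median-autosomal":
        med = {}
        for s in mat.columns:
            vals = mat.loc[is_auto.to_numpy(), s]
            vals = vals[vals > threshold]
            med[s] = float(np.log2(vals).median())
        target = float(np.median(list(med.values())))
        for s in mat.columns:
            mat[s] = mat[s] * 2.0 ** (target - med[s])
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")

    def class_mean(samples, mask):
        logs = []
        for s in samples:
            vals = mat.loc[mask.to_numpy(), s]
            vals = vals[vals > threshold]
            logs.append(np.log2(vals).mean())
        return float(np.mean(logs))

    auto_ratio = 2.0 ** (class_mean(males, is_auto) - class_mean(females, is_auto))
    z_ratio = 2.0 ** (class_mean(males, is_z) - class_mean(females, is_z))
    return float(auto_ratio), float(z_ratio)
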