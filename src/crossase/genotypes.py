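"""Parental DNA variant filtering, informative loci and reference masking.

Two inbred lines that are homozygous for different alleles at a locus
produce F1 offspring that are predictably heterozygous there, with a known
allele-to-parent assignment.  This module filters the parental calls
(depth > 10, sequencing-error heterozygote reassignment), intersects the
two lines to find those informative loci, assigns loci to genes, and masks
all parental SNP positions with 'N' in the reference to mitigate
alignment reference bias.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "filter_parental_calls",
    "reassign_het_to_hom",
    "find_informative_loci",
    "assign_genes",
    "mask_reference",
    "genotype_consistency",
]

_SNV_BASES = frozenset("ACGT")


class DataIntegrityError(ValueError):
    """Conflicting or malformed variant records."""


def filter_parental_calls(calls: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Keep calls with read depth strictly greater than ``min_depth``.

    Records with missing DP are dropped with a warning.
    """
    dp = pd.to_numeric(calls["DP"], errors="coerce")
    missing = dp.isna()
    if missing.any():
        logger.warning("dropping %d calls with missing DP", int(missing.sum()))
    keep = dp > min_depth
    return calls.loc[keep & ~missing].copy()


def reassign_het_to_hom(calls: pd.DataFrame, error_frac: float = 0.01) -> pd.DataFrame:
    """Reassign heterozygous calls whose minor-allele count is below
    ``DP * error_frac`` to homozygous for the major allele.

    The minor count is treated as sequencing error.  Equal allele counts
    are left unchanged (no major allele to collapse to).
    """
    out = calls.copy()
    het = out["genotype"].to_numpy() == "het"
    ref_c = out["ref_count"].to_numpy(dtype=float)
    alt_c = out["alt_count"].to_numpy(dtype=float)
    dp = out["DP"].to_numpy(dtype=float)
    minor = np.minimum(ref_c, alt_c)
    flip = het & (minor < dp * error_frac) & (ref_c != alt_c)
    major_is_ref = ref_c > alt_c
    gt = out["genotype"].to_numpy(dtype=object)
    gt[flip & major_is_ref] = "hom_ref"
    gt[flip & ~major_is_ref] = "hom_alt"
    out["genotype"] = gt
    return out


def _hom_allele(calls: pd.DataFrame) -> pd.DataFrame:
    """Homozygous SNV calls with the carried allele; drops het calls,
    indels and non-ACGT alleles."""
    is_snv = calls["ref"].isin(_SNV_BASES) & calls["alt"].isin(_SNV_BASES)
    n_non_snv = int((~is_snv).sum())
    if n_non_snv:
        logger.info("excluding %d non-SNV/multi-allelic records", n_non_snv)
    hom = calls.loc[is_snv & calls["genotype"].isin(["hom_ref", "hom_alt"])].copy()
    hom["allele"] = np.where(hom["genotype"] == "hom_ref", hom["ref"], hom["alt"])
    dup = hom.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        conflicting = hom.loc[dup].groupby(["chrom", "pos"])["allele"].nunique()
        if (conflicting > 1).any():
            raise DataIntegrityError(
                "conflicting duplicate records at "
                f"{conflicting[conflicting > 1].index.tolist()[:5]}")
        hom = hom.drop_duplicates(subset=["chrom", "pos"])
    return hom[["chrom", "pos", "ref", "alt", "allele"]]


def find_informative_loci(fayoumi: pd.DataFrame, leghorn: pd.DataFrame,
                          genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Loci where both lines are homozygous for different alleles.

    F1 offspring are predicted heterozygous at every returned locus, with
    the Fayoumi and Leghorn alleles recorded.  ``genes`` (optional BED-style
    table with gene_id, chrom, start0, end) adds a ``gene_ids`` column.

    Input tables must already be depth-filtered and error-reassigned.
    """
    fay = _hom_allele(fayoumi).rename(columns={"allele": "fayoumi_allele"})
    leg = _hom_allele(leghorn).rename(columns={"allele": "leghorn_allele"})
    merged = fay.merge(leg[["chrom", "pos", "leghorn_allele"]],
                       on=["chrom", "pos"], how="inner")
    informative = merged.loc[merged.fayoumi_allele != merged.leghorn_allele].copy()
    informative = informative.sort_values(["chrom", "pos"], kind="stable")
    informative = informative.reset_index(drop=True)
    if genes is not None:
        informative = assign_genes(informative, genes)
    else:
        informative["gene_ids"] = ""
    return informative


def assign_genes(loci: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate loci with every gene whose interval contains them.

    ``genes`` uses BED conventions (0-based half-open start0/end); locus
    positions are 1-based.  Overlapping genes all contribute; gene ids are
    comma-joined, sorted, empty when intergenic.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        if row.end <= row.start0:
            raise DataIntegrityError(f"empty gene interval for {row.gene_id}")
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start0, row.end, row.gene_id)
    out = loci.copy()
    ids = []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree[pos - 1]) if tree is not None else []
        ids.append(",".join(hits))
    out["gene_ids"] = ids
    return out


def mask_reference(sequences: dict, sites) -> dict:
    """Replace the base at each (chrom, 1-based pos) site with 'N'.

    Sites on sequences absent from the reference are dropped with a
    warning (unplaced scaffolds); sites beyond a sequence's length raise.
    Idempotent: masking an already-masked position is a no-op.
    """
    by_chrom: dict[str, set] = {}
    n_dropped = 0
    for chrom, pos in sites:
        if chrom not in sequences:
            n_dropped += 1
            continue
        if not 1 <= pos <= len(sequences[chrom]):
            raise IndexError(
                f"site {chrom}:{pos} beyond sequence length {len(sequences[chrom])}")
        by_chrom.setdefault(chrom, set()).add(pos)
    if n_dropped:
        logger.warning("dropped %d sites on sequences absent from reference",
                       n_dropped)
    masked = {}
    for chrom, seq in sequences.items():
        positions = by_chrom.get(chrom)
        if not positions:
            masked[chrom] = seq
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        arr[np.fromiter(positions, dtype=np.int64) - 1] = b"N"
        masked[chrom] = arr.tobytes().decode()
    return masked


def genotype_consistency(predicted: dict, observed: dict) -> dict:
    """Compare two genotype maps keyed by (chrom, pos).

    Returns counts of shared/exclusive loci and the percentage of shared
    loci with identical genotype (None when nothing is shared).
    """
    shared = predicted.keys() & observed.keys()
    n_equal = sum(predicted[k] == observed[k] for k in shared)
    pct = 100.0 * n_equal / len(shared) if shared else None
    return {
        "n_shared": len(shared),
        "n_only_predicted": len(predicted.keys() - observed.keys()),
        "n_only_observed": len(observed.keys() - predicted.keys()),
        "n_equal": n_equal,
        "pct_consistent": pct,
    }
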