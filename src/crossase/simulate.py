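"""Synthetic reciprocal-cross data with known ground truth.

Emulates the study design this package analyses: two highly inbred lines
(Fayoumi and Leghorn) that are homozygous for different alleles at a large
set of fixed-difference loci, reciprocal F1 crosses (FL = Fayoumi sire x
Leghorn dam, LF = the reverse), RNA allelic read counts at the predicted
heterozygous loci, and a per-sample FPKM expression matrix with depressed
Z-linked expression.

Ground truth records, per locus, whether allelic expression is neutral,
line-of-origin biased (cis), parent-of-origin biased (imprinted) or
mitochondrial (maternal-only), so every downstream stage of the pipeline
can be validated against what was simulated.

All randomness derives from ``SimConfig.seed``; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Genome",
    "ParentalSim",
    "build_genome",
    "simulate_parental_vcfs",
    "simulate_f1_counts",
    "simulate_expression_matrix",
]

BASES = np.array(["A", "C", "G", "T"])

# minimum spacing between simulated SNPs so the 3-in-35bp cluster filter
# only ever fires on deliberately constructed fixtures, not by accident
_MIN_LOCUS_SPACING = 40


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the reciprocal-cross simulation.

    Rates are probabilities in [0, 1].  ``cis_effect`` and
    ``imprint_effect`` are the expected expression fraction of the
    preferred allele, in (0.5, 1.0].  ``depth_mean``/``depth_dispersion``
    parameterise a negative binomial per-locus RNA depth (dispersion is
    the NB size; larger = closer to Poisson).  ``reference_bias`` is an
    additive shift of the expected reference-allele read fraction in the
    un-masked ("original reference") alignment; the default 0.0098
    emulates a mean reference ratio of ~50.98% against ~50% without bias.
    ``z_shift`` is the mean log2 depression of Z-linked expression in
    males relative to autosomes; ``z_male_female_ratio`` the male/female
    expression ratio of Z-linked genes after autosomal equalisation.
    """

    seed: int = 0
    n_loci: int = 2000
    n_genes: int = 400
    n_autosomes: int = 5
    frac_z: float = 0.08
    frac_mito: float = 0.01
    n_samples_per_cross: int = 4
    tissues: tuple = ("brain", "liver")
    residual_het_rate: float = 0.0
    shared_allele_rate: float = 0.0
    frac_cis_ase: float = 0.0
    cis_effect: float = 0.7
    frac_imprinted: float = 0.0
    imprint_effect: float = 0.9
    imprint_direction: str = "paternal"
    depth_mean: float = 80.0
    depth_dispersion: float = 8.0
    dna_depth_mean: float = 60.0
    reference_bias: float = 0.0098
    error_rate: float = 0.001
    contaminant_rate: float = 0.02
    z_shift: float = -0.34
    z_male_female_ratio: float = 1.35
    fpkm_noise_sd: float = 0.5
    mean_log2_fpkm: float = 3.0
    between_gene_sd: float = 1.5
    n_female_samples: int = 0

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ConfigError("n_loci must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_samples_per_cross <= 0:
            raise ConfigError("n_samples_per_cross must be positive")
        for name in ("residual_het_rate", "shared_allele_rate", "frac_cis_ase",
                     "frac_imprinted", "error_rate", "contaminant_rate",
                     "frac_z", "frac_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.frac_cis_ase + self.frac_imprinted > 1.0:
            raise ConfigError("frac_cis_ase + frac_imprinted must not exceed 1")
        for name in ("cis_effect", "imprint_effect"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ConfigError(f"{name}={v} outside (0.5, 1.0]")
        if self.imprint_direction not in ("paternal", "maternal"):
            raise ConfigError("imprint_direction must be 'paternal' or 'maternal'")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth model parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        return cls(**d)


class Genome(NamedTuple):
    sequences: dict          # chrom -> str
    genes: pd.DataFrame      # gene_id, chrom, start0, end, length


class ParentalSim(NamedTuple):
    fayoumi: pd.DataFrame
    leghorn: pd.DataFrame
    reference: dict
    truth: pd.DataFrame
    genes: pd.DataFrame


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per simulation stage
    return np.random.default_rng([int(config.seed), stream])


def build_genome(config: SimConfig) -> Genome:
    """Lay out genes on autosomes, the Z chromosome and the mitochondrion,
    and generate a random reference sequence covering them."""
    config.validate()
    rng = _rng(config, 0)

    n_mito = max(1, int(round(config.frac_mito * config.n_genes)))
    n_z = max(1, int(round(config.frac_z * config.n_genes)))
    n_auto = config.n_genes - n_mito - n_z
    if n_auto < config.n_autosomes:
        raise ConfigError("n_genes too small for the requested chromosome layout")

    chroms = [str(i + 1) for i in range(config.n_autosomes)]
    per_auto = [n_auto // config.n_autosomes] * config.n_autosomes
    for i in range(n_auto % config.n_autosomes):
        per_auto[i] += 1
    layout = list(zip(chroms, per_auto)) + [("Z", n_z), ("MT", n_mito)]

    records = []
    sequences = {}
    gi = 0
    for chrom, n_g in layout:
        pos = 500
        for _ in range(n_g):
            length = int(rng.integers(1200, 2400))
            records.append((f"G{gi:05d}", chrom, pos, pos + length, length))
            gi += 1
            pos += length + 500
        seq_len = pos + 500
        codes = rng.integers(0, 4, size=seq_len)
        sequences[chrom] = (np.frombuffer(b"ACGT", dtype="S1")[codes]
                            .tobytes().decode())
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start0", "end", "length"])
    return Genome(sequences, genes)


def _assign_classes(config: SimConfig, genes: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene expression class: mito genes are maternal-only; a fraction
    of nuclear genes get a cis (line) effect, a fraction of autosomal genes
    a parent-of-origin effect; the rest are neutral."""
    genes = genes.copy()
    genes["class_"] = "neutral"
    genes.loc[genes.chrom == "MT", "class_"] = "mito"
    nuclear = genes.index[genes.chrom != "MT"].to_numpy()
    autosomal = genes.index[~genes.chrom.isin(["MT", "Z"])].to_numpy()

    n_imp = int(round(config.frac_imprinted * len(nuclear)))
    imp_idx = rng.choice(autosomal, size=min(n_imp, len(autosomal)), replace=False)
    genes.loc[imp_idx, "class_"] = "imprinted"

    remaining = np.setdiff1d(nuclear, imp_idx)
    n_cis = int(round(config.frac_cis_ase * len(nuclear)))
    cis_idx = rng.choice(remaining, size=min(n_cis, len(remaining)), replace=False)
    genes.loc[cis_idx, "class_"] = "cis_ase"

    genes["preferred_line"] = ""
    genes.loc[cis_idx, "preferred_line"] = rng.choice(
        ["fayoumi", "leghorn"], size=len(cis_idx))
    genes["imprint_origin"] = ""
    genes.loc[imp_idx, "imprint_origin"] = config.imprint_direction
    return genes


def _place_loci(config: SimConfig, genome: Genome,
                rng: np.random.Generator) -> pd.DataFrame:
    """Distribute SNP loci across genes, evenly spaced inside each gene."""
    genes = _assign_classes(config, genome.genes, rng)
    n_genes = len(genes)
    gene_of_locus = np.arange(config.n_loci) % n_genes
    counts = np.bincount(gene_of_locus, minlength=n_genes)

    rows = []
    for g_idx, k in enumerate(counts):
        if k == 0:
            continue
        g = genes.iloc[g_idx]
        spacing = g.length // (k + 1)
        if spacing < _MIN_LOCUS_SPACING:
            raise ConfigError(
                f"too many loci per gene (spacing {spacing} < {_MIN_LOCUS_SPACING}); "
                "increase n_genes or reduce n_loci")
        for j in range(k):
            pos = int(g.start0 + spacing * (j + 1))  # 0-based offset in gene
            rows.append((g.chrom, pos + 1, g.gene_id, g.class_,
                         g.preferred_line, g.imprint_origin))
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "gene_id", "class_",
                       "preferred_line", "imprint_origin"])
    truth = truth.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return truth


def simulate_parental_vcfs(config: SimConfig):
    """Simulate parental-line DNA variant calls over a generated reference.

    Returns a :class:`ParentalSim` with per-line call tables (chrom, pos,
    ref, alt, genotype, DP, ref_count, alt_count, GQ), the reference
    sequences, the ground-truth locus table and the gene table.

    Most loci are fixed differences between the lines; ``residual_het_rate``
    makes a parental call truly heterozygous and ``shared_allele_rate``
    gives both lines the same alternative allele (neither kind is
    informative for F1 analysis).  Sequencing error can add a spurious
    minor-allele read to a homozygous call, which is then emitted as a
    heterozygous genotype — the DP*1% reassignment rule downstream is
    expected to recover these.
    """
    config.validate()
    genome = build_genome(config)
    rng = _rng(config, 1)
    truth = _place_loci(config, genome, rng)
    L = len(truth)

    ref = np.array([genome.sequences[c][p - 1]
                    for c, p in zip(truth.chrom, truth.pos)])
    # alternative allele differs from the reference base
    offsets = rng.integers(1, 4, size=L)
    base_idx = np.searchsorted(BASES, ref)
    alt = BASES[(base_idx + offsets) % 4]

    fay_is_ref = rng.random(L) < 0.5
    shared = rng.random(L) < config.shared_allele_rate
    fay_het = rng.random(L) < config.residual_het_rate
    leg_het = rng.random(L) < config.residual_het_rate

    truth["ref"] = ref
    truth["alt"] = alt
    # at shared loci both lines carry the alternative allele
    truth["fay_allele"] = np.where(shared, alt, np.where(fay_is_ref, ref, alt))
    truth["leg_allele"] = np.where(shared, alt, np.where(fay_is_ref, alt, ref))
    truth["fay_het"] = fay_het
    truth["leg_het"] = leg_het
    truth["is_informative"] = (~shared) & (~fay_het) & (~leg_het)
    truth["locus_id"] = truth.chrom + ":" + truth.pos.astype(str)

    def line_calls(own_allele, het_mask):
        # DP floored above the depth filter so the informative set is
        # determined by genotype structure, not by stochastic depth loss
        dp = 12 + rng.negative_binomial(
            5, 5 / (5 + max(config.dna_depth_mean - 12, 1.0)), size=L)
        own_is_ref = own_allele == ref
        own_count = np.where(het_mask, rng.binomial(dp, 0.5), dp)
        err = rng.binomial(dp - np.where(het_mask, own_count, 0),
                           config.error_rate)
        other_count = np.where(het_mask, dp - own_count, err)
        own_count = np.where(het_mask, own_count, dp - err)
        ref_count = np.where(own_is_ref, own_count, other_count)
        alt_count = np.where(own_is_ref, other_count, own_count)
        genotype = np.where(
            het_mask | (other_count > 0), "het",
            np.where(own_is_ref, "hom_ref", "hom_alt"))
        return pd.DataFrame({
            "chrom": truth.chrom, "pos": truth.pos,
            "ref": ref, "alt": alt, "genotype": genotype,
            "DP": dp, "ref_count": ref_count, "alt_count": alt_count,
            "GQ": rng.integers(60, 100, size=L),
        })

    fay = line_calls(truth.fay_allele.to_numpy(), fay_het)
    leg = line_calls(truth.leg_allele.to_numpy(), leg_het)
    return ParentalSim(fay, leg, genome.sequences, truth, genome.genes)


def make_sample_sheet(config: SimConfig, include_females: bool = False) -> pd.DataFrame:
    """F1 analysis units: one row per (individual, tissue)."""
    rows = []
    for tissue in config.tissues:
        for cross in ("FL", "LF"):
            for i in range(1, config.n_samples_per_cross + 1):
                rows.append((f"{cross}{i}_{tissue}", cross, tissue, "M"))
        if include_females:
            for i in range(1, config.n_female_samples + 1):
                rows.append((f"F{i}_{tissue}", "FL", tissue, "F"))
    return pd.DataFrame(rows, columns=["sample", "cross", "tissue", "sex"])


def _expected_fayoumi_fraction(truth: pd.DataFrame, cross: str,
                               config: SimConfig) -> np.ndarray:
    """Expected fraction of reads carrying the Fayoumi allele, per locus."""
    p = np.full(len(truth), 0.5)

    cis = truth.class_.to_numpy() == "cis_ase"
    pref_fay = truth.preferred_line.to_numpy() == "fayoumi"
    p[cis & pref_fay] = config.cis_effect
    p[cis & ~pref_fay] = 1.0 - config.cis_effect

    # FL = Fayoumi sire x Leghorn dam; LF the reverse
    fay_is_father = cross == "FL"
    imp = truth.class_.to_numpy() == "imprinted"
    origin = truth.imprint_origin.to_numpy()
    toward_fay = np.where(origin == "paternal", fay_is_father, not fay_is_father)
    p[imp & toward_fay] = config.imprint_effect
    p[imp & ~toward_fay] = 1.0 - config.imprint_effect

    # mitochondria are maternally inherited: only the dam's allele is seen
    mito = truth.class_.to_numpy() == "mito"
    p[mito] = 0.0 if fay_is_father else 1.0
    return p


def simulate_f1_counts(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample allelic read counts at every simulated locus.

    Two count pairs are emitted per observation: ``ref_count``/``alt_count``
    from the N-masked alignment (no reference bias) and
    ``ref_count_original``/``alt_count_original`` from the original
    reference (expected reference fraction shifted by
    ``config.reference_bias``).  Site-level QD/FS and per-observation
    DP/GQ carry a contaminant tail so the quality filters remove a known
    nonzero subset.
    """
    config.validate()
    required = {"chrom", "pos", "class_", "fay_allele", "ref", "alt",
                "preferred_line", "imprint_origin", "gene_id"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"ground-truth table lacks columns: {sorted(missing)}")

    rng = _rng(config, 2)
    sheet = make_sample_sheet(config)
    L = len(truth)
    fay_is_ref = (truth.fay_allele == truth.ref).to_numpy()

    # site-level (INFO) annotations, shared by all samples
    qd = rng.uniform(10, 35, size=L)
    fs = rng.exponential(3.0, size=L)
    bad_qd = rng.random(L) < config.contaminant_rate
    bad_fs = rng.random(L) < config.contaminant_rate
    qd[bad_qd] = rng.uniform(0.0, 1.9, size=bad_qd.sum())
    fs[bad_fs] = rng.uniform(31.0, 60.0, size=bad_fs.sum())

    disp = config.depth_dispersion
    nb_p = disp / (disp + config.depth_mean)

    frames = []
    for row in sheet.itertuples(index=False):
        p_fay = _expected_fayoumi_fraction(truth, row.cross, config)
        e = config.error_rate
        p_fay_eff = p_fay * (1 - e) + (1 - p_fay) * e
        p_ref = np.where(fay_is_ref, p_fay_eff, 1 - p_fay_eff)

        dp = rng.negative_binomial(disp, nb_p, size=L)
        low_dp = rng.random(L) < config.contaminant_rate
        dp[low_dp] = rng.integers(0, 10, size=low_dp.sum())

        ref_masked = rng.binomial(dp, p_ref)
        p_ref_orig = np.clip(p_ref + config.reference_bias, 0.0, 1.0)
        ref_orig = rng.binomial(dp, p_ref_orig)

        gq = rng.integers(50, 100, size=L)
        bad_gq = rng.random(L) < config.contaminant_rate
        gq[bad_gq] = rng.integers(0, 30, size=bad_gq.sum())

        frames.append(pd.DataFrame({
            "sample": row.sample, "cross": row.cross, "tissue": row.tissue,
            "chrom": truth.chrom.to_numpy(), "pos": truth.pos.to_numpy(),
            "ref_count": ref_masked, "alt_count": dp - ref_masked,
            "ref_count_original": ref_orig, "alt_count_original": dp - ref_orig,
            "DP": dp, "GQ": gq, "QD": qd, "FS": fs,
        }))
    obs = pd.concat(frames, ignore_index=True)
    return obs


def simulate_expression_matrix(config: SimConfig):
    """Per-sample FPKM matrix with depressed Z-linked expression.

    Gene baselines are lognormal; Z-linked genes in male samples are
    shifted by ``z_shift`` on the log2 scale, and female Z expression sits
    a further log2(``z_male_female_ratio``) below male.  Mitochondrial
    genes get a high constant baseline (heavily expressed organelle).

    Returns ``(fpkm, gene_map, sample_sheet)`` where ``fpkm`` is a genes x
    samples DataFrame.
    """
    config.validate()
    genome = build_genome(config)
    rng = _rng(config, 3)
    genes = genome.genes
    sheet = make_sample_sheet(config, include_females=config.n_female_samples > 0)

    base = rng.normal(config.mean_log2_fpkm, config.between_gene_sd, size=len(genes))
    is_mt = genes.chrom.to_numpy() == "MT"
    is_z = (genes.chrom == "Z").to_numpy()
    is_auto = ~is_mt & ~is_z
    # centre baselines within each chromosome class so the configured
    # z_shift is the exact expected Z-minus-autosome difference rather
    # than being confounded with the random draw of gene means
    for mask in (is_auto, is_z):
        if mask.any():
            base[mask] += config.mean_log2_fpkm - base[mask].mean()
    base[is_mt] = config.mean_log2_fpkm + 4.0

    cols = {}
    for row in sheet.itertuples(index=False):
        mu = base.copy()
        shift = config.z_shift
        if row.sex == "F":
            shift -= np.log2(config.z_male_female_ratio)
        mu[is_z] += shift
        noise = rng.normal(0.0, config.fpkm_noise_sd, size=len(genes))
        cols[row.sample] = np.exp2(mu + noise)
    fpkm = pd.DataFrame(cols, index=genes.gene_id)
    gene_map = genes[["gene_id", "chrom", "length"]].copy()
    return fpkm, gene_map, sheet
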