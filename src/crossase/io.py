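"""File input/output: FASTA, VCF, BED and the pipeline's TSV tables."""

from __future__ import annotations

import os

import pandas as pd
import pysam
from pyfaidx import Fasta

__all__ = [
    "write_fasta", "read_fasta",
    "write_parental_vcf", "read_parental_vcf",
    "write_bed", "read_bed",
    "write_tsv", "read_tsv",
]

_GT_CODE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}
_GT_NAME = {v: k for k, v in _GT_CODE.items()}


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def _vcf_header(contig_lengths: dict, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("QD", 1, "Float", "Variant quality by depth")
    header.info.add("FS", 1, "Float", "Phred-scaled strand-bias Fisher p")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample)
    return header


def write_parental_vcf(calls: pd.DataFrame, contig_lengths: dict, path,
                       sample: str) -> None:
    """Write a single-sample VCF (v4.2, uncompressed) of parental calls.

    ``calls`` columns: chrom, pos, ref, alt, genotype, DP, ref_count,
    alt_count, GQ; optional QD/FS go to INFO.
    """
    header = _vcf_header(contig_lengths, sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in calls.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom, start=row.pos - 1, stop=row.pos,
                alleles=(row.ref, row.alt))
            if hasattr(row, "QD"):
                rec.info["QD"] = float(row.QD)
            if hasattr(row, "FS"):
                rec.info["FS"] = float(row.FS)
            rec.samples[sample]["GT"] = _GT_CODE[row.genotype]
            rec.samples[sample]["AD"] = (int(row.ref_count), int(row.alt_count))
            rec.samples[sample]["DP"] = int(row.DP)
            rec.samples[sample]["GQ"] = int(row.GQ)
            vcf.write(rec)


def read_parental_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF into the parental-call table layout.

    Non-SNV records are kept (downstream informative-locus selection
    excludes them); multi-allelic records keep the first ALT.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            data = rec.samples[sample]
            gt = _GT_NAME.get(tuple(data["GT"]), "het")
            ad = data.get("AD") or (None, None)
            rows.append((rec.chrom, rec.pos, rec.ref,
                         rec.alts[0] if rec.alts else ".",
                         gt, data.get("DP"), ad[0], ad[1], data.get("GQ")))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "genotype",
        "DP", "ref_count", "alt_count", "GQ"])


def write_bed(genes: pd.DataFrame, path) -> None:
    """Write gene intervals as BED (0-based half-open)."""
    genes[["chrom", "start0", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start0", "end", "gene_id"],
                     dtype={"chrom": str})
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("dtype", {"chrom": str})
    kwargs.setdefault("keep_default_na", True)
    return pd.read_csv(path, sep="\t", **kwargs)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
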