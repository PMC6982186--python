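"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 1-based and closed everywhere; BED output is
converted (start-1) at the boundary only.  The canonical interchange for
per-SNP allele depths is a plain TSV with header
``chrom pos ref alt L_ref L_alt S_ref S_alt``; VCF input (two samples
named L and S with AD fields) is supported additively via cyvcf2.
Writers accept a provenance mapping (seed, config hash, ...) that is
embedded as ``# key=value`` comment lines; readers skip comments.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .finemap import GENOTYPE_CODES, MarkerGenotypeTable
from .simdata import DEPTH_COLUMNS

log = logging.getLogger("bsamap")

__all__ = [
    "read_depth_table",
    "write_depth_table",
    "write_depth_vcf",
    "write_regions_bed",
    "read_regions_bed",
    "write_marker_table",
    "read_marker_table",
    "write_ct_table",
    "read_ct_table",
    "write_fasta",
    "read_fasta",
]

_BASES = frozenset("ACGT")


def _provenance_lines(provenance: Mapping[str, object] | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


# ---------------------------------------------------------------- depth tables


def read_depth_table(path: str | Path, fmt: str = "auto") -> pd.DataFrame:
    """Read per-SNP per-bulk allele depths from TSV or VCF.

    Malformed TSV rows and non-biallelic-SNP VCF records are skipped with
    a logged warning; the skip counts are available in ``df.attrs``
    (``n_skipped``, ``skipped_lines``).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in {".vcf", ".bcf", ".gz"} else "tsv"
    if fmt == "tsv":
        return _read_depth_tsv(path)
    if fmt == "vcf":
        return _read_depth_vcf(path)
    raise ValueError(f"unknown depth-table format {fmt!r}")


def _valid_depth_row(row: pd.Series) -> bool:
    try:
        pos = int(row["pos"])
        depths = [int(row[c]) for c in ("L_ref", "L_alt", "S_ref", "S_alt")]
    except (TypeError, ValueError):
        return False
    ref, alt = str(row["ref"]), str(row["alt"])
    return (
        pos >= 1
        and all(d >= 0 for d in depths)
        and ref in _BASES
        and alt in _BASES
        and ref != alt
    )


def _read_depth_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ok = df.apply(_valid_depth_row, axis=1) if len(df) else pd.Series(dtype=bool)
    skipped = [int(i) + 2 for i in df.index[~ok]] if len(df) else []
    for line in skipped:
        log.warning("%s: skipping malformed row at line %d", path, line)
    out = df.loc[ok, list(DEPTH_COLUMNS)].reset_index(drop=True)
    for col in ("pos", "L_ref", "L_alt", "S_ref", "S_alt"):
        out[col] = out[col].astype(np.int64)
    out.attrs["n_skipped"] = len(skipped)
    out.attrs["skipped_lines"] = skipped
    return out


def _read_depth_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for needed in ("L", "S"):
        if needed not in samples:
            raise ValueError(f"{path}: VCF must contain a sample named {needed!r}")
    i_l, i_s = samples.index("L"), samples.index("S")

    rows = []
    n_skipped = 0
    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
            or variant.REF not in _BASES
            or variant.ALT[0] not in _BASES
        ):
            n_skipped += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            n_skipped += 1
            continue
        rows.append(
            (
                variant.CHROM,
                variant.POS,
                variant.REF,
                variant.ALT[0],
                int(ad[i_l][0]),
                int(ad[i_l][1]),
                int(ad[i_s][0]),
                int(ad[i_s][1]),
            )
        )
    if n_skipped:
        log.warning("%s: skipped %d non-biallelic/AD-less records", path, n_skipped)
    df = pd.DataFrame(rows, columns=list(DEPTH_COLUMNS))
    df.attrs["n_skipped"] = n_skipped
    return df


def write_depth_table(
    records: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        records[list(DEPTH_COLUMNS)].to_csv(fh, sep="\t", index=False)
    return path


def write_depth_vcf(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a minimal two-sample VCF (samples L and S, GT:AD:DP)."""
    path = Path(path)
    lengths = records.groupby("chrom")["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL\tS\n")
        for row in records.itertuples(index=False):
            l_dp = row.L_ref + row.L_alt
            s_dp = row.S_ref + row.S_alt
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t./.:{row.L_ref},{row.L_alt}:{l_dp}\t"
                f"./.:{row.S_ref},{row.S_alt}:{s_dp}\n"
            )
    return path


# ----------------------------------------------------------------- BED regions


def write_regions_bed(
    regions: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None
) -> Path:
    """Write candidate regions as BED (0-based half-open).

    Internal 1-based closed coordinates convert by start-1; the name field
    carries the peak delta.  An empty region list yields a file with only
    the header comment.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# candidate regions: chrom, start (0-based), end, peak_delta, peak_pos\n")
        fh.write(_provenance_lines(provenance))
        for row in regions.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                f"delta={row.peak_delta:.4f}\t{row.peak_pos}\n"
            )
    return path


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read a regions BED back into internal 1-based closed coordinates."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, peak_pos = line.split("\t")
        rows.append(
            (chrom, int(start) + 1, int(end), float(name.split("=")[1]), int(peak_pos))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_delta", "peak_pos"])


# ---------------------------------------------------------------- marker table


def write_marker_table(
    table: MarkerGenotypeTable, path: str | Path, provenance: Mapping[str, object] | None = None
) -> Path:
    """Marker TSV: header cells ``name:chrom:pos``, codes A/H/B/-,
    final phenotype column."""
    path = Path(path)
    header = ["individual"] + [
        f"{r.name}:{r.chromosome}:{r.position}" for r in table.markers.itertuples(index=False)
    ] + ["phenotype"]
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("\t".join(header) + "\n")
        for ind in table.individuals:
            codes = [table.genotypes.loc[ind, m] for m in table.markers["name"]]
            fh.write("\t".join([ind, *codes, table.phenotypes.loc[ind]]) + "\n")
    return path


def read_marker_table(path: str | Path) -> MarkerGenotypeTable:
    lines = [
        line for line in Path(path).read_text().splitlines()
        if line and not line.startswith("#")
    ]
    header = lines[0].split("\t")
    if header[0] != "individual" or header[-1] != "phenotype":
        raise ValueError(f"{path}: malformed marker-table header")
    names, chroms, positions = [], [], []
    for cell in header[1:-1]:
        name, chrom, pos = cell.rsplit(":", 2)
        names.append(name)
        chroms.append(chrom)
        positions.append(int(pos))
    ids, rows, phenos = [], [], []
    for line in lines[1:]:
        fields = line.split("\t")
        ids.append(fields[0])
        rows.append(fields[1:-1])
        phenos.append(fields[-1])
    genotypes = pd.DataFrame(rows, columns=names, index=ids)
    bad = set(np.unique(genotypes.values)) - GENOTYPE_CODES if len(names) else set()
    if bad:
        raise ValueError(f"{path}: unknown genotype codes {sorted(bad)}")
    markers = pd.DataFrame({"name": names, "chromosome": chroms, "position": positions})
    return MarkerGenotypeTable(
        genotypes=genotypes,
        markers=markers,
        phenotypes=pd.Series(phenos, index=ids, name="phenotype"),
    )


# -------------------------------------------------------------------- Ct table


def write_ct_table(
    table: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        table[["sample", "tissue", "gene", "replicate", "ct"]].to_csv(
            fh, sep="\t", index=False
        )
    return path


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"sample", "gene", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ----------------------------------------------------------------------- FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
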