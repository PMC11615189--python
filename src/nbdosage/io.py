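"""File I/O for the analysis tables and read sets.

Tables are TSV with a header row and 1-based inclusive coordinates.
Genotypes travel in a minimal VCF 4.2 with a phased GT field; reads in
plain 4-line FASTQ.  Readers validate the declared dialects and raise
:class:`~nbdosage.errors.InputError` naming the offending file and record.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import pandas as pd

from .errors import InputError

_FLOAT_FMT = "%.6g"

SNP_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "refN", "altN", "refT", "altT", "genotype"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_major", "n_minor"]
ASE_SITE_COLUMNS = [
    "sample", "gene", "chrom", "pos", "ref_count", "alt_count",
    "other_count", "raw_depth", "hap_a_allele",
]
GENE_COUNT_COLUMNS = ["sample", "gene", "A", "B"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise InputError(f"missing input file: {path}")
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"{path}: cannot parse TSV ({exc})")


def read_snp_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, SNP_COLUMNS, path)
    for col in ("refN", "altN", "refT", "altT"):
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0])
            raise InputError(f"{path}: negative depth in column {col}, line {row + 2}")
    if (df["pos"] < 1).any():
        raise InputError(f"{path}: positions must be 1-based (>= 1)")
    return df


def read_segments(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, SEGMENT_COLUMNS, path)
    if (df["start"] > df["end"]).any():
        row = int(df.index[df["start"] > df["end"]][0])
        raise InputError(f"{path}: start > end at line {row + 2}")
    if (df["n_major"] < df["n_minor"]).any() or (df["n_minor"] < 0).any():
        raise InputError(f"{path}: require n_major >= n_minor >= 0")
    dup = df.duplicated(subset=["sample", "chrom", "start"])
    if dup.any():
        raise InputError(f"{path}: duplicate segment key at line {int(df.index[dup][0]) + 2}")
    return df


def read_ase_sites(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ASE_SITE_COLUMNS, path)
    bad = df["ref_count"] + df["alt_count"] > df["raw_depth"]
    if bad.any():
        raise InputError(
            f"{path}: ref + alt exceeds raw_depth at line {int(df.index[bad][0]) + 2}"
        )
    return df


def read_gene_counts(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, GENE_COUNT_COLUMNS, path)
    return df


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["sample", "purity", "ploidy"], path)
    return df


def read_matrix(path) -> pd.DataFrame:
    """Genes x samples matrix with gene ids in the first column."""
    df = _read_tsv(path)
    return df.set_index(df.columns[0])


def write_vcf_min(records: pd.DataFrame, path, require_phased: bool = True) -> None:
    """Write a minimal multi-sample VCF 4.2 of phased genotypes.

    ``records`` has one row per sample x site with columns
    ``sample, chrom, pos, ref, alt, genotype``.
    """
    samples = list(pd.unique(records["sample"]))
    pivot = records.pivot_table(
        index=["chrom", "pos", "ref", "alt"],
        columns="sample",
        values="genotype",
        aggfunc="first",
    ).reindex(columns=samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for (chrom, pos, ref, alt), row in pivot.iterrows():
            gts = [row[s] if isinstance(row[s], str) else "./." for s in samples]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf_min(path, require_phased: bool = True) -> pd.DataFrame:
    """Read a minimal VCF into a long sample x site genotype table.

    Heterozygous genotypes must be phased ('0|1'/'1|0') when
    ``require_phased`` is set; an unphased het GT raises ``InputError``.
    """
    rows = []
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if not samples:
                raise InputError(f"{path}: missing #CHROM header before line {lineno}")
            chrom, pos, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise InputError(f"{path}: no GT field at line {lineno}")
            for s, val in zip(samples, fields[9:]):
                gt = val.split(":")[gt_idx]
                if require_phased and gt in ("0/1", "1/0"):
                    raise InputError(
                        f"{path}: unphased heterozygous GT {gt!r} for sample {s} at line {lineno}"
                    )
                rows.append(
                    {"sample": s, "chrom": chrom, "pos": int(pos), "ref": ref,
                     "alt": alt, "genotype": gt}
                )
    return pd.DataFrame(rows)


def write_fastq(seqs: Iterable[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> Iterator[str]:
    """Yield sequences from a 4-line FASTQ; tolerates CRLF line endings.

    Raises ``InputError`` with the record index on malformed records.
    """
    with open(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            header, seq, plus, qual = (
                s.rstrip("\r\n") for s in (header, seq, plus, qual)
            )
            if not header.startswith("@"):
                raise InputError(f"{path}: record {record}: header must start with '@'")
            if not plus.startswith("+"):
                raise InputError(f"{path}: record {record}: missing '+' separator")
            if len(seq) != len(qual):
                raise InputError(
                    f"{path}: record {record}: sequence/quality length mismatch"
                )
            yield seq
            record += 1
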