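"""Readers and writers for the light-weight text formats the pipeline exchanges.

All coordinates are 1-based inclusive at every I/O boundary.  The VCF support
is a deliberately minimal dialect: only CHROM/POS/REF/ALT/QUAL and per-sample
allele depths (AD) are consumed by the pipeline, header lines other than
``#CHROM`` are ignored, and malformed body lines are reported with their line
number.  FASTA goes through Biopython; tabular data through pandas.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "VariantRecord",
    "FormatError",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_genotype_table",
    "write_genotype_table",
    "MISSING_TOKENS",
    "GENOTYPE_CODES",
]

#: tokens accepted for a missing genotype / phenotype cell
MISSING_TOKENS = frozenset({"NA", ".", "-", ""})

#: the three observable F2 / panel genotype codes; B is the im-parent allele
GENOTYPE_CODES = frozenset({"AA", "AB", "BB"})

# IUPAC nucleotide alphabet (DNA, with ambiguity codes)
_IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """A file violated the documented schema for its format."""


class VcfParseError(FormatError):
    """Malformed VCF content; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One variant call: SNP iff ``len(ref) == len(alt)``, else indel.

    ``depths`` maps sample name to an ``(ref_depth, alt_depth)`` pair when the
    source VCF carried AD fields (the bulk VCFs written by the simulator do).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depths: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.qual < 0:
            raise ValueError(f"negative QUAL {self.qual} at {self.chrom}:{self.pos}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Absolute length difference between alleles (0 for SNPs)."""
        return abs(len(self.ref) - len(self.alt))


_VCF_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a minimal VCF into records, preserving file order.

    Only the eight mandatory columns plus optional FORMAT/sample columns with
    an AD (``ref,alt`` depths) field are interpreted.  Raises
    :class:`VcfParseError` with a line number for malformed body lines.
    """
    records: list[VariantRecord] = []
    sample_names: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM") or line.startswith("#"):
                fields = line.lstrip("#").split("\t")
                if len(fields) > 9:
                    sample_names = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) < len(_VCF_COLUMNS):
                raise VcfParseError(
                    f"expected >= {len(_VCF_COLUMNS)} tab-separated columns, got {len(fields)}",
                    lineno,
                )
            chrom, pos_s, _id, ref, alt, qual_s = fields[:6]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(f"non-integer POS {pos_s!r}", lineno) from None
            try:
                qual = 0.0 if qual_s == "." else float(qual_s)
            except ValueError:
                raise VcfParseError(f"non-numeric QUAL {qual_s!r}", lineno) from None
            depths = None
            if len(fields) > 9:
                fmt_keys = fields[8].split(":")
                if "AD" in fmt_keys:
                    ad_idx = fmt_keys.index("AD")
                    depths = {}
                    names = sample_names or [f"sample{i}" for i in range(len(fields) - 9)]
                    for name, sample in zip(names, fields[9:]):
                        parts = sample.split(":")
                        try:
                            ref_d, alt_d = (int(x) for x in parts[ad_idx].split(",")[:2])
                        except (ValueError, IndexError):
                            raise VcfParseError(
                                f"malformed AD field {sample!r}", lineno
                            ) from None
                        depths[name] = (ref_d, alt_d)
            try:
                records.append(
                    VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, depths=depths)
                )
            except ValueError as exc:
                raise VcfParseError(str(exc), lineno) from None
    return records


def write_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as minimal VCF v4.2; AD depths become per-sample columns."""
    records = list(records)
    sample_names: list[str] = []
    for rec in records:
        if rec.depths:
            for name in rec.depths:
                if name not in sample_names:
                    sample_names.append(name)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        header = list(_VCF_COLUMNS)
        if sample_names:
            header += ["FORMAT", *sample_names]
        fh.write("#" + "\t".join(header) + "\n")
        for rec in records:
            row = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, f"{rec.qual:g}", "PASS", "."]
            if sample_names:
                row.append("AD")
                for name in sample_names:
                    if rec.depths and name in rec.depths:
                        ref_d, alt_d = rec.depths[name]
                        row.append(f"{ref_d},{alt_d}")
                    else:
                        row.append(".")
            fh.write("\t".join(row) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}``, uppercasing sequences.

    Rejects duplicate record names and non-IUPAC nucleotide characters.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write ``{name: sequence}`` as wrapped FASTA (uppercased)."""
    records = [SeqRecord(Seq(s.upper()), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | None = None,
    index_col: str | None = None,
) -> pd.DataFrame:
    """Read a TSV with a header row, optionally validating column dtypes.

    ``schema`` maps required column names to python types (int, float, str);
    a column that is absent or fails conversion raises :class:`FormatError`
    naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if schema:
        for col, typ in schema.items():
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
            if typ is str:
                continue
            cleaned = df[col].where(~df[col].isin(MISSING_TOKENS), other=None)
            try:
                df[col] = cleaned.astype(float if typ is float else "Int64" if typ is int else typ)
            except (ValueError, TypeError) as exc:
                raise FormatError(f"column {col!r} is not of type {typ.__name__}: {exc}") from None
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_genotype_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    """Read a genotype matrix (rows = individuals/accessions, cols = markers).

    Cells must be in {AA, AB, BB} or a missing token; missing becomes ``pd.NA``.
    Marker (column) names must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if index_col is None:
        index_col = df.columns[0]
    df = df.set_index(index_col)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"duplicate marker columns: {dupes}")
    df = df.where(~df.isin(MISSING_TOKENS), other=pd.NA)
    bad = set(df.stack().unique()) - GENOTYPE_CODES
    if bad:
        raise FormatError(f"invalid genotype codes: {sorted(bad)}")
    return df


def write_genotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df.fillna("NA").to_csv(path, sep="\t", index=True, index_label=df.index.name or "id")
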