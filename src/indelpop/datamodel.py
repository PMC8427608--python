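"""Domain types and table I/O for indel genotype, phenotype, panel and qPCR data.

Record tables (genotypes, phenotypes, CT values, panel counts) are carried as
:class:`pandas.DataFrame` with validated columns; the scalar domain objects
(:class:`IndelLocus`, :class:`GenotypePanel`) are frozen dataclasses.

All delimited files are UTF-8 text with a header row.  The default delimiter
is tab; ``dialect="csv"`` switches to comma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("indelpop")

#: Valid genotype calls at a biallelic insertion/deletion locus.
GENOTYPES = ("DD", "ID", "II")
#: Sentinel values accepted for a missing genotype call.
MISSING_TOKENS = ("", "NA", "na", "NN", "./.", "missing")

GENOTYPE_COLUMNS = ["individual_id", "population", "genotype"]
PANEL_COLUMNS = ["population", "n_DD", "n_ID", "n_II"]
CT_COLUMNS = ["sample_id", "group", "tissue", "ct_target", "ct_reference"]
PHENOTYPE_ID_COLUMNS = ["individual_id", "sex", "hatch", "family", "slaughter_weight"]


class ValidationError(ValueError):
    """Raised when an input table violates the documented column contracts."""


@dataclass(frozen=True)
class IndelLocus:
    """Identity and amplicon conventions of one biallelic indel.

    Coordinates are 1-based inclusive on the reference assembly; ``start`` and
    ``end`` delimit the inserted/deleted segment itself, so the span equals the
    indel length.  The I allele carries the segment, the D allele lacks it.

    Parameters
    ----------
    locus_id : str
        Free-form marker name.
    chrom : str
        Chromosome name as used by the assembly.
    start, end : int
        1-based inclusive coordinates of the indel segment.
    indel_len : int
        Length of the segment in bp; must equal ``end - start + 1``.
    amplicon_len_I, amplicon_len_D : int
        Diagnostic PCR product sizes for the two alleles; their difference
        must equal ``indel_len``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    indel_len: int
    amplicon_len_I: int
    amplicon_len_D: int
    allele_labels: tuple[str, str] = ("I", "D")

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.indel_len:
            raise ValidationError(
                f"locus span {self.chrom}:{self.start}-{self.end} is "
                f"{self.end - self.start + 1} bp, not indel_len={self.indel_len}"
            )
        if self.amplicon_len_I - self.amplicon_len_D != self.indel_len:
            raise ValidationError(
                "amplicon size difference "
                f"{self.amplicon_len_I}-{self.amplicon_len_D} != {self.indel_len}"
            )


#: The 104-bp indel in the 5'UTR of chicken ADPRHL1 (galGal reference,
#: chromosome 1).  PCR of the region yields a 218-bp product from the
#: insertion allele and 114 bp from the deletion allele.
ADPRHL1_INDEL = IndelLocus(
    locus_id="ADPRHL1_104bp",
    chrom="1",
    start=138752529,
    end=138752632,
    indel_len=104,
    amplicon_len_I=218,
    amplicon_len_D=114,
)


@dataclass(frozen=True)
class GenotypePanel:
    """Genotype counts for one population at one biallelic indel locus."""

    population: str
    n_DD: int
    n_ID: int
    n_II: int

    def __post_init__(self) -> None:
        for field in ("n_DD", "n_ID", "n_II"):
            if getattr(self, field) < 0:
                raise ValidationError(f"{field} must be >= 0")

    @property
    def n(self) -> int:
        """Number of genotyped individuals."""
        return self.n_DD + self.n_ID + self.n_II

    def as_counts(self) -> tuple[int, int, int]:
        return (self.n_DD, self.n_ID, self.n_II)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect in ("tsv", "\t", "tab"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns {missing}")


def read_genotypes(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genotype call table.

    Columns: ``individual_id``, ``population``, ``genotype`` with genotype in
    {II, ID, DD} or a missing-value token (left as :data:`pandas.NA`).

    Raises
    ------
    ValidationError
        On an unrecognised genotype string (the offending rows are named) or
        a duplicated ``individual_id``.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    _require_columns(df, GENOTYPE_COLUMNS, "genotype")
    df = df[GENOTYPE_COLUMNS].copy()
    df["genotype"] = df["genotype"].str.strip()
    is_missing = df["genotype"].isin(MISSING_TOKENS)
    bad = ~(df["genotype"].isin(GENOTYPES) | is_missing)
    if bad.any():
        rows = df.index[bad].tolist()
        values = df.loc[bad, "genotype"].unique().tolist()
        raise ValidationError(
            f"invalid genotype value(s) {values} in rows {rows} of {path}"
        )
    df.loc[is_missing, "genotype"] = pd.NA
    dup = df["individual_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate individual_id(s) {df.loc[dup, 'individual_id'].tolist()} in {path}"
        )
    logger.info("read %d genotype records from %s", len(df), path)
    return df


def write_genotypes(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    _require_columns(df, GENOTYPE_COLUMNS, "genotype")
    df[GENOTYPE_COLUMNS].to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def read_panels(path: str | Path, dialect: str = "tsv") -> list[GenotypePanel]:
    """Read per-population genotype count summaries into panels."""
    df = pd.read_csv(path, sep=_sep(dialect))
    _require_columns(df, PANEL_COLUMNS, "panel")
    panels = [
        GenotypePanel(str(r.population), int(r.n_DD), int(r.n_ID), int(r.n_II))
        for r in df.itertuples()
    ]
    logger.info("read %d genotype panels from %s", len(panels), path)
    return panels


def write_panels(panels: Iterable[GenotypePanel], path: str | Path,
                 dialect: str = "tsv") -> None:
    df = pd.DataFrame(
        [(p.population, p.n, p.n_DD, p.n_ID, p.n_II) for p in panels],
        columns=["population", "n", "n_DD", "n_ID", "n_II"],
    )
    df.to_csv(path, sep=_sep(dialect), index=False)


def read_phenotypes(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a wide phenotype table.

    Fixed columns ``individual_id, sex, hatch, family, slaughter_weight``;
    every further column is a trait, named by its trait code.  Missing trait
    values are NA and are dropped listwise per trait at analysis time, never
    here.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    _require_columns(df, PHENOTYPE_ID_COLUMNS, "phenotype")
    dup = df["individual_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate individual_id(s) in phenotype table {path}"
        )
    for col in ("sex", "hatch", "family"):
        df[col] = df[col].astype(str)
    logger.info("read %d phenotype records from %s", len(df), path)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    df.to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def read_ct(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a qPCR CT table (sample_id, group, tissue, ct_target, ct_reference)."""
    df = pd.read_csv(path, sep=_sep(dialect))
    _require_columns(df, CT_COLUMNS, "CT")
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(df[col], errors="coerce")
        finite = vals.notna() & (vals > 0)
        if not finite.all():
            n_bad = int((~finite).sum())
            logger.warning("%d rows with missing/non-positive %s in %s", n_bad, col, path)
        df[col] = vals
    logger.info("read %d CT records from %s", len(df), path)
    return df


def write_ct(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    _require_columns(df, CT_COLUMNS, "CT")
    df[CT_COLUMNS].to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def counts_from_records(records: pd.DataFrame, population: str) -> GenotypePanel:
    """Aggregate genotype records of one population into a count panel.

    Missing genotypes are excluded from the counts (and logged); at least one
    non-missing record is required.
    """
    _require_columns(records, GENOTYPE_COLUMNS, "genotype")
    sub = records[records["population"] == population]
    n_missing = int(sub["genotype"].isna().sum())
    called = sub.dropna(subset=["genotype"])
    if called.empty:
        raise ValidationError(
            f"no non-missing genotype records for population {population!r}"
        )
    if n_missing:
        logger.info("population %s: %d missing genotype(s) excluded", population, n_missing)
    counts = called["genotype"].value_counts()
    return GenotypePanel(
        population=population,
        n_DD=int(counts.get("DD", 0)),
        n_ID=int(counts.get("ID", 0)),
        n_II=int(counts.get("II", 0)),
    )


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

_VCF_GT = {True: {"II": "0/0", "ID": "0/1", "DD": "1/1"},
           False: {"DD": "0/0", "ID": "0/1", "II": "1/1"}}


def export_vcf(locus: IndelLocus, records: pd.DataFrame, path: str | Path,
               ref_has_insertion: bool = True, contig_length: int | None = None) -> None:
    """Write the locus and genotype calls as a single-record VCF 4.2 file.

    The record is anchored one base before the indel segment, following VCF
    convention for deletions/insertions.  With ``ref_has_insertion`` the
    reference allele carries the segment (REF = anchor + segment, ALT =
    anchor) and II is encoded 0/0; otherwise the encoding is flipped.  The
    segment sequence itself is unknown here, so it is written as ``N`` bases —
    allele identity is carried by length, which is what the diagnostic assay
    measures.
    """
    _require_columns(records, GENOTYPE_COLUMNS, "genotype")
    anchor = "N"
    segment = "N" * locus.indel_len
    if ref_has_insertion:
        ref, alt = anchor + segment, anchor
    else:
        ref, alt = anchor, anchor + segment
    pos = locus.start - 1
    gt_map = _VCF_GT[ref_has_insertion]
    samples = records["individual_id"].tolist()
    calls = [
        gt_map[g] if isinstance(g, str) else "./."
        for g in records["genotype"].tolist()
    ]
    length = contig_length if contig_length is not None else locus.end + 10_000
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={locus.chrom},length={length}>",
        f'##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Indel length">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        "\t".join(
            [locus.chrom, str(pos), locus.locus_id, ref, alt, ".", "PASS",
             f"SVLEN={-locus.indel_len if ref_has_insertion else locus.indel_len}",
             "GT"] + calls
        ),
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    logger.info("wrote VCF with %d samples to %s", len(samples), path)


def genotypes_from_vcf(path: str | Path, population: str = "unknown",
                       ref_has_insertion: bool = True) -> pd.DataFrame:
    """Read back a single-record indel VCF into a genotype table."""
    inverse = {v: k for k, v in _VCF_GT[ref_has_insertion].items()}
    inverse["1/0"] = "ID"
    header: list[str] = []
    record: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#CHROM"):
            header = line.lstrip("#").split("\t")
        elif not line.startswith("#") and line.strip():
            record = line.split("\t")
    if not header or not record:
        raise ValidationError(f"no VCF record found in {path}")
    samples = header[9:]
    calls = record[9:]
    genos = [inverse.get(c.split(":")[0], pd.NA) for c in calls]
    return pd.DataFrame(
        {"individual_id": samples, "population": population, "genotype": genos}
    )
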