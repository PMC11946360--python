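"""Parsing, curation and classification of a phenotype-associated-variant catalogue.

The catalogue is an OMIA-style delimited table in which each row describes one
published trait- or disease-associated variant: gene symbol, a genomic
("g.<pos>") or mitochondrial ("m.<pos>") location, reference-build tag,
ref/alt alleles, a location class (CDS / intron / UTR / promoter), an
inheritance mode, the publication year and a free-text phene label.

Raw catalogue entries are frequently incomplete or inconsistent — that is the
reason curation exists. Curation applies four criteria:

1. the location string is a plain genomic or mitochondrial coordinate
   ("g.<digits>" or "m.<digits>");
2. the record is annotated on the accepted reference build;
3. the gene symbol is present and well-formed;
4. the variant is at most ``max_size`` (default 20) base pairs.

Records failing 1–3 are excluded in stage 1 (annotation problems); records
failing 4 in stage 2 (size), mirroring the two-pass narrative of the original
screen. Retained records become :class:`CatalogueVariant` objects with a
category assignment used throughout the depth-QC stage:

* ``CDS_1BP`` — single-nucleotide variants inside coding sequence;
* ``NONCODING_1BP`` — single-nucleotide variants in introns, UTRs or
  promoters (analysed as one off-target group);
* ``LARGER`` — variants of 2–20 bp regardless of location.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Category",
    "Inheritance",
    "Reason",
    "RawCatalogueRecord",
    "CatalogueVariant",
    "CurationReport",
    "CatalogueDialect",
    "parse_catalogue",
    "curate",
    "classify",
    "split_by_year",
    "YearSplit",
    "write_curated",
    "read_curated",
]


class Category(str, Enum):
    CDS_1BP = "CDS_1BP"
    NONCODING_1BP = "NONCODING_1BP"
    LARGER = "LARGER"


class Inheritance(str, Enum):
    AUTOSOMAL_RECESSIVE = "AUTOSOMAL_RECESSIVE"
    AUTOSOMAL_DOMINANT = "AUTOSOMAL_DOMINANT"
    X_LINKED = "X_LINKED"
    MITOCHONDRIAL = "MITOCHONDRIAL"
    COMPLEX = "COMPLEX"
    UNKNOWN = "UNKNOWN"


class Reason(str, Enum):
    """Primary exclusion reason for a record that failed curation."""

    NO_GENOMIC_LOCATION = "NO_GENOMIC_LOCATION"  # criterion 1
    WRONG_BUILD = "WRONG_BUILD"                  # criterion 2
    BAD_GENE_SYMBOL = "BAD_GENE_SYMBOL"          # criterion 3
    BAD_ALLELES = "BAD_ALLELES"                  # alleles unusable (annotation problem)
    SIZE_GT_MAX = "SIZE_GT_MAX"                  # criterion 4


#: reasons counted as stage-1 (annotation) exclusions; everything else is stage 2
_STAGE1_REASONS = {
    Reason.NO_GENOMIC_LOCATION,
    Reason.WRONG_BUILD,
    Reason.BAD_GENE_SYMBOL,
    Reason.BAD_ALLELES,
}

_LOCATION_RE = re.compile(r"^(g|m)\.(\d+)$")
_GENE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.-]*$")
_ALLELE_RE = re.compile(r"^[ACGTacgt]*$")


@dataclass
class RawCatalogueRecord:
    """One unvalidated catalogue row; any field other than record_id may be malformed."""

    record_id: str
    gene_symbol: str | None
    location_string: str
    build_tag: str
    ref_allele: str
    alt_allele: str
    chromosome: str | None
    publication_year: int | None
    location_class_raw: str
    inheritance_raw: str
    phene: str
    is_disease: bool = True


@dataclass(frozen=True)
class CatalogueVariant:
    """A curated panel entry with validated coordinates and a category assignment."""

    record_id: str
    gene_symbol: str
    chromosome: str
    position: int  # 1-based; for pure insertions, the right-flank base
    ref_allele: str
    alt_allele: str
    size_bp: int
    category: Category
    inheritance: Inheritance
    publication_year: int | None
    phene: str
    is_disease: bool


@dataclass
class CurationReport:
    n_input: int
    n_excluded_stage1: int
    n_excluded_stage2: int
    n_retained: int
    exclusions: list[tuple[str, Reason]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_excluded_stage1 + self.n_excluded_stage2 + self.n_retained, (
            "curation counts do not reconcile"
        )

    def to_json(self) -> str:
        payload = {
            "n_input": self.n_input,
            "n_excluded_stage1": self.n_excluded_stage1,
            "n_excluded_stage2": self.n_excluded_stage2,
            "n_retained": self.n_retained,
            "exclusions": [
                {"record_id": rid, "reason": reason.value} for rid, reason in self.exclusions
            ],
        }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        lines = [
            f"Catalogue curation: {self.n_input} input records",
            f"  stage 1 (annotation) exclusions: {self.n_excluded_stage1}",
            f"  stage 2 (size/location) exclusions: {self.n_excluded_stage2}",
            f"  retained: {self.n_retained}",
        ]
        for rid, reason in self.exclusions:
            lines.append(f"    excluded {rid}: {reason.value}")
        return "\n".join(lines)


@dataclass
class CatalogueDialect:
    """Column mapping and delimiter for a catalogue file."""

    delimiter: str = "\t"
    record_id: str = "record_id"
    gene: str = "gene"
    location: str = "location"
    build: str = "build"
    chromosome: str = "chrom"
    ref: str = "ref"
    alt: str = "alt"
    location_class: str = "location_class"
    inheritance: str = "inheritance"
    year: str = "year"
    phene: str = "phene"
    is_disease: str = "is_disease"

    #: columns that must be present in the header
    def mandatory_columns(self) -> list[str]:
        return [
            self.record_id, self.gene, self.location, self.build, self.chromosome,
            self.ref, self.alt, self.location_class, self.inheritance, self.year,
            self.phene, self.is_disease,
        ]


DEFAULT_DIALECT = CatalogueDialect()

_TRUTHY = {"1", "true", "yes", "y", "disease"}


def _parse_bool(value: object, default: bool = True) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("", "nan", "none"):
        return default
    return s in _TRUTHY


def _parse_year(value: object) -> int | None:
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none"):
        return None
    try:
        return int(float(s))
    except ValueError:
        return None


def parse_catalogue(
    path: str | Path,
    dialect: CatalogueDialect = DEFAULT_DIALECT,
) -> list[RawCatalogueRecord]:
    """Read a raw catalogue table into records, performing no validation.

    Row order is preserved. Blank fields become ``None``/empty strings; all
    validation is deferred to :func:`curate`.

    Raises
    ------
    ConfigurationError
        If a mandatory column is missing from the header (the message names it).
    OSError
        If the file cannot be read.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for col in dialect.mandatory_columns():
        if col not in df.columns:
            raise ConfigurationError(f"catalogue file {path} is missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        gene = row[dialect.gene].strip()
        chrom = row[dialect.chromosome].strip()
        records.append(
            RawCatalogueRecord(
                record_id=row[dialect.record_id].strip(),
                gene_symbol=gene or None,
                location_string=row[dialect.location].strip(),
                build_tag=row[dialect.build].strip(),
                ref_allele=row[dialect.ref].strip(),
                alt_allele=row[dialect.alt].strip(),
                chromosome=chrom or None,
                publication_year=_parse_year(row[dialect.year]),
                location_class_raw=row[dialect.location_class].strip(),
                inheritance_raw=row[dialect.inheritance].strip(),
                phene=row[dialect.phene].strip(),
                is_disease=_parse_bool(row[dialect.is_disease]),
            )
        )
    return records


def classify(size_bp: int, location_class_raw: str) -> Category:
    """Assign the depth-analysis category from variant size and location class.

    Size-1 variants split into coding (``CDS_1BP``) and non-coding
    (``NONCODING_1BP`` — intron, UTR and promoter fold together); anything
    larger than 1 bp is ``LARGER`` regardless of location.
    """
    if not 1 <= size_bp <= 20:
        raise ValidationError(f"size_bp must be in [1, 20], got {size_bp}")
    if size_bp > 1:
        return Category.LARGER
    if location_class_raw.strip().upper() == "CDS":
        return Category.CDS_1BP
    return Category.NONCODING_1BP


_INHERITANCE_MAP = {
    "autosomal recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "ar": Inheritance.AUTOSOMAL_RECESSIVE,
    "recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "autosomal dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "ad": Inheritance.AUTOSOMAL_DOMINANT,
    "dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "x-linked": Inheritance.X_LINKED,
    "x linked": Inheritance.X_LINKED,
    "x-linked recessive": Inheritance.X_LINKED,
    "mitochondrial": Inheritance.MITOCHONDRIAL,
    "complex": Inheritance.COMPLEX,
}


def _parse_inheritance(raw: str) -> Inheritance:
    if raw.strip() and raw.strip().upper() in Inheritance.__members__:
        return Inheritance[raw.strip().upper()]
    return _INHERITANCE_MAP.get(raw.strip().lower(), Inheritance.UNKNOWN)


def curate(
    records: Iterable[RawCatalogueRecord],
    accepted_build: str = "CanFam3.1",
    max_size: int = 20,
) -> tuple[list[CatalogueVariant], CurationReport]:
    """Apply the four curation criteria and convert survivors to panel entries.

    A record is retained iff its location is a plain "g.<digits>"/"m.<digits>"
    coordinate, its build tag equals ``accepted_build``, its gene symbol is a
    well-formed token, its alleles are parseable ACGT strings (not both
    empty), and its size is at most ``max_size`` bp. Malformed records are
    excluded with a single primary reason code — never a fatal error.

    Mitochondrial records ("m." locations) are placed on chromosome "MT"
    regardless of the raw chromosome column; "g." records require a
    chromosome annotation.
    """
    if not accepted_build:
        raise ConfigurationError("accepted_build must be non-empty")
    variants: list[CatalogueVariant] = []
    exclusions: list[tuple[str, Reason]] = []
    n_input = 0
    for rec in records:
        n_input += 1
        reason = _failure_reason(rec, accepted_build, max_size)
        if reason is not None:
            exclusions.append((rec.record_id, reason))
            continue
        m = _LOCATION_RE.match(rec.location_string)
        assert m is not None
        is_mito = m.group(1) == "m"
        chromosome = "MT" if is_mito else str(rec.chromosome)
        ref = rec.ref_allele.upper()
        alt = rec.alt_allele.upper()
        size_bp = max(len(ref), len(alt))
        variants.append(
            CatalogueVariant(
                record_id=rec.record_id,
                gene_symbol=str(rec.gene_symbol),
                chromosome=chromosome,
                position=int(m.group(2)),
                ref_allele=ref,
                alt_allele=alt,
                size_bp=size_bp,
                category=classify(size_bp, rec.location_class_raw),
                inheritance=_parse_inheritance(rec.inheritance_raw),
                publication_year=rec.publication_year,
                phene=rec.phene,
                is_disease=rec.is_disease,
            )
        )
    n_stage1 = sum(1 for _, r in exclusions if r in _STAGE1_REASONS)
    report = CurationReport(
        n_input=n_input,
        n_excluded_stage1=n_stage1,
        n_excluded_stage2=len(exclusions) - n_stage1,
        n_retained=len(variants),
        exclusions=exclusions,
    )
    return variants, report


def _failure_reason(
    rec: RawCatalogueRecord, accepted_build: str, max_size: int
) -> Reason | None:
    """First failing curation criterion, or None if the record is retained."""
    m = _LOCATION_RE.match(rec.location_string)
    if m is None:
        return Reason.NO_GENOMIC_LOCATION
    if m.group(1) == "g" and not rec.chromosome:
        return Reason.NO_GENOMIC_LOCATION
    if rec.build_tag != accepted_build:
        return Reason.WRONG_BUILD
    if rec.gene_symbol is None or not _GENE_RE.match(rec.gene_symbol):
        return Reason.BAD_GENE_SYMBOL
    ref, alt = rec.ref_allele, rec.alt_allele
    if not (_ALLELE_RE.match(ref) and _ALLELE_RE.match(alt)) or (not ref and not alt):
        return Reason.BAD_ALLELES
    if ref.upper() == alt.upper():
        return Reason.BAD_ALLELES
    if max(len(ref), len(alt)) > max_size:
        return Reason.SIZE_GT_MAX
    return None


@dataclass
class YearSplit:
    """Partition of a curated panel around the capture design's publication year."""

    pre_design: list[CatalogueVariant]
    post_design: list[CatalogueVariant]
    missing_year: list[CatalogueVariant]


def split_by_year(
    variants: Sequence[CatalogueVariant], design_year: int = 2014
) -> YearSplit:
    """Split the panel into variants published up to vs after the design year.

    Variants published strictly after ``design_year`` go to ``post_design``;
    a record with no publication year is excluded from both lists and
    reported in ``missing_year``.
    """
    pre, post, missing = [], [], []
    for v in variants:
        if v.publication_year is None:
            missing.append(v)
        elif v.publication_year > design_year:
            post.append(v)
        else:
            pre.append(v)
    return YearSplit(pre_design=pre, post_design=post, missing_year=missing)


# ---------------------------------------------------------------------------
# curated-catalogue round trip (TSV)

_CURATED_COLUMNS = [
    "record_id", "gene_symbol", "chromosome", "position", "ref_allele",
    "alt_allele", "size_bp", "category", "inheritance", "publication_year",
    "phene", "is_disease",
]


def write_curated(variants: Sequence[CatalogueVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        d = asdict(v)
        d["category"] = v.category.value
        d["inheritance"] = v.inheritance.value
        rows.append(d)
    df = pd.DataFrame(rows, columns=_CURATED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_curated(path: str | Path) -> list[CatalogueVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            CatalogueVariant(
                record_id=row["record_id"],
                gene_symbol=row["gene_symbol"],
                chromosome=row["chromosome"],
                position=int(row["position"]),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                size_bp=int(row["size_bp"]),
                category=Category(row["category"]),
                inheritance=Inheritance(row["inheritance"]),
                publication_year=_parse_year(row["publication_year"]),
                phene=row["phene"],
                is_disease=_parse_bool(row["is_disease"]),
            )
        )
    return out
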