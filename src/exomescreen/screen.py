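"""Scan a multi-sample VCF for panel variants and interpret zygosity.

Matching catalogue descriptions to caller output requires a shared allele
representation: both sides are reduced to a minimal form by trimming the
shared suffix and then the shared prefix of ref/alt (reference-sequence-free;
no realignment). After trimming, a pure insertion's coordinate is the base
immediately right of the insertion point and its ref is empty; deletions keep
the deleted bases as ref with an empty alt. Multi-allelic records are split
into one candidate per alternate allele before matching.

Zygosity interpretation is inheritance-aware: autosomal dosages map to
wild-type / carrier / homozygous-alternate; any alternate allele on the male
X is hemizygous; mitochondrial calls are present/absent (homoplasmic
assumption). Sites that failed the caller's hard quality filter, or whose
genotype is uncalled, are not assessable. A panel locus absent from the VCF
is reported wild-type only when its span qualified at the reporting depth
threshold — variant callers emit variant sites only, so absence without
coverage is no evidence of the reference genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .alleles import NormalizedAllele, normalize
from .catalogue import CatalogueVariant, Inheritance
from .depthqc import QualificationMatrix
from .errors import ConfigurationError, ValidationError

__all__ = [
    "Status",
    "NormalizedAllele",
    "GenotypeCall",
    "DogSummary",
    "normalize",
    "interpret",
    "scan_vcf",
    "detection_matrix",
    "per_dog_summary",
    "read_metadata",
]

logger = logging.getLogger(__name__)


class Status(str, Enum):
    WILDTYPE = "WILDTYPE"
    CARRIER = "CARRIER"
    HOMOZYGOUS_ALT = "HOMOZYGOUS_ALT"
    HEMIZYGOUS_ALT = "HEMIZYGOUS_ALT"
    MITO_PRESENT = "MITO_PRESENT"
    NOT_ASSESSABLE = "NOT_ASSESSABLE"


@dataclass(frozen=True)
class GenotypeCall:
    """Matched alternate-allele dosage and interpreted status for one sample x variant."""

    sample_id: str
    record_id: str
    alt_count: int
    status: Status
    filter_pass: bool


def interpret(
    alt_count: int,
    inheritance: Inheritance,
    sex: str,
    chromosome: str,
) -> Status:
    """Map an alternate-allele dosage to a zygosity status.

    Autosomal (and complex/unknown) modes: 0 -> wild-type, 1 -> carrier,
    2 -> homozygous-alternate. X-linked males are hemizygous for any
    alternate allele; X-linked females follow the autosomal mapping.
    Mitochondrial variants are reported present/absent. A dosage of 2 on the
    male X is a data inconsistency: it is logged and still reported
    hemizygous.
    """
    if sex not in ("male", "female"):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    if chromosome == "MT" or inheritance is Inheritance.MITOCHONDRIAL:
        return Status.MITO_PRESENT if alt_count >= 1 else Status.WILDTYPE
    if chromosome == "X" and sex == "male":
        if alt_count >= 2:
            logger.warning(
                "male X genotype with dosage %d: inconsistent, reported hemizygous", alt_count
            )
        return Status.HEMIZYGOUS_ALT if alt_count >= 1 else Status.WILDTYPE
    return {0: Status.WILDTYPE, 1: Status.CARRIER, 2: Status.HOMOZYGOUS_ALT}[alt_count]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load the sample metadata TSV (sample_id, sex, breed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "sex", "breed"):
        if col not in df.columns:
            raise ConfigurationError(f"metadata file {path} is missing column {col!r}")
    return df


def _site_candidates(vcf_path: str | Path) -> dict[tuple[str, int, str, str], dict]:
    """Index a VCF by normalized allele key, splitting multi-allelic records.

    Each entry carries the record's filter status and, per sample, the dosage
    of the matched alternate allele (None when the genotype is uncalled).
    Duplicate keys keep the first record in position order, with a warning.
    """
    index: dict[tuple[str, int, str, str], dict] = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            filters = list(rec.filter.keys())
            filter_pass = filters in ([], ["PASS"])
            for ai, alt in enumerate(rec.alts or (), start=1):
                try:
                    key = normalize(rec.chrom, rec.pos, rec.ref, alt).key
                except ValidationError:
                    continue  # symbolic or degenerate alt: not matchable
                if key in index:
                    logger.warning(
                        "duplicate VCF records match key %s; keeping the first", key
                    )
                    continue
                dosages: dict[str, int | None] = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        dosages[s] = None
                    else:
                        dosages[s] = sum(1 for a in gt if a == ai)
                index[key] = {"filter_pass": filter_pass, "dosages": dosages}
    return index


def scan_vcf(
    vcf_path: str | Path,
    panel: Sequence[CatalogueVariant],
    metadata: pd.DataFrame,
    qm: QualificationMatrix | None = None,
    depth_threshold: int = 10,
) -> list[GenotypeCall]:
    """Search a multi-sample VCF for the curated panel and call every sample.

    For each (sample, panel variant) pair the VCF is searched for a record
    whose normalized allele matches the catalogue entry. Matched sites yield
    the genotype's alternate-allele dosage and an interpreted status; sites
    failing the hard filter or with uncalled genotypes are NOT_ASSESSABLE.
    A panel locus with no VCF record is WILDTYPE when its span qualified at
    ``depth_threshold`` (per ``qm``) and NOT_ASSESSABLE otherwise; with no
    qualification matrix supplied, coverage is assumed adequate.

    Raises
    ------
    ConfigurationError
        If a metadata sample is absent from the VCF.
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = set(vf.header.samples)
    sample_sex = dict(zip(metadata["sample_id"], metadata["sex"]))
    missing = sorted(set(sample_sex) - vcf_samples)
    if missing:
        raise ConfigurationError(f"samples in metadata but absent from VCF: {missing}")

    index = _site_candidates(vcf_path)
    calls: list[GenotypeCall] = []
    for v in panel:
        key = normalize(v.chromosome, v.position, v.ref_allele, v.alt_allele).key
        entry = index.get(key)
        for sample_id, sex in sample_sex.items():
            if entry is None:
                covered = (
                    qm is None
                    or qm.qualified(sample_id, v.record_id, depth_threshold)
                )
                status = Status.WILDTYPE if covered else Status.NOT_ASSESSABLE
                calls.append(GenotypeCall(sample_id, v.record_id, 0, status, True))
                continue
            if not entry["filter_pass"]:
                calls.append(
                    GenotypeCall(sample_id, v.record_id, 0, Status.NOT_ASSESSABLE, False)
                )
                continue
            dosage = entry["dosages"].get(sample_id)
            if dosage is None:
                calls.append(
                    GenotypeCall(sample_id, v.record_id, 0, Status.NOT_ASSESSABLE, True)
                )
                continue
            status = interpret(dosage, v.inheritance, sex, v.chromosome)
            calls.append(GenotypeCall(sample_id, v.record_id, dosage, status, True))
    return calls


def detection_matrix(
    calls: Sequence[GenotypeCall], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Pivot calls into a samples x variants dosage matrix (NaN = not assessable)."""
    rows = [
        {
            "sample_id": c.sample_id,
            "record_id": c.record_id,
            "alt_count": np.nan if c.status is Status.NOT_ASSESSABLE else c.alt_count,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows)
    dm = df.pivot(index="sample_id", columns="record_id", values="alt_count")
    return dm.reindex(index=sorted(metadata["sample_id"]))


@dataclass(frozen=True)
class DogSummary:
    """Histogram of distinct detected variants per sample (zygosity-agnostic)."""

    counts_per_sample: Mapping[str, int]
    histogram: Mapping[int, int]
    n_samples: int
    n_with_at_least_one: int

    @property
    def proportion(self) -> float:
        return self.n_with_at_least_one / self.n_samples


def per_dog_summary(
    dm: pd.DataFrame,
    panel: Sequence[CatalogueVariant],
    disease_only: bool = False,
) -> DogSummary:
    """Count distinct detected panel variants per sample.

    A variant is detected when its dosage is >= 1, irrespective of zygosity;
    ``disease_only`` restricts the count to disease-flagged panel entries.
    """
    keep = [v.record_id for v in panel if (v.is_disease or not disease_only)]
    keep = [r for r in keep if r in dm.columns]
    detected = dm[keep].fillna(0) >= 1
    counts = detected.sum(axis=1).astype(int)
    histogram: dict[int, int] = {}
    for c in counts:
        histogram[int(c)] = histogram.get(int(c), 0) + 1
    return DogSummary(
        counts_per_sample=counts.to_dict(),
        histogram=dict(sorted(histogram.items())),
        n_samples=len(counts),
        n_with_at_least_one=int((counts >= 1).sum()),
    )
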