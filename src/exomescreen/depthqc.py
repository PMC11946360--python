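"""Per-base depth qualification of panel loci and sample-level summaries.

A variant locus counts as successfully sequenced in a sample only if *every*
base of its span reaches the depth cutoff — a single shallow base fails the
whole variant. Spans are: the single position for an SNV, all deleted
positions for a deletion, the two flanking anchor bases for an insertion
(inserted bases have no reference coordinate), and the union of replaced
positions for a delins. Qualification is evaluated at three cutoffs (>=10x,
>=20x, >=30x), which makes the result monotone in the threshold.

Depth input is either a per-sample three-column TSV (chrom, pos, depth) or a
GATK DepthOfCoverage-style per-locus table with a ``Locus`` ("chrom:pos")
column and one ``Depth_for_<sample>`` column per sample. Positions absent
from a track have depth 0, so uncovered loci need no sentinel values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import normalize
from .catalogue import CatalogueVariant, Category
from .errors import ConfigurationError, ValidationError

__all__ = [
    "DepthTrack",
    "VariantSpan",
    "QualificationMatrix",
    "CategorySummary",
    "DEFAULT_THRESHOLDS",
    "variant_span",
    "qualify",
    "build_qualification_matrix",
    "per_variant_depth",
    "category_depth_means",
    "per_sample_counts",
    "summarize_category",
    "summarize_all_categories",
    "percent_of",
]

DEFAULT_THRESHOLDS: tuple[int, ...] = (10, 20, 30)


@dataclass
class DepthTrack:
    """Per-sample map from (chromosome, 1-based position) to read depth.

    Lookups never fail: a position absent from the map has depth 0.
    """

    sample_id: str
    depth: dict[tuple[str, int], int] = field(default_factory=dict)

    def get(self, chromosome: str, position: int) -> int:
        return self.depth.get((chromosome, position), 0)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "DepthTrack":
        """Load a 3-column (chrom, pos, depth) TSV; sample id defaults to the file stem."""
        sid = sample_id if sample_id is not None else Path(path).stem
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                         dtype={"chrom": str, "pos": int, "depth": int}, comment="#")
        depth = {(c, p): d for c, p, d in zip(df["chrom"], df["pos"], df["depth"])}
        return cls(sample_id=sid, depth=depth)

    @classmethod
    def from_gatk_table(cls, path: str | Path) -> list["DepthTrack"]:
        """Load a GATK DepthOfCoverage per-locus table; one track per Depth_for_* column."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "Locus" not in df.columns:
            raise ConfigurationError(f"depth table {path} has no 'Locus' column")
        sample_cols = [c for c in df.columns if c.startswith("Depth_for_")]
        if not sample_cols:
            raise ConfigurationError(f"depth table {path} has no 'Depth_for_<sample>' columns")
        loci = [tuple(l.rsplit(":", 1)) for l in df["Locus"]]
        tracks = []
        for col in sample_cols:
            sid = col[len("Depth_for_"):]
            depths = df[col].astype(int)
            track = {(chrom, int(pos)): d for (chrom, pos), d in zip(loci, depths)}
            tracks.append(cls(sample_id=sid, depth=track))
        return tracks


@dataclass(frozen=True)
class VariantSpan:
    """The set of reference positions whose depth must all qualify for one variant."""

    chromosome: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValidationError("VariantSpan must be non-empty")


def variant_span(v: CatalogueVariant) -> VariantSpan:
    """Reference positions covered by a panel variant.

    SNVs and delins span the replaced reference bases; a deletion of *k*
    bases spans all *k* positions; a pure insertion spans its two flanking
    anchor bases — inserted bases have no reference coordinate. The variant
    is normalized first, so anchored catalogue representations yield the
    same span as their minimal form.
    """
    na = normalize(v.chromosome, v.position, v.ref_allele, v.alt_allele)
    if na.ref == "":  # insertion: position is the right-flank base after trimming
        pos = na.position
        positions = (pos - 1, pos) if pos > 1 else (pos, pos + 1)
    else:
        positions = tuple(range(na.position, na.position + len(na.ref)))
    return VariantSpan(chromosome=na.chromosome, positions=positions)


def qualify(track: DepthTrack, span: VariantSpan, threshold: int) -> bool:
    """True iff every position of the span has depth >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    return all(track.get(span.chromosome, p) >= threshold for p in span.positions)


@dataclass
class QualificationMatrix:
    """sample x variant x threshold boolean results of the all-base depth check.

    The entries are monotone in the threshold: qualified at >=30x implies
    qualified at >=20x implies qualified at >=10x.
    """

    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    entries: dict[tuple[str, str, int], bool] = field(default_factory=dict)

    def qualified(self, sample_id: str, record_id: str, threshold: int) -> bool:
        return self.entries[(sample_id, record_id, threshold)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "record_id": r, "threshold": t, "qualified": q}
            for (s, r, t), q in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "record_id", "threshold", "qualified"])


def build_qualification_matrix(
    tracks: Sequence[DepthTrack],
    variants: Sequence[CatalogueVariant],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> QualificationMatrix:
    """Evaluate the all-base rule for every (sample, variant, threshold) triple."""
    thresholds = tuple(sorted(thresholds))
    qm = QualificationMatrix(thresholds=thresholds)
    spans = {v.record_id: variant_span(v) for v in variants}
    for track in tracks:
        for v in variants:
            span = spans[v.record_id]
            # compute once from the minimum span depth; monotone by construction
            min_depth = min(track.get(span.chromosome, p) for p in span.positions)
            for t in thresholds:
                qm.entries[(track.sample_id, v.record_id, t)] = min_depth >= t
    return qm


def per_variant_depth(
    tracks: Sequence[DepthTrack], span: VariantSpan
) -> dict[str, float]:
    """Mean/min/max over samples of the per-sample mean depth across a span."""
    if not tracks:
        raise ValidationError("per_variant_depth requires at least one sample")
    means = [
        float(np.mean([t.get(span.chromosome, p) for p in span.positions]))
        for t in tracks
    ]
    return {"mean": float(np.mean(means)), "min": min(means), "max": max(means)}


def category_depth_means(
    tracks: Sequence[DepthTrack], variants: Sequence[CatalogueVariant]
) -> dict[Category, dict[str, float]]:
    """Per-category depth summary: mean of per-variant mean depths, global min/max."""
    out: dict[Category, dict[str, float]] = {}
    for cat in Category:
        cat_variants = [v for v in variants if v.category == cat]
        if not cat_variants:
            continue
        stats = [per_variant_depth(tracks, variant_span(v)) for v in cat_variants]
        out[cat] = {
            "mean": float(np.mean([s["mean"] for s in stats])),
            "min": min(s["min"] for s in stats),
            "max": max(s["max"] for s in stats),
            "n_variants": len(cat_variants),
        }
    return out


def per_sample_counts(
    qm: QualificationMatrix, variants: Sequence[CatalogueVariant]
) -> pd.DataFrame:
    """Count qualified variants per (sample, category, threshold).

    Returns a long-format frame with columns sample_id, category, threshold,
    count. Counts are non-increasing in the threshold for every
    (sample, category) pair.
    """
    samples = sorted({s for (s, _, _) in qm.entries})
    by_cat: dict[Category, list[str]] = {}
    for v in variants:
        by_cat.setdefault(v.category, []).append(v.record_id)
    rows = []
    for s in samples:
        for cat, rids in by_cat.items():
            for t in qm.thresholds:
                count = sum(qm.entries[(s, rid, t)] for rid in rids)
                rows.append(
                    {"sample_id": s, "category": cat.value, "threshold": t, "count": count}
                )
    return pd.DataFrame(rows, columns=["sample_id", "category", "threshold", "count"])


def percent_of(value: float | int, n: int) -> float:
    """100 * value / n, rounded half-up to 2 decimals (table formatting rule)."""
    pct = Decimal(str(value)) * 100 / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategorySummary:
    """Order statistics of per-sample qualified counts for one category x cutoff."""

    category: str
    threshold: int
    n_variants: int
    min: int
    max: int
    median: float
    mean: float
    min_pct: float
    max_pct: float
    median_pct: float
    mean_pct: float


def summarize_category(
    counts: Sequence[int],
    n_variants: int,
    category: str = "",
    threshold: int = 0,
) -> CategorySummary:
    """Summarize per-sample qualified counts into min/max/median/mean (+ percentages).

    The median uses the standard midpoint rule for even sample counts;
    percentages are each statistic expressed as a fraction of ``n_variants``,
    rounded half-up to 2 decimals.
    """
    if len(counts) == 0:
        raise ValidationError("summarize_category requires at least one sample count")
    if n_variants < 1:
        raise ValidationError("n_variants must be >= 1")
    arr = np.asarray(counts, dtype=float)
    cmin, cmax = int(arr.min()), int(arr.max())
    cmed, cmean = float(np.median(arr)), float(arr.mean())
    return CategorySummary(
        category=category,
        threshold=threshold,
        n_variants=n_variants,
        min=cmin,
        max=cmax,
        median=cmed,
        mean=cmean,
        min_pct=percent_of(cmin, n_variants),
        max_pct=percent_of(cmax, n_variants),
        median_pct=percent_of(cmed, n_variants),
        mean_pct=percent_of(round(cmean, 2), n_variants),
    )


def summarize_all_categories(
    counts: pd.DataFrame, variants: Sequence[CatalogueVariant]
) -> pd.DataFrame:
    """Build the per-sample performance table (one row per category x threshold)."""
    n_by_cat = {}
    for v in variants:
        n_by_cat[v.category.value] = n_by_cat.get(v.category.value, 0) + 1
    rows = []
    for (cat, t), grp in counts.groupby(["category", "threshold"], sort=True):
        s = summarize_category(grp["count"].tolist(), n_by_cat[cat], category=cat, threshold=int(t))
        rows.append({f: getattr(s, f) for f in s.__dataclass_fields__})
    return pd.DataFrame(rows)
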