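"""Synthetic study generator: catalogue, depth tracks, VCF, metadata + ground truth.

Emulates the inputs of a targeted exome screen on a small artificial genome
(four autosomes plus "X" and "MT", kilobase scale) so every pipeline stage is
testable without downloads. Three generators share one seed stream:

* :func:`generate_catalogue` — a raw OMIA-style table with the study's
  category structure (251 coding SNVs, 7 non-coding 1 bp variants, 94 larger
  2–20 bp variants by default; 323 of 352 disease-flagged; 118/6/46 of them
  published after the 2014 capture design) plus planted records violating
  each curation criterion.
* :func:`generate_depth` — per-sample per-base depth tracks drawn from a
  negative-binomial coverage model with category-specific means (on-target
  coding loci ~35x, off-target non-coding loci ~5x) and a capture-dropout
  mass so fully uncovered loci occur.
* :func:`generate_vcf` — a multi-sample VCF with genotypes drawn per
  inheritance mode respecting sample sex (no male-X heterozygotes; haploid
  male-X and mitochondrial GTs), a configurable fraction of hard-filter
  failures, planted multi-allelic sites, and indels emitted in an anchored
  (and optionally padded) representation that differs from the catalogue's
  minimal form, to exercise allele normalization.

Every generator records what it planted in a truth table serialized next to
the outputs, so recovery can be asserted exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import Category, Inheritance, Reason

__all__ = [
    "CHROMOSOMES",
    "generate_metadata",
    "generate_catalogue",
    "generate_depth",
    "generate_vcf",
    "simulate_study",
    "StudyPaths",
]

#: artificial mini-genome contig order
CHROMOSOMES = ("chr1", "chr2", "chr3", "chr4", "X", "MT")

_BASES = np.array(list("ACGT"))

_BREEDS = [
    "Labrador Retriever", "Deerhound", "Malinois", "Bloodhound", "Crossbreed",
    "Dutch Partridge Dog", "Belgian Shepherd", "English Cocker Spaniel",
    "Pitbull", "Irish Setter", "American Staffordshire", "Chesapeake Bay Retriever",
    "French Bulldog", "Jack Russell Terrier",
]

# study-scale defaults for the cohort and panel composition
DEFAULT_N_SAMPLES = 49
DEFAULT_N_CDS = 251
DEFAULT_N_NONCODING = 7
DEFAULT_N_LARGER = 94
DEFAULT_N_DISEASE = 323
DEFAULT_N_POST_DESIGN = {"CDS_1BP": 118, "NONCODING_1BP": 6, "LARGER": 46}
DEFAULT_DESIGN_YEAR = 2014
# X-linked and mitochondrial variants use observed-scale carrier rates (a
# hemizygous X variant in ~5/49 samples, a mitochondrial one in ~3/49); the
# base disease rate is set so the expected fraction of samples with >=1
# disease-panel hit stays ~0.84 on a 323-variant panel
DEFAULT_DISEASE_CARRIER_RATE = 0.00437
DEFAULT_XLINKED_CARRIER_RATE = 0.10
DEFAULT_MITO_CARRIER_RATE = 0.06
DEFAULT_NONDISEASE_CARRIER_RATE = 0.08
DEFAULT_DEPTH_MEANS = {"CDS_1BP": 35.0, "NONCODING_1BP": 5.0, "LARGER": 37.0}
DEFAULT_DROPOUT = {"CDS_1BP": 0.02, "NONCODING_1BP": 0.30, "LARGER": 0.02}


def _rand_bases(rng: np.random.Generator, k: int) -> str:
    return "".join(rng.choice(_BASES, size=k))


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return str(rng.choice(choices))


def generate_metadata(
    n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0, n_male: int | None = None
) -> pd.DataFrame:
    """Sample metadata with a study-like sex split (22 male / 27 female at n=49)."""
    if n_male is None:
        n_male = round(n_samples * 22 / 49)
    rng = np.random.default_rng(seed)
    sexes = np.array(["male"] * n_male + ["female"] * (n_samples - n_male))
    rng.shuffle(sexes)
    return pd.DataFrame(
        {
            "sample_id": [f"dog{i + 1:03d}" for i in range(n_samples)],
            "sex": sexes,
            "breed": [_BREEDS[i % len(_BREEDS)] for i in range(n_samples)],
        }
    )


def generate_catalogue(
    path: str | Path,
    seed: int = 0,
    n_cds: int = DEFAULT_N_CDS,
    n_noncoding: int = DEFAULT_N_NONCODING,
    n_larger: int = DEFAULT_N_LARGER,
    n_disease: int = DEFAULT_N_DISEASE,
    n_post_design: Mapping[str, int] | None = None,
    n_invalid_per_reason: int = 3,
    design_year: int = DEFAULT_DESIGN_YEAR,
    year_range: tuple[int, int] = (1991, 2021),
    accepted_build: str = "CanFam3.1",
) -> dict:
    """Write a raw catalogue TSV with planted curation violations; return the truth.

    Valid records carry consistent coordinates on the mini-genome; X-linked
    variants sit on "X", mitochondrial ones on "MT" with "m." locations.
    Invalid records violate one curation criterion each: a non-genomic
    location string, a wrong build tag, a missing gene symbol, unusable
    alleles, or a size above 20 bp.
    """
    if n_post_design is None:
        n_post_design = DEFAULT_N_POST_DESIGN
    rng = np.random.default_rng(seed)
    cursors = {c: 1000 for c in CHROMOSOMES}
    autosome_cycle = 0

    def next_pos(chrom: str) -> int:
        pos = cursors[chrom]
        cursors[chrom] += 100
        return pos

    n_valid = n_cds + n_noncoding + n_larger
    categories = (
        [Category.CDS_1BP] * n_cds
        + [Category.NONCODING_1BP] * n_noncoding
        + [Category.LARGER] * n_larger
    )

    # inheritance plants: a few X-linked / mitochondrial / dominant / complex
    # among 1 bp CDS variants, the remainder autosomal recessive
    inheritances = [Inheritance.AUTOSOMAL_RECESSIVE] * n_valid
    special = (
        [Inheritance.X_LINKED] * 3
        + [Inheritance.MITOCHONDRIAL] * 2
        + [Inheritance.AUTOSOMAL_DOMINANT] * 4
        + [Inheritance.COMPLEX] * 2
    )
    for i, inh in enumerate(special[: n_cds]):
        inheritances[i] = inh

    disease_idx = set(rng.choice(n_valid, size=min(n_disease, n_valid), replace=False).tolist())

    # publication years: per category, n_post_design records strictly after the
    # design year, the rest at or before it
    years: list[int] = []
    post_left = dict(n_post_design)
    per_cat_seen: dict[str, int] = {}
    cat_totals = {"CDS_1BP": n_cds, "NONCODING_1BP": n_noncoding, "LARGER": n_larger}
    for cat in categories:
        seen = per_cat_seen.get(cat.value, 0)
        per_cat_seen[cat.value] = seen + 1
        if seen < post_left.get(cat.value, 0):
            years.append(int(rng.integers(design_year + 1, year_range[1] + 1)))
        else:
            years.append(int(rng.integers(year_range[0], design_year + 1)))

    rows: list[dict] = []
    truth_catalogue: dict[str, dict] = {}
    for i in range(n_valid):
        cat = categories[i]
        inh = inheritances[i]
        if inh is Inheritance.MITOCHONDRIAL:
            chrom = "MT"
        elif inh is Inheritance.X_LINKED:
            chrom = "X"
        else:
            chrom = CHROMOSOMES[autosome_cycle % 4]
            autosome_cycle += 1
        pos = next_pos(chrom)
        if cat is Category.LARGER:
            size = int(rng.integers(2, 21))
            kind = str(rng.choice(["deletion", "insertion", "delins"]))
            if kind == "deletion":
                ref, alt = _rand_bases(rng, size), ""
            elif kind == "insertion":
                ref, alt = "", _rand_bases(rng, size)
            else:  # delins, minimal form: differing first and last characters
                ref = _rand_bases(rng, size)
                alt_len = int(rng.integers(1, size + 1))
                if alt_len == 1:
                    alt = _other_base(rng, ref[0], ref[-1])
                else:
                    first = _other_base(rng, ref[0])
                    last = _other_base(rng, ref[-1])
                    middle = _rand_bases(rng, alt_len - 2)
                    alt = first + middle + last
        else:
            ref = _rand_bases(rng, 1)
            alt = _other_base(rng, ref)
        loc_class = (
            "CDS"
            if cat is Category.CDS_1BP
            else str(rng.choice(["intron", "UTR", "promoter"]))
            if cat is Category.NONCODING_1BP
            else str(rng.choice(["CDS", "intron"]))
        )
        rid = f"OMIA{i + 1:06d}"
        rows.append(
            {
                "record_id": rid,
                "gene": f"GENE{i + 1}",
                "location": f"{'m' if chrom == 'MT' else 'g'}.{pos}",
                "build": accepted_build,
                "chrom": chrom,
                "ref": ref,
                "alt": alt,
                "location_class": loc_class,
                "inheritance": inh.value,
                "year": years[i],
                "phene": f"trait_{i + 1}",
                "is_disease": "1" if i in disease_idx else "0",
            }
        )
        truth_catalogue[rid] = {
            "valid": True,
            "reason": None,
            "category": cat.value,
            "inheritance": inh.value,
            "is_disease": i in disease_idx,
            "publication_year": years[i],
            "chromosome": chrom,
            "position": pos,
            "ref": ref,
            "alt": alt,
        }

    # planted violations, one criterion each
    violations = [
        (Reason.NO_GENOMIC_LOCATION, {"location": "c.76del"}),
        (Reason.WRONG_BUILD, {"build": "CanFam2.0"}),
        (Reason.BAD_GENE_SYMBOL, {"gene": ""}),
        (Reason.BAD_ALLELES, {"ref": "NN", "alt": "A"}),
        (Reason.SIZE_GT_MAX, {"ref_size": int(rng.integers(21, 31))}),
    ]
    bad_i = 0
    for reason, override in violations:
        for _ in range(n_invalid_per_reason):
            bad_i += 1
            chrom = CHROMOSOMES[autosome_cycle % 4]
            autosome_cycle += 1
            pos = next_pos(chrom)
            size = override.get("ref_size", 1)
            row = {
                "record_id": f"BAD{bad_i:04d}",
                "gene": override.get("gene", f"BADGENE{bad_i}"),
                "location": override.get("location", f"g.{pos}"),
                "build": override.get("build", accepted_build),
                "chrom": chrom,
                "ref": override.get("ref", _rand_bases(rng, size)),
                "alt": override.get("alt", _other_base(rng, "")[0] if size == 1 else "A"),
                "location_class": "CDS",
                "inheritance": "AUTOSOMAL_RECESSIVE",
                "year": int(rng.integers(*year_range)),
                "phene": f"bad_trait_{bad_i}",
                "is_disease": "1",
            }
            rows.append(row)
            truth_catalogue[row["record_id"]] = {
                "valid": False,
                "reason": reason.value,
                "category": None,
            }

    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order])
    df.to_csv(path, sep="\t", index=False)
    return {
        "catalogue": truth_catalogue,
        "n_valid": n_valid,
        "n_invalid": len(rows) - n_valid,
        "category_mix": cat_totals,
        "n_disease": len(disease_idx),
        "design_year": design_year,
        "n_post_design": dict(n_post_design),
    }


def generate_depth(
    sample_ids: Sequence[str],
    variants: Sequence,
    outdir: str | Path,
    seed: int = 0,
    means: Mapping[str, float] | None = None,
    dropout: Mapping[str, float] | None = None,
    dispersion: float = 5.0,
    flank: int = 2,
) -> dict:
    """Write one depth TSV per sample covering every panel span +/- ``flank``.

    Per-base depths are negative binomial with a category-specific mean and a
    per-locus capture-dropout mass (the whole locus reads zero). The NB mean
    is inflated by 1/(1 - dropout) so the *marginal* per-base mean equals the
    requested value; the truth table records those marginal means.
    """
    from .depthqc import variant_span  # local import to avoid cycles

    if means is None:
        means = DEFAULT_DEPTH_MEANS
    if dropout is None:
        dropout = DEFAULT_DROPOUT
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spans = [(v, variant_span(v)) for v in variants]
    paths = {}
    for sid in sample_ids:
        records = []
        for v, span in spans:
            cat = v.category.value
            zi = dropout[cat]
            m = means[cat] / (1.0 - zi)
            lo = span.positions[0] - flank
            hi = span.positions[-1] + flank
            n_pos = hi - lo + 1
            if rng.random() < zi:
                depths = np.zeros(n_pos, dtype=int)
            else:
                p = dispersion / (dispersion + m)
                depths = rng.negative_binomial(dispersion, p, size=n_pos)
            for pos, d in zip(range(lo, hi + 1), depths):
                records.append((span.chromosome, pos, int(d)))
        records.sort(key=lambda r: (CHROMOSOMES.index(r[0]), r[1]))
        path = outdir / f"{sid}.depth.tsv"
        with open(path, "w") as fh:
            for chrom, pos, d in records:
                fh.write(f"{chrom}\t{pos}\t{d}\n")
        paths[sid] = str(path)
    return {
        "depth_model": {
            cat: {"mean": float(means[cat]), "dropout": float(dropout[cat])}
            for cat in means
        },
        "dispersion": dispersion,
        "flank": flank,
        "paths": paths,
    }


def _draw_dosage(
    rng: np.random.Generator, carrier_rate: float, inheritance: Inheritance,
    chromosome: str, sex: str,
) -> int:
    """Dosage draw respecting inheritance mode and sex.

    ``carrier_rate`` is the probability a sample carries >=1 alternate
    allele; the per-allele frequency is derived from it (q = 1 - sqrt(1-c)
    for diploid contexts).
    """
    if chromosome == "MT" or inheritance is Inheritance.MITOCHONDRIAL:
        return int(rng.random() < carrier_rate)
    q = 1.0 - sqrt(1.0 - carrier_rate)
    if chromosome == "X" and sex == "male":
        return int(rng.random() < q)
    return int(rng.random() < q) + int(rng.random() < q)


def generate_vcf(
    metadata: pd.DataFrame,
    variants: Sequence,
    vcf_path: str | Path,
    seed: int = 0,
    disease_carrier_rate: float = DEFAULT_DISEASE_CARRIER_RATE,
    nondisease_carrier_rate: float = DEFAULT_NONDISEASE_CARRIER_RATE,
    xlinked_carrier_rate: float = DEFAULT_XLINKED_CARRIER_RATE,
    mito_carrier_rate: float = DEFAULT_MITO_CARRIER_RATE,
    filter_fail_rate: float = 0.02,
    multiallelic_frac: float = 0.10,
    pad_frac: float = 0.30,
) -> dict:
    """Write a multi-sample VCF with planted genotypes; return the truth dosages.

    Only sites with at least one alternate allele in the cohort are emitted
    (variant callers emit variant sites only). Indels are emitted in an
    anchored representation (with an invented anchor base chosen to keep
    trimming unambiguous), a fraction of them additionally padded with a
    shared trailing base; a fraction of SNV sites is emitted multi-allelic
    with a decoy second alternate carried by one dosage-0 sample. A fraction
    of emitted sites fails the hard filter ("LowQual").
    """
    rng = np.random.default_rng(seed)
    samples = list(metadata["sample_id"])
    sexes = dict(zip(metadata["sample_id"], metadata["sex"]))

    dosages: dict[str, dict[str, int]] = {}
    emitted: list[str] = []
    filter_failed: list[str] = []
    multiallelic: list[str] = []
    shifted: list[str] = []
    records: list[tuple[str, int, str]] = []  # (chrom, pos, line)

    max_pos: dict[str, int] = {}
    for v in variants:
        if v.inheritance is Inheritance.X_LINKED:
            rate = xlinked_carrier_rate
        elif v.inheritance is Inheritance.MITOCHONDRIAL:
            rate = mito_carrier_rate
        elif v.is_disease:
            rate = disease_carrier_rate
        else:
            rate = nondisease_carrier_rate
        ds = {
            s: _draw_dosage(rng, rate, v.inheritance, v.chromosome, sexes[s])
            for s in samples
        }
        dosages[v.record_id] = ds
        max_pos[v.chromosome] = max(max_pos.get(v.chromosome, 0), v.position + 30)
        if not any(ds.values()):
            continue
        emitted.append(v.record_id)

        ref, alt, pos = v.ref_allele, v.alt_allele, v.position
        alt_index = 1
        alts = [alt]
        if len(ref) == 1 and len(alt) == 1:
            if rng.random() < multiallelic_frac:
                decoy = _other_base(rng, ref, alt)
                alts = [alt, decoy]
                multiallelic.append(v.record_id)
        else:
            # anchored emission; anchor must not extend a trimmable run
            if alt == "":  # deletion: catalogue (pos, ref, "") -> (pos-1, B+ref, B)
                anchor = _other_base(rng, ref[-1])
                ref_out, alt_out, pos_out = anchor + ref, anchor, pos - 1
            elif ref == "":  # insertion at right flank pos -> (pos-1, B, B+alt)
                anchor = _other_base(rng, alt[-1])
                ref_out, alt_out, pos_out = anchor, anchor + alt, pos - 1
            else:  # delins: plain anchored form
                anchor = _other_base(rng, "")
                ref_out, alt_out, pos_out = anchor + ref, anchor + alt, pos - 1
            if rng.random() < pad_frac:
                pad = _rand_bases(rng, 1)
                ref_out, alt_out = ref_out + pad, alt_out + pad
            shifted.append(v.record_id)
            ref, alt, pos = ref_out, alt_out, pos_out
            alts = [alt]

        fails = rng.random() < filter_fail_rate
        if fails:
            filter_failed.append(v.record_id)

        decoy_sample = None
        if len(alts) == 2:
            zeros = [s for s in samples if dosages[v.record_id][s] == 0]
            if zeros:
                decoy_sample = zeros[0]

        gts = []
        for s in samples:
            d = dosages[v.record_id][s]
            haploid = v.chromosome == "MT" or (v.chromosome == "X" and sexes[s] == "male")
            if haploid:
                gts.append(str(min(d, 1) * alt_index))
            elif s == decoy_sample:
                gts.append("0/2")
            elif d == 0:
                gts.append("0/0")
            elif d == 1:
                gts.append(f"0/{alt_index}")
            else:
                gts.append(f"{alt_index}/{alt_index}")
        line = "\t".join(
            [
                v.chromosome, str(pos), v.record_id, ref if ref else "N",
                ",".join(alts), "50", "LowQual" if fails else "PASS", ".", "GT",
            ]
            + gts
        )
        records.append((v.chromosome, pos, line))

    records.sort(key=lambda r: (CHROMOSOMES.index(r[0]), r[1]))
    header = ["##fileformat=VCFv4.2"]
    for chrom in CHROMOSOMES:
        if chrom in max_pos:
            header.append(f"##contig=<ID={chrom},length={max_pos[chrom] + 1000}>")
    header.append('##FILTER=<ID=LowQual,Description="Failed hard quality filter">')
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for _, _, line in records:
            fh.write(line + "\n")
    return {
        "dosages": dosages,
        "emitted": emitted,
        "filter_failed": filter_failed,
        "multiallelic": multiallelic,
        "shifted_representation": shifted,
        "params": {
            "disease_carrier_rate": disease_carrier_rate,
            "nondisease_carrier_rate": nondisease_carrier_rate,
            "filter_fail_rate": filter_fail_rate,
        },
    }


@dataclass
class StudyPaths:
    """File locations of one simulated study."""

    outdir: Path
    raw_catalogue: Path
    metadata: Path
    depth_dir: Path
    vcf: Path
    truth: Path


def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
    **catalogue_kwargs,
) -> StudyPaths:
    """Generate a complete synthetic study (catalogue, metadata, depth, VCF, truth).

    All randomness derives from ``seed`` via independent child streams, so
    the same seed reproduces every file byte-for-byte.
    """
    from .catalogue import curate, parse_catalogue

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in child]

    paths = StudyPaths(
        outdir=outdir,
        raw_catalogue=outdir / "raw_catalogue.tsv",
        metadata=outdir / "metadata.tsv",
        depth_dir=outdir / "depth",
        vcf=outdir / "cohort.vcf",
        truth=outdir / "truth.json",
    )
    cat_truth = generate_catalogue(paths.raw_catalogue, seed=seeds[0], **catalogue_kwargs)
    metadata = generate_metadata(n_samples=n_samples, seed=seeds[1])
    metadata.to_csv(paths.metadata, sep="\t", index=False)

    build = catalogue_kwargs.get("accepted_build", "CanFam3.1")
    variants, _ = curate(parse_catalogue(paths.raw_catalogue), accepted_build=build)
    depth_truth = generate_depth(
        list(metadata["sample_id"]), variants, paths.depth_dir, seed=seeds[2]
    )
    vcf_truth = generate_vcf(metadata, variants, paths.vcf, seed=seeds[3])

    truth = {"seed": seed, **cat_truth, **depth_truth, **vcf_truth}
    with open(paths.truth, "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
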