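"""Clinical-style screening reports and the end-to-end pipeline driver.

A screening report answers, for one sample: which fraction of the panel
could be reliably assessed (the reportable range at the reporting depth
threshold), which loci could not (too shallow, hard-filter failures,
uncalled genotypes) and must therefore be listed rather than silently
dropped, and which findings were made, grouped by inheritance mode because
the breeding consequences differ (recessive carriers remain usable for
breeding; dominant and X-linked findings need flagging).

The reporting threshold defaults to >=10x — the screen's headline operating
point — but is configurable, as no consensus minimal depth exists for
veterinary germline calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import accumulation as accum
from . import catalogue as cat
from . import depthqc as dq
from . import screen as scr
from .errors import ConfigurationError, PipelineError

__all__ = ["ScreeningReport", "build_report", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class ScreeningReport:
    sample_id: str
    threshold: int
    reportable_range: float  # fraction of panel variants with qualified spans
    n_panel: int
    n_qualified: int
    unassessable_loci: list[tuple[str, str]]  # (record_id, reason)
    findings: list[scr.GenotypeCall]
    findings_by_inheritance: dict[str, list[str]]
    category_breakdown: pd.DataFrame  # per category: n, n_qualified, pct

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "threshold": self.threshold,
                "reportable_range": self.reportable_range,
                "n_panel": self.n_panel,
                "n_qualified": self.n_qualified,
                "unassessable_loci": [
                    {"record_id": r, "reason": why} for r, why in self.unassessable_loci
                ],
                "findings": [
                    {
                        "record_id": f.record_id,
                        "alt_count": f.alt_count,
                        "status": f.status.value,
                    }
                    for f in self.findings
                ],
                "findings_by_inheritance": self.findings_by_inheritance,
                "category_breakdown": self.category_breakdown.to_dict(orient="records"),
            },
            indent=2,
        )


def build_report(
    sample_id: str,
    panel: Sequence[cat.CatalogueVariant],
    qm: dq.QualificationMatrix,
    calls: Sequence[scr.GenotypeCall],
    threshold: int = 10,
) -> ScreeningReport:
    """Assemble the per-sample screening report.

    The unassessable list contains exactly the panel loci whose span did not
    qualify at ``threshold`` plus any hard-filter-failed or uncalled sites,
    so the panel always reconciles: |panel| = |qualified| + |depth-unassessable|.
    """
    sample_calls = {c.record_id: c for c in calls if c.sample_id == sample_id}
    if not sample_calls:
        raise ConfigurationError(f"no calls for sample {sample_id!r}")
    unassessable: list[tuple[str, str]] = []
    n_qualified = 0
    cat_rows: dict[str, dict[str, int]] = {}
    for v in panel:
        row = cat_rows.setdefault(v.category.value, {"n": 0, "n_qualified": 0})
        row["n"] += 1
        if qm.qualified(sample_id, v.record_id, threshold):
            n_qualified += 1
            row["n_qualified"] += 1
        else:
            unassessable.append((v.record_id, "LOW_DEPTH"))
        call = sample_calls.get(v.record_id)
        if call is not None and call.status is scr.Status.NOT_ASSESSABLE:
            if not call.filter_pass:
                unassessable.append((v.record_id, "FILTER_FAIL"))
            elif qm.qualified(sample_id, v.record_id, threshold):
                # covered but uncalled or otherwise unassessable in the VCF
                unassessable.append((v.record_id, "GENOTYPE_MISSING"))
    findings = [
        sample_calls[v.record_id]
        for v in panel
        if v.record_id in sample_calls
        and sample_calls[v.record_id].status
        not in (scr.Status.WILDTYPE, scr.Status.NOT_ASSESSABLE)
    ]
    by_inh: dict[str, list[str]] = {}
    inh_of = {v.record_id: v.inheritance.value for v in panel}
    for f in findings:
        by_inh.setdefault(inh_of[f.record_id], []).append(f.record_id)
    breakdown = pd.DataFrame(
        [
            {
                "category": c,
                "n": r["n"],
                "n_qualified": r["n_qualified"],
                "pct_qualified": dq.percent_of(r["n_qualified"], r["n"]),
            }
            for c, r in sorted(cat_rows.items())
        ]
    )
    return ScreeningReport(
        sample_id=sample_id,
        threshold=threshold,
        reportable_range=n_qualified / len(panel),
        n_panel=len(panel),
        n_qualified=n_qualified,
        unassessable_loci=unassessable,
        findings=findings,
        findings_by_inheritance=by_inh,
        category_breakdown=breakdown,
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    return config


_REQUIRED_KEYS = ("catalogue", "depth_dir", "vcf", "metadata", "outdir")


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run curation, depth QC, screening, accumulation and reporting end to end.

    ``config`` is a mapping (or path to a YAML file) with keys: catalogue,
    depth_dir, vcf, metadata, outdir, and optionally thresholds,
    reporting_threshold, accepted_build, max_size, design_year, and an
    ``accumulation`` sub-mapping (step, n_replicates, seed, mode). All
    tabular outputs are written deterministically, so a rerun with the same
    inputs and seed is byte-identical.

    Returns a dict of the in-memory stage products (variants, report,
    summaries, calls, curve, paths).
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise ConfigurationError(f"config is missing required key {key!r}")
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = tuple(config.get("thresholds", dq.DEFAULT_THRESHOLDS))
    reporting_threshold = int(config.get("reporting_threshold", 10))
    acc_cfg = dict(config.get("accumulation", {}))

    try:
        records = cat.parse_catalogue(config["catalogue"])
        variants, curation = cat.curate(
            records,
            accepted_build=config.get("accepted_build", "CanFam3.1"),
            max_size=int(config.get("max_size", 20)),
        )
        cat.write_curated(variants, outdir / "curated_catalogue.tsv")
        (outdir / "curation_report.json").write_text(curation.to_json())
        (outdir / "curation_report.txt").write_text(curation.to_text())
    except Exception as e:  # noqa: BLE001 - stage-named propagation
        raise PipelineError(f"[catalogue] {e}") from e

    try:
        metadata = scr.read_metadata(config["metadata"])
        depth_dir = Path(config["depth_dir"])
        tracks = [
            dq.DepthTrack.from_tsv(p, sample_id=p.name.removesuffix(".depth.tsv"))
            for p in sorted(depth_dir.glob("*.depth.tsv"))
        ]
        if not tracks:
            raise ConfigurationError(f"no *.depth.tsv files under {depth_dir}")
        qm = dq.build_qualification_matrix(tracks, variants, thresholds)
        qm.to_frame().to_csv(outdir / "qualification_matrix.tsv", sep="\t", index=False)
        counts = dq.per_sample_counts(qm, variants)
        summary = dq.summarize_all_categories(counts, variants)
        summary.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
        split = cat.split_by_year(variants, design_year=int(config.get("design_year", 2014)))
        if split.post_design:
            post_counts = dq.per_sample_counts(qm, split.post_design)
            post_summary = dq.summarize_all_categories(post_counts, split.post_design)
            post_summary.to_csv(
                outdir / "category_summary_post_design.tsv", sep="\t", index=False
            )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"[depthqc] {e}") from e

    try:
        calls = scr.scan_vcf(
            config["vcf"], variants, metadata, qm=qm, depth_threshold=reporting_threshold
        )
        calls_df = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "record_id": c.record_id,
                    "alt_count": c.alt_count,
                    "status": c.status.value,
                    "filter_pass": c.filter_pass,
                }
                for c in calls
            ]
        )
        calls_df.to_csv(outdir / "genotype_calls.tsv", sep="\t", index=False)
        dm = scr.detection_matrix(calls, metadata)
        dm.to_csv(outdir / "detection_matrix.tsv", sep="\t", float_format="%.0f")
        summary_all = scr.per_dog_summary(dm, variants, disease_only=False)
        summary_disease = scr.per_dog_summary(dm, variants, disease_only=True)
        hist_rows = [
            {"panel": name, "n_variants_detected": k, "n_samples": n}
            for name, s in (("all", summary_all), ("disease", summary_disease))
            for k, n in s.histogram.items()
        ]
        pd.DataFrame(hist_rows).to_csv(outdir / "per_dog_histogram.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"[screen] {e}") from e

    try:
        disease_panel = [v for v in variants if v.is_disease]
        dm_disease = dm[[v.record_id for v in disease_panel if v.record_id in dm.columns]]
        curve = accum.accumulate(
            dm_disease,
            seed=int(acc_cfg.get("seed", 0)),
            n_replicates=int(acc_cfg.get("n_replicates", 100)),
            mode=accum.Mode(acc_cfg.get("mode", "NESTED")),
            step=int(acc_cfg.get("step", 50)),
        )
        accum.write_curve(curve, outdir / "accumulation_curve.tsv")
        accum.plot_curve(curve, outdir / "accumulation_curve.png")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"[accumulation] {e}") from e

    try:
        reports_dir = outdir / "reports"
        reports_dir.mkdir(exist_ok=True)
        reports = {}
        for sid in metadata["sample_id"]:
            rep = build_report(sid, variants, qm, calls, threshold=reporting_threshold)
            (reports_dir / f"{sid}.json").write_text(rep.to_json())
            reports[sid] = rep
    except Exception as e:
        raise PipelineError(f"[report] {e}") from e

    logger.info(
        "pipeline complete: %d variants, %d samples, outputs in %s",
        len(variants), len(metadata), outdir,
    )
    return {
        "variants": variants,
        "curation": curation,
        "qm": qm,
        "counts": counts,
        "summary": summary,
        "calls": calls,
        "detection_matrix": dm,
        "dog_summary_all": summary_all,
        "dog_summary_disease": summary_disease,
        "curve": curve,
        "reports": reports,
        "outdir": outdir,
    }
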