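"""End-to-end orchestration: extract -> classify -> summarize -> burden.

Two entry points: :func:`run_pipeline` consumes trio VCFs plus annotation,
transcript and panel files and produces the full report bundle;
:func:`run_summary_only` consumes a per-class count table directly, so a
published count table can be re-analysed without any VCF input.  Every
number in the human-readable report also appears in the JSON twin.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .burden import (
    CohortSummary,
    DNMBurdenModel,
    NullRates,
    per_trio_histogram,
    summarize_cohort,
)
from .consequence import DamagingCriteria, classify_worst, is_predicted_damaging
from .datasets import default_null_rates, load_default_panels
from .filters import FilterConfig, annotate_records, extract_dnms
from .io import (
    Pedigree,
    read_annotation_table,
    read_callable_summary,
    read_transcript_models,
    read_trio_vcf,
    write_dnm_table,
)
from .screen import find_inherited_candidates
from .types import GenePanel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    vcfs: Sequence[str | Path]
    peds: Sequence[str | Path]
    annotations: str | Path
    transcripts: str | Path
    fasta: str | Path
    callable_summary: str | Path
    outdir: str | Path
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    damaging_criteria: DamagingCriteria = field(default_factory=DamagingCriteria)
    nulls: Optional[NullRates] = None
    panels: Optional[Sequence[GenePanel]] = None
    alternative: str = "greater"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.vcfs) != len(self.peds):
            raise ValueError("one PED file per VCF required")


def _results_json(results, summary: CohortSummary, histogram: dict[int, int],
                  filter_cfg: FilterConfig) -> dict:
    payload = results.as_dict()
    payload["class_counts"] = {
        cls.value: int(n) for cls, n in sorted(
            summary.class_counts.items(), key=lambda kv: kv[0].value
        )
    }
    payload["avg_coding_snv_per_trio"] = summary.avg_coding_snv_per_trio
    payload["missense_fraction"] = (
        summary.missense_fraction if summary.coding_snvs else 0.0
    )
    payload["lof_snv_fraction"] = (
        summary.lof_snv_fraction if summary.coding_snvs else 0.0
    )
    payload["per_trio_histogram"] = {str(k): v for k, v in histogram.items()}
    payload["thresholds"] = {
        "min_depth": filter_cfg.min_depth,
        "min_alt_reads": filter_cfg.min_alt_reads,
        "min_vaf": filter_cfg.min_vaf,
        "max_panel_af": filter_cfg.max_panel_af,
        "max_inhouse_fraction": filter_cfg.max_inhouse_fraction,
        "mosaic_vaf_threshold": filter_cfg.mosaic_vaf_threshold,
        "max_parent_alt_reads": filter_cfg.max_parent_alt_reads,
        "max_parent_vaf": filter_cfg.max_parent_vaf,
        "require_parent_depth": filter_cfg.require_parent_depth,
    }
    return payload


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run extraction, classification, burden tests and the inherited screen.

    Writes the DNM table, inherited-candidate table and a JSON report into
    ``cfg.outdir``; returns the JSON payload as a dict.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panels = list(cfg.panels) if cfg.panels is not None else load_default_panels()
    nulls = cfg.nulls if cfg.nulls is not None else default_null_rates()

    stage = "read inputs"
    try:
        annotations = read_annotation_table(cfg.annotations)
        models = read_transcript_models(cfg.transcripts, cfg.fasta)
        callable_bases = read_callable_summary(cfg.callable_summary)
        trios = []
        for vcf, ped in zip(cfg.vcfs, cfg.peds):
            pedigree = Pedigree.from_ped_file(ped)
            trios.extend(read_trio_vcf(vcf, pedigree))

        stage = "extract DNMs"
        records = extract_dnms(trios, annotations, cfg.filter_config)

        stage = "classify consequences"
        records = annotate_records(
            records,
            classify_fn=lambda site: classify_worst(site, models),
            panels=panels,
            damaging_fn=lambda ann, cls: is_predicted_damaging(
                ann, cls, cfg.damaging_criteria
            ),
            annotations=annotations,
        )
        write_dnm_table(records, outdir / "dnm_table.tsv")

        stage = "summarize and test burden"
        n_trios = len(cfg.vcfs)
        summary = summarize_cohort(
            records, n_trios, sum(callable_bases.values()), name="pipeline"
        )
        model = DNMBurdenModel(summary, nulls, dnms=records)
        results = model.fit(alternative=cfg.alternative)
        histogram = per_trio_histogram(summary)

        stage = "inherited screen"
        candidates = find_inherited_candidates(
            trios, annotations, panels, models=models,
            cfg=cfg.filter_config, crit=cfg.damaging_criteria,
        )
        _write_candidates(candidates, outdir / "inherited_candidates.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    payload = _results_json(results, summary, histogram, cfg.filter_config)
    payload["inherited_candidates"] = [
        {
            "trio_id": c.trio_id,
            "gene": c.gene,
            "mechanism": c.mechanism,
            "variants": [
                {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                 "origin": origin}
                for s, origin in c.variants
            ],
        }
        for c in candidates
    ]
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(results.summary() + "\n")
    return payload


def _write_candidates(candidates, path: Path) -> None:
    lines = ["trio_id\tgene\tmechanism\tchrom\tpos\tref\talt\torigin"]
    for c in candidates:
        for site, origin in c.variants:
            lines.append(
                f"{c.trio_id}\t{c.gene}\t{c.mechanism}\t{site.chrom}\t{site.pos}"
                f"\t{site.ref}\t{site.alt}\t{origin}"
            )
    path.write_text("\n".join(lines) + "\n")


def run_summary_only(
    summary: CohortSummary,
    nulls: Optional[NullRates] = None,
    alternative: str = "greater",
    outdir: Optional[str | Path] = None,
) -> dict:
    """Burden analysis from a class-count table alone (no VCF input)."""
    nulls = nulls if nulls is not None else default_null_rates()
    model = DNMBurdenModel(summary, nulls)
    results = model.fit(alternative=alternative)
    histogram = (
        per_trio_histogram(summary) if summary.per_trio_counts else {}
    )
    payload = _results_json(results, summary, histogram, FilterConfig())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
        (outdir / "report.txt").write_text(results.summary() + "\n")
    return payload
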