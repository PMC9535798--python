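"""End-to-end study orchestration.

run_study composes the stages: GTF parsing, per-factor replicate peak
reconciliation and binding classification, per-knockdown differential
expression, the 3x3 cross-classification with percentages, regulated-set
overlap between the two factors, optional term enrichment, scale-regions
metaprofiles, and the co-IP candidate funnel. A single summary JSON
mirrors the per-class bookkeeping tree (n, %, up/down/unchanged n and %)
plus the two-factor Venn counts; every threshold used is logged and
recorded in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from chipcross import expression, integrate, metaprofile, peaks, proteomics
from chipcross.genome import parse_gtf, read_chrom_sizes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_study"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one study run (JSON round-trippable)."""

    gtf: str
    output_dir: str
    peak_files: dict[str, list[str]] = field(default_factory=dict)
    counts_files: dict[str, str] = field(default_factory=dict)
    condition_map: str | None = None
    chrom_sizes: str | None = None
    coverage_files: dict[str, str] = field(default_factory=dict)
    quant_table: str | None = None
    term_annotation: str | None = None
    control_condition: str = "control"
    kd_conditions: dict[str, str] = field(default_factory=dict)
    promoter_upstream_bp: int = 350
    promoter_downstream_bp: int = 100
    max_neg_log10_q: float = 100.0
    fdr_threshold: float = 0.01
    pseudocount: float = 0.5
    ratio_min: float = 4.0
    psm_min_exclusive: int = 1
    target_categories: list[str] = field(
        default_factory=lambda: ["DNA binding", "chromatin regulation"]
    )
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def validate(self) -> None:
        missing = []
        for p in [self.gtf, self.condition_map, self.chrom_sizes,
                  self.quant_table, self.term_annotation]:
            if p is not None and not Path(p).exists():
                missing.append(p)
        for files in self.peak_files.values():
            missing += [f for f in files if not Path(f).exists()]
        for coll in (self.counts_files, self.coverage_files):
            missing += [f for f in coll.values() if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input files: {', '.join(map(str, missing))}"
            )


def run_study(config: PipelineConfig) -> dict:
    """Run every configured stage; returns (and writes) the summary dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = parse_gtf(config.gtf)
    universe = [g.gene_id for g in genes]
    sizes = (
        read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
    )
    logger.info(
        "universe: %d genes; promoter window -%d/+%d bp; q-filter %g; "
        "FDR %g",
        len(universe), config.promoter_upstream_bp,
        config.promoter_downstream_bp, config.max_neg_log10_q,
        config.fdr_threshold,
    )

    summary: dict = {
        "parameters": {
            "promoter_upstream_bp": config.promoter_upstream_bp,
            "promoter_downstream_bp": config.promoter_downstream_bp,
            "max_neg_log10_q": config.max_neg_log10_q,
            "fdr_threshold": config.fdr_threshold,
            "ratio_min": config.ratio_min,
            "psm_min_exclusive": config.psm_min_exclusive,
            "seed": config.seed,
        },
        "universe_size": len(universe),
        "factors": {},
    }

    cond_map = (
        expression.read_condition_map(config.condition_map)
        if config.condition_map else None
    )

    regulated_up: dict[str, set[str]] = {}
    for factor, rep_paths in sorted(config.peak_files.items()):
        reps = [
            peaks.filter_peaks_by_q(
                peaks.read_narrowpeak(p, label=f"{factor}_rep{i + 1}"),
                config.max_neg_log10_q,
            )
            for i, p in enumerate(rep_paths)
        ]
        if len(reps) == 2:
            common = peaks.common_peaks(reps[0], reps[1])
        elif len(reps) == 1:
            common = reps[0]
        else:
            raise ValueError(f"{factor}: expected 1 or 2 replicate files")
        peaks.write_narrowpeak(common, out / f"{factor}_common.narrowPeak")
        calls = peaks.assign_binding_class(
            genes, common, factor=factor,
            upstream_bp=config.promoter_upstream_bp,
            downstream_bp=config.promoter_downstream_bp,
            chrom_sizes=sizes,
        )
        peaks.write_binding_calls(calls, out / f"{factor}_binding.tsv")

        factor_summary: dict = {
            "n_common_peaks": len(common),
            "n_replicate_peaks": [len(r) for r in reps],
        }

        de_results = []
        if factor in config.counts_files:
            counts = expression.read_counts_tsv(
                config.counts_files[factor], cond_map
            )
            kd = config.kd_conditions.get(factor, f"{factor}_kd")
            group_a = counts.samples_for(config.control_condition)
            group_b = counts.samples_for(kd)
            if len(group_a) < 2 or len(group_b) < 2:
                raise ValueError(
                    f"{factor}: conditions {config.control_condition!r}/"
                    f"{kd!r} need >=2 samples each"
                )
            de_results = expression.de_test(
                counts, group_a, group_b,
                fdr_threshold=config.fdr_threshold,
                pseudocount=config.pseudocount,
            )
            expression.write_de_results(de_results, out / f"{factor}_de.tsv")

            table = integrate.cross_classify(
                calls, de_results, universe, factor=factor
            )
            integrate.write_regulation_tsv(
                table, out / f"{factor}_regulation.tsv"
            )
            factor_summary.update(table.summary())
            regulated_up[factor] = integrate.regulated_gene_set(table, "up")
            integrate.write_gene_set(
                regulated_up[factor], out / f"{factor}_regulated_up.txt"
            )

        if factor in config.coverage_files:
            if sizes is None:
                raise ValueError("metaprofile stage needs chrom_sizes")
            track = metaprofile.read_bedgraph(
                config.coverage_files[factor], sizes
            )
            matrix = metaprofile.scale_regions_matrix(track, genes)
            metaprofile.write_matrix_tsv(
                matrix.sorted_by_mean(), out / f"{factor}_metaprofile.tsv"
            )
            metaprofile.write_summary_tsv(
                metaprofile.summary_profile(matrix),
                out / f"{factor}_metaprofile_summary.tsv",
            )
            factor_summary["metaprofile_bins"] = matrix.scheme.n_bins

        summary["factors"][factor] = factor_summary

    if len(regulated_up) == 2:
        (fa, sa), (fb, sb) = sorted(regulated_up.items())
        ov = integrate.overlap_sets(sa, sb, label_a=fa, label_b=fb)
        integrate.write_overlap_report(ov, out / "regulated_overlap.json")
        summary["regulated_overlap"] = {
            "label_a": fa, "label_b": fb,
            "n_a": ov.size_a, "n_b": ov.size_b,
            "n_shared": len(ov.shared),
            "n_only_a": len(ov.only_a), "n_only_b": len(ov.only_b),
        }
        if config.term_annotation:
            annotation = integrate.read_term_annotation(
                config.term_annotation
            )
            enrichment = integrate.hypergeometric_enrichment(
                ov.shared, annotation, set(universe)
            )
            summary["enrichment"] = [
                {
                    "term_id": r.term_id,
                    "overlap": r.overlap,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
                for r in enrichment[:20]
            ]

    if config.quant_table:
        records = proteomics.read_quant_table(config.quant_table)
        candidates = proteomics.select_candidates(
            records, ratio_min=config.ratio_min,
            psm_min_exclusive=config.psm_min_exclusive,
        )
        proteomics.write_candidate_report(
            candidates, out / "copurify_candidates.tsv"
        )
        tagged = proteomics.categorize_candidates(
            candidates, None, set(config.target_categories)
        )
        summary["copurification"] = {
            "n_quantified": len(records),
            "n_candidates": len(candidates),
            "n_in_target_categories": len(tagged),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
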