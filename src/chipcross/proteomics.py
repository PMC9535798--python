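"""Quantitative co-IP interactor filtering.

The candidate funnel mirrors a bait-depletion AP-MS design: a protein is a
candidate interactor when its abundance drops more than four-fold after
knockdown of the bait (control/KD ratio strictly > 4; proteins detected
only in the control count as passing) and it has more than one
peptide-spectrum match. Ribosomal proteins and the bait itself are then
excluded, and the survivors are ranked by Sum Pep Score. A final
annotation step tags candidates whose category labels intersect a target
set (e.g. DNA binding / chromatin regulation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "ProteinQuant", "read_quant_table", "write_quant_table",
    "select_candidates", "categorize_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class ProteinQuant:
    protein_id: str
    sum_pep_score: float
    psm: int
    abundance_control: float
    abundance_kd: float
    is_ribosomal: bool = False
    is_bait: bool = False
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.psm < 0 or self.abundance_control < 0 or self.abundance_kd < 0:
            raise ValueError("psm and abundances must be non-negative")
        self.categories = frozenset(self.categories)


def select_candidates(
    records: list[ProteinQuant],
    ratio_min: float = 4.0,
    psm_min_exclusive: int = 1,
    zero_kd_passes: bool = True,
) -> list[ProteinQuant]:
    """Apply the abundance-ratio and PSM thresholds, then exclusions.

    Keeps records with control/KD abundance ratio strictly above
    ``ratio_min`` and psm strictly above ``psm_min_exclusive``; drops
    ribosomal proteins and the bait; orders by descending Sum Pep Score,
    ties by protein_id. A record with KD abundance 0 but control > 0 passes
    the ratio test when ``zero_kd_passes`` (an infinite ratio — detection
    only with the bait present); records with both abundances 0 are
    skipped with a warning.
    """
    kept: list[ProteinQuant] = []
    for rec in records:
        if rec.abundance_control == 0 and rec.abundance_kd == 0:
            logger.warning(
                "protein %s has zero abundance in both conditions; skipped",
                rec.protein_id,
            )
            continue
        if rec.abundance_kd == 0:
            ratio_ok = zero_kd_passes and rec.abundance_control > 0
        else:
            ratio_ok = rec.abundance_control / rec.abundance_kd > ratio_min
        if not ratio_ok or rec.psm <= psm_min_exclusive:
            continue
        if rec.is_ribosomal or rec.is_bait:
            continue
        kept.append(rec)
    kept.sort(key=lambda r: (-r.sum_pep_score, r.protein_id))
    return kept


def categorize_candidates(
    candidates: list[ProteinQuant],
    annotation: dict[str, set[str]] | None,
    target_categories: set[str],
) -> list[ProteinQuant]:
    """Candidates whose categories intersect ``target_categories``.

    ``annotation`` optionally overrides/extends each record's own category
    labels. Candidates with no annotation at all are reported (logged) as
    unannotated rather than silently dropped from consideration.
    """
    tagged: list[ProteinQuant] = []
    for rec in candidates:
        cats = set(rec.categories)
        if annotation is not None:
            cats |= annotation.get(rec.protein_id, set())
        if not cats:
            logger.warning("candidate %s is unannotated", rec.protein_id)
        if cats & set(target_categories):
            tagged.append(rec)
    return tagged


def read_quant_table(path) -> list[ProteinQuant]:
    """Quant TSV: protein_id, sum_pep_score, psm, abundance_control,
    abundance_kd, is_ribosomal, is_bait, categories (comma-separated)."""
    records: list[ProteinQuant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "protein_id", "sum_pep_score", "psm", "abundance_control",
            "abundance_kd", "is_ribosomal", "is_bait", "categories",
        ]
        if header != expected:
            raise ValueError(f"quant table header must be {expected}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                ProteinQuant(
                    protein_id=f[0],
                    sum_pep_score=float(f[1]),
                    psm=int(f[2]),
                    abundance_control=float(f[3]),
                    abundance_kd=float(f[4]),
                    is_ribosomal=f[5] == "1",
                    is_bait=f[6] == "1",
                    categories=frozenset(
                        c for c in f[7].split(",") if c
                    ),
                )
            )
    return records


def write_quant_table(records: list[ProteinQuant], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tsum_pep_score\tpsm\tabundance_control\t"
            "abundance_kd\tis_ribosomal\tis_bait\tcategories\n"
        )
        for r in records:
            fh.write(
                f"{r.protein_id}\t{r.sum_pep_score:g}\t{r.psm}\t"
                f"{r.abundance_control:g}\t{r.abundance_kd:g}\t"
                f"{int(r.is_ribosomal)}\t{int(r.is_bait)}\t"
                f"{','.join(sorted(r.categories))}\n"
            )


def write_candidate_report(candidates: list[ProteinQuant], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tprotein_id\tsum_pep_score\tpsm\tratio\tcategories\n")
        for i, r in enumerate(candidates, start=1):
            ratio = (
                "inf" if r.abundance_kd == 0
                else f"{r.abundance_control / r.abundance_kd:g}"
            )
            fh.write(
                f"{i}\t{r.protein_id}\t{r.sum_pep_score:g}\t{r.psm}\t"
                f"{ratio}\t{','.join(sorted(r.categories))}\n"
            )
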