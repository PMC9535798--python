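"""Crossing binding with expression: the 3x3 regulation table and friends.

The regulation table is the central bookkeeping object: every gene in the
universe carries exactly one (binding class, expression class) pair, and
the 3x3 count matrix over {promoter, nonpromoter_genic, unbound} x
{up, down, unchanged} partitions the universe. Regulated gene sets (bound
and up- or downregulated), pairwise set overlaps, hypergeometric term
enrichment, and the ellipsoid brain-lobe volume live here too.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from chipcross.expression import EXPR_CLASSES, DEResult, bh_adjust
from chipcross.peaks import BINDING_CLASSES, BindingCall

__all__ = [
    "RegulationTable", "GeneSetOverlap", "EnrichmentResult",
    "LobeMeasurement", "cross_classify", "percent_of_group",
    "regulated_gene_set", "overlap_sets", "hypergeometric_enrichment",
    "ellipsoid_volume",
]


@dataclass
class RegulationTable:
    """Per-gene (binding, expression) assignment plus the 3x3 count matrix."""

    factor: str
    per_gene: dict[str, tuple[str, str]]
    universe_size: int = 0

    def __post_init__(self) -> None:
        if self.universe_size == 0:
            self.universe_size = len(self.per_gene)
        if self.universe_size != len(self.per_gene):
            raise ValueError("universe_size must equal the assignment count")

    def count(self, binding_class: str, expr_class: str) -> int:
        return sum(
            1 for b, e in self.per_gene.values()
            if b == binding_class and e == expr_class
        )

    @property
    def counts(self) -> list[list[int]]:
        """Rows = binding classes, columns = up/down/unchanged."""
        return [
            [self.count(b, e) for e in EXPR_CLASSES] for b in BINDING_CLASSES
        ]

    def binding_count(self, binding_class: str) -> int:
        return sum(1 for b, _ in self.per_gene.values() if b == binding_class)

    def summary(self) -> dict:
        """Nested per-binding-class summary with percentages.

        Binding-class percentages are of the universe; expression-class
        percentages are within each binding class (the convention of the
        published bookkeeping).
        """
        out: dict = {
            "factor": self.factor,
            "universe_size": self.universe_size,
            "classes": {},
        }
        for b in BINDING_CLASSES:
            nb = self.binding_count(b)
            entry = {
                "n": nb,
                "pct_of_universe": percent_of_group(nb, self.universe_size),
            }
            for e in EXPR_CLASSES:
                k = self.count(b, e)
                entry[e] = {
                    "n": k,
                    "pct_of_class": percent_of_group(k, nb) if nb else None,
                }
            out["classes"][b] = entry
        bound = self.binding_count("promoter") + self.binding_count(
            "nonpromoter_genic"
        )
        out["bound"] = {
            "n": bound,
            "pct_of_universe": percent_of_group(bound, self.universe_size),
        }
        return out


@dataclass
class GeneSetOverlap:
    """Venn-style decomposition of two gene sets."""

    only_a: set[str]
    shared: set[str]
    only_b: set[str]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if (self.only_a & self.shared) or (self.only_b & self.shared) or (
            self.only_a & self.only_b
        ):
            raise ValueError("overlap parts must be pairwise disjoint")

    @property
    def size_a(self) -> int:
        return len(self.only_a) + len(self.shared)

    @property
    def size_b(self) -> int:
        return len(self.only_b) + len(self.shared)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_size_in_universe: int
    query_size: int
    overlap: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.term_size_in_universe, self.query_size):
            raise ValueError("overlap exceeds term/query size")


@dataclass(frozen=True)
class LobeMeasurement:
    """Brain-lobe semiaxes: a = major, b = minor (same length units)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b < 0 or self.a < self.b:
            raise ValueError("require a >= b >= 0")


def cross_classify(
    binding: list[BindingCall],
    expr: list[DEResult],
    universe: list[str],
    factor: str | None = None,
) -> RegulationTable:
    """Build the 3x3 regulation table over ``universe``.

    Every universe gene must carry a binding call; genes missing from the
    DE results are classed "unchanged" (they were typically filtered as
    all-zero upstream).
    """
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate gene ids in universe")
    bind_by_gene = {c.gene_id: c for c in binding}
    if len(bind_by_gene) != len(binding):
        raise ValueError("duplicate gene ids in binding calls")
    expr_by_gene = {r.gene_id: r for r in expr}
    if len(expr_by_gene) != len(expr):
        raise ValueError("duplicate gene ids in DE results")
    missing = [g for g in universe if g not in bind_by_gene]
    if missing:
        raise ValueError(
            f"{len(missing)} universe genes lack binding calls, "
            f"e.g. {missing[:3]}"
        )
    per_gene: dict[str, tuple[str, str]] = {}
    for gid in universe:
        b = bind_by_gene[gid].binding_class
        e = expr_by_gene[gid].expr_class if gid in expr_by_gene else "unchanged"
        per_gene[gid] = (b, e)
    return RegulationTable(
        factor=factor or (binding[0].factor if binding else "factor"),
        per_gene=per_gene,
    )


def percent_of_group(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded half-away-from-zero to ``decimals`` places."""
    if n <= 0:
        raise ValueError("group size must be positive")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    q = Decimal(100 * k) / Decimal(n)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def regulated_gene_set(table: RegulationTable, direction: str) -> set[str]:
    """Genes bound by the factor (promoter or genic) and regulated in
    ``direction`` ("up" or "down") upon its depletion."""
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    return {
        gid
        for gid, (b, e) in table.per_gene.items()
        if b in {"promoter", "nonpromoter_genic"} and e == direction
    }


def overlap_sets(
    a: set[str], b: set[str], label_a: str = "A", label_b: str = "B"
) -> GeneSetOverlap:
    a, b = set(a), set(b)
    return GeneSetOverlap(
        only_a=a - b, shared=a & b, only_b=b - a,
        label_a=label_a, label_b=label_b,
    )


def hypergeometric_enrichment(
    query: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    Terms are restricted to the universe; terms with no universe members
    are skipped. BH adjustment is across the tested terms. Results are
    sorted by ascending p, ties by term_id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not set(query) <= universe:
        raise ValueError("query must be a subset of the universe")
    query = set(query)
    rows = []
    for term_id in sorted(annotation):
        members = annotation[term_id] & universe
        if not members:
            continue
        k = len(query & members)
        # P(overlap >= k) with M = |universe|, n = |term|, N = |query|
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(members), len(query))
        )
        rows.append((term_id, len(members), k, min(p, 1.0)))
    qvals = bh_adjust([r[3] for r in rows]) if rows else []
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_size_in_universe=nterm,
            query_size=len(query),
            overlap=k,
            p_value=p,
            q_value=float(q),
        )
        for (term_id, nterm, k, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def ellipsoid_volume(m: LobeMeasurement) -> float:
    """Prolate-spheroid volume V = (4/3) * pi * a * b^2."""
    return (4.0 / 3.0) * math.pi * m.a * m.b**2


# --- report I/O -------------------------------------------------------------


def write_regulation_report(table: RegulationTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(table.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_regulation_tsv(table: RegulationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbinding_class\texpr_class\n")
        for gid in sorted(table.per_gene):
            b, e = table.per_gene[gid]
            fh.write(f"{gid}\t{b}\t{e}\n")


def write_overlap_report(ov: GeneSetOverlap, path) -> None:
    payload = {
        "label_a": ov.label_a,
        "label_b": ov.label_b,
        "n_a": ov.size_a,
        "n_b": ov.size_b,
        "n_shared": len(ov.shared),
        "n_only_a": len(ov.only_a),
        "n_only_b": len(ov.only_b),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_gene_set(path) -> set[str]:
    """One gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: set[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_term_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> term membership map."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, gene = line.split("\t")
            out.setdefault(term, set()).add(gene)
    return out
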