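"""Count normalization and negative-binomial differential expression.

The differential test is a deliberately simple NB Wald test, not a DESeq2
re-implementation: counts are scaled by median-of-ratios size factors,
per-gene dispersion is estimated by method of moments and moderated toward
the across-gene median, and the knockdown/control log2 ratio is tested
against a normal reference using the delta-method variance of the log
ratio under Var(X) = mu + alpha*mu^2. Genes are classed "up" or "down" at
BH FDR < 0.01 by the sign of the fold change, everything else "unchanged".

Why moderate the dispersion: with three replicates per condition the raw
method-of-moments estimate collapses to the floor for roughly half of all
genes (sample variance below the mean), which makes a per-gene Wald test
badly anti-conservative. Taking the elementwise maximum of the per-gene
estimate and the across-gene median keeps genuine high-dispersion genes
conservative while restoring calibration for the rest — the same idea
(share dispersion information across genes) that DESeq2 and edgeR apply
with more machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix", "DEResult", "EXPR_CLASSES", "rpm_normalize", "fpkm",
    "size_factors", "estimate_dispersion", "de_test", "bh_adjust",
    "read_counts_tsv", "write_counts_tsv", "write_de_results",
    "read_de_results",
]

EXPR_CLASSES = ("up", "down", "unchanged")

ALPHA_FLOOR = 1e-8
DEFAULT_FDR = 0.01
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Gene x sample raw counts with per-sample condition labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    conditions: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints
    library_sizes: np.ndarray | None = None  # defaults to column sums

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match ids")
        if len(self.conditions) != len(self.sample_ids):
            raise ValueError("one condition label per sample required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if np.any(self.library_sizes < self.counts.sum(axis=0) - 1e-6):
                raise ValueError(
                    "library_sizes must cover the column count sums"
                )

    def columns(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.counts[:, idx]

    def samples_for(self, condition: str) -> list[str]:
        return [
            s for s, c in zip(self.sample_ids, self.conditions)
            if c == condition
        ]


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p_value: float
    q_value: float
    expr_class: str

    def __post_init__(self) -> None:
        if self.expr_class not in EXPR_CLASSES:
            raise ValueError(f"unknown expr class {self.expr_class!r}")


def rpm_normalize(counts: CountMatrix) -> np.ndarray:
    """Reads per million mapped reads: count * 1e6 / library size."""
    if np.any(counts.library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    return counts.counts * 1e6 / counts.library_sizes[None, :]


def fpkm(counts: CountMatrix, gene_lengths: dict[str, float]) -> np.ndarray:
    """Fragments per kilobase per million: count * 1e9 / (libsize * length)."""
    if np.any(counts.library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths, e.g. {missing[:3]}")
    lengths = np.array([gene_lengths[g] for g in counts.gene_ids], float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    return counts.counts * 1e9 / (
        counts.library_sizes[None, :] * lengths[:, None]
    )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per column.

    Ratios are taken to the geometric mean over samples, using only genes
    with all-positive counts; when fewer than 10 such genes exist the
    factors fall back to library-size scaling (column sum / mean column
    sum).
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= 10:
        logc = np.log(counts[positive])
        geo = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - geo, axis=0))
    else:
        colsum = counts.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError("cannot derive size factors from empty columns")
        sf = colsum / colsum.mean()
    return sf


def estimate_dispersion(
    normalized: np.ndarray,
    condition_index: list[np.ndarray] | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> np.ndarray:
    """Method-of-moments NB dispersion per gene.

    Within each condition alpha = max(floor, (var - mean) / mean^2); the
    per-condition estimates are pooled by a normalized-count-weighted
    average. All-zero genes get NaN (excluded from testing downstream).
    """
    normalized = np.atleast_2d(np.asarray(normalized, dtype=float))
    if condition_index is None:
        condition_index = [np.arange(normalized.shape[1])]
    alphas = np.zeros((normalized.shape[0], len(condition_index)))
    weights = np.zeros_like(alphas)
    for j, idx in enumerate(condition_index):
        block = normalized[:, idx]
        mean = block.mean(axis=1)
        var = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / mean**2
        alphas[:, j] = np.where(mean > 0, np.maximum(a, alpha_floor), np.nan)
        weights[:, j] = block.sum(axis=1)
    total = weights.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pooled = np.nansum(alphas * weights, axis=1) / total
    pooled = np.where(total > 0, np.maximum(pooled, alpha_floor), np.nan)
    return pooled


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    fdr_threshold: float = DEFAULT_FDR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    moderate_dispersion: bool = True,
) -> list[DEResult]:
    """NB Wald differential expression of group_b (KD) over group_a (control).

    Returns one DEResult per gene in input order. All-zero genes are
    reported with log2fc 0, p = q = 1, class "unchanged".
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    raw = counts.columns(group_a + group_b)
    sf = size_factors(raw)
    norm = raw / sf[None, :]
    na, nb = len(group_a), len(group_b)
    idx_a, idx_b = np.arange(na), np.arange(na, na + nb)

    alpha = estimate_dispersion(norm, [idx_a, idx_b])
    testable = ~np.isnan(alpha)
    if moderate_dispersion and testable.sum() > 0:
        alpha_trend = float(np.median(alpha[testable]))
        alpha = np.where(testable, np.maximum(alpha, alpha_trend), alpha)

    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.where(
        testable,
        np.log2((mean_b + pseudocount) / (mean_a + pseudocount)),
        0.0,
    )

    # delta method: Var(log2 mean) ~= Var(mean) / (ln2 * (mean+pc))^2, with
    # NB Var(mean over n reps) = (mu + alpha mu^2) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a = (mean_a + alpha * mean_a**2) / na
        var_b = (mean_b + alpha * mean_b**2) / nb
        se2 = (
            var_a / (mean_a + pseudocount) ** 2
            + var_b / (mean_b + pseudocount) ** 2
        ) / np.log(2) ** 2
        z = np.where((se2 > 0) & testable, log2fc / np.sqrt(se2), 0.0)
    p = np.where(testable, 2 * stats.norm.sf(np.abs(z)), 1.0)

    q = np.ones_like(p)
    if testable.any():
        q[testable] = bh_adjust(p[testable])

    results = []
    for i, gid in enumerate(counts.gene_ids):
        if q[i] < fdr_threshold and log2fc[i] > 0:
            cls = "up"
        elif q[i] < fdr_threshold and log2fc[i] < 0:
            cls = "down"
        else:
            cls = "unchanged"
        results.append(
            DEResult(
                gene_id=gid,
                base_mean=float(base_mean[i]),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                expr_class=cls,
            )
        )
    return results


# --- TSV I/O ----------------------------------------------------------------


def read_counts_tsv(path, condition_map: dict[str, str] | None = None) -> CountMatrix:
    """Genes x samples count TSV (first column gene_id, header = sample ids).

    ``condition_map`` assigns each sample id a condition label; without it
    every sample gets condition "unknown".
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    sample_ids = [str(c) for c in df.columns]
    conditions = [
        condition_map.get(s, "unknown") if condition_map else "unknown"
        for s in sample_ids
    ]
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        conditions=conditions,
        counts=df.to_numpy(dtype=np.int64),
    )


def write_counts_tsv(counts: CountMatrix, path) -> None:
    df = pd.DataFrame(
        counts.counts, index=counts.gene_ids, columns=counts.sample_ids
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_condition_map(path) -> dict[str, str]:
    """Two-column TSV sample_id -> condition."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, cond = line.split("\t")
            out[sample] = cond
    return out


def write_de_results(results: list[DEResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbase_mean\tlog2fc\tp_value\tq_value\texpr_class\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.base_mean:.6g}\t{r.log2fc:.6g}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{r.expr_class}\n"
            )


def read_de_results(path) -> list[DEResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEResult(
            gene_id=str(row.gene_id),
            base_mean=float(row.base_mean),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
            expr_class=str(row.expr_class),
        )
        for row in df.itertuples()
    ]
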