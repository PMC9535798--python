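"""narrowPeak ingestion, replicate reconciliation, binding classification.

The replicate-reconciliation rule keeps *common* peaks, not merged ones:
every overlapping pair between the two replicate peak sets contributes the
intersection interval, carrying the smaller -log10(q) of the pair. A
hyper-significance filter removes peaks whose -log10(q) exceeds a cutoff
(default 100); the cutoff is configurable because such extreme q-values are
typically pile-up artifacts rather than bona fide sites.

Binding classification is per gene with promoter precedence: a peak
anywhere in any promoter window makes the gene "promoter"; otherwise a peak
anywhere in the gene span (introns included) makes it "nonpromoter_genic";
otherwise "unbound". Peaks are strandless and may support several genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from chipcross.genome import (
    DEFAULT_DOWNSTREAM_BP,
    DEFAULT_UPSTREAM_BP,
    GeneModel,
    GenomicInterval,
    promoter_windows,
)

__all__ = [
    "Peak", "PeakSet", "BindingCall", "BINDING_CLASSES",
    "read_narrowpeak", "write_narrowpeak", "filter_peaks_by_q",
    "common_peaks", "assign_binding_class", "classify_by_tss_distance",
    "replicate_correlation", "peak_tss_distance",
]

logger = logging.getLogger(__name__)

BINDING_CLASSES = ("promoter", "nonpromoter_genic", "unbound")


@dataclass(frozen=True)
class Peak:
    """One ChIP peak interval with its MACS2-style statistics."""

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal: float = 0.0
    neg_log10_p: float = 0.0
    neg_log10_q: float = 0.0
    summit_offset: int = -1  # bp from start; -1 when absent

    def __post_init__(self) -> None:
        if self.neg_log10_q < 0:
            raise ValueError("neg_log10_q must be >= 0")
        if self.summit_offset >= len(self.interval):
            raise ValueError("summit_offset beyond peak end")


@dataclass
class PeakSet:
    """Peaks of one replicate/factor, kept sorted by (chrom, start)."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start,
                                       p.interval.end, p.name))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(p)
        return out


@dataclass
class BindingCall:
    """Per-gene, per-factor binding classification with evidence."""

    gene_id: str
    factor: str
    binding_class: str
    supporting_peaks: list[str] = field(default_factory=list)
    min_tss_distance: int | None = None

    def __post_init__(self) -> None:
        if self.binding_class not in BINDING_CLASSES:
            raise ValueError(f"unknown binding class {self.binding_class!r}")
        if (self.binding_class == "unbound") != (not self.supporting_peaks):
            raise ValueError(
                "unbound calls must have no supporting peaks and vice versa"
            )


def read_narrowpeak(path, label: str | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file into a sorted PeakSet."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path} line {lineno}: narrowPeak needs 10 columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, _strand = fields[:6]
            signal, neg_p, neg_q, summit = fields[6:]
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    name=name,
                    score=0 if score == "." else int(score),
                    signal=float(signal),
                    neg_log10_p=float(neg_p),
                    neg_log10_q=float(neg_q),
                    summit_offset=int(summit),
                )
            )
    return PeakSet(label=label or str(path), peaks=peaks)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    """Write a PeakSet in bit-exact narrowPeak column order."""
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score}\t.\t"
                f"{p.signal:.10g}\t{p.neg_log10_p:.10g}\t"
                f"{p.neg_log10_q:.10g}\t{p.summit_offset}\n"
            )


def write_bed3(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def filter_peaks_by_q(
    peakset: PeakSet, max_neg_log10_q: float = 100.0
) -> PeakSet:
    """Drop hyper-significant peaks with -log10(q) strictly above the cutoff."""
    kept = [p for p in peakset if p.neg_log10_q <= max_neg_log10_q]
    return PeakSet(label=peakset.label, peaks=kept)


def common_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Common (intersection) peaks between two replicates.

    Every strictly overlapping rep1 x rep2 pair yields one output peak whose
    interval is the intersection and whose -log10(q) (and display score) is
    the minimum of the pair. Abutting intervals do not count. One rep1 peak
    overlapping two rep2 peaks therefore yields two common peaks.
    """
    out: list[Peak] = []
    by2 = rep2.by_chrom()
    for chrom, peaks1 in rep1.by_chrom().items():
        peaks2 = by2.get(chrom, [])
        j0 = 0
        for p1 in peaks1:
            # sorted sweep: advance past rep2 peaks entirely left of p1
            while j0 < len(peaks2) and peaks2[j0].interval.end <= p1.interval.start:
                j0 += 1
            j = j0
            while j < len(peaks2) and peaks2[j].interval.start < p1.interval.end:
                p2 = peaks2[j]
                j += 1
                lo = max(p1.interval.start, p2.interval.start)
                hi = min(p1.interval.end, p2.interval.end)
                if lo >= hi:
                    continue
                out.append(
                    Peak(
                        interval=GenomicInterval(chrom, lo, hi),
                        name=f"{p1.name}&{p2.name}",
                        score=min(p1.score, p2.score),
                        signal=min(p1.signal, p2.signal),
                        neg_log10_p=min(p1.neg_log10_p, p2.neg_log10_p),
                        neg_log10_q=min(p1.neg_log10_q, p2.neg_log10_q),
                        summit_offset=-1,
                    )
                )
    return PeakSet(label=f"{rep1.label}∩{rep2.label}", peaks=out)


def merged_peaks(*peaksets: PeakSet) -> PeakSet:
    """Union-merge of the intervals of one or more peak sets.

    Overlapping or abutting intervals collapse into one; statistics are the
    max over the merged members. This is the "merged peaks" geometry used
    only as the region set for replicate-correlation checks, never for
    classification (classification uses :func:`common_peaks`).
    """
    all_peaks = sorted(
        (p for ps in peaksets for p in ps),
        key=lambda p: (p.interval.chrom, p.interval.start),
    )
    out: list[Peak] = []
    for p in all_peaks:
        if (
            out
            and out[-1].interval.chrom == p.interval.chrom
            and p.interval.start <= out[-1].interval.end
        ):
            last = out[-1]
            out[-1] = Peak(
                interval=GenomicInterval(
                    last.interval.chrom,
                    last.interval.start,
                    max(last.interval.end, p.interval.end),
                ),
                name=last.name,
                score=max(last.score, p.score),
                signal=max(last.signal, p.signal),
                neg_log10_p=max(last.neg_log10_p, p.neg_log10_p),
                neg_log10_q=max(last.neg_log10_q, p.neg_log10_q),
                summit_offset=-1,
            )
        else:
            out.append(replace(p, summit_offset=-1))
    return PeakSet(label="merged", peaks=out)


def _peak_trees(peakset: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peakset:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )
    return trees


def peak_tss_distance(peak: Peak, tss_positions: list[int]) -> int:
    """Distance from a peak to the nearest TSS: 0 if a TSS lies inside the
    peak, else the gap to the nearest peak edge."""
    best = None
    for t in tss_positions:
        if peak.interval.contains(t):
            return 0
        d = peak.interval.start - t if t < peak.interval.start else t - peak.interval.end
        if best is None or d < best:
            best = d
    if best is None:
        raise ValueError("no TSS positions given")
    return best


def assign_binding_class(
    genes: list[GeneModel],
    peaks: PeakSet,
    factor: str = "factor",
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    chrom_sizes: dict[str, int] | None = None,
) -> list[BindingCall]:
    """Classify every gene as promoter / nonpromoter_genic / unbound.

    The promoter of a gene is the union of the windows over all its
    transcript TSSs. A single peak may support calls for multiple genes.
    Peaks on chromosomes absent from the annotation are ignored with a
    logged warning.
    """
    trees = _peak_trees(peaks)
    known_chroms = {g.span.chrom for g in genes}
    for chrom in set(trees) - known_chroms:
        logger.warning(
            "peaks on chromosome %s have no annotated genes; ignored", chrom
        )

    calls: list[BindingCall] = []
    for gene in genes:
        chrom = gene.span.chrom
        tree = trees.get(chrom)
        clen = chrom_sizes.get(chrom) if chrom_sizes else None
        windows = promoter_windows(gene, upstream_bp, downstream_bp, clen)
        hits: dict[str, Peak] = {}
        promoter_hit = False
        for w in windows:
            for node in tree.overlap(w.interval.start, w.interval.end) if tree else ():
                hits[node.data.name] = node.data
                promoter_hit = True
        if not promoter_hit and tree is not None:
            for node in tree.overlap(gene.span.start, gene.span.end):
                hits[node.data.name] = node.data
        if promoter_hit:
            cls = "promoter"
        elif hits:
            cls = "nonpromoter_genic"
        else:
            cls = "unbound"
        min_d: int | None = None
        if hits:
            tss = gene.tss_positions
            min_d = min(peak_tss_distance(p, tss) for p in hits.values())
        calls.append(
            BindingCall(
                gene_id=gene.gene_id,
                factor=factor,
                binding_class=cls,
                supporting_peaks=sorted(hits),
                min_tss_distance=min_d,
            )
        )
    return calls


def classify_by_tss_distance(
    genes: list[GeneModel],
    peaks: PeakSet,
    bin_edges: list[int],
    **kwargs,
) -> dict[str, int]:
    """Assign each bound gene a TSS-distance bin.

    ``bin_edges`` must be strictly increasing; a gene with minimum
    peak-to-nearest-TSS distance d gets bin i such that
    edges[i] <= d < edges[i+1], with distances below the first edge in bin
    -1... in practice pass edges starting at 0. Distances at or beyond the
    last edge land in the final open bin len(edges)-1.
    """
    edges = np.asarray(bin_edges)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    calls = assign_binding_class(genes, peaks, **kwargs)
    out: dict[str, int] = {}
    for call in calls:
        if call.binding_class == "unbound":
            continue
        assert call.min_tss_distance is not None
        out[call.gene_id] = int(
            np.searchsorted(edges, call.min_tss_distance, side="right") - 1
        )
    return out


def replicate_correlation(cov1, cov2) -> float:
    """Pearson correlation between paired per-region read counts.

    Raises ValueError on mismatched lengths or when either vector has zero
    variance (correlation undefined).
    """
    x = np.asarray(cov1, dtype=float)
    y = np.asarray(cov2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("replicate vectors must be 1-D and equal length")
    if x.size < 2 or np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def write_binding_calls(calls: list[BindingCall], path) -> None:
    """Binding-call TSV: gene_id, factor, class, n_peaks, min_tss_distance."""
    with open(path, "w") as fh:
        fh.write("gene_id\tfactor\tbinding_class\tn_peaks\tmin_tss_distance\n")
        for c in calls:
            d = "" if c.min_tss_distance is None else str(c.min_tss_distance)
            fh.write(
                f"{c.gene_id}\t{c.factor}\t{c.binding_class}\t"
                f"{len(c.supporting_peaks)}\t{d}\n"
            )


def read_binding_calls(path) -> list[BindingCall]:
    calls: list[BindingCall] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id\t"):
            raise ValueError("binding-call TSV missing header")
        for line in fh:
            gid, factor, cls, n_peaks, d = line.rstrip("\n").split("\t")
            n = int(n_peaks)
            calls.append(
                BindingCall(
                    gene_id=gid,
                    factor=factor,
                    binding_class=cls,
                    # peak names are not persisted; keep placeholders so the
                    # unbound <-> no-evidence invariant survives round trips
                    supporting_peaks=[f"peak{i}" for i in range(n)],
                    min_tss_distance=int(d) if d else None,
                )
            )
    return calls
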