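"""Scale-regions coverage metaprofiles over gene bodies with fixed flanks.

Each gene contributes one row: a fixed-width upstream flank (default 3 kb
in 50 bp bins), the gene body resampled to a constant virtual length
(default 5 kb -> 100 bins) by fractional-base averaging, and a fixed
downstream flank. Rows of minus-strand genes are orientation-flipped so
column 0 is always the 5'-most bin. Flank positions beyond the chromosome
ends contribute zeros.

Fractional-base averaging: body bin i covers genomic range
[L*i/100, L*(i+1)/100) in gene-local bases (L = gene length); partial
bases at the bin edges are weighted by the covered fraction, computed
exactly from the cumulative sum of the per-base signal. This makes the
mean of the body bins equal the mean per-base coverage of the body
exactly, and avoids aliasing on genes shorter than one bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chipcross.genome import GeneModel

__all__ = [
    "CoverageTrack", "MetaMatrix", "BinScheme", "read_bedgraph",
    "write_bedgraph", "scale_regions_matrix", "summary_profile",
]


@dataclass(frozen=True)
class BinScheme:
    upstream_bp: int = 3000
    body_target_bp: int = 5000
    downstream_bp: int = 3000
    bin_bp: int = 50

    def __post_init__(self) -> None:
        for v in (self.upstream_bp, self.body_target_bp, self.downstream_bp):
            if v % self.bin_bp:
                raise ValueError("region lengths must be multiples of bin_bp")

    @property
    def n_upstream(self) -> int:
        return self.upstream_bp // self.bin_bp

    @property
    def n_body(self) -> int:
        return self.body_target_bp // self.bin_bp

    @property
    def n_downstream(self) -> int:
        return self.downstream_bp // self.bin_bp

    @property
    def n_bins(self) -> int:
        return self.n_upstream + self.n_body + self.n_downstream


@dataclass
class CoverageTrack:
    """Dense per-base signal per chromosome (float32 to keep genomes cheap)."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=np.float32)
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.values[chrom] = arr

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom])

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end), zero-padded outside bounds."""
        arr = self.values[chrom]
        out = np.zeros(end - start, dtype=np.float64)
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start: hi - start] = arr[lo:hi]
        return out


@dataclass
class MetaMatrix:
    gene_ids: list[str]
    scores: np.ndarray  # rows x n_bins
    scheme: BinScheme = field(default_factory=BinScheme)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.gene_ids), self.scheme.n_bins):
            raise ValueError("scores shape does not match ids/scheme")

    def sorted_by_mean(self) -> "MetaMatrix":
        """Heatmap row order: descending row mean, original ids retained."""
        order = np.argsort(-self.scores.mean(axis=1), kind="stable")
        return MetaMatrix(
            gene_ids=[self.gene_ids[i] for i in order],
            scores=self.scores[order],
            scheme=self.scheme,
        )


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Dense per-base track from a bedGraph; uncovered bases are zero.

    Overlapping bedGraph intervals are rejected as an ill-formed track.
    """
    values = {
        chrom: np.zeros(length, dtype=np.float32)
        for chrom, length in chrom_sizes.items()
    }
    covered_until: dict[str, int] = {}
    last_sorted = True
    seen: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s, val_s = line.split("\t")
            start, end, val = int(start_s), int(end_s), float(val_s)
            if chrom not in values:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom}")
            if not (0 <= start < end <= len(values[chrom])):
                raise ValueError(
                    f"line {lineno}: interval outside chromosome bounds"
                )
            seen.setdefault(chrom, []).append((start, end))
            values[chrom][start:end] = val
    for chrom, ivs in seen.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping bedGraph intervals on {chrom}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
    return CoverageTrack(values=values)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encode the dense track back to bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in track.values:
            arr = np.asarray(track.values[chrom], dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _resample_body(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a per-base signal into n_bins equal fractional-width bins."""
    L = vals.size
    # cumulative integral of the base-level step function at integer knots
    cum = np.concatenate(([0.0], np.cumsum(vals)))
    edges = np.linspace(0.0, L, n_bins + 1)
    integ = np.interp(edges, np.arange(L + 1), cum)
    widths = np.diff(edges)
    return np.diff(integ) / widths


def scale_regions_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    scheme: BinScheme | None = None,
) -> MetaMatrix:
    """Scale-regions matrix: per-gene [upstream | scaled body | downstream]."""
    scheme = scheme or BinScheme()
    rows = np.empty((len(genes), scheme.n_bins), dtype=np.float64)
    for i, gene in enumerate(genes):
        span = gene.span
        vals = track.window(
            span.chrom,
            span.start - scheme.upstream_bp,
            span.end + scheme.downstream_bp,
        )
        if gene.strand == "-":
            vals = vals[::-1]
        up = vals[: scheme.upstream_bp]
        body = vals[scheme.upstream_bp: scheme.upstream_bp + len(span)]
        down = vals[scheme.upstream_bp + len(span):]
        rows[i, : scheme.n_upstream] = up.reshape(
            scheme.n_upstream, scheme.bin_bp
        ).mean(axis=1)
        rows[i, scheme.n_upstream: scheme.n_upstream + scheme.n_body] = (
            _resample_body(body, scheme.n_body)
        )
        rows[i, scheme.n_upstream + scheme.n_body:] = down.reshape(
            scheme.n_downstream, scheme.bin_bp
        ).mean(axis=1)
    return MetaMatrix(
        gene_ids=[g.gene_id for g in genes], scores=rows, scheme=scheme
    )


def summary_profile(matrix: MetaMatrix) -> np.ndarray:
    """Average profile: column means over all rows."""
    if matrix.scores.shape[0] == 0:
        raise ValueError("empty metaprofile matrix")
    return matrix.scores.mean(axis=0)


def write_matrix_tsv(matrix: MetaMatrix, path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"bin{i}" for i in range(matrix.scheme.n_bins))
        fh.write(f"gene_id\t{cols}\n")
        for gid, row in zip(matrix.gene_ids, matrix.scores):
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_summary_tsv(profile: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tmean_score\n")
        for i, v in enumerate(profile):
            fh.write(f"{i}\t{v:.6g}\n")
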