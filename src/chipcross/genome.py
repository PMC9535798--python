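"""Gene annotation model: GTF parsing, promoter windows, TSS geometry.

Internal coordinates are 0-based half-open throughout; GTF's 1-based closed
convention is converted at the I/O boundary and nowhere else. A gene's
promoter is modelled per transcript TSS as a fixed window running
``upstream_bp`` (default 350) upstream of the TSS to ``downstream_bp``
(default 100) downstream, the TSS base included on the downstream side, so
the default window is exactly 450 bp on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval", "TranscriptModel", "GeneModel", "PromoterWindow",
    "GtfParseError", "parse_gtf", "write_gtf", "promoter_windows",
    "nearest_tss_distance", "read_chrom_sizes", "write_chrom_sizes",
]

DEFAULT_UPSTREAM_BP = 350
DEFAULT_DOWNSTREAM_BP = 100


class GtfParseError(ValueError):
    """Raised on a malformed GTF record, carrying the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with derived TSS/TES positions.

    ``tss`` is the first transcribed base and ``tes`` the last: on the +
    strand tss == interval.start and tes == interval.end - 1; on the -
    strand the two are swapped.
    """

    transcript_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def tes(self) -> int:
        if self.interval.strand == "-":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class GeneModel:
    """A gene with its transcripts and the union span they cover."""

    gene_id: str
    name: str
    biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.interval.chrom for t in self.transcripts}
        strands = {t.interval.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id}: transcripts disagree on chrom/strand"
            )

    @property
    def strand(self) -> str:
        return self.transcripts[0].interval.strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.transcripts[0].interval.chrom,
            min(t.interval.start for t in self.transcripts),
            max(t.interval.end for t in self.transcripts),
            self.strand,
        )

    @property
    def tss_positions(self) -> list[int]:
        """Distinct transcript TSS positions, ascending."""
        return sorted({t.tss for t in self.transcripts})


@dataclass(frozen=True)
class PromoterWindow:
    """Fixed window around one transcript TSS, clipped at chromosome ends."""

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    upstream_bp: int = DEFAULT_UPSTREAM_BP
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP


def promoter_windows(
    gene: GeneModel,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    chrom_length: int | None = None,
) -> list[PromoterWindow]:
    """One promoter window per distinct transcript TSS of ``gene``.

    On the + strand a TSS at t yields [t - upstream, t + downstream); on the
    - strand the mirror image [t - downstream + 1, t + upstream + 1). Both
    contain the TSS base. Windows are clipped to [0, chrom_length) when a
    chromosome length is given.
    """
    windows: list[PromoterWindow] = []
    seen: set[int] = set()
    for tx in gene.transcripts:
        t = tx.tss
        if t in seen:
            continue
        seen.add(t)
        if gene.strand == "-":
            lo, hi = t - downstream_bp + 1, t + upstream_bp + 1
        else:
            lo, hi = t - upstream_bp, t + downstream_bp
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        if lo >= hi:
            continue
        windows.append(
            PromoterWindow(
                gene_id=gene.gene_id,
                transcript_id=tx.transcript_id,
                interval=GenomicInterval(
                    tx.interval.chrom, lo, hi, gene.strand
                ),
                upstream_bp=upstream_bp,
                downstream_bp=downstream_bp,
            )
        )
    windows.sort(key=lambda w: (w.interval.start, w.transcript_id))
    return windows


def nearest_tss_distance(
    pos: int, genes: list[GeneModel]
) -> tuple[str, str, int]:
    """Nearest transcript TSS to ``pos`` over all genes.

    Returns (gene_id, transcript_id, distance). Ties are broken by smaller
    distance, then lexicographic gene_id, then transcript_id.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    best: tuple[int, str, str] | None = None
    for gene in genes:
        for tx in gene.transcripts:
            d = abs(pos - tx.tss)
            key = (d, gene.gene_id, tx.transcript_id)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[1], best[2], best[0]


# --- GTF I/O ----------------------------------------------------------------
#
# Attribute dialect: semicolon-delimited `key "value"` pairs, as in the
# FlyBase/Ensembl GTF releases. Only gene_id / transcript_id / gene_symbol /
# gene_biotype attributes are interpreted.


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: bad attribute {chunk!r}")
        key, _, raw = chunk.partition(" ")
        attrs[key] = raw.strip().strip('"')
    return attrs


def parse_gtf(
    path, biotype_filter: set[str] | None = frozenset({"protein_coding"})
) -> list[GeneModel]:
    """Parse a GTF annotation into GeneModels.

    Transcript records (feature ``transcript`` or ``mRNA``) define the
    models; 1-based closed coordinates become 0-based half-open. Genes whose
    biotype is outside ``biotype_filter`` are dropped (pass ``None`` to keep
    everything). Output is ordered by (chrom, span start, gene_id).

    Raises GtfParseError on malformed lines, and ValueError when a gene's
    transcripts disagree on chromosome or strand.
    """
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in {"transcript", "mRNA"}:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"line {lineno}: invalid 1-based coordinates "
                    f"{start1}..{end1}"
                )
            attrs = _parse_attributes(attr_s, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: missing gene_id/transcript_id"
                )
            gid = attrs["gene_id"]
            rec = per_gene.setdefault(
                gid,
                {
                    "name": attrs.get("gene_symbol", gid),
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                    "transcripts": [],
                },
            )
            rec["transcripts"].append(
                TranscriptModel(
                    transcript_id=attrs["transcript_id"],
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                )
            )
    genes = []
    for gid, rec in per_gene.items():
        if biotype_filter is not None and rec["biotype"] not in biotype_filter:
            continue
        genes.append(
            GeneModel(
                gene_id=gid,
                name=rec["name"],
                biotype=rec["biotype"],
                transcripts=sorted(
                    rec["transcripts"],
                    key=lambda t: (t.interval.start, t.transcript_id),
                ),
            )
        )
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write GeneModels as transcript GTF records (round-trips parse_gtf)."""
    with open(path, "w") as fh:
        for gene in sorted(
            genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)
        ):
            for tx in gene.transcripts:
                iv = tx.interval
                attrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{tx.transcript_id}"; '
                    f'gene_symbol "{gene.name}"; '
                    f'gene_biotype "{gene.biotype}";'
                )
                fh.write(
                    f"{iv.chrom}\tchipcross\ttranscript\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column (chrom, length) TSV -> mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"chrom sizes line {lineno}: need 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
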