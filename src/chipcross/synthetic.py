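"""Seeded synthetic study generator with planted ground truth.

Emulates the structure of the real study design this package analyzes: a
compact gene annotation, duplicate ChIP peak sets per factor with planted
promoter/genic/unbound classes, triplicate RNA-seq count matrices for a
control and two knockdown conditions with planted log2 fold changes, ChIP
coverage tracks, and a co-IP protein quantification table with planted
bait-dependent interactors. Every artifact regenerates bit-identically
from (seed, parameters) via numpy's PCG64 generator seeded through
SeedSequence spawning.

Default study conditions (chosen once, as what the emulated study design
looks like; see docs/methods.md):

* binding-class mix 53.5% promoter / 7.6% genic / 38.9% unbound;
* NB dispersion alpha = 0.05, triplicates, baseline means log-normal
  around ~100 counts;
* planted effects: among promoter-bound genes 16% derepressed (+2 log2)
  and 14% down (-2); among genic-bound 17% up; among unbound 4% up
  (indirect effects); everything else 0;
* duplicate ChIP replicates with <=20 bp positional jitter and 5
  intergenic noise peaks per Mb per replicate;
* proteomics funnel of 100 proteins: 21 pass the ratio/PSM thresholds, 4
  of them ribosomal-or-bait, 7 of the surviving 17 chromatin-annotated.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from chipcross.expression import CountMatrix, write_counts_tsv
from chipcross.genome import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    write_chrom_sizes,
    write_gtf,
)
from chipcross.metaprofile import CoverageTrack, write_bedgraph
from chipcross.peaks import Peak, PeakSet, write_narrowpeak
from chipcross.proteomics import ProteinQuant, write_quant_table

__all__ = [
    "SyntheticTruth", "generate_genome", "generate_chip", "generate_counts",
    "generate_coverage", "generate_quant_table", "generate_study",
    "simulate_replicate_counts", "DEFAULT_EFFECT_RULE",
]

DEFAULT_FRAC_PROMOTER = 0.535
DEFAULT_FRAC_GENIC = 0.076
DEFAULT_NOISE_PEAKS_PER_MB = 5.0
DEFAULT_PEAK_WIDTH_RANGE = (150, 600)
DEFAULT_REPLICATE_JITTER = 20
DEFAULT_ALPHA = 0.05
DEFAULT_N_REP = 3

# fraction of each binding class planted with a given log2 fold change in
# the knockdown; mirrors the proportions the emulated design exhibits
DEFAULT_EFFECT_RULE: dict[str, list[tuple[float, float]]] = {
    "promoter": [(0.16, 2.0), (0.14, -2.0)],
    "nonpromoter_genic": [(0.17, 2.0)],
    "unbound": [(0.04, 2.0)],
}


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated study."""

    seed: int
    params: dict = field(default_factory=dict)
    binding: dict[str, dict[str, str]] = field(default_factory=dict)
    log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    interactors: list[str] = field(default_factory=list)
    flagged_passing: list[str] = field(default_factory=list)
    chromatin_candidates: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "params": self.params,
                    "binding": self.binding,
                    "log2fc": self.log2fc,
                    "interactors": self.interactors,
                    "flagged_passing": self.flagged_passing,
                    "chromatin_candidates": self.chromatin_candidates,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def generate_genome(
    n_genes: int,
    n_chroms: int = 4,
    chrom_length: int = 8_000_000,
    seed: int = 0,
    min_gap: int = 1000,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene models on ``n_chroms`` chromosomes.

    Gene lengths are log-uniform in [1, 20] kb, strands Bernoulli(0.5),
    1-3 transcripts each with TSS jitter <= 200 bp, and at least
    ``min_gap`` bp between neighbouring spans. Raises if the genes cannot
    be placed at the requested density.
    """
    if n_genes < 0 or n_chroms <= 0 or chrom_length <= 0:
        raise ValueError("generator parameters must be positive")
    rng = _rng(seed, 1)
    sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    gidx = 0
    margin = 5000  # keep genes clear of chromosome ends
    for ci, chrom in enumerate(sizes):
        cursor = margin
        for _ in range(per_chrom[ci]):
            length = int(np.exp(rng.uniform(np.log(1000), np.log(20000))))
            gap = min_gap + int(rng.integers(0, 2000))
            start = cursor + gap
            end = start + length
            if end > chrom_length - margin:
                raise ValueError(
                    f"cannot place {n_genes} genes on {n_chroms} x "
                    f"{chrom_length} bp chromosomes; increase chrom_length "
                    f"or n_chroms"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gidx:05d}"
            n_tx = int(rng.integers(1, 4))
            transcripts = [
                TranscriptModel(
                    transcript_id=f"{gid}.t0",
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            ]
            for ti in range(1, n_tx):
                jitter = int(rng.integers(0, 201))
                if strand == "+":
                    iv = GenomicInterval(chrom, start + jitter, end, strand)
                else:
                    iv = GenomicInterval(chrom, start, end - jitter, strand)
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"{gid}.t{ti}", interval=iv
                    )
                )
            transcripts.sort(
                key=lambda t: (t.interval.start, t.transcript_id)
            )
            genes.append(
                GeneModel(
                    gene_id=gid,
                    name=f"g{gidx}",
                    biotype="protein_coding",
                    transcripts=transcripts,
                )
            )
            cursor = end
            gidx += 1
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes, sizes


def _plant_classes(
    genes: list[GeneModel],
    frac_promoter: float,
    frac_genic: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    if frac_promoter + frac_genic > 1:
        raise ValueError("class fractions must sum to <= 1")
    n = len(genes)
    n_prom = int(round(frac_promoter * n))
    n_genic = int(round(frac_genic * n))
    order = rng.permutation(n)
    classes: dict[str, str] = {}
    for rank, idx in enumerate(order):
        gid = genes[idx].gene_id
        if rank < n_prom:
            classes[gid] = "promoter"
        elif rank < n_prom + n_genic:
            classes[gid] = "nonpromoter_genic"
        else:
            classes[gid] = "unbound"
    return classes


def _planted_peak_position(
    gene: GeneModel, cls: str, width: int, rng: np.random.Generator
) -> tuple[int, int]:
    """(start, width) of the factor's planted peak for one gene."""
    span = gene.span
    if cls == "promoter":
        tss = gene.transcripts[0].tss
        return tss - width // 2, width
    # genic: inside the span, clear of all promoter windows of this gene
    # (they occupy <= 300 bp at the 5' end plus upstream flank)
    margin = 350
    if gene.strand == "+":
        lo, hi = span.start + margin, span.end
    else:
        lo, hi = span.start, span.end - margin
    width = min(width, max(hi - lo - 10, 60))
    start = int(rng.integers(lo, max(hi - width, lo + 1)))
    return start, width


def generate_chip(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    factor: str = "factorA",
    frac_promoter: float = DEFAULT_FRAC_PROMOTER,
    frac_genic: float = DEFAULT_FRAC_GENIC,
    noise_peaks_per_mb: float = DEFAULT_NOISE_PEAKS_PER_MB,
    peak_width_range: tuple[int, int] = DEFAULT_PEAK_WIDTH_RANGE,
    replicate_jitter: int = DEFAULT_REPLICATE_JITTER,
    seed: int = 0,
    classes: dict[str, str] | None = None,
) -> tuple[PeakSet, PeakSet, dict[str, str]]:
    """Duplicate narrowPeak sets with planted binding classes.

    Promoter-class genes get a peak over a promoter window in both
    replicates (independent positional jitter); genic-class genes a peak
    inside the span clear of promoter windows; unbound genes none. Poisson
    noise peaks land in intergenic space per replicate (independent, so
    replicate reconciliation removes most); a small fraction of noise
    peaks carries -log10(q) > 100 to exercise the hyper-significance
    filter.
    """
    rng = _rng(seed, 2, zlib.crc32(factor.encode()))
    if classes is None:
        classes = _plant_classes(genes, frac_promoter, frac_genic, rng)

    planted: list[tuple[str, int, int]] = []  # (chrom, start, width)
    for gene in genes:
        cls = classes[gene.gene_id]
        if cls == "unbound":
            continue
        width = int(rng.integers(*peak_width_range))
        start, width = _planted_peak_position(gene, cls, width, rng)
        planted.append((gene.span.chrom, start, width))

    spans = sorted((g.span.chrom, g.span.start, g.span.end) for g in genes)
    span_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in spans:
        span_by_chrom.setdefault(chrom, []).append((s, e))

    def intergenic(chrom: str, start: int, end: int) -> bool:
        for s, e in span_by_chrom.get(chrom, []):
            if start < e and s < end:
                return False
        return True

    total_mb = sum(chrom_sizes.values()) / 1e6
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    reps: list[PeakSet] = []
    for rep in (1, 2):
        peaks: list[Peak] = []
        for i, (chrom, start, width) in enumerate(planted):
            shift = int(rng.integers(-replicate_jitter, replicate_jitter + 1))
            s = max(start + shift, 0)
            e = min(s + width, chrom_sizes[chrom])
            q = min(float(rng.gamma(4.0, 8.0)), 99.5)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, s, e),
                    name=f"{factor}_r{rep}_p{i}",
                    score=int(min(1000, 10 * q)),
                    signal=q / 2,
                    neg_log10_p=q + 2,
                    neg_log10_q=q,
                    summit_offset=(e - s) // 2,
                )
            )
        n_noise = int(rng.poisson(noise_peaks_per_mb * total_mb))
        placed = 0
        attempts = 0
        while placed < n_noise and attempts < 50 * max(n_noise, 1):
            attempts += 1
            chrom = chroms[
                int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            ]
            width = int(rng.integers(*peak_width_range))
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            if not intergenic(chrom, start, start + width):
                continue
            if rng.random() < 0.05:  # hyper-significant artifact peak
                q = float(rng.uniform(101.0, 300.0))
            else:
                q = float(rng.gamma(2.0, 5.0))
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + width),
                    name=f"{factor}_r{rep}_n{placed}",
                    score=int(min(1000, 10 * q)),
                    signal=q / 2,
                    neg_log10_p=q + 2,
                    neg_log10_q=q,
                    summit_offset=width // 2,
                )
            )
            placed += 1
        reps.append(PeakSet(label=f"{factor}_rep{rep}", peaks=peaks))
    return reps[0], reps[1], classes


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean mu, Var mu + alpha mu^2) counts; Poisson when alpha ~ 0."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def plant_effects(
    classes: dict[str, str],
    effect_rule: dict[str, list[tuple[float, float]]],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-gene planted log2 fold changes drawn from the effect rule."""
    lfc: dict[str, float] = {}
    for gid in sorted(classes):
        cls = classes[gid]
        u = rng.random()
        acc = 0.0
        value = 0.0
        for frac, effect in effect_rule.get(cls, []):
            acc += frac
            if u < acc:
                value = effect
                break
        lfc[gid] = value
    return lfc


def generate_counts(
    genes: list[GeneModel],
    log2fc: dict[str, float],
    condition_kd: str,
    n_rep: int = DEFAULT_N_REP,
    depth: float = 1.0,
    alpha: float = DEFAULT_ALPHA,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> CountMatrix:
    """Triplicate control + knockdown NB count matrix with planted effects.

    Baseline means are log-normal (median ~depth*100 counts); knockdown
    means are baseline * 2**log2fc.
    """
    rng = _rng(seed, 3, zlib.crc32(condition_kd.encode()))
    gene_ids = [g.gene_id for g in genes]
    base = depth * rng.lognormal(baseline_log_mean, baseline_log_sd,
                                 len(gene_ids))
    lfc = np.array([log2fc.get(g, 0.0) for g in gene_ids])
    cols = []
    sample_ids, conditions = [], []
    for i in range(n_rep):
        cols.append(_nb_draw(rng, base, alpha))
        sample_ids.append(f"control_rep{i + 1}")
        conditions.append("control")
    kd_mean = base * 2.0**lfc
    for i in range(n_rep):
        cols.append(_nb_draw(rng, kd_mean, alpha))
        sample_ids.append(f"{condition_kd}_rep{i + 1}")
        conditions.append(condition_kd)
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        conditions=conditions,
        counts=np.stack(cols, axis=1),
    )


def generate_coverage(
    peaks: PeakSet,
    chrom_sizes: dict[str, int],
    background: float = 0.1,
    seed: int = 0,
) -> CoverageTrack:
    """Box-signal coverage track from a peak set plus flat background."""
    rng = _rng(seed, 4)
    values = {
        chrom: np.full(length, background, dtype=np.float32)
        for chrom, length in chrom_sizes.items()
    }
    for p in peaks:
        height = background + float(rng.gamma(3.0, 2.0)) + p.signal / 10
        iv = p.interval
        values[iv.chrom][iv.start: iv.end] += np.float32(height)
    return CoverageTrack(values=values)


def simulate_replicate_counts(
    regions: PeakSet,
    mean_depth: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-region read counts for two replicates of one ChIP.

    Each region has a log-normal latent enrichment shared by the
    replicates; counts are Poisson around depth * enrichment. Used to
    exercise the replicate-correlation check on merged-peak regions.
    """
    rng = _rng(seed, 5)
    lam = mean_depth * rng.lognormal(0.0, 0.8, len(regions.peaks))
    return rng.poisson(lam), rng.poisson(lam)


def generate_quant_table(
    n_background: int = 79,
    n_interactors: int = 21,
    n_ribosomal_passing: int = 3,
    bait_passing: bool = True,
    n_chromatin: int = 7,
    seed: int = 0,
) -> tuple[list[ProteinQuant], SyntheticTruth]:
    """Co-IP quant table with a planted interactor funnel.

    ``n_interactors`` proteins pass the ratio/PSM thresholds; among them
    ``n_ribosomal_passing`` are ribosomal and (optionally) one is the bait
    itself, exercising the exclusion step; ``n_chromatin`` of the
    remaining candidates carry a chromatin-regulation annotation.
    Background proteins have ratios capped below 4 (or PSM <= 1).
    """
    n_flagged = n_ribosomal_passing + int(bait_passing)
    if n_flagged > n_interactors:
        raise ValueError("more flagged passers than passing proteins")
    if n_chromatin > n_interactors - n_flagged:
        raise ValueError("more chromatin candidates than candidates")
    rng = _rng(seed, 6)
    records: list[ProteinQuant] = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n_interactors):
        pid = f"P{i:03d}"
        control = float(rng.lognormal(np.log(1e7), 1.0))
        if rng.random() < 0.2:
            kd = 0.0  # detected only with bait present
        else:
            kd = control / float(rng.uniform(4.5, 40.0))
        is_bait = bait_passing and i == 0
        first_ribo = 1 if bait_passing else 0
        is_ribo = first_ribo <= i < first_ribo + n_ribosomal_passing
        records.append(
            ProteinQuant(
                protein_id=pid,
                sum_pep_score=float(rng.gamma(6.0, 30.0)),
                psm=int(rng.integers(2, 80)),
                abundance_control=control,
                abundance_kd=kd,
                is_ribosomal=bool(is_ribo),
                is_bait=bool(is_bait),
            )
        )
    passing = [r for r in records]
    flagged = [r.protein_id for r in passing if r.is_ribosomal or r.is_bait]
    unflagged = [r for r in passing if not (r.is_ribosomal or r.is_bait)]
    chrom_ids = [r.protein_id for r in unflagged[:n_chromatin]]
    for r in records:
        if r.protein_id in chrom_ids:
            r.categories = frozenset({"chromatin regulation"})
        elif not (r.is_ribosomal or r.is_bait) and rng.random() < 0.3:
            r.categories = frozenset({"metabolism"})
    for i in range(n_background):
        pid = f"B{i:03d}"
        control = float(rng.lognormal(np.log(3e6), 1.0))
        low_psm = rng.random() < 0.25
        ratio = float(rng.uniform(0.3, 3.9))
        records.append(
            ProteinQuant(
                protein_id=pid,
                sum_pep_score=float(rng.gamma(3.0, 20.0)),
                psm=1 if low_psm else int(rng.integers(2, 40)),
                abundance_control=control,
                abundance_kd=control / ratio,
                is_ribosomal=bool(rng.random() < 0.1),
                categories=(
                    frozenset({"metabolism"})
                    if rng.random() < 0.4 else frozenset()
                ),
            )
        )
    truth.interactors = [r.protein_id for r in passing]
    truth.flagged_passing = flagged
    truth.chromatin_candidates = chrom_ids
    truth.params = {
        "n_background": n_background,
        "n_interactors": n_interactors,
        "n_ribosomal_passing": n_ribosomal_passing,
        "bait_passing": bait_passing,
        "n_chromatin": n_chromatin,
    }
    rng.shuffle(records)
    return records, truth


def generate_study(
    outdir,
    n_genes: int = 500,
    n_chroms: int = 4,
    chrom_length: int = 3_000_000,
    factors: tuple[str, str] = ("factorA", "factorB"),
    noise_peaks_per_mb: float = DEFAULT_NOISE_PEAKS_PER_MB,
    alpha: float = DEFAULT_ALPHA,
    depth: float = 1.0,
    effect_rule: dict[str, list[tuple[float, float]]] | None = None,
    write_coverage: bool = True,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate a complete study directory with truth.json.

    Writes genome.gtf, chrom.sizes, {factor}_rep{1,2}.narrowPeak,
    coverage_{factor}.bedGraph, counts_{factor}.tsv (control + KD
    triplicates), condition_map.tsv, quant.tsv and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effect_rule = effect_rule or DEFAULT_EFFECT_RULE
    genes, sizes = generate_genome(
        n_genes, n_chroms, chrom_length, seed=seed
    )
    write_gtf(genes, outdir / "genome.gtf")
    write_chrom_sizes(sizes, outdir / "chrom.sizes")
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_chroms": n_chroms,
            "chrom_length": chrom_length,
            "factors": list(factors),
            "noise_peaks_per_mb": noise_peaks_per_mb,
            "alpha": alpha,
            "depth": depth,
            "effect_rule": {
                k: [list(t) for t in v] for k, v in effect_rule.items()
            },
        },
    )
    cond_lines = []
    for fi, factor in enumerate(factors):
        rep1, rep2, classes = generate_chip(
            genes, sizes, factor=factor,
            noise_peaks_per_mb=noise_peaks_per_mb, seed=seed,
        )
        write_narrowpeak(rep1, outdir / f"{factor}_rep1.narrowPeak")
        write_narrowpeak(rep2, outdir / f"{factor}_rep2.narrowPeak")
        truth.binding[factor] = classes
        if write_coverage:
            cov = generate_coverage(rep1, sizes, seed=seed)
            write_bedgraph(cov, outdir / f"coverage_{factor}.bedGraph")
        rng = _rng(seed, 7, fi)
        lfc = plant_effects(classes, effect_rule, rng)
        kd = f"{factor}_kd"
        counts = generate_counts(
            genes, lfc, kd, depth=depth, alpha=alpha, seed=seed
        )
        write_counts_tsv(counts, outdir / f"counts_{factor}.tsv")
        truth.log2fc[kd] = lfc
        for s, c in zip(counts.sample_ids, counts.conditions):
            cond_lines.append(f"{s}\t{c}")
    with open(outdir / "condition_map.tsv", "w") as fh:
        fh.write("\n".join(dict.fromkeys(cond_lines)) + "\n")
    quant, qt = generate_quant_table(seed=seed)
    write_quant_table(quant, outdir / "quant.tsv")
    truth.interactors = qt.interactors
    truth.flagged_passing = qt.flagged_passing
    truth.chromatin_candidates = qt.chromatin_candidates
    truth.to_json(outdir / "truth.json")
    return truth
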