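"""Gene-centric ChIP-seq signal quantification and peak-set statistics.

Signal around a TSS is computed from peak score x overlap (the pipeline
consumes peak BED files, not raw reads): for a window of half-width w the
signal is sum(score * overlap_bp) / (2w). Promoter windows use w = 1 kb
(H3K4me3, H3K27me3); distal windows w = 50 kb (H3K4me1, PU.1). Windows are
clipped at chromosome ends but keep the nominal 2w denominator so
near-telomeric genes are not inflated.

Differential peaks between two states are called on the merged peak
universe from library-normalized score ratios with a 0.5 pseudocount;
present/absent peaks fall out of the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneAnnotation, GenomicInterval, PeakSet, merge_intervals

PROMOTER_HALF_WIDTH = 1_000
DISTAL_HALF_WIDTH = 50_000


def tss_window_signal(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    half_width: int = PROMOTER_HALF_WIDTH,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.Series:
    """Per-gene windowed signal: sum(score x overlap bp) / (2*half_width).

    Genes on chromosomes with no peaks get 0. If ``chrom_sizes`` is given,
    annotation chromosomes absent from it raise; windows are clipped to
    [0, size) with the denominator unchanged.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    denom = 2.0 * half_width
    out = {}
    for gene in annotation.iter_genes():
        if chrom_sizes is not None and gene.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {gene.chrom!r} in annotation")
        w_start = gene.tss - half_width
        w_end = gene.tss + half_width
        c_start = max(0, w_start)
        c_end = min(chrom_sizes[gene.chrom], w_end) if chrom_sizes else w_end
        total = 0.0
        for iv in peaks.overlapping(gene.chrom, c_start, c_end):
            ov = min(iv.end, c_end) - max(iv.start, c_start)
            if ov > 0:
                total += iv.score * ov
        out[gene.gene_id] = total / denom
    return pd.Series(out, name=f"{peaks.mark}:{peaks.cell_state}")


def signal_matrix(
    peak_sets: dict[str, PeakSet],
    annotation: GeneAnnotation,
    half_width: int,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """genes x states signal matrix for one mark (keys = states)."""
    return pd.DataFrame(
        {
            st: tss_window_signal(ps, annotation, half_width, chrom_sizes)
            for st, ps in peak_sets.items()
        }
    )


def classify_regions(
    h3k4me1: PeakSet, h3k4me3: PeakSet, pu1: PeakSet
) -> pd.DataFrame:
    """Label each PU.1 peak active_promoter / enhancer / neither.

    A peak overlapping (>=1 bp) both an H3K4me1 and an H3K4me3 peak is an
    active promoter; overlapping H3K4me1 only, an enhancer.
    """
    rows = []
    for iv in pu1:
        me1 = h3k4me1.any_overlap(iv.chrom, iv.start, iv.end)
        me3 = h3k4me3.any_overlap(iv.chrom, iv.start, iv.end)
        if me1 and me3:
            label = "active_promoter"
        elif me1:
            label = "enhancer"
        else:
            label = "neither"
        rows.append(
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "label": label}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def detect_bivalent(
    h3k4me3: PeakSet,
    h3k27me3: PeakSet,
    annotation: GeneAnnotation,
    half_width: int = PROMOTER_HALF_WIDTH,
) -> list[str]:
    """Genes whose TSS +/- half_width carries both H3K4me3 and H3K27me3."""
    out = []
    for gene in annotation.iter_genes():
        s, e = gene.tss - half_width, gene.tss + half_width
        if h3k4me3.any_overlap(gene.chrom, s, e) and h3k27me3.any_overlap(
            gene.chrom, s, e
        ):
            out.append(gene.gene_id)
    return out


@dataclass
class DifferentialPeakCall:
    interval: GenomicInterval
    signal_a: float
    signal_b: float
    direction: str  # "a-specific" | "b-specific" | "shared"
    fold_change: float  # normalized (a+pc)/(b+pc)


def differential_peaks(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[DifferentialPeakCall]:
    """Call state-specific peaks on the merged universe of both sets.

    Scores are library-normalized to equal totals, summed per merged
    region, and compared as (a+pc)/(b+pc). Ratio >= fc_threshold =>
    a-specific; <= 1/fc_threshold => b-specific; else shared. A region with
    no peak on one side is automatically specific to the other provided its
    normalized score clears the pseudocount ratio.
    """
    if len(peaks_a) == 0 and len(peaks_b) == 0:
        return []
    tot_a, tot_b = peaks_a.total_score(), peaks_b.total_score()
    target = (tot_a + tot_b) / 2.0 if (tot_a > 0 and tot_b > 0) else max(tot_a, tot_b)
    scale_a = target / tot_a if tot_a > 0 else 1.0
    scale_b = target / tot_b if tot_b > 0 else 1.0

    regions = merge_intervals(list(peaks_a) + list(peaks_b))
    calls = []
    for chrom, start, end in regions:
        sig_a = scale_a * sum(iv.score for iv in peaks_a.overlapping(chrom, start, end))
        sig_b = scale_b * sum(iv.score for iv in peaks_b.overlapping(chrom, start, end))
        ratio = (sig_a + pseudocount) / (sig_b + pseudocount)
        if ratio >= fc_threshold:
            direction = "a-specific"
        elif ratio <= 1.0 / fc_threshold:
            direction = "b-specific"
        else:
            direction = "shared"
        calls.append(
            DifferentialPeakCall(
                GenomicInterval(chrom, start, end, max(sig_a, sig_b)),
                float(sig_a),
                float(sig_b),
                direction,
                float(ratio),
            )
        )
    return calls


def differential_peak_table(calls: list[DifferentialPeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "signal_a": [c.signal_a for c in calls],
            "signal_b": [c.signal_b for c in calls],
            "direction": [c.direction for c in calls],
            "fold_change": [c.fold_change for c in calls],
        }
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization (rank -> mean of sorted columns).

    Ties within a column receive the mean of the values they would have
    taken, via average ranks.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in input matrix")
    if X.shape[1] < 2:
        raise ValueError("need >=2 columns to quantile normalize")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pca(matrix: pd.DataFrame, n_components: int = 2):
    """Column-centered SVD PCA of a samples x features matrix.

    Components are sign-fixed so each component's largest-magnitude feature
    loading is positive. Returns (coordinates DataFrame with columns
    PC1..PCk, explained-variance fractions). A constant matrix yields zero
    coordinates and zero variance fractions.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs >=2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = (Xc**2).sum() / (n - 1)
    k = min(n_components, min(Xc.shape))
    if total_var <= 0:
        coords = np.zeros((n, k))
        evr = np.zeros(k)
    else:
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for comp in range(len(S)):
            i_max = np.argmax(np.abs(Vt[comp]))
            if Vt[comp, i_max] < 0:
                Vt[comp] *= -1.0
                U[:, comp] *= -1.0
        coords = (U * S)[:, :k]
        evr = (S[:k] ** 2 / (n - 1)) / total_var
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(coords, index=matrix.index, columns=cols), evr


def overlap_fraction(peaks_a: PeakSet, peaks_b: PeakSet) -> float:
    """Fraction of a-peaks overlapping >=1 b-peak by >=1 bp; NaN if a empty."""
    if len(peaks_a) == 0:
        return float("nan")
    n = sum(1 for iv in peaks_a if peaks_b.any_overlap(iv.chrom, iv.start, iv.end))
    return n / len(peaks_a)


def fisher_target_enrichment(
    target_genes: set[str], de_genes: set[str], universe: set[str]
) -> tuple[float, float]:
    """One-sided Fisher enrichment of targets among DE genes.

    2x2 table: (DE, not-DE) x (target, non-target) over the universe.
    Returns (odds_ratio, one-sided greater p). The odds ratio uses the
    Haldane-Anscombe +0.5-on-all-cells convention when any cell is zero;
    the p-value is the untouched hypergeometric tail.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not target_genes <= universe or not de_genes <= universe:
        raise ValueError("target and DE genes must be subsets of the universe")
    a = len(de_genes & target_genes)
    b = len(de_genes - target_genes)
    c = len(target_genes - de_genes)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    return float(oddsr), float(p)
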