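"""PWM scanning and motif enrichment in differential PU.1 peaks.

A motif is a position probability matrix over ACGT scored as log2 odds
against a 0-order background. Scan thresholds are calibrated per motif to a
target false-positive rate under the background via exact dynamic
programming over the discretized score distribution (0.01-bit grid), with a
Monte-Carlo fallback for motifs longer than 20 bp.

Enrichment of a motif in foreground versus background peak regions is
region-level presence/absence (>=1 hit) with a one-sided Fisher's exact
test, BH-corrected across motifs; regions are standardized to +/-250 bp
around the peak midpoint so region length does not bias hit probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

from .expression import DEResult, bh_adjust
from .genome import Genome
from .intervals import GenomicInterval, PeakSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_FPR = 1e-4
SCORE_STEP = 0.01  # bits


@dataclass
class MotifModel:
    motif_id: str
    tf_name: str
    matrix: np.ndarray  # (L, 4) position probabilities, columns ACGT
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"motif {self.motif_id}: length must be >=4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.motif_id}: matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p/bg); zero probabilities floored at 1e-9."""
        p = np.maximum(self.matrix, 1e-9)
        return np.log2(p / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


@dataclass
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    log_odds_score: float


# ---------------------------------------------------------------------------
# motif file I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def _counts_to_probs(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    return (counts + pseudocount) / (totals + 4.0 * pseudocount)


def read_motifs(
    path: str | Path, format: str = "JASPAR", pseudocount: float = 1.0
) -> list[MotifModel]:
    """Read a JASPAR or MEME (minimal) motif collection.

    JASPAR count matrices are converted to probabilities with
    (count + pc) / (total + 4 pc) per column. MEME letter-probability
    matrices are smoothed the same way using the recorded nsites (default
    20 when absent). Background defaults to uniform.
    """
    fmt = format.upper()
    if fmt not in ("JASPAR", "MEME"):
        raise ValueError(f"unknown motif format {format!r}")
    parser_fmt = "jaspar" if fmt == "JASPAR" else "minimal"
    with open(path) as fh:
        records = list(bio_motifs.parse(fh, parser_fmt))
    # the minimal parser drops the alternate (TF) name on MOTIF lines
    alt_names: dict[str, str] = {}
    if fmt == "MEME":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 3 and parts[0] == "MOTIF":
                    alt_names[parts[1]] = parts[2]
    out = []
    for m in records:
        motif_id = getattr(m, "matrix_id", None) or m.name or f"motif_{len(out)}"
        name = alt_names.get(str(m.name or ""), m.name or motif_id)
        try:
            counts = np.array(
                [[m.counts[b][i] for b in BASES] for i in range(m.length)], float
            )
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed matrix for motif {motif_id!r}") from exc
        if counts.min() < 0 or not np.all(np.isfinite(counts)):
            raise ValueError(f"malformed matrix for motif {motif_id!r}")
        if fmt == "MEME" and counts.max() <= 1.0 + 1e-9:
            nsites = getattr(m, "num_occurrences", 0) or 20
            counts = counts * float(nsites)
        probs = _counts_to_probs(counts, pseudocount)
        out.append(
            MotifModel(str(motif_id), str(name), probs, pseudocount=pseudocount)
        )
    return out


def write_motifs_meme(motifs: Sequence[MotifModel], path: str | Path) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg))
            + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.tf_name}\n")
            # large nsites so probability matrices survive count-based
            # round-tripping at 1e-6 precision
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        for b in (base, base.lower()):
            codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(b)] = idx
    return codes


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every offset; windows containing N (code -1) get -inf."""
    L = lo.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        col = codes[i : i + n]
        bad = col < 0
        valid &= ~bad
        scores += lo[i, np.where(bad, 0, col)]
    scores[~valid] = -np.inf
    return scores


def scan_motif(
    model: MotifModel,
    sequence: str,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
    threshold: float | None = None,
) -> list[MotifHit]:
    """All positions where the motif's log-odds score reaches threshold.

    ``threshold`` defaults to the model's ``score_threshold`` (which must
    then be set). Hit intervals are reported in 0-based half-open
    coordinates shifted by ``offset`` (the genomic start of ``sequence``).
    Windows containing N are skipped. Minus-strand hits are scored on the
    reverse complement and reported on the same forward interval.
    """
    thr = threshold if threshold is not None else model.score_threshold
    if thr is None:
        raise ValueError(f"motif {model.motif_id}: no score threshold set")
    L = len(model)
    if len(sequence) < L:
        return []
    codes = _encode(sequence)
    hits = []
    lo = model.log_odds
    strands = [("+", lo)]
    if both_strands:
        strands.append(("-", lo[::-1, ::-1]))
    for strand, mat in strands:
        scores = _window_scores(codes, mat)
        for pos in np.nonzero(scores >= thr)[0]:
            hits.append(
                MotifHit(
                    model.motif_id,
                    GenomicInterval(chrom or ".", offset + int(pos), offset + int(pos) + L),
                    strand,
                    float(scores[pos]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def calibrate_threshold(
    model: MotifModel,
    fpr: float = DEFAULT_FPR,
    step: float = SCORE_STEP,
    max_exact_length: int = 20,
    mc_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Smallest score t with P(score >= t | background) <= fpr.

    Exact dynamic programming over the per-position score distribution on a
    ``step``-bit grid for motifs up to ``max_exact_length``; Monte-Carlo
    sampling of background windows beyond that. fpr=1 returns the minimum
    achievable score.
    """
    if not (0.0 < fpr <= 1.0):
        raise ValueError("fpr must be in (0, 1]")
    lo = model.log_odds
    L = lo.shape[0]
    if L > max_exact_length:
        rng = np.random.default_rng(seed)
        windows = rng.choice(4, size=(mc_samples, L), p=model.background)
        scores = lo[np.arange(L)[None, :], windows].sum(axis=1)
        return float(np.quantile(scores, 1.0 - fpr, method="higher"))

    q = np.rint(lo / step).astype(np.int64)  # grid units per (position, base)
    pmf = np.array([1.0])  # pmf[k] = P(grid score == offset + k)
    offset = 0
    for i in range(L):
        qmin, qmax = int(q[i].min()), int(q[i].max())
        new = np.zeros(len(pmf) + (qmax - qmin))
        for b in range(4):
            sh = int(q[i, b]) - qmin
            new[sh : sh + len(pmf)] += model.background[b] * pmf
        pmf = new
        offset += qmin
    tail = np.cumsum(pmf[::-1])[::-1]
    idx = np.nonzero(tail <= fpr + 1e-12)[0]
    if len(idx) == 0:
        # not even the top score is rare enough under the background
        return (offset + len(pmf)) * step
    return (offset + int(idx[0])) * step


def calibrate_all(
    motifs: Sequence[MotifModel], fpr: float = DEFAULT_FPR, **kwargs
) -> None:
    """Set ``score_threshold`` in place for every motif lacking one."""
    for m in motifs:
        if m.score_threshold is None:
            m.score_threshold = calibrate_threshold(m, fpr=fpr, **kwargs)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def standardize_regions(peaks: PeakSet, flank: int = 250) -> list[GenomicInterval]:
    """+/-flank bp around each peak midpoint (summit proxy), clipped at 0."""
    out = []
    for iv in peaks:
        mid = iv.midpoint
        out.append(
            GenomicInterval(iv.chrom, max(0, mid - flank), mid + flank, iv.score, iv.name)
        )
    return out


def _region_has_hit(model: MotifModel, genome: Genome, iv: GenomicInterval) -> bool:
    end = min(iv.end, genome.chrom_sizes[iv.chrom])
    seq = genome.fetch(iv.chrom, iv.start, end)
    return len(scan_motif(model, seq, chrom=iv.chrom, offset=iv.start)) > 0


def motif_enrichment(
    motifs: Sequence[MotifModel],
    fg_regions: PeakSet,
    bg_regions: PeakSet,
    genome: Genome,
    flank: int = 250,
    alpha: float = 0.05,
    fpr: float = DEFAULT_FPR,
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of region-level hits, fg vs bg.

    Returns a DataFrame indexed by motif_id with columns tf_name, p_value,
    adjusted_p, odds_ratio, fg_hit_count, bg_hit_count, fg_total, bg_total,
    significant (BH-adjusted p < alpha).
    """
    if len(fg_regions) == 0 or len(bg_regions) == 0:
        raise ValueError("foreground and background region sets must be non-empty")
    for iv in list(fg_regions) + list(bg_regions):
        if iv.chrom not in genome:
            raise ValueError(f"region chromosome {iv.chrom!r} not in genome")
        if iv.end > genome.chrom_sizes[iv.chrom] + flank:
            raise ValueError(f"region {iv.chrom}:{iv.start}-{iv.end} outside genome")
    calibrate_all(motifs, fpr=fpr)
    fg = standardize_regions(fg_regions, flank)
    bg = standardize_regions(bg_regions, flank)
    rows = []
    for m in motifs:
        fg_hit = sum(_region_has_hit(m, genome, iv) for iv in fg)
        bg_hit = sum(_region_has_hit(m, genome, iv) for iv in bg)
        table = [[fg_hit, len(fg) - fg_hit], [bg_hit, len(bg) - bg_hit]]
        _, p = stats.fisher_exact(table, alternative="greater")
        cells = np.array(table, float)
        if cells.min() == 0:
            cells = cells + 0.5
        oddsr = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
        rows.append(
            {
                "motif_id": m.motif_id,
                "tf_name": m.tf_name,
                "p_value": float(p),
                "odds_ratio": float(oddsr),
                "fg_hit_count": int(fg_hit),
                "bg_hit_count": int(bg_hit),
                "fg_total": len(fg),
                "bg_total": len(bg),
            }
        )
    df = pd.DataFrame(rows).set_index("motif_id")
    df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["adjusted_p"] < alpha
    return df


@dataclass
class CofactorSelection:
    partners: dict[str, list[str]]  # state -> TF gene ids
    signatures: dict[str, tuple[bool, ...]]  # TF -> enrichment pattern
    pattern_clusters: dict[tuple[bool, ...], list[str]]
    skipped_motifs: list[str]


def select_cofactors(
    enrichment: Mapping[str, pd.DataFrame],
    motif_to_tf: Mapping[str, str],
    tf_state_means: pd.DataFrame,
    de_results: Mapping[tuple[str, str], Sequence[DEResult]],
) -> CofactorSelection:
    """Expression-consistent PU.1 co-binding partners per cell state.

    A TF is a partner in state s iff its motif is significantly enriched in
    s and its expression does not oppose activity there: state-mean
    expression in s >= its median over the states, or the TF is
    significantly up in s in any DE contrast involving s. Partners are
    grouped by their binary enrichment signature across the states.
    """
    states = list(enrichment.keys())
    up_in_state: dict[str, set[str]] = {s: set() for s in states}
    for (a, b), results in de_results.items():
        for r in results:
            if r.is_de and r.log2_fold_change > 0 and a in up_in_state:
                up_in_state[a].add(r.gene_id)
            if r.is_de and r.log2_fold_change < 0 and b in up_in_state:
                up_in_state[b].add(r.gene_id)

    skipped: list[str] = []
    enriched_states: dict[str, set[str]] = {}
    for s in states:
        for motif_id, row in enrichment[s].iterrows():
            tf = motif_to_tf.get(str(motif_id))
            if tf is None:
                if str(motif_id) not in skipped:
                    skipped.append(str(motif_id))
                    warnings.warn(
                        f"motif {motif_id!r} has no TF mapping; skipped",
                        stacklevel=2,
                    )
                continue
            if bool(row["significant"]):
                enriched_states.setdefault(tf, set()).add(s)

    partners: dict[str, list[str]] = {s: [] for s in states}
    signatures: dict[str, tuple[bool, ...]] = {}
    for tf, enr_states in sorted(enriched_states.items()):
        signatures[tf] = tuple(s in enr_states for s in states)
        if tf not in tf_state_means.index:
            continue
        expr = tf_state_means.loc[tf, states]
        med = float(np.median(expr.to_numpy(dtype=float)))
        for s in enr_states:
            not_opposing = float(expr[s]) >= med or tf in up_in_state[s]
            if not_opposing:
                partners[s].append(tf)
    for s in states:
        partners[s].sort()

    clusters: dict[tuple[bool, ...], list[str]] = {}
    selected = {tf for tfs in partners.values() for tf in tfs}
    for tf in sorted(selected):
        clusters.setdefault(signatures[tf], []).append(tf)
    return CofactorSelection(partners, signatures, clusters, skipped)


def footprint_enrichment(
    footprints: PeakSet,
    pu1_peaks: PeakSet,
    motifs: Sequence[MotifModel],
    genome: Genome,
    require_pu1: bool = True,
    **kwargs,
) -> pd.DataFrame | None:
    """Motif enrichment within footprints stratified by PU.1 overlap.

    Foreground = footprints overlapping (require_pu1=True) or not
    overlapping (False) a PU.1 peak; background = the complementary
    stratum. Returns None when the chosen stratum is empty.
    """
    inside, outside = [], []
    for iv in footprints:
        (inside if pu1_peaks.any_overlap(iv.chrom, iv.start, iv.end) else outside).append(iv)
    fg_ivs, bg_ivs = (inside, outside) if require_pu1 else (outside, inside)
    if not fg_ivs or not bg_ivs:
        return None
    fg = PeakSet(fg_ivs, footprints.cell_state, "footprint")
    bg = PeakSet(bg_ivs, footprints.cell_state, "footprint")
    return motif_enrichment(motifs, fg, bg, genome, **kwargs)
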