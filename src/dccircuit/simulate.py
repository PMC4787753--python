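"""Synthetic genome, expression, peak tracks and a planted truth network.

The generator emulates the four-state dendritic-cell developmental design
(MPP -> CDP -> cDC/pDC): six expression clusters with fixed on/off
archetypes over the states, TSS-proximal H3K4me3/H3K27me3 peaks following
cluster activity (plus planted bivalent genes), distal H3K4me1 and PU.1
peaks near active genes, and a ground-truth TF network whose every edge is
realized in the data — the source TF's consensus motif is written into a
state-specific differential PU.1 peak within the association window of a
target that is differentially expressed in that state's contrast.

Background sequence is i.i.d. uniform ACGT and planted motif instances are
exact consensus strings, so the planted truth is unambiguous for any
reasonable scan threshold. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome import Genome, reverse_complement
from .intervals import GeneAnnotation, GenomicInterval, PeakSet
from .motifs import MotifModel, write_motifs_meme

STATES = ("MPP", "CDP", "cDC", "pDC")

# fixed binary on/off archetypes over (MPP, CDP, cDC, pDC)
ARCHETYPES: dict[str, tuple[int, int, int, int]] = {
    "MPP/CDP": (1, 1, 0, 0),
    "MPP": (1, 0, 0, 0),
    "CDP": (0, 1, 0, 0),
    "pan-DC": (0, 0, 1, 1),
    "cDC": (0, 0, 1, 0),
    "pDC": (0, 0, 0, 1),
}
CLUSTER_ORDER = tuple(ARCHETYPES)

# the two pairwise contrasts driving the networks
CONTRASTS = (("MPP", "CDP"), ("cDC", "pDC"))

_OPPOSITE = {"MPP": "CDP", "CDP": "MPP", "cDC": "pDC", "pDC": "cDC"}
# expression cluster for a decoy TF enriched in a given state: off in that
# state but on in two others, so its state mean falls below its median and
# the opposing-pattern rule excludes it
_DECOY_CLUSTER = {"MPP": "pan-DC", "CDP": "pan-DC", "cDC": "MPP/CDP", "pDC": "MPP/CDP"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 6_000_000
    n_genes: int = 200
    n_tfs: int = 20
    cell_states: tuple[str, str, str, str] = STATES
    replicates_per_state: int = 4
    log2_effect_size: float = 2.0
    noise_sd: float = 0.25
    peak_width: int = 400
    motif_length: int = 12
    planted_autoloops: int = 2
    seed: int = 0
    # secondary knobs (defaults are the study conditions)
    targets_per_tf: int = 10
    n_decoy_tfs: int = 0
    fraction_flat_genes: float = 0.2
    n_bivalent_genes: int = 10
    pu1_h3k4me1_overlap: float = 0.7
    fraction_score_differential: float = 0.15
    score_fold: float = 3.0
    baseline_expression: float = 6.0
    gene_spacing: int = 60_000

    def __post_init__(self) -> None:
        if len(self.cell_states) != 4:
            raise ConfigurationError("exactly four cell states are required")
        if self.n_tfs + self.n_decoy_tfs > self.n_genes:
            raise ConfigurationError("n_tfs (+decoys) must not exceed n_genes")
        if self.replicates_per_state < 2:
            raise ConfigurationError(
                "replicates_per_state must be >=2 (DE testing impossible otherwise)"
            )
        if self.log2_effect_size <= 0:
            raise ConfigurationError("log2_effect_size must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.motif_length < 4:
            raise ConfigurationError("motif_length must be >= 4")
        if self.planted_autoloops > self.n_tfs:
            raise ConfigurationError("more auto-loops requested than TFs")
        if self.n_genes > 0 and self._spacing() < 4 * self.peak_width:
            raise ConfigurationError(
                f"{self.n_genes} genes do not fit on "
                f"{self.n_chromosomes} x {self.chromosome_length} bp"
            )

    def _spacing(self) -> int:
        if self.n_genes == 0:
            return self.gene_spacing
        total = self.n_chromosomes * self.chromosome_length
        return min(self.gene_spacing, total // self.n_genes)


@dataclass
class GroundTruth:
    gene_clusters: dict[str, str] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    motif_instances: list[dict] = field(default_factory=list)
    diff_peak_labels: dict[str, list[tuple[str, int, int, str]]] = field(
        default_factory=dict
    )
    bivalent_genes: list[str] = field(default_factory=list)
    tf_genes: list[str] = field(default_factory=list)
    decoy_tfs: list[str] = field(default_factory=list)
    tf_state: dict[str, str] = field(default_factory=dict)
    autoloop_tfs: list[str] = field(default_factory=list)

    def cluster_members(self, cluster: str) -> list[str]:
        return [g for g, c in self.gene_clusters.items() if c == cluster]


def _activity(cluster: str, state: str, states: tuple[str, ...]) -> bool:
    """Flat ('none') genes are constitutively active; others follow archetype."""
    if cluster == "none":
        return True
    return bool(ARCHETYPES[cluster][states.index(state)])


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------


def generate_genome(config: SyntheticConfig) -> tuple[Genome, GeneAnnotation]:
    """Random i.i.d.-uniform chromosomes and evenly spaced gene TSS records."""
    rng = np.random.default_rng(config.seed)
    sequences = {}
    for c in range(config.n_chromosomes):
        arr = rng.integers(0, 4, size=config.chromosome_length)
        sequences[f"chr{c + 1}"] = _BASES[arr].tobytes().decode()
    genome = Genome(sequences)

    if config.n_genes == 0:
        return genome, GeneAnnotation(
            pd.DataFrame(columns=list(GeneAnnotation.REQUIRED))
        )

    spacing = config._spacing()
    per_chrom_capacity = config.chromosome_length // spacing
    if per_chrom_capacity * config.n_chromosomes < config.n_genes:
        raise ConfigurationError("genes do not fit on the chromosomes")
    jitter_max = max(1, min(2000, spacing // 8))
    rows = []
    gi = 0
    width = len(str(config.n_genes))
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for j in range(per_chrom_capacity):
            if gi >= config.n_genes:
                break
            tss = spacing // 2 + j * spacing + int(rng.integers(-jitter_max, jitter_max))
            tss = int(np.clip(tss, 0, config.chromosome_length - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {
                    "gene_id": f"g{gi + 1:0{width}d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                }
            )
            gi += 1
    annotation = GeneAnnotation(pd.DataFrame(rows))
    return genome, annotation


# ---------------------------------------------------------------------------
# truth plan
# ---------------------------------------------------------------------------


def _random_distinct_consensi(
    rng: np.random.Generator, n: int, length: int
) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if s in seen or reverse_complement(s) in seen:
            continue
        seen.add(s)
        out.append(s)
    return out


def _consensus_matrix(consensus: str, p: float = 0.97) -> np.ndarray:
    mat = np.full((len(consensus), 4), (1.0 - p) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return mat


def generate_truth(
    config: SyntheticConfig, annotation: GeneAnnotation
) -> tuple[GroundTruth, list[MotifModel], dict[str, str]]:
    """Cluster labels, TF motifs and the planted edge set.

    Returns (truth, motif models for TFs and decoys, motif_id -> TF map).
    Every TF gene sits in the state cluster where it acts; decoy TFs get an
    enrichment state whose opposite state hosts their expression cluster,
    so the opposing-pattern rule must exclude them.
    """
    rng = np.random.default_rng(config.seed + 1)
    states = tuple(config.cell_states)
    genes = annotation.gene_ids
    n_special = config.n_tfs + config.n_decoy_tfs
    if n_special > len(genes):
        raise ConfigurationError("not enough genes for TFs and decoys")

    special = (
        [str(g) for g in rng.choice(genes, size=n_special, replace=False)]
        if n_special
        else []
    )
    tf_genes = special[: config.n_tfs]
    decoys = special[config.n_tfs :]

    truth = GroundTruth(tf_genes=list(tf_genes), decoy_tfs=list(decoys))
    for i, tf in enumerate(tf_genes):
        truth.tf_state[tf] = states[i % 4]
        truth.gene_clusters[tf] = states[i % 4]
    for i, tf in enumerate(decoys):
        enr_state = states[i % 4]
        truth.tf_state[tf] = enr_state
        truth.gene_clusters[tf] = _DECOY_CLUSTER[enr_state]

    rest = [g for g in genes if g not in set(special)]
    n_flat = int(round(config.fraction_flat_genes * len(rest)))
    flat = set(rng.choice(rest, size=n_flat, replace=False)) if n_flat else set()
    clustered = [g for g in rest if g not in flat]
    for g in flat:
        truth.gene_clusters[g] = "none"
    labels = rng.integers(0, len(CLUSTER_ORDER), size=len(clustered))
    for g, k in zip(clustered, labels):
        truth.gene_clusters[g] = CLUSTER_ORDER[int(k)]

    consensi = _random_distinct_consensi(rng, n_special, config.motif_length)
    motif_models = []
    motif_to_tf = {}
    for tf, cons in zip(tf_genes + decoys, consensi):
        mid = f"M_{tf}"
        motif_models.append(MotifModel(mid, tf, _consensus_matrix(cons)))
        motif_to_tf[mid] = tf

    # true edges: each TF regulates targets_per_tf genes of its own state cluster
    for tf in tf_genes:
        s = truth.tf_state[tf]
        candidates = [g for g in truth.cluster_members(s) if g != tf]
        k = min(config.targets_per_tf, len(candidates))
        targets = rng.choice(candidates, size=k, replace=False) if k else []
        for t in targets:
            truth.edges.append((tf, str(t), s))

    # planted auto-regulatory loops, spread across states
    by_state: dict[str, list[str]] = {s: [] for s in states}
    for tf in tf_genes:
        by_state[truth.tf_state[tf]].append(tf)
    loops: list[str] = []
    si = 0
    while len(loops) < config.planted_autoloops:
        s = states[si % 4]
        pool = [tf for tf in by_state[s] if tf not in loops]
        if pool:
            loops.append(pool[0])
        si += 1
        if si > 4 * config.n_tfs:
            raise ConfigurationError("cannot place the requested auto-loops")
    for tf in loops:
        truth.edges.append((tf, tf, truth.tf_state[tf]))
        truth.autoloop_tfs.append(tf)
    truth.edges = sorted(set(truth.edges))

    # bivalent genes: DC-cluster genes poised in the progenitor states
    dc_genes = [
        g
        for g in genes
        if truth.gene_clusters[g] in ("pan-DC", "cDC", "pDC") and g not in truth.tf_state
    ]
    k = min(config.n_bivalent_genes, len(dc_genes))
    truth.bivalent_genes = (
        sorted(str(g) for g in rng.choice(dc_genes, size=k, replace=False)) if k else []
    )
    return truth, motif_models, motif_to_tf


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    config: SyntheticConfig, truth: GroundTruth
) -> ExpressionMatrix:
    """Archetype-mean log2 expression with Gaussian replicate noise."""
    if config.replicates_per_state < 2:
        raise ConfigurationError("replicates_per_state must be >=2")
    rng = np.random.default_rng(config.seed + 2)
    states = tuple(config.cell_states)
    genes = sorted(truth.gene_clusters)
    samples = [
        f"{s}_rep{r + 1}" for s in states for r in range(config.replicates_per_state)
    ]
    means = np.empty((len(genes), 4))
    for i, g in enumerate(genes):
        cl = truth.gene_clusters[g]
        arch = (0, 0, 0, 0) if cl == "none" else ARCHETYPES[cl]
        means[i] = config.baseline_expression + config.log2_effect_size * np.asarray(
            arch, dtype=float
        )
    values = np.repeat(means, config.replicates_per_state, axis=1)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, {s: s.rsplit("_", 1)[0] for s in samples})


# ---------------------------------------------------------------------------
# peak tracks and motif planting
# ---------------------------------------------------------------------------


def _contrast_label(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def generate_peak_tracks(
    config: SyntheticConfig,
    truth: GroundTruth,
    annotation: GeneAnnotation,
    genome: Genome,
    motif_models: Mapping[str, MotifModel] | None = None,
) -> dict[tuple[str, str], PeakSet]:
    """Place per-state peak tracks and write motif instances into the genome.

    Mutates ``genome`` in place (consensus strings overwrite background
    sequence inside PU.1 peaks) and fills ``truth.motif_instances`` and
    ``truth.diff_peak_labels``. Returns {(state, mark): PeakSet}.
    """
    rng = np.random.default_rng(config.seed + 3)
    states = tuple(config.cell_states)
    sizes = genome.chrom_sizes
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    models = dict(motif_models or {})

    peaks: dict[tuple[str, str], list[GenomicInterval]] = {
        (s, m): [] for s in states for m in ("H3K4me1", "H3K4me3", "H3K27me3", "PU.1")
    }
    prom_half = 600  # promoter peaks span TSS +/- 600 bp, inside the 1 kb window

    # per-gene PU.1 peak bookkeeping for motif planting
    pu1_region: dict[str, tuple[str, int, int]] = {}
    pu1_states: dict[str, list[str]] = {}
    pu1_scores: dict[str, dict[str, float]] = {}
    slot_next: dict[str, int] = {}

    def clip(chrom: str, start: int, end: int) -> tuple[int, int]:
        cs, ce = max(0, start), min(sizes[chrom], end)
        if (cs, ce) != (start, end):
            warnings.warn(
                f"peak {chrom}:{start}-{end} clipped to chromosome bounds",
                stacklevel=2,
            )
        return cs, ce

    state_specific_genes = {
        g for g, c in truth.gene_clusters.items() if c in states
    }
    # a subset of state-specific genes carries score-fold (present-in-both)
    # differential peaks instead of presence/absence ones
    ss_sorted = sorted(state_specific_genes)
    n_fold = int(round(config.fraction_score_differential * len(ss_sorted)))
    fold_genes = (
        set(rng.choice(ss_sorted, size=n_fold, replace=False)) if n_fold else set()
    )

    for gene in annotation.iter_genes():
        g = gene.gene_id
        cluster = truth.gene_clusters.get(g, "none")
        active = {s for s in states if _activity(cluster, s, states)}

        # promoter marks
        ps, pe = clip(gene.chrom, gene.tss - prom_half, gene.tss + prom_half)
        for s in states:
            if s in active:
                peaks[(s, "H3K4me3")].append(
                    GenomicInterval(gene.chrom, ps, pe, float(rng.uniform(8, 12)), g)
                )
            else:
                peaks[(s, "H3K27me3")].append(
                    GenomicInterval(gene.chrom, ps, pe, float(rng.uniform(8, 12)), g)
                )
        if g in truth.bivalent_genes:
            for s in ("MPP", "CDP"):
                if s in states:
                    peaks[(s, "H3K4me3")].append(
                        GenomicInterval(gene.chrom, ps, pe, float(rng.uniform(4, 6)), g)
                    )
                    peaks[(s, "H3K27me3")].append(
                        GenomicInterval(gene.chrom, ps, pe, float(rng.uniform(4, 6)), g)
                    )

        if not active:
            continue

        # one distal PU.1 peak location per gene, shared across states
        off = int(rng.integers(2000, 8001))
        start, end = clip(gene.chrom, gene.tss + off, gene.tss + off + config.peak_width)
        base_score = float(rng.uniform(8, 12))
        pu1_region[g] = (gene.chrom, start, end)
        slot_next[g] = start + 10
        if g in fold_genes and cluster in states:
            # present in both states of the contrast, score_fold x higher in
            # the active one
            other = _OPPOSITE[cluster]
            present = sorted({cluster, other}, key=states.index)
            scores = {
                cluster: base_score * config.score_fold,
                other: base_score,
            }
        else:
            present = sorted(active, key=states.index)
            scores = {
                s: base_score * float(rng.uniform(0.95, 1.05)) for s in present
            }
        pu1_states[g] = present
        pu1_scores[g] = scores
        for s in present:
            peaks[(s, "PU.1")].append(
                GenomicInterval(gene.chrom, start, end, scores[s], g)
            )
            # H3K4me1 co-occurrence, Bernoulli at the configured fraction
            if rng.random() < config.pu1_h3k4me1_overlap:
                k4_start, k4_end = clip(
                    gene.chrom, start - 100, end + 100
                )
            else:
                k4_start, k4_end = clip(
                    gene.chrom, end + 500, end + 500 + config.peak_width
                )
            peaks[(s, "H3K4me1")].append(
                GenomicInterval(
                    gene.chrom, k4_start, k4_end, float(rng.uniform(8, 12)), g
                )
            )

    # plant motif instances: one per true edge, inside the target's PU.1 peak
    def plant(tf: str, target: str, state: str, record_edge: bool) -> None:
        model = models.get(f"M_{tf}")
        if model is None:
            raise ConfigurationError(f"no motif model for TF {tf!r}")
        chrom, start, end = pu1_region[target]
        L = len(model)
        pos = slot_next[target]
        if pos + L > end - 4:
            raise ConfigurationError(
                f"PU.1 peak of {target} too narrow for its motif instances; "
                "increase peak_width"
            )
        slot_next[target] = pos + L + 4
        strand = "+" if rng.random() < 0.5 else "-"
        cons = model.consensus if strand == "+" else reverse_complement(model.consensus)
        seqs[chrom][pos : pos + L] = cons.encode()
        truth.motif_instances.append(
            {
                "tf": tf,
                "target": target,
                "state": state,
                "chrom": chrom,
                "start": int(pos),
                "end": int(pos + L),
                "strand": strand,
                "decoy": not record_edge,
            }
        )

    for tf, target, state in truth.edges:
        if target not in pu1_region:
            raise ConfigurationError(
                f"true-edge target {target!r} has no PU.1 peak (inactive gene)"
            )
        plant(tf, target, state, record_edge=True)

    # decoy TFs: enriched in their state's peaks but expressed opposingly
    for decoy in truth.decoy_tfs:
        s = truth.tf_state[decoy]
        hosts = [
            g
            for g in sorted(state_specific_genes)
            if truth.gene_clusters[g] == s and g in pu1_region
        ]
        k = max(3, int(0.6 * len(hosts)))
        for host in hosts[: min(k, len(hosts))]:
            plant(decoy, host, s, record_edge=False)

    genome.sequences = {c: bytes(b).decode() for c, b in seqs.items()}

    # truth labels for differential PU.1 peaks, per contrast
    for contrast in CONTRASTS:
        a, b = contrast
        if a not in states or b not in states:
            continue
        lab = []
        for g, (chrom, start, end) in sorted(pu1_region.items()):
            present = set(pu1_states[g])
            if a in present and b not in present:
                lab.append((chrom, start, end, "a-specific"))
            elif b in present and a not in present:
                lab.append((chrom, start, end, "b-specific"))
            elif a in present and b in present:
                ratio = pu1_scores[g][a] / pu1_scores[g][b]
                if ratio >= config.score_fold - 1e-9:
                    lab.append((chrom, start, end, "a-specific"))
                elif ratio <= 1.0 / config.score_fold + 1e-9:
                    lab.append((chrom, start, end, "b-specific"))
                else:
                    lab.append((chrom, start, end, "shared"))
        truth.diff_peak_labels[_contrast_label(contrast)] = lab

    return {
        key: PeakSet(ivs, cell_state=key[0], mark=key[1])
        for key, ivs in peaks.items()
    }


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Genome
    annotation: GeneAnnotation
    expression: ExpressionMatrix
    peak_tracks: dict[tuple[str, str], PeakSet]
    motifs: list[MotifModel]
    motif_to_tf: dict[str, str]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.write_fasta(out / "genome.fa")
        self.annotation.write_tsv(out / "genes.tsv")
        self.expression.write_tsv(out / "expression.tsv")
        write_motifs_meme(self.motifs, out / "motifs.meme")
        for (state, mark), ps in self.peak_tracks.items():
            safe_mark = mark.replace(".", "")
            ps.write_bed(out / f"peaks_{state}_{safe_mark}.bed")
        pd.DataFrame(
            self.truth.edges, columns=["source", "target", "state"]
        ).to_csv(out / "truth_edges.tsv", sep="\t", index=False)
        labels = {
            "gene_clusters": self.truth.gene_clusters,
            "bivalent_genes": self.truth.bivalent_genes,
            "tf_genes": self.truth.tf_genes,
            "decoy_tfs": self.truth.decoy_tfs,
            "tf_state": self.truth.tf_state,
            "autoloop_tfs": self.truth.autoloop_tfs,
            "diff_peak_labels": self.truth.diff_peak_labels,
            "motif_instances": self.truth.motif_instances,
            "config": asdict(self.config),
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(labels, fh, indent=1, default=list)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete self-consistent dataset for one configuration."""
    genome, annotation = generate_genome(config)
    truth, motif_models, motif_to_tf = generate_truth(config, annotation)
    expression = generate_expression(config, truth)
    tracks = generate_peak_tracks(
        config,
        truth,
        annotation,
        genome,
        {m.motif_id: m for m in motif_models},
    )
    return SyntheticDataset(
        config, genome, annotation, expression, tracks, motif_models, motif_to_tf, truth
    )
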