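"""End-to-end inference: expression -> peaks -> motifs -> networks.

`run_pipeline` executes the full integrative procedure on a dataset
(synthetic or loaded from files): differential expression for the
commitment (MPP vs CDP) and subset-specification (cDC vs pDC) contrasts
plus the two bridging contrasts used for clustering, fuzzy c-means into six
clusters, differential PU.1 peak calling per contrast, per-state motif
enrichment in state-specific peaks, expression-consistent co-factor
selection, and the three-condition stage networks integrated into one
circuitry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .chip import DifferentialPeakCall, differential_peaks
from .expression import (
    ClusterAssignment,
    DEResult,
    ExpressionMatrix,
    differential_expression,
    fuzzy_cmeans,
)
from .genome import Genome
from .intervals import GeneAnnotation, PeakSet
from .motifs import (
    CofactorSelection,
    MotifModel,
    calibrate_all,
    motif_enrichment,
    scan_motif,
    select_cofactors,
)
from .network import (
    Circuitry,
    RegulatoryEdge,
    assign_peaks_to_genes,
    audit_stage_network,
    build_stage_network,
    integrate_circuitry,
)

STATES = ("MPP", "CDP", "cDC", "pDC")
NETWORK_CONTRASTS: dict[str, tuple[str, str]] = {
    "MPP": ("MPP", "CDP"),
    "CDP": ("MPP", "CDP"),
    "cDC": ("cDC", "pDC"),
    "pDC": ("cDC", "pDC"),
}
CLUSTERING_CONTRASTS = (
    ("MPP", "CDP"),
    ("CDP", "cDC"),
    ("CDP", "pDC"),
    ("cDC", "pDC"),
)


@dataclass
class PipelineParams:
    fc_threshold: float = 2.0
    alpha: float = 0.05
    de_method: str = "moderated"
    de_gate: str = "raw"
    n_clusters: int = 6
    fuzzifier: float = 2.0
    cluster_seed: int = 0
    peak_fc_threshold: float = 2.0
    peak_pseudocount: float = 0.5
    scan_fpr: float = 1e-4
    enrich_flank: int = 250
    enrich_alpha: float = 0.05
    assign_window: int = 50_000
    assign_mode: str = "window"


@dataclass
class PipelineResult:
    de_results: dict[tuple[str, str], list[DEResult]]
    clusters: list[ClusterAssignment]
    diff_calls: dict[tuple[str, str], list[DifferentialPeakCall]]
    enrichment: dict[str, pd.DataFrame]
    cofactors: CofactorSelection
    stage_networks: dict[str, list[RegulatoryEdge]]
    circuitry: Circuitry
    audit_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def edges(self) -> list[RegulatoryEdge]:
        return self.circuitry.edges


def _stage_specific_calls(
    calls: Sequence[DifferentialPeakCall], stage: str, contrast: tuple[str, str]
) -> list[DifferentialPeakCall]:
    want = "a-specific" if stage == contrast[0] else "b-specific"
    return [c for c in calls if c.direction == want]


def run_pipeline(
    expression: ExpressionMatrix,
    pu1_tracks: Mapping[str, PeakSet],
    genome: Genome,
    annotation: GeneAnnotation,
    motifs: Sequence[MotifModel],
    motif_to_tf: Mapping[str, str],
    params: PipelineParams | None = None,
    literature_edges: pd.DataFrame | None = None,
    extra_nodes: Sequence[str] = (),
) -> PipelineResult:
    params = params or PipelineParams()

    # 1. differential expression for network and clustering contrasts
    de_results: dict[tuple[str, str], list[DEResult]] = {}
    for contrast in CLUSTERING_CONTRASTS:
        de_results[contrast] = differential_expression(
            expression,
            *contrast,
            fc_threshold=params.fc_threshold,
            alpha=params.alpha,
            method=params.de_method,
            gate=params.de_gate,
        )

    # 2. fuzzy c-means over the union of DE genes
    de_genes = sorted(
        {r.gene_id for res in de_results.values() for r in res if r.is_de}
    )
    state_means = expression.state_means(STATES)
    if len(de_genes) >= params.n_clusters:
        clusters = fuzzy_cmeans(
            state_means.loc[de_genes],
            c=params.n_clusters,
            fuzzifier=params.fuzzifier,
            seed=params.cluster_seed,
        )
    else:
        clusters = []

    # 3. differential PU.1 peaks per contrast
    diff_calls = {
        contrast: differential_peaks(
            pu1_tracks[contrast[0]],
            pu1_tracks[contrast[1]],
            fc_threshold=params.peak_fc_threshold,
            pseudocount=params.peak_pseudocount,
        )
        for contrast in (("MPP", "CDP"), ("cDC", "pDC"))
    }

    # 4. per-state motif enrichment: fg = state-specific differential peaks,
    #    bg = the differential peaks specific to the other states (pooling
    #    both contrasts keeps the background large enough for a well-powered
    #    region-level Fisher test)
    calibrate_all(list(motifs), fpr=params.scan_fpr)
    enrichment: dict[str, pd.DataFrame] = {}
    stage_regions: dict[str, list[DifferentialPeakCall]] = {}
    specific = {
        s: _stage_specific_calls(diff_calls[NETWORK_CONTRASTS[s]], s, NETWORK_CONTRASTS[s])
        for s in STATES
    }
    for stage in STATES:
        fg_calls = specific[stage]
        bg_calls = [c for s in STATES if s != stage for c in specific[s]]
        stage_regions[stage] = fg_calls
        fg = PeakSet([c.interval for c in fg_calls], stage, "PU.1")
        bg = PeakSet([c.interval for c in bg_calls], "", "PU.1")
        enrichment[stage] = motif_enrichment(
            list(motifs),
            fg,
            bg,
            genome,
            flank=params.enrich_flank,
            alpha=params.enrich_alpha,
            fpr=params.scan_fpr,
        )

    # 5. expression-consistent co-binding partners
    tf_genes = sorted(set(motif_to_tf.values()))
    tf_means = state_means.loc[[g for g in tf_genes if g in state_means.index]]
    cofactors = select_cofactors(enrichment, motif_to_tf, tf_means, de_results)

    # 6. stage networks under the three-condition rule
    tf_motif = {tf: m for m in motifs for tf in [motif_to_tf.get(m.motif_id)] if tf}
    stage_networks: dict[str, list[RegulatoryEdge]] = {}
    audit_fractions: dict[str, float] = {}
    for stage in STATES:
        contrast = NETWORK_CONTRASTS[stage]
        fg_calls = stage_regions[stage]
        peak_gene_map = assign_peaks_to_genes(
            [c.interval for c in fg_calls],
            annotation,
            window=params.assign_window,
            mode=params.assign_mode,
        )
        hits = {}
        for tf in cofactors.partners[stage]:
            model = tf_motif[tf]
            tf_hits = []
            for c in fg_calls:
                iv = c.interval
                end = min(iv.end, genome.chrom_sizes[iv.chrom])
                seq = genome.fetch(iv.chrom, iv.start, end)
                tf_hits.extend(
                    scan_motif(model, seq, chrom=iv.chrom, offset=iv.start)
                )
            hits[tf] = tf_hits
        edges = build_stage_network(
            stage,
            contrast,
            cofactors.partners[stage],
            de_results[contrast],
            fg_calls,
            hits,
            peak_gene_map,
            extra_nodes=extra_nodes,
        )
        stage_networks[stage] = edges
        audit_fractions[stage] = audit_stage_network(
            edges,
            stage,
            contrast,
            cofactors.partners[stage],
            de_results[contrast],
            fg_calls,
            hits,
            peak_gene_map,
        )

    circuitry = integrate_circuitry(stage_networks, literature_edges)
    return PipelineResult(
        de_results,
        clusters,
        diff_calls,
        enrichment,
        cofactors,
        stage_networks,
        circuitry,
        audit_fractions,
    )


def run_pipeline_on_dataset(dataset, params: PipelineParams | None = None, **kwargs):
    """Convenience wrapper running the pipeline on a SyntheticDataset."""
    pu1 = {s: dataset.peak_tracks[(s, "PU.1")] for s in STATES}
    return run_pipeline(
        dataset.expression,
        pu1,
        dataset.genome,
        dataset.annotation,
        dataset.motifs,
        dataset.motif_to_tf,
        params=params,
        **kwargs,
    )
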