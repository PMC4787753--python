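"""Stage-specific TF regulatory networks and the integrated circuitry.

An inferred edge a -> b in cell state s requires the conjunction of three
conditions: (i) a is an expression-consistent co-binding partner (motif
significantly enriched) in s, (ii) b is differentially expressed in the
stage direction of s's contrast, and (iii) >=1 binding site of a's motif
lies inside an s-specific differential PU.1 peak assigned to b. Inferred
edges are always activations; inhibitions enter only as signed literature
edges, which are never used as inference evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .chip import DifferentialPeakCall
from .expression import DEResult
from .intervals import GeneAnnotation, GenomicInterval, PeakSet
from .motifs import MotifHit

DEFAULT_STATES = ("MPP", "CDP", "cDC", "pDC")


@dataclass
class RegulatoryEdge:
    source_tf: str
    target_gene: str
    cell_state: str
    sign: str = "activation"
    evidence: dict = field(
        default_factory=lambda: {
            "enriched_in_state": False,
            "target_de": False,
            "tfbs_in_diff_peak": False,
            "literature": False,
        }
    )
    supporting_hits: list[MotifHit] = field(default_factory=list)
    citation: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_tf, self.target_gene, self.cell_state)

    @property
    def is_self_loop(self) -> bool:
        return self.source_tf == self.target_gene


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval] | PeakSet,
    annotation: GeneAnnotation,
    window: int = 50_000,
    mode: str = "window",
) -> list[list[str]]:
    """Gene ids assigned to each peak (parallel to the input order).

    A peak is assigned to every gene whose TSS +/- window interval it
    overlaps by >=1 bp; ``mode="nearest"`` keeps only the gene whose TSS is
    closest to the peak midpoint (ties -> smaller TSS coordinate).
    """
    if mode not in ("window", "nearest"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    ivs = list(peaks)
    genes = list(annotation.iter_genes())
    out: list[list[str]] = []
    for iv in ivs:
        cands = [
            g
            for g in genes
            if g.chrom == iv.chrom and iv.start < g.tss + window and g.tss - window < iv.end
        ]
        if mode == "nearest" and len(cands) > 1:
            mid = iv.midpoint
            cands = [min(cands, key=lambda g: (abs(g.tss - mid), g.tss))]
        out.append([g.gene_id for g in cands])
    return out


def build_stage_network(
    stage: str,
    contrast: tuple[str, str],
    cofactors: Sequence[str],
    de_results: Sequence[DEResult],
    diff_peaks: Sequence[DifferentialPeakCall],
    hits: Mapping[str, Sequence[MotifHit]],
    peak_gene_map: Sequence[Sequence[str]],
    extra_nodes: Sequence[str] = (),
) -> list[RegulatoryEdge]:
    """Emit all edges satisfying the three-condition rule for one stage.

    ``contrast`` is the (a, b) state pair the DE results and differential
    peak calls were computed on; ``stage`` must be one of the two and fixes
    the direction (up-in-stage genes, stage-specific peaks). ``hits`` maps
    each cofactor TF to its motif hits in genome coordinates;
    ``peak_gene_map`` is parallel to ``diff_peaks``. ``extra_nodes`` may
    appear as targets only (they are already plain genes here; the
    restriction is that they are never sources).
    """
    if stage == contrast[0]:
        want_dir, want_up = "a-specific", 1
    elif stage == contrast[1]:
        want_dir, want_up = "b-specific", -1
    else:
        raise ValueError(f"stage {stage!r} is not part of contrast {contrast!r}")
    if len(peak_gene_map) != len(diff_peaks):
        raise ValueError("peak_gene_map must be parallel to diff_peaks")

    de_up = {
        r.gene_id
        for r in de_results
        if r.is_de and r.log2_fold_change * want_up > 0
    }
    edges: dict[tuple[str, str, str], RegulatoryEdge] = {}
    for call, genes in zip(diff_peaks, peak_gene_map):
        if call.direction != want_dir:
            continue
        region = call.interval
        for tf in cofactors:
            tf_hits = [
                h
                for h in hits.get(tf, [])
                if h.interval.overlaps(region)
            ]
            if not tf_hits:
                continue
            for gene in genes:
                if gene not in de_up:
                    continue
                key = (tf, gene, stage)
                if key not in edges:
                    edges[key] = RegulatoryEdge(
                        tf,
                        gene,
                        stage,
                        evidence={
                            "enriched_in_state": True,
                            "target_de": True,
                            "tfbs_in_diff_peak": True,
                            "literature": False,
                        },
                    )
                edges[key].supporting_hits.extend(tf_hits)
    return [edges[k] for k in sorted(edges)]


def audit_stage_network(
    edges: Sequence[RegulatoryEdge],
    stage: str,
    contrast: tuple[str, str],
    cofactors: Sequence[str],
    de_results: Sequence[DEResult],
    diff_peaks: Sequence[DifferentialPeakCall],
    hits: Mapping[str, Sequence[MotifHit]],
    peak_gene_map: Sequence[Sequence[str]],
) -> float:
    """Fraction of non-literature edges that re-satisfy all three conditions.

    Rebuilds the stage network from the stored evidence inputs and checks
    each audited edge is reproduced with all evidence flags true.
    """
    rebuilt = {
        e.key
        for e in build_stage_network(
            stage, contrast, cofactors, de_results, diff_peaks, hits, peak_gene_map
        )
    }
    audited = [e for e in edges if not e.evidence.get("literature", False)]
    if not audited:
        return float("nan")
    ok = sum(
        1
        for e in audited
        if e.key in rebuilt
        and e.evidence["enriched_in_state"]
        and e.evidence["target_de"]
        and e.evidence["tfbs_in_diff_peak"]
    )
    return ok / len(audited)


def detect_self_loops(network: Sequence[RegulatoryEdge]) -> list[RegulatoryEdge]:
    """Auto-regulatory edges (source == target), deduplicated by key."""
    merged: dict[tuple[str, str, str], RegulatoryEdge] = {}
    for e in network:
        if not e.is_self_loop:
            continue
        if e.key in merged:
            merged[e.key].supporting_hits.extend(e.supporting_hits)
            for k, v in e.evidence.items():
                merged[e.key].evidence[k] = merged[e.key].evidence.get(k, False) or v
        else:
            merged[e.key] = RegulatoryEdge(
                e.source_tf,
                e.target_gene,
                e.cell_state,
                e.sign,
                dict(e.evidence),
                list(e.supporting_hits),
                e.citation,
            )
    return [merged[k] for k in sorted(merged)]


@dataclass
class Circuitry:
    nodes: dict[str, set[str]]  # node -> stages where it acts
    edges: list[RegulatoryEdge]
    self_loops: list[RegulatoryEdge]

    def activation_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.sign == "activation":
                g.add_edge(e.source_tf, e.target_gene)
        return g


def integrate_circuitry(
    stage_networks: Mapping[str, Sequence[RegulatoryEdge]],
    literature_edges: pd.DataFrame | None = None,
    expected_states: Sequence[str] = DEFAULT_STATES,
) -> Circuitry:
    """Union the four stage networks and append signed literature edges.

    ``literature_edges`` columns: source, target, sign ("activation" or
    "inhibition"), citation. Stage edges are deduplicated by
    (source, target, state); node stage annotations are the union of the
    states of incident edges.
    """
    if set(stage_networks) != set(expected_states):
        raise ValueError(
            f"expected stage networks for {sorted(expected_states)}, "
            f"got {sorted(stage_networks)}"
        )
    merged: dict[tuple[str, str, str], RegulatoryEdge] = {}
    for stage in expected_states:
        for e in stage_networks[stage]:
            if e.cell_state != stage:
                raise ValueError(
                    f"edge {e.key} filed under stage {stage!r}"
                )
            if e.key in merged:
                merged[e.key].supporting_hits.extend(e.supporting_hits)
            else:
                merged[e.key] = e
    edges = [merged[k] for k in sorted(merged)]

    if literature_edges is not None:
        for row in literature_edges.itertuples(index=False):
            sign = str(row.sign)
            if sign not in ("activation", "inhibition"):
                raise ValueError(f"literature edge with unknown sign {sign!r}")
            citation = str(getattr(row, "citation", ""))
            if not citation:
                raise ValueError(
                    f"literature edge {row.source}->{row.target} lacks a citation"
                )
            edges.append(
                RegulatoryEdge(
                    str(row.source),
                    str(row.target),
                    cell_state="",
                    sign=sign,
                    evidence={
                        "enriched_in_state": False,
                        "target_de": False,
                        "tfbs_in_diff_peak": False,
                        "literature": True,
                    },
                    citation=citation,
                )
            )

    nodes: dict[str, set[str]] = {}
    for e in edges:
        for node in (e.source_tf, e.target_gene):
            nodes.setdefault(node, set())
            if e.cell_state:
                nodes[node].add(e.cell_state)
    circ = Circuitry(nodes, edges, [])
    circ.self_loops = detect_self_loops(edges)
    return circ


def find_feedback_cycles(
    circuitry: Circuitry, max_length: int = 4
) -> list[tuple[str, ...]]:
    """Simple directed cycles of length <= max_length among activation edges.

    Each cycle is reported once, rotated so its lexicographically smallest
    node comes first; self-loops appear as length-1 cycles.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    g = circuitry.activation_graph()
    cycles = []
    for cyc in nx.simple_cycles(g, length_bound=max_length):
        i = min(range(len(cyc)), key=lambda k: cyc[k])
        cycles.append(tuple(cyc[i:] + cyc[:i]))
    return sorted(set(cycles), key=lambda c: (len(c), c))


def node_connectivity(circuitry: Circuitry) -> pd.DataFrame:
    """Per-node in/out/total degree over unique (source, target, state) edges."""
    seen = set()
    rows = {n: {"in_degree": 0, "out_degree": 0} for n in circuitry.nodes}
    for e in circuitry.edges:
        if e.key in seen:
            continue
        seen.add(e.key)
        rows.setdefault(e.source_tf, {"in_degree": 0, "out_degree": 0})
        rows.setdefault(e.target_gene, {"in_degree": 0, "out_degree": 0})
        rows[e.source_tf]["out_degree"] += 1
        rows[e.target_gene]["in_degree"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df["total_degree"] = df["in_degree"] + df["out_degree"]
    df.index.name = "node"
    return df


def edges_to_frame(edges: Sequence[RegulatoryEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [e.source_tf for e in edges],
            "target": [e.target_gene for e in edges],
            "state": [e.cell_state for e in edges],
            "sign": [e.sign for e in edges],
            "enriched_in_state": [e.evidence.get("enriched_in_state", False) for e in edges],
            "target_de": [e.evidence.get("target_de", False) for e in edges],
            "tfbs_in_diff_peak": [e.evidence.get("tfbs_in_diff_peak", False) for e in edges],
            "literature": [e.evidence.get("literature", False) for e in edges],
            "n_hits": [len(e.supporting_hits) for e in edges],
        }
    )


def write_edges_tsv(edges: Sequence[RegulatoryEdge], path: str | Path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)


def write_graphml(circuitry: Circuitry, path: str | Path) -> None:
    g = nx.MultiDiGraph()
    for node, stages in circuitry.nodes.items():
        g.add_node(node, stages=",".join(sorted(stages)))
    for e in circuitry.edges:
        g.add_edge(
            e.source_tf, e.target_gene, state=e.cell_state, sign=e.sign,
            literature=bool(e.evidence.get("literature", False)),
        )
    nx.write_graphml(g, str(path))


def read_literature_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"source", "target", "sign", "citation"}
    if not required <= set(df.columns):
        raise ValueError(f"literature edge table needs columns {sorted(required)}")
    return df
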