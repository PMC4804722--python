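"""Tracking hub-centered clusters across the five developmental stages.

A cluster's hub is the node with maximal within-cluster weighted degree.
For each hub a presence table records, per partner TFBS, a five-stage boolean
vector: true exactly in the stages where the hub-partner edge lies inside the
hub's cluster.  Rows are classified into temporal categories, pairs are
annotated with TF-gene expression relative to an FPKM threshold (default 10),
and per-stage counts are summarized with an hourglass profile (the location
of the minimum across the five stages).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .mcl import ClusterSet
from .preprocess import DEFAULT_STAGES, ExpressionMatrix, StageDefinition

TEMPORAL_CATEGORIES = ("all_stages", "interrupted", "stage_specific", "other")

ANNOTATION_MODES = ("synergistic_candidate", "antagonistic_candidate", "indeterminate")


@dataclasses.dataclass
class StagePresenceTable:
    """Hub-centered pair x stage presence (+/-) table.

    ``rows`` maps each partner TFBS id to a length-5 boolean vector ordered by
    stage (d0-3, d3-8, d8-13, d13-29, d29-60 by default).  Every row has at
    least one true entry and the hub is never among the partners.
    """

    hub: str
    rows: dict[str, tuple[bool, ...]]
    stage_names: tuple[str, ...] = tuple(s.name for s in DEFAULT_STAGES)

    def __post_init__(self) -> None:
        n = len(self.stage_names)
        for partner, vec in self.rows.items():
            if partner == self.hub:
                raise ValueError("hub must not appear among partners")
            if len(vec) != n:
                raise ValueError(f"{partner}: presence vector must have length {n}")
            if not any(vec):
                raise ValueError(f"{partner}: presence vector must have a true entry")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["pair\t" + "\t".join(self.stage_names)]
        for partner in sorted(self.rows):
            cells = "\t".join("+" if v else "-" for v in self.rows[partner])
            lines.append(f"{self.hub} - {partner}\t{cells}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass(frozen=True)
class ExpressionAnnotation:
    """Expressed-timepoint sets of a pair's two sides and the resulting mode."""

    pair: tuple[str, str]
    expressed_a: frozenset[int]
    expressed_b: frozenset[int]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ANNOTATION_MODES:
            raise ValueError(f"unknown annotation mode: {self.mode}")


def within_cluster_degree(cluster: Iterable[str], net: nx.Graph) -> dict[str, float]:
    """Weighted degree of each cluster node inside the induced subgraph."""
    sub = net.subgraph(cluster)
    return {n: float(d) for n, d in sub.degree(weight="weight")}


def find_hub(cluster: Iterable[str], net: nx.Graph) -> str:
    """Cluster center: maximal within-cluster weighted degree, ties broken
    lexicographically."""
    cluster = list(cluster)
    if not cluster:
        raise ValueError("cluster must be non-empty")
    degrees = within_cluster_degree(cluster, net)
    best = max(degrees.values(), default=0.0)
    return sorted(n for n in cluster if degrees.get(n, 0.0) == best)[0]


def filter_reportable_clusters(clusters: ClusterSet, net: nx.Graph) -> ClusterSet:
    """Keep clusters whose induced subgraph has >= 3 edges (>= 3 interactions);
    singletons are always dropped."""
    kept = []
    for c in clusters.clusters:
        if len(c) < 2:
            continue
        if net.subgraph(c).number_of_edges() >= 3:
            kept.append(c)
    return ClusterSet(stage=clusters.stage, clusters=kept)


def track_hub_across_stages(
    clusters_by_stage: Mapping[str, ClusterSet],
    nets_by_stage: Mapping[str, nx.Graph],
    hub: str,
    stage_names: Sequence[str] | None = None,
) -> StagePresenceTable:
    """Presence table of a hub's partners across all stages.

    Per stage, the partners are the nodes adjacent to the hub *within the
    hub's cluster* at that stage; the table's rows are the union of partners
    over all stages, each with a per-stage boolean vector.
    """
    if stage_names is None:
        stage_names = [s.name for s in DEFAULT_STAGES]
    per_stage_partners: list[set[str]] = []
    for stage in stage_names:
        partners: set[str] = set()
        cs = clusters_by_stage.get(stage)
        net = nets_by_stage.get(stage)
        if cs is not None and net is not None and hub in net:
            cluster = cs.cluster_of(hub)
            if cluster is not None:
                partners = set(net.neighbors(hub)) & set(cluster)
        per_stage_partners.append(partners)
    union = sorted(set().union(*per_stage_partners)) if per_stage_partners else []
    if not union:
        raise ValueError(f"hub {hub} is never clustered with partners in any stage")
    rows = {
        p: tuple(p in partners for partners in per_stage_partners) for p in union
    }
    return StagePresenceTable(hub=hub, rows=rows, stage_names=tuple(stage_names))


def classify_temporal(presence: Sequence[bool]) -> str:
    """Temporal category of a presence vector.

    all true -> ``all_stages``; any true-false-true pattern -> ``interrupted``;
    exactly one true -> ``stage_specific``; anything else -> ``other``.
    """
    vec = [bool(v) for v in presence]
    if not any(vec):
        raise ValueError("presence vector must have at least one true entry")
    if all(vec):
        return "all_stages"
    if sum(vec) == 1:
        return "stage_specific"
    true_idx = [i for i, v in enumerate(vec) if v]
    if any(not vec[j] for j in range(true_idx[0], true_idx[-1])):
        return "interrupted"
    return "other"


def count_union_pairs(table: StagePresenceTable) -> int:
    """Total number of partner rows (pairs in the union over all stages)."""
    return len(table.rows)


def count_all_stage_pairs(table: StagePresenceTable) -> int:
    """Number of rows present in every stage."""
    return sum(1 for vec in table.rows.values() if all(vec))


def expressed_timepoints(
    genes: Sequence[str],
    expr: ExpressionMatrix,
    threshold: float = 10.0,
) -> frozenset[int]:
    """Timepoints where any of the genes has replicate-mean FPKM >= threshold."""
    means = expr.mean_by_timepoint()
    present = [g for g in genes if g in means.index]
    if not present:
        return frozenset()
    sub = means.loc[present]
    return frozenset(int(day) for day in sub.columns if (sub[day] >= threshold).any())


def annotate_expression(
    pair: tuple[str, str],
    presence: Sequence[bool],
    tf_mapping: Mapping[str, Sequence[str]],
    expr: ExpressionMatrix,
    threshold: float = 10.0,
    stages: Sequence[StageDefinition] = DEFAULT_STAGES,
) -> ExpressionAnnotation:
    """Expression-threshold annotation of a TFBS pair.

    Each side's expressed set holds the timepoints where the maximum
    replicate-mean FPKM over its mapped TF genes reaches the threshold
    (inclusive).  The pair is a ``synergistic_candidate`` when the two sides'
    expressed sets share a timepoint inside *every* stage where the pair is
    present, an ``antagonistic_candidate`` when both sets are non-empty yet
    disjoint within every present stage, and ``indeterminate`` otherwise.
    """
    side_sets = []
    for pwm_id in pair:
        genes = list(tf_mapping.get(pwm_id, []))
        genes = [g for g in genes if g in expr.genes]
        if not genes:
            raise ValueError(f"no mapped TF gene with expression data for {pwm_id}")
        side_sets.append(expressed_timepoints(genes, expr, threshold))
    ex_a, ex_b = side_sets
    present_stages = [s for s, p in zip(stages, presence) if p]
    if ex_a and ex_b and present_stages:
        syn = all(
            ex_a & ex_b & set(s.timepoints) for s in present_stages
        )
        ant = all(
            not ((ex_a & set(s.timepoints)) & (ex_b & set(s.timepoints)))
            for s in present_stages
        )
    else:
        syn = ant = False
    if syn:
        mode = "synergistic_candidate"
    elif ant and ex_a and ex_b:
        mode = "antagonistic_candidate"
    else:
        mode = "indeterminate"
    return ExpressionAnnotation(pair=tuple(pair), expressed_a=ex_a, expressed_b=ex_b,
                                mode=mode)


def hourglass_profile(counts: Sequence[int]) -> tuple[int, bool]:
    """Location of the minimum in a five-stage count profile.

    Returns the 1-based stage index of the minimum (first occurrence on ties)
    and whether it lies strictly inside the profile (stages 2-4), i.e. whether
    the counts display the hourglass shape of high early/late divergence with
    a mid-developmental waist.
    """
    counts = list(counts)
    if len(counts) != 5 or any(c < 0 for c in counts):
        raise ValueError("expected 5 non-negative per-stage counts")
    argmin = min(range(5), key=lambda i: (counts[i], i)) + 1
    return argmin, argmin in (2, 3, 4)


def annotation_to_json(annotations: Iterable[ExpressionAnnotation],
                       path: str | Path) -> None:
    payload = [
        {
            "pair": list(a.pair),
            "expressed_a": sorted(a.expressed_a),
            "expressed_b": sorted(a.expressed_b),
            "mode": a.mode,
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
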