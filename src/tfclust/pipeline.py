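"""End-to-end pipeline: expression -> unique DEGs -> promoters -> pair
frequencies -> per-stage networks -> MCL clusters -> hub presence tables.

``run_pipeline`` drives the whole analysis on in-memory inputs (the CLI and
the synthetic fixtures both feed it); ``evaluate_against_truth`` scores a
result against a fixture's ground truth.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx

from .composites import (
    CompositeModel,
    PairFrequencyTable,
    aggregate_frequencies,
)
from .mcl import ClusterSet, MCLParams, build_network, cluster_network
from .preprocess import (
    DEFAULT_STAGES,
    ExpressionMatrix,
    GeneAnnotation,
    StageDefinition,
    call_stage_degs,
    extract_promoters,
    filter_unique_degs,
    remove_overlapping_promoters,
)
from .pwm import PWM
from .stages import (
    ExpressionAnnotation,
    StagePresenceTable,
    annotate_expression,
    classify_temporal,
    filter_reportable_clusters,
    find_hub,
    hourglass_profile,
    track_hub_across_stages,
)
from .simulate import Fixture, GroundTruth


@dataclasses.dataclass
class PipelineResult:
    stage_names: list[str]
    unique_degs: dict[str, set[str]]
    promoters_by_stage: dict[str, dict[str, str]]
    frequency_tables: dict[str, PairFrequencyTable]
    networks: dict[str, nx.Graph]
    clusters: dict[str, ClusterSet]
    reportable: dict[str, ClusterSet]
    hub_tables: dict[str, StagePresenceTable]
    temporal_categories: dict[str, dict[str, str]]
    annotations: dict[str, list[ExpressionAnnotation]]
    pair_counts: list[int]
    hourglass: tuple[int, bool]


def run_pipeline(
    expression: ExpressionMatrix,
    annotations: Mapping[str, GeneAnnotation],
    genome: Mapping[str, str],
    pwms: Mapping[str, PWM],
    library: Sequence[CompositeModel],
    tf_mapping: Mapping[str, Sequence[str]] | None = None,
    stages: Sequence[StageDefinition] = DEFAULT_STAGES,
    window: tuple[int, int] = (-1000, 0),
    counting_mode: str = "promoters",
    mcl_params: MCLParams | None = None,
    fpkm_threshold: float = 10.0,
    p_max: float = 0.05,
    fdr_max: float = 0.01,
) -> PipelineResult:
    """Run the full stage-specific TFBS-cluster analysis."""
    mcl_params = mcl_params or MCLParams()
    stage_names = [s.name for s in stages]

    calls = {s.name: call_stage_degs(expression, s) for s in stages}
    unique = filter_unique_degs(calls, annotations, p_max=p_max, fdr_max=fdr_max)

    sequences, regions = extract_promoters(
        [annotations[g] for g in sorted(annotations)], genome, window=window
    )
    kept = remove_overlapping_promoters(regions)
    pair_nodes = {m.pair_id: (m.pwm_a, m.pwm_b) for m in library}

    promoters_by_stage: dict[str, dict[str, str]] = {}
    freq_tables: dict[str, PairFrequencyTable] = {}
    networks: dict[str, nx.Graph] = {}
    clusters: dict[str, ClusterSet] = {}
    reportable: dict[str, ClusterSet] = {}
    for name in stage_names:
        proms = {g: sequences[g] for g in sorted(unique[name]) if g in kept}
        promoters_by_stage[name] = proms
        if proms:
            freq = aggregate_frequencies(
                library, proms, pwms, mode=counting_mode, stage=name
            )
        else:
            freq = PairFrequencyTable(stage=name, weights={})
        freq_tables[name] = freq
        net = build_network(freq, pair_nodes)
        networks[name] = net
        if net.number_of_nodes() > 0:
            _, cs = cluster_network(net, mcl_params, stage=name)
        else:
            cs = ClusterSet(stage=name, clusters=[])
        clusters[name] = cs
        reportable[name] = filter_reportable_clusters(cs, net)

    hubs: set[str] = set()
    for name in stage_names:
        for cluster in reportable[name].clusters:
            hubs.add(find_hub(cluster, networks[name]))

    hub_tables: dict[str, StagePresenceTable] = {}
    temporal: dict[str, dict[str, str]] = {}
    annos: dict[str, list[ExpressionAnnotation]] = {}
    for hub in sorted(hubs):
        try:
            table = track_hub_across_stages(
                reportable, networks, hub, stage_names=stage_names
            )
        except ValueError:
            continue
        hub_tables[hub] = table
        temporal[hub] = {
            partner: classify_temporal(vec) for partner, vec in table.rows.items()
        }
        if tf_mapping:
            hub_annos = []
            for partner, vec in sorted(table.rows.items()):
                try:
                    hub_annos.append(
                        annotate_expression(
                            (hub, partner),
                            vec,
                            tf_mapping,
                            expression,
                            threshold=fpkm_threshold,
                            stages=stages,
                        )
                    )
                except ValueError:
                    continue
            annos[hub] = hub_annos

    pair_counts = [len(freq_tables[name].weights) for name in stage_names]
    if len(pair_counts) == 5:
        hourglass = hourglass_profile(pair_counts)
    else:
        hourglass = (0, False)

    return PipelineResult(
        stage_names=stage_names,
        unique_degs=unique,
        promoters_by_stage=promoters_by_stage,
        frequency_tables=freq_tables,
        networks=networks,
        clusters=clusters,
        reportable=reportable,
        hub_tables=hub_tables,
        temporal_categories=temporal,
        annotations=annos,
        pair_counts=pair_counts,
        hourglass=hourglass,
    )


def run_pipeline_on_fixture(fixture: Fixture, **kwargs) -> PipelineResult:
    """Convenience wrapper binding a synthetic fixture's pieces to the pipeline."""
    return run_pipeline(
        expression=fixture.expression,
        annotations=fixture.annotations,
        genome=fixture.genome,
        pwms=fixture.pwm_dict,
        library=fixture.library,
        tf_mapping=fixture.tf_mapping,
        window=(-fixture.spec.promoter_length, 0),
        **kwargs,
    )


@dataclasses.dataclass
class TruthEvaluation:
    """Per-fixture agreement between a pipeline run and the planted structure."""

    deg_sets_exact: bool
    deg_recall: float
    multi_stage_leakage: int
    pair_tables_exact: bool
    hubs_recovered: bool
    n_hub_stage_checks: int
    n_hub_stage_correct: int


def evaluate_against_truth(result: PipelineResult, truth: GroundTruth) -> TruthEvaluation:
    """Score a pipeline result against the generator's ground truth.

    Hub recovery is judged per stage on the raw MCL partition: for every hub
    with planted partners in a stage, some cluster must equal {hub} union its
    planted partners for that stage.
    """
    total_truth = 0
    total_found = 0
    exact = True
    for stage, genes in truth.unique_degs.items():
        found = result.unique_degs.get(stage, set())
        total_truth += len(genes)
        total_found += len(found & set(genes))
        if found != set(genes):
            exact = False
    recall = total_found / total_truth if total_truth else 1.0

    all_found: set[str] = set()
    for found in result.unique_degs.values():
        all_found |= found
    # genes planted as DE in two stages must never appear in any unique set
    multi = len(all_found & set(truth.two_stage_degs))

    pair_exact = all(
        dict(result.frequency_tables[stage].weights) == truth.pair_frequencies[stage]
        for stage in truth.pair_frequencies
        if stage in result.frequency_tables
    )

    checks = 0
    correct = 0
    for stage, hub_map in truth.hub_members.items():
        cs = result.clusters.get(stage)
        cluster_sets = [set(c) for c in cs.clusters] if cs else []
        for hub, partners in hub_map.items():
            if not partners:
                continue
            checks += 1
            expected = {hub} | set(partners)
            if expected in cluster_sets:
                correct += 1
    return TruthEvaluation(
        deg_sets_exact=exact,
        deg_recall=recall,
        multi_stage_leakage=multi,
        pair_tables_exact=pair_exact,
        hubs_recovered=(checks > 0 and correct == checks),
        n_hub_stage_checks=checks,
        n_hub_stage_correct=correct,
    )
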