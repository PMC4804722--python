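"""Seeded synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline expects: a six-timepoint
(days 0, 3, 8, 13, 29, 60) FPKM time course with stage-unique differentially
expressed genes, promoters carrying planted composite TFBS pairs organized in
a hub-and-spoke topology (dense intra-hub pair frequencies, weight-1
cross-hub bridges), TF genes whose expression crosses the FPKM-10 threshold
in designed stage patterns (including one all-stages synergistic pair and one
early/late antagonistic pair), plus a ground-truth record so every pipeline
stage has an oracle.

All randomness flows through one ``numpy.random.Generator`` seeded from the
fixture spec; a fixed seed yields byte-identical emitted files.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .composites import CompositeModel, find_all_occurrences, write_library_tsv
from .preprocess import (
    DEFAULT_STAGES,
    DEFAULT_TIMEPOINTS,
    ExpressionMatrix,
    GeneAnnotation,
    extract_promoters,
    write_annotations,
    write_fasta,
)
from .pwm import ALPHABET, PWM, reverse_complement, score_site, write_transfac

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


class OverconstrainedPlantingError(ValueError):
    """More planted sites were requested than the promoters can hold."""


@dataclasses.dataclass
class FixtureSpec:
    """Study conditions of the synthetic fixture.

    The defaults are the generator's fixed study design: 300 genes, 1 kb
    promoters, 4 hubs with 3-6 partner TFBSs each, per-pair planted
    frequencies of 4-7 promoters per present stage, a log2 effect size of 4
    with log2-scale noise sd 0.25 over 3 replicates, and baseline FPKM levels
    straddling the threshold of 10.
    """

    seed: int = 0
    n_genes: int = 300
    promoter_length: int = 1000
    n_hubs: int = 4
    partners_per_hub: tuple[int, int] = (3, 6)
    pair_frequency: tuple[int, int] = (4, 7)
    de_genes_per_stage: int = 40
    n_two_stage_de: int = 6
    effect_log2: float = 4.0
    noise_sd_log2: float = 0.25
    replicates: int = 3
    gc: float = 0.5
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    pwm_length: tuple[int, int] = (10, 12)
    pwm_ic: tuple[float, float] = (12.0, 16.0)
    site_score_floor: float = 0.97
    min_gap: int = 5
    max_gap: int = 20
    model_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_genes < 5 * self.de_genes_per_stage + self.n_two_stage_de + 3:
            raise ValueError(
                "n_genes must cover the per-stage DE blocks plus decoy genes"
            )
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for the stand-in DEG test")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure: the oracle for every downstream pipeline stage."""

    unique_degs: dict[str, list[str]]
    pair_frequencies: dict[str, dict[str, int]]
    pair_patterns: dict[str, list[bool]]
    hub_members: dict[str, dict[str, list[str]]]
    hub_partner_union: dict[str, list[str]]
    planted_occurrences: list[dict]
    two_stage_degs: list[str]
    expressed_timepoints: dict[str, list[int]]
    synergistic_pair: str
    antagonistic_pair: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclasses.dataclass
class Fixture:
    """In-memory fixture plus the file formats the pipeline consumes."""

    spec: FixtureSpec
    genome: dict[str, str]
    annotations: dict[str, GeneAnnotation]
    pwms: list[PWM]
    library: list[CompositeModel]
    expression: ExpressionMatrix
    tf_mapping: dict[str, list[str]]
    promoters: dict[str, str]
    ground_truth: GroundTruth

    @property
    def pwm_dict(self) -> dict[str, PWM]:
        return {p.id: p for p in self.pwms}

    @property
    def pair_nodes(self) -> dict[str, tuple[str, str]]:
        return {m.pair_id: (m.pwm_a, m.pwm_b) for m in self.library}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "annotations": out / "annotations.tsv",
            "tf_list": out / "tf_list.txt",
            "pwms": out / "pwms.transfac",
            "library": out / "library.tsv",
            "expression": out / "expression.tsv",
            "tf_mapping": out / "tf_mapping.tsv",
            "promoters": out / "promoters.fasta",
            "ground_truth": out / "ground_truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        anns = [self.annotations[g] for g in sorted(self.annotations)]
        write_annotations(anns, paths["annotations"], paths["tf_list"])
        write_transfac(self.pwms, paths["pwms"])
        write_library_tsv(self.library, paths["library"])
        self.expression.to_tsv(paths["expression"])
        lines = ["pwm_id\tgene_id"]
        for pwm_id in sorted(self.tf_mapping):
            for gene in self.tf_mapping[pwm_id]:
                lines.append(f"{pwm_id}\t{gene}")
        paths["tf_mapping"].write_text("\n".join(lines) + "\n")
        write_fasta(
            {g: self.promoters[g] for g in sorted(self.promoters)}, paths["promoters"]
        )
        self.ground_truth.to_json(paths["ground_truth"])
        return paths


# ---------------------------------------------------------------------------
# PWM generation
# ---------------------------------------------------------------------------


def _per_position_ic(p: float) -> float:
    """IC (bits, uniform background) of a position with dominant prob p."""
    rest = (1.0 - p) / 3.0
    ic = 0.0
    if p > 0:
        ic += p * np.log2(4.0 * p)
    if rest > 0:
        ic += (1.0 - p) * np.log2(4.0 * rest)
    return ic


def _solve_dominant_prob(target_bits: float) -> float:
    """Dominant-letter probability whose position IC equals target_bits."""
    if target_bits >= 2.0 - 1e-9:
        return 1.0
    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _per_position_ic(mid) < target_bits:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _kmers(word: str, k: int) -> set[str]:
    return {word[i : i + k] for i in range(len(word) - k + 1)}


def make_pwms(
    n: int,
    length_range: tuple[int, int] = (10, 12),
    ic_range: tuple[float, float] = (12.0, 16.0),
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    ids: Sequence[str] | None = None,
    distinct_kmer: int | None = None,
) -> list[PWM]:
    """Generate PWMs whose information content lands in the target range.

    Each matrix position gets one dominant letter with probability solved so
    the per-position IC sums to the sampled target; the realized IC (computed
    with the package's own IC at pseudocount 0) is verified to lie within
    +/- 0.5 bits of that target.

    With ``distinct_kmer=k`` the consensi are kept mutually dissimilar: no
    consensus shares a k-mer with any other consensus or its reverse
    complement (curated motif libraries keep their matrices distinguishable;
    without this, coincidental shared words let one motif's planted sites
    cross-match another matrix).

    Raises
    ------
    ValueError
        if the IC target exceeds the 2 bits/position ceiling.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if ids is not None and len(ids) != n:
        raise ValueError("ids must match n")
    lo_len, hi_len = length_range
    if ic_range[0] > 2.0 * hi_len:
        raise ValueError("IC target infeasible: exceeds 2 bits per position")
    pwms: list[PWM] = []
    used_kmers: set[str] = set()
    for i in range(n):
        length = int(rng.integers(lo_len, hi_len + 1))
        target = float(rng.uniform(*ic_range))
        if target > 2.0 * length + 1e-9:
            raise ValueError(
                f"IC target {target:.2f} infeasible for length {length}"
            )
        p = _solve_dominant_prob(target / length)
        rest = (1.0 - p) / 3.0
        for _attempt in range(200):
            counts = np.full((length, 4), rest * 1000.0)
            dominant = rng.integers(0, 4, size=length)
            counts[np.arange(length), dominant] = p * 1000.0
            counts = np.rint(counts)
            pwm = PWM(
                id=ids[i] if ids is not None else f"SYN{i + 1:03d}",
                counts=counts,
                pseudocount=0.0,
            )
            if distinct_kmer is None:
                break
            consensus = pwm.consensus()
            if not (_kmers(consensus, distinct_kmer) & used_kmers):
                used_kmers |= _kmers(consensus, distinct_kmer)
                used_kmers |= _kmers(reverse_complement(consensus), distinct_kmer)
                break
        else:
            raise RuntimeError(
                f"could not draw a motif distinct at k={distinct_kmer} "
                f"after 200 attempts"
            )
        if abs(pwm.information_content() - target) > 0.5:
            raise RuntimeError(
                f"{pwm.id}: realized IC {pwm.information_content():.2f} missed "
                f"target {target:.2f}"
            )
        pwms.append(pwm)
    return pwms


def sample_planted_site(
    pwm: PWM,
    rng: np.random.Generator,
    floor: float = 0.97,
    max_tries: int = 60,
) -> str:
    """A word drawn from the PWM distribution with a floor on realized score.

    Falls back to the consensus if the floor is not reached in ``max_tries``
    draws, so planted sites are always detectable at library thresholds.
    """
    probs = pwm.probabilities()
    for _ in range(max_tries):
        word = "".join(
            ALPHABET[rng.choice(4, p=row / row.sum())] for row in probs
        )
        if score_site(pwm, word, 0, "+") >= floor:
            return word
    return pwm.consensus()


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    return bytearray(_LETTERS[codes].tobytes())


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------


def _partner_patterns(
    k: int, hub_index: int, n_hubs: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Stage-presence patterns for one hub's partners.

    Partner 0 is present at all stages (keeps the hub alive throughout and
    supplies an all-stages pair), partner 1 is interrupted, partner 2 is
    either stage-specific or — for the last hub — the early/late antagonistic
    demo pattern; further partners get random non-empty patterns.
    """
    patterns = [np.ones(5, dtype=bool)]
    if k > 1:
        patterns.append(np.array([True, True, False, True, True]))
    if k > 2:
        if hub_index == n_hubs - 1:
            patterns.append(np.array([True, False, False, False, True]))
        else:
            vec = np.zeros(5, dtype=bool)
            vec[hub_index % 5] = True
            patterns.append(vec)
    while len(patterns) < k:
        vec = rng.random(5) < 0.6
        if vec.any():
            patterns.append(vec)
    return patterns


def _tf_gene_name(pwm_id: str) -> str:
    return "TF_" + pwm_id.replace("V$", "").replace("_01", "")


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Build the complete synthetic fixture for one seed.

    Raises
    ------
    OverconstrainedPlantingError
        if a stage's planted pair demand exceeds its promoters' site capacity.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    stages = DEFAULT_STAGES
    days = list(spec.timepoints)
    n_stages = len(stages)
    if len(days) != n_stages + 1:
        raise ValueError("timepoints must bound the five stages")

    # --- hubs, partners, PWMs -------------------------------------------------
    hub_ids = [f"V$HUB{i + 1}_01" for i in range(spec.n_hubs)]
    k_lo, k_hi = spec.partners_per_hub
    k_list = [int(rng.integers(k_lo, k_hi + 1)) for _ in range(spec.n_hubs)]
    partner_ids = [
        [f"V$H{i + 1}P{j + 1}_01" for j in range(k)] for i, k in enumerate(k_list)
    ]
    all_ids = hub_ids + [p for ps in partner_ids for p in ps]
    pwms = make_pwms(
        len(all_ids),
        length_range=spec.pwm_length,
        ic_range=spec.pwm_ic,
        rng=rng,
        ids=all_ids,
        distinct_kmer=6,
    )
    pwm_by_id = {p.id: p for p in pwms}

    # --- composite library and stage patterns ---------------------------------
    library: list[CompositeModel] = []
    patterns: dict[str, np.ndarray] = {}

    def add_model(pair_id: str, a: str, b: str) -> None:
        library.append(
            CompositeModel(
                pair_id=pair_id,
                pwm_a=a,
                pwm_b=b,
                threshold_a=spec.model_threshold,
                threshold_b=spec.model_threshold,
                min_gap=spec.min_gap,
                max_gap=spec.max_gap,
                orientation="any",
            )
        )

    synergistic_pair = ""
    antagonistic_pair = ""
    for i, hub in enumerate(hub_ids):
        hub_patterns = _partner_patterns(k_list[i], i, spec.n_hubs, rng)
        for j, partner in enumerate(partner_ids[i]):
            pair_id = f"{hub}~{partner}"
            add_model(pair_id, hub, partner)
            patterns[pair_id] = hub_patterns[j]
            if i == 0 and j == 0:
                synergistic_pair = pair_id
            if i == spec.n_hubs - 1 and j == 2:
                antagonistic_pair = pair_id

    bridge_pairs: list[str] = []
    if spec.n_hubs >= 2:
        seen_bridges: set[tuple[str, str]] = set()
        for i in range(spec.n_hubs):
            a, b = hub_ids[i], hub_ids[(i + 1) % spec.n_hubs]
            key = tuple(sorted((a, b)))
            if key in seen_bridges:
                continue
            seen_bridges.add(key)
            pair_id = f"{a}~{b}"
            add_model(pair_id, a, b)
            patterns[pair_id] = np.ones(5, dtype=bool)
            bridge_pairs.append(pair_id)

    # per-stage planted frequencies (bridges stay at weight 1)
    f_lo, f_hi = spec.pair_frequency
    frequencies: dict[str, list[int]] = {}
    for model in library:
        pid = model.pair_id
        if pid in bridge_pairs:
            frequencies[pid] = [1 if p else 0 for p in patterns[pid]]
        else:
            frequencies[pid] = [
                int(rng.integers(f_lo, f_hi + 1)) if p else 0 for p in patterns[pid]
            ]

    # --- gene roster ----------------------------------------------------------
    n_de = spec.de_genes_per_stage
    gene_names = [f"G{i:04d}" for i in range(spec.n_genes)]
    unique_de = {
        stages[s].name: gene_names[s * n_de : (s + 1) * n_de] for s in range(n_stages)
    }
    cursor = n_stages * n_de
    two_stage_pairs = [(0, 2), (1, 3), (2, 4)]
    two_stage_genes: list[tuple[str, int, int]] = []
    for t in range(spec.n_two_stage_de):
        s1, s2 = two_stage_pairs[t % len(two_stage_pairs)]
        two_stage_genes.append((gene_names[cursor], s1, s2))
        cursor += 1
    nc_de_gene = gene_names[cursor]          # DE but non-coding: filtered out
    cursor += 1
    overlap_decoys = gene_names[cursor : cursor + 2]   # null, overlapping promoters
    cursor += 2
    null_genes = gene_names[cursor:]

    tf_mapping: dict[str, list[str]] = {
        pwm_id: [_tf_gene_name(pwm_id)] for pwm_id in all_ids
    }
    tf_mapping[hub_ids[0]].append(_tf_gene_name(hub_ids[0]) + "B")
    tf_genes = sorted({g for gs in tf_mapping.values() for g in gs})

    # --- promoter planting ----------------------------------------------------
    slot_pitch = 240
    first_offset = 10
    n_slots = max(0, (spec.promoter_length - first_offset) // slot_pitch)
    if n_slots < 1:
        raise OverconstrainedPlantingError("promoter too short for one planted pair")

    plants: dict[str, list[tuple[int, str, str]]] = {g: [] for g in gene_names}
    for s in range(n_stages):
        stage_genes = unique_de[stages[s].name]
        demand = sum(frequencies[pid][s] for pid in frequencies)
        if demand > len(stage_genes) * n_slots:
            raise OverconstrainedPlantingError(
                f"stage {stages[s].name}: {demand} planted pairs exceed capacity "
                f"{len(stage_genes) * n_slots}"
            )
        usage = {g: 0 for g in stage_genes}
        for pid in sorted(frequencies):
            f = frequencies[pid][s]
            if f == 0:
                continue
            candidates = [g for g in stage_genes if usage[g] < n_slots]
            order = list(rng.permutation(candidates))
            order.sort(key=lambda g: usage[g])
            for g in order[:f]:
                plants[g].append((usage[g], pid, stages[s].name))
                usage[g] += 1

    model_by_pair = {m.pair_id: m for m in library}
    promoter_seqs: dict[str, str] = {}
    planted_occurrences: list[dict] = []
    for gene in gene_names:
        # fix the planted layout first (sites, strands, gaps) ...
        layouts: list[dict] = []
        for slot, pid, stage_name in plants[gene]:
            model = model_by_pair[pid]
            word_a = sample_planted_site(
                pwm_by_id[model.pwm_a], rng, spec.site_score_floor
            )
            word_b = sample_planted_site(
                pwm_by_id[model.pwm_b], rng, spec.site_score_floor
            )
            strand_a = "+" if rng.random() < 0.5 else "-"
            strand_b = "+" if rng.random() < 0.5 else "-"
            gap = int(rng.integers(spec.min_gap, spec.max_gap + 1))
            a_first = rng.random() < 0.5
            off = first_offset + slot * slot_pitch
            if a_first:
                a_start = off
                b_start = off + len(word_a) + gap
            else:
                b_start = off
                a_start = off + len(word_b) + gap
            layouts.append(
                {
                    "stage": stage_name,
                    "pair_id": pid,
                    "gene": gene,
                    "word_a": word_a,
                    "word_b": word_b,
                    "a_start": a_start,
                    "a_end": a_start + len(word_a),
                    "a_strand": strand_a,
                    "b_start": b_start,
                    "b_end": b_start + len(word_b),
                    "b_strand": strand_b,
                    "gap": gap,
                }
            )
        expected = {
            (
                lay["pair_id"],
                frozenset(
                    {(lay["a_start"], lay["a_end"]), (lay["b_start"], lay["b_end"])}
                ),
            )
            for lay in layouts
        }
        # ... then rejection-sample the background until the promoter contains
        # exactly the recorded occurrences: background letters adjacent to a
        # planted site can otherwise complete another motif's consensus and
        # fabricate a co-located pair the bookkeeping does not know about
        for _attempt in range(30):
            prom = _random_nt(rng, spec.promoter_length, spec.gc)
            for lay in layouts:
                for word, strand, start in (
                    (lay["word_a"], lay["a_strand"], lay["a_start"]),
                    (lay["word_b"], lay["b_strand"], lay["b_start"]),
                ):
                    placed = word if strand == "+" else reverse_complement(word)
                    prom[start : start + len(word)] = placed.encode("ascii")
            if not layouts:
                break
            occs = find_all_occurrences(
                library, {gene: prom.decode("ascii")}, pwm_by_id
            )
            got = {
                (
                    o.pair_id,
                    frozenset(
                        {
                            (o.site_a.start, o.site_a.end),
                            (o.site_b.start, o.site_b.end),
                        }
                    ),
                )
                for o in occs
            }
            if got == expected:
                break
        else:
            raise RuntimeError(
                f"could not draw a background consistent with the planted "
                f"occurrences for {gene}"
            )
        promoter_seqs[gene] = prom.decode("ascii")
        for lay in layouts:
            planted_occurrences.append(
                {k: v for k, v in lay.items() if not k.startswith("word_")}
            )

    # --- genome assembly ------------------------------------------------------
    all_gene_order = gene_names + tf_genes
    slot_len = spec.promoter_length + 100
    margin = 1000
    chrom_len = margin + len(all_gene_order) * slot_len + margin
    genome_arr = _random_nt(rng, chrom_len, spec.gc)
    annotations: dict[str, GeneAnnotation] = {}
    tss_by_gene: dict[str, int] = {}
    for idx, gene in enumerate(all_gene_order):
        base = margin + idx * slot_len
        strand = "+" if rng.random() < 0.5 else "-"
        tss = base + spec.promoter_length if strand == "+" else base
        if gene in promoter_seqs:
            prom = promoter_seqs[gene]
            placed = prom if strand == "+" else reverse_complement(prom)
            genome_arr[base : base + spec.promoter_length] = placed.encode("ascii")
        annotations[gene] = GeneAnnotation(
            gene=gene,
            chrom="chr1",
            tss=tss,
            strand=strand,
            protein_coding=(gene != nc_de_gene),
            is_tf=gene in tf_genes,
        )
        tss_by_gene[gene] = tss
    # second overlap decoy: shift its TSS to overlap the first decoy's promoter
    d1, d2 = overlap_decoys
    ann1 = annotations[d1]
    annotations[d1] = dataclasses.replace(ann1, strand="+",
                                          tss=tss_by_gene[d1] if ann1.strand == "+"
                                          else tss_by_gene[d1] + spec.promoter_length)
    annotations[d2] = dataclasses.replace(
        annotations[d2], strand="+", tss=annotations[d1].tss - spec.promoter_length // 2
    )
    genome = {"chr1": genome_arr.decode("ascii")}

    # --- expression design ----------------------------------------------------
    n_all = len(all_gene_order)
    means = np.zeros((n_all, len(days)))
    gene_index = {g: i for i, g in enumerate(all_gene_order)}

    for gene in null_genes + list(overlap_decoys):
        means[gene_index[gene], :] = 2.0 ** rng.uniform(1.0, 5.6)

    def step_profile(stage_idx: int) -> np.ndarray:
        low = 2.0 ** rng.uniform(0.5, 2.0)
        high = low * 2.0 ** spec.effect_log2
        up = rng.random() < 0.5
        profile = np.full(len(days), low if up else high)
        profile[stage_idx + 1 :] = high if up else low
        return profile

    for s in range(n_stages):
        for gene in unique_de[stages[s].name]:
            means[gene_index[gene], :] = step_profile(s)
    for gene, s1, s2 in two_stage_genes:
        low = 2.0 ** rng.uniform(0.5, 2.0)
        high = low * 2.0 ** spec.effect_log2
        profile = np.full(len(days), low)
        profile[s1 + 1 : s2 + 1] = high
        means[gene_index[gene], :] = profile
    means[gene_index[nc_de_gene], :] = step_profile(0)

    # TF genes: expressed at all timepoints unless given a designed pattern
    expressed_truth: dict[str, list[int]] = {}
    for gene in tf_genes:
        means[gene_index[gene], :] = 30.0
    means[gene_index[_tf_gene_name(hub_ids[0]) + "B"], :] = 1.0
    if spec.n_hubs >= 2 and antagonistic_pair:
        hub_last = hub_ids[-1]
        partner = antagonistic_pair.split("~")[1]
        early = np.array([30.0, 30.0, 1.0, 1.0, 1.0, 1.0])
        late = np.array([1.0, 1.0, 1.0, 1.0, 30.0, 30.0])
        means[gene_index[_tf_gene_name(hub_last)], :] = early
        means[gene_index[_tf_gene_name(partner)], :] = late
    if spec.n_hubs >= 3:
        # a TF gene with a genuine expression step: must still be excluded
        # from unique DEG sets by the is_tf flag
        ramp = np.array([2.0, 2.0, 32.0, 32.0, 32.0, 32.0])
        means[gene_index[_tf_gene_name(hub_ids[1])], :] = ramp
    for gene in tf_genes:
        expressed_truth[gene] = [
            int(d) for d, v in zip(days, means[gene_index[gene]]) if v >= 10.0
        ]

    noise = 2.0 ** rng.normal(
        0.0, spec.noise_sd_log2, size=(n_all, len(days), spec.replicates)
    )
    values = means[:, :, None] * noise
    expression = ExpressionMatrix.from_arrays(all_gene_order, days, values)

    # --- ground truth ---------------------------------------------------------
    pair_freq_truth = {
        stages[s].name: {
            pid: frequencies[pid][s] for pid in sorted(frequencies)
            if frequencies[pid][s] > 0
        }
        for s in range(n_stages)
    }
    hub_members = {
        stages[s].name: {
            hub_ids[i]: sorted(
                partner_ids[i][j]
                for j in range(k_list[i])
                if patterns[f"{hub_ids[i]}~{partner_ids[i][j]}"][s]
            )
            for i in range(spec.n_hubs)
        }
        for s in range(n_stages)
    }
    ground_truth = GroundTruth(
        unique_degs={name: sorted(genes) for name, genes in unique_de.items()},
        pair_frequencies=pair_freq_truth,
        pair_patterns={pid: [bool(v) for v in patterns[pid]] for pid in sorted(patterns)},
        hub_members=hub_members,
        hub_partner_union={
            hub_ids[i]: sorted(partner_ids[i]) for i in range(spec.n_hubs)
        },
        planted_occurrences=planted_occurrences,
        two_stage_degs=sorted(g for g, _s1, _s2 in two_stage_genes),
        expressed_timepoints=expressed_truth,
        synergistic_pair=synergistic_pair,
        antagonistic_pair=antagonistic_pair,
    )

    promoters_extracted, _ = extract_promoters(
        [annotations[g] for g in all_gene_order], genome,
        window=(-spec.promoter_length, 0),
    )
    return Fixture(
        spec=spec,
        genome=genome,
        annotations=annotations,
        pwms=pwms,
        library=library,
        expression=expression,
        tf_mapping=tf_mapping,
        promoters=promoters_extracted,
        ground_truth=ground_truth,
    )
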