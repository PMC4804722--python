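"""Composite-module detection: co-localized TFBS pairs in single promoters.

A composite model pairs two PWMs with per-side score thresholds, an
edge-to-edge gap window in nucleotides, and an orientation constraint.
Detected pair occurrences are aggregated into per-stage frequency tables that
become the edge weights of the TFBS co-occurrence network.
"""
from __future__ import annotations

import csv
import dataclasses
import itertools
from pathlib import Path
from typing import Iterable, Mapping

from .pwm import PWM, ScoredSite, scan

ORIENTATIONS = ("same", "opposite", "any")


@dataclasses.dataclass(frozen=True)
class CompositeModel:
    """Library entry describing a known-to-interact TFBS pair.

    ``min_gap``/``max_gap`` bound the number of nucleotides strictly between
    the two (non-overlapping) site spans.  ``orientation`` constrains the
    strands: ``same`` requires equal strands, ``opposite`` unequal, ``any``
    none.  ``ordered`` requires the pwm_a site upstream of the pwm_b site;
    by default the two orders are equivalent (pairs are unordered).
    """

    pair_id: str
    pwm_a: str
    pwm_b: str
    threshold_a: float
    threshold_b: float
    min_gap: int
    max_gap: int
    orientation: str = "any"
    ordered: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_gap <= self.max_gap):
            raise ValueError(f"{self.pair_id}: require 0 <= min_gap <= max_gap")
        for t in (self.threshold_a, self.threshold_b):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"{self.pair_id}: thresholds must lie in [0, 1]")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"{self.pair_id}: orientation must be one of {ORIENTATIONS}"
            )

    @property
    def homotypic(self) -> bool:
        return self.pwm_a == self.pwm_b


@dataclasses.dataclass(frozen=True)
class PairOccurrence:
    """One detected composite instance: two sites and the gap between them."""

    pair_id: str
    seq_id: str
    site_a: ScoredSite
    site_b: ScoredSite
    gap: int


@dataclasses.dataclass
class PairFrequencyTable:
    """Per-stage pair weights w(v_i, v_j); zero-frequency pairs are absent."""

    stage: str
    weights: dict[str, int]

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.weights.values()):
            raise ValueError("all weights must be >= 1")


def _orientation_ok(model: CompositeModel, sa: ScoredSite, sb: ScoredSite) -> bool:
    if model.orientation == "same":
        return sa.strand == sb.strand
    if model.orientation == "opposite":
        return sa.strand != sb.strand
    return True


def _match_hits(
    model: CompositeModel,
    seq_id: str,
    hits_a: list[ScoredSite],
    hits_b: list[ScoredSite],
) -> list[PairOccurrence]:
    """Pair up pre-computed hits of the two PWMs under the model constraints."""
    if model.homotypic:
        combos: Iterable[tuple[ScoredSite, ScoredSite]] = itertools.combinations(
            hits_a, 2
        )
    else:
        combos = itertools.product(hits_a, hits_b)

    occs: list[PairOccurrence] = []
    for sa, sb in combos:
        if sa.overlaps(sb):
            continue
        if sa.end <= sb.start:
            gap = sb.start - sa.end
            a_first = True
        else:
            gap = sa.start - sb.end
            a_first = False
        if model.ordered and not a_first:
            continue
        if not (model.min_gap <= gap <= model.max_gap):
            continue
        if not _orientation_ok(model, sa, sb):
            continue
        occs.append(
            PairOccurrence(
                pair_id=model.pair_id, seq_id=seq_id, site_a=sa, site_b=sb, gap=gap
            )
        )
    occs.sort(key=lambda o: (min(o.site_a.start, o.site_b.start), o.site_a.start))
    return occs


def detect_pairs(
    model: CompositeModel,
    seq_id: str,
    sequence: str,
    pwms: Mapping[str, PWM],
) -> list[PairOccurrence]:
    """All occurrences of a composite model in one promoter sequence.

    Every combination of one pwm_a hit and one pwm_b hit with non-overlapping
    spans, an in-window edge-to-edge gap, and a satisfied orientation rule is
    reported.

    Raises
    ------
    KeyError
        if the model references a PWM id absent from ``pwms``.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pid in (model.pwm_a, model.pwm_b):
        if pid not in pwms:
            raise KeyError(f"unknown PWM id in composite model: {pid}")
    hits_a = scan(pwms[model.pwm_a], seq_id, sequence, model.threshold_a)
    if model.homotypic:
        hits_b = hits_a
    else:
        hits_b = scan(pwms[model.pwm_b], seq_id, sequence, model.threshold_b)
    return _match_hits(model, seq_id, hits_a, hits_b)


def find_all_occurrences(
    library: Iterable[CompositeModel],
    promoters: Mapping[str, str],
    pwms: Mapping[str, PWM],
) -> list[PairOccurrence]:
    """Detect every library model in every promoter.

    Scan results are cached per (PWM, threshold, promoter) so each matrix
    passes over each sequence once.
    """
    cache: dict[tuple[str, float, str], list[ScoredSite]] = {}

    def hits(pwm_id: str, threshold: float, seq_id: str, seq: str) -> list[ScoredSite]:
        key = (pwm_id, threshold, seq_id)
        if key not in cache:
            cache[key] = scan(pwms[pwm_id], seq_id, seq, threshold)
        return cache[key]

    occs: list[PairOccurrence] = []
    for model in library:
        for pid in (model.pwm_a, model.pwm_b):
            if pid not in pwms:
                raise KeyError(f"unknown PWM id in composite model: {pid}")
        for seq_id in sorted(promoters):
            seq = promoters[seq_id]
            if not seq:
                continue
            ha = hits(model.pwm_a, model.threshold_a, seq_id, seq)
            hb = ha if model.homotypic else hits(
                model.pwm_b, model.threshold_b, seq_id, seq
            )
            occs.extend(_match_hits(model, seq_id, ha, hb))
    return occs


def aggregate_frequencies(
    library: Iterable[CompositeModel],
    promoters: Mapping[str, str],
    pwms: Mapping[str, PWM],
    mode: str = "promoters",
    stage: str = "",
) -> PairFrequencyTable:
    """Pair frequencies over a promoter set.

    ``mode="promoters"`` (default) counts distinct promoters containing at
    least one occurrence of the pair; ``mode="occurrences"`` counts every
    occurrence.  Pairs with zero count are omitted.
    """
    if not promoters:
        raise ValueError("promoter set must be non-empty")
    if mode not in ("promoters", "occurrences"):
        raise ValueError(f"unknown counting mode: {mode}")
    occs = find_all_occurrences(library, promoters, pwms)
    weights: dict[str, int] = {}
    if mode == "occurrences":
        for occ in occs:
            weights[occ.pair_id] = weights.get(occ.pair_id, 0) + 1
    else:
        seen: dict[str, set[str]] = {}
        for occ in occs:
            seen.setdefault(occ.pair_id, set()).add(occ.seq_id)
        weights = {pid: len(s) for pid, s in seen.items()}
    return PairFrequencyTable(stage=stage, weights=dict(sorted(weights.items())))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

LIBRARY_COLUMNS = (
    "pair_id",
    "pwm_a",
    "pwm_b",
    "threshold_a",
    "threshold_b",
    "min_gap",
    "max_gap",
    "orientation",
    "ordered",
)


def read_library_tsv(path: str | Path) -> list[CompositeModel]:
    models: list[CompositeModel] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            models.append(
                CompositeModel(
                    pair_id=row["pair_id"],
                    pwm_a=row["pwm_a"],
                    pwm_b=row["pwm_b"],
                    threshold_a=float(row["threshold_a"]),
                    threshold_b=float(row["threshold_b"]),
                    min_gap=int(row["min_gap"]),
                    max_gap=int(row["max_gap"]),
                    orientation=row.get("orientation", "any"),
                    ordered=row.get("ordered", "false").lower()
                    in ("1", "true", "yes"),
                )
            )
    return models


def write_library_tsv(models: Iterable[CompositeModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LIBRARY_COLUMNS)
        for m in models:
            w.writerow(
                [
                    m.pair_id,
                    m.pwm_a,
                    m.pwm_b,
                    f"{m.threshold_a:g}",
                    f"{m.threshold_b:g}",
                    m.min_gap,
                    m.max_gap,
                    m.orientation,
                    str(m.ordered).lower(),
                ]
            )


def write_occurrences_tsv(occs: Iterable[PairOccurrence], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "pair_id",
                "seq_id",
                "start_a",
                "end_a",
                "strand_a",
                "score_a",
                "start_b",
                "end_b",
                "strand_b",
                "score_b",
                "gap",
            ]
        )
        for o in occs:
            w.writerow(
                [
                    o.pair_id,
                    o.seq_id,
                    o.site_a.start,
                    o.site_a.end,
                    o.site_a.strand,
                    f"{o.site_a.score:.6f}",
                    o.site_b.start,
                    o.site_b.end,
                    o.site_b.strand,
                    f"{o.site_b.score:.6f}",
                    o.gap,
                ]
            )
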