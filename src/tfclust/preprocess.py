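"""Stage-specific unique DEG selection and promoter extraction.

The time course has six timepoints (days 0, 3, 8, 13, 29, 60 by default)
whose consecutive pairs bound five developmental stages.  A gene is a unique
DEG of a stage when it passes the differential-expression thresholds in that
stage and in no other, is protein-coding, and is not itself a transcription
factor.  Promoters are upstream windows relative to the annotated TSS
(default 1 kb), in 0-based half-open BED coordinates; promoters that overlap
any other promoter are discarded entirely (both members of a pair).

The heavyweight moderated linear-model fit used on real data is out of scope;
the pluggable stand-in is a per-gene pooled-variance t-test between the
stage's two bounding timepoints on log2(FPKM + 1), with Benjamini-Hochberg
FDR within the stage.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pwm import reverse_complement

DEFAULT_TIMEPOINTS = (0, 3, 8, 13, 29, 60)


@dataclasses.dataclass(frozen=True)
class StageDefinition:
    """A developmental stage bounded by two timepoints (days)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must precede end")

    @property
    def timepoints(self) -> tuple[int, int]:
        return (self.start, self.end)


DEFAULT_STAGES = (
    StageDefinition("mesoderm_induction", 0, 3),
    StageDefinition("early_specification", 3, 8),
    StageDefinition("late_specification", 8, 13),
    StageDefinition("early_maturation", 13, 29),
    StageDefinition("late_maturation", 29, 60),
)


@dataclasses.dataclass(frozen=True)
class DEGCall:
    gene: str
    stage: str
    p_value: float
    fdr: float
    direction: str | None  # "up", "down", or None when there is no signal


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    chrom: str
    tss: int
    strand: str
    protein_coding: bool = True
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene}: tss must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")


@dataclasses.dataclass(frozen=True)
class Region:
    """Half-open genomic interval attached to a gene."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


class ExpressionMatrix:
    """FPKM values per gene x timepoint x replicate.

    Backed by a DataFrame with a (day, replicate) column MultiIndex.  The TSV
    representation uses columns named ``d<day>_r<rep>`` (or plain ``d<day>``
    for a single replicate) with genes as the first column.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValueError("expected a (day, replicate) column MultiIndex")
        if (data.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        days = [int(d) for d in data.columns.get_level_values(0)]
        uniq = sorted(set(days))
        if uniq != sorted(uniq):
            raise ValueError("timepoints must be strictly increasing")
        self.data = data.sort_index(axis=1)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> list[int]:
        return sorted({int(d) for d in self.data.columns.get_level_values(0)})

    @classmethod
    def from_arrays(
        cls,
        genes: Sequence[str],
        days: Sequence[int],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        """Build from a (gene, day, replicate) array."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[:, :, None]
        n_genes, n_days, n_reps = values.shape
        cols = pd.MultiIndex.from_tuples(
            [(int(d), r + 1) for d in days for r in range(n_reps)],
            names=["day", "rep"],
        )
        frame = pd.DataFrame(
            values.reshape(n_genes, n_days * n_reps), index=list(genes), columns=cols
        )
        return cls(frame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        tuples = []
        for col in raw.columns:
            name = str(col)
            if not name.startswith("d"):
                raise ValueError(f"unrecognized expression column: {name}")
            body = name[1:]
            if "_r" in body:
                day, rep = body.split("_r", 1)
            else:
                day, rep = body, "1"
            tuples.append((int(day), int(rep)))
        raw.columns = pd.MultiIndex.from_tuples(tuples, names=["day", "rep"])
        return cls(raw)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = [f"d{d}_r{r}" for d, r in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.4f")

    def values_at(self, day: int) -> pd.DataFrame:
        """Genes x replicates at one timepoint."""
        if day not in self.timepoints:
            raise KeyError(f"timepoint day {day} absent from expression matrix")
        return self.data.xs(day, axis=1, level="day")

    def mean_by_timepoint(self) -> pd.DataFrame:
        """Genes x days, replicate-averaged FPKM."""
        return self.data.T.groupby(level="day").mean().T


def _pooled_t_p_values(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance t-test p-values per row.

    The pooled (equal-variance) form mirrors the common-variance assumption
    of moderated linear-model fits and keeps the full n1+n2-2 degrees of
    freedom at small replicate counts.  Rows with zero variance in both
    groups get p = 1 when the means agree and p = 0 when they differ (the
    limiting case of the test).
    """
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(x.mean(axis=1), y.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (FDR)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def call_stage_degs(
    matrix: ExpressionMatrix,
    stage: StageDefinition,
    test: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> list[DEGCall]:
    """Differential-expression calls between the stage's bounding timepoints.

    One call per gene; p-values come from the pluggable two-group ``test``
    (default: pooled-variance t-test on log2(FPKM+1) across replicates), FDR
    values are BH-adjusted within the stage.
    """
    for day in stage.timepoints:
        if day not in matrix.timepoints:
            raise ValueError(
                f"stage {stage.name}: timepoint day {day} missing from matrix"
            )
    x = np.log2(matrix.values_at(stage.start).to_numpy() + 1.0)
    y = np.log2(matrix.values_at(stage.end).to_numpy() + 1.0)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError(
            f"stage {stage.name}: the per-gene two-sample test requires >= 2 "
            "replicates per timepoint"
        )
    if test is None:
        p = _pooled_t_p_values(x, y)
    else:
        p = np.array([float(test(xi, yi)) for xi, yi in zip(x, y)])
    p = np.clip(p, 0.0, 1.0)
    fdr = benjamini_hochberg(p)
    mean_diff = y.mean(axis=1) - x.mean(axis=1)
    calls = []
    for gene, pv, fv, d in zip(matrix.genes, p, fdr, mean_diff):
        direction = None if np.isclose(d, 0.0) else ("up" if d > 0 else "down")
        calls.append(
            DEGCall(gene=gene, stage=stage.name, p_value=float(pv), fdr=float(fv),
                    direction=direction)
        )
    return calls


def filter_unique_degs(
    calls_by_stage: Mapping[str, Sequence[DEGCall]],
    annotations: Mapping[str, GeneAnnotation],
    p_max: float = 0.05,
    fdr_max: float = 0.01,
) -> dict[str, set[str]]:
    """Per-stage unique DEG sets.

    A gene is retained for stage s iff it passes p <= p_max and fdr <= fdr_max
    in s and in no other stage, is protein-coding, and is not flagged as a TF.
    The resulting sets are disjoint by construction.
    """
    passing: dict[str, set[str]] = {}
    for stage, calls in calls_by_stage.items():
        passing[stage] = {
            c.gene for c in calls if c.p_value <= p_max and c.fdr <= fdr_max
        }
    unique: dict[str, set[str]] = {}
    for stage, genes in passing.items():
        others: set[str] = set()
        for other, g in passing.items():
            if other != stage:
                others |= g
        kept = set()
        for gene in genes - others:
            ann = annotations.get(gene)
            if ann is None or not ann.protein_coding or ann.is_tf:
                continue
            kept.add(gene)
        unique[stage] = kept
    return unique


def extract_promoters(
    annotations: Iterable[GeneAnnotation],
    genome: Mapping[str, str],
    window: tuple[int, int] = (-1000, 0),
) -> tuple[dict[str, str], dict[str, Region]]:
    """Upstream promoter sequences and regions relative to each TSS.

    For a window (a, b) relative to the TSS, a plus-strand gene yields the
    region [tss+a, tss+b) and a minus-strand gene the mirrored region
    [tss-b, tss-a), reverse-complemented.  Regions truncated at chromosome
    edges are returned at their achieved length; zero-length regions are
    dropped.  Standard window choices: (-1000, 0), (-500, 0), (-500, +100).
    """
    a, b = window
    if b - a <= 0:
        raise ValueError("window length must be > 0")
    sequences: dict[str, str] = {}
    regions: dict[str, Region] = {}
    for ann in annotations:
        if ann.chrom not in genome:
            raise KeyError(f"{ann.gene}: unknown chromosome {ann.chrom}")
        chrom_seq = genome[ann.chrom]
        if ann.strand == "+":
            start, end = ann.tss + a, ann.tss + b
        else:
            start, end = ann.tss - b, ann.tss - a
        start = max(0, start)
        end = min(len(chrom_seq), end)
        if end <= start:
            continue
        seq = chrom_seq[start:end].upper()
        if ann.strand == "-":
            seq = reverse_complement(seq)
        sequences[ann.gene] = seq
        regions[ann.gene] = Region(
            gene=ann.gene, chrom=ann.chrom, start=start, end=end, strand=ann.strand
        )
    return sequences, regions


def remove_overlapping_promoters(
    regions: Mapping[str, Region],
) -> dict[str, Region]:
    """Drop every region that shares >= 1 base with another (strand-agnostic).

    Both members of an overlapping pair are removed; the operation is
    idempotent.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions.values():
        by_chrom.setdefault(r.chrom, []).append(r)
    overlapping: set[str] = set()
    for chrom_regions in by_chrom.values():
        chrom_regions.sort(key=lambda r: (r.start, r.end))
        active: list[Region] = []
        for r in chrom_regions:
            active = [a for a in active if a.end > r.start]
            for a in active:
                overlapping.add(a.gene)
                overlapping.add(r.gene)
            active.append(r)
    return {g: r for g, r in regions.items() if g not in overlapping}


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_annotations(
    bed_path: str | Path, tf_list_path: str | Path | None = None
) -> dict[str, GeneAnnotation]:
    """BED6-like annotation table: chrom, tss, tss+1, gene, biotype, strand."""
    tf_genes: set[str] = set()
    if tf_list_path is not None:
        tf_genes = {
            line.strip()
            for line in Path(tf_list_path).read_text().splitlines()
            if line.strip()
        }
    annotations: dict[str, GeneAnnotation] = {}
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, tss, _tss1, gene, biotype, strand = line.split("\t")[:6]
        annotations[gene] = GeneAnnotation(
            gene=gene,
            chrom=chrom,
            tss=int(tss),
            strand=strand,
            protein_coding=(biotype == "protein_coding"),
            is_tf=gene in tf_genes,
        )
    return annotations


def write_annotations(
    annotations: Iterable[GeneAnnotation],
    bed_path: str | Path,
    tf_list_path: str | Path | None = None,
) -> None:
    lines = []
    tf_lines = []
    for ann in annotations:
        biotype = "protein_coding" if ann.protein_coding else "lincRNA"
        lines.append(
            f"{ann.chrom}\t{ann.tss}\t{ann.tss + 1}\t{ann.gene}\t{biotype}\t{ann.strand}"
        )
        if ann.is_tf:
            tf_lines.append(ann.gene)
    Path(bed_path).write_text("\n".join(lines) + "\n")
    if tf_list_path is not None:
        Path(tf_list_path).write_text("\n".join(tf_lines) + ("\n" if tf_lines else ""))


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
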