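"""Position weight matrices: representation, information content, dual-strand scanning.

A PWM models a transcription-factor binding motif as per-position nucleotide
counts over the alphabet ACGT.  Scoring follows the bounded min-max-normalized
log-probability scheme ("MATCH-style"): the summed per-position log2
probability of a window is rescaled so that the best achievable word scores
1.0 and the worst 0.0.  Scanning evaluates every window of a sequence on both
strands; minus-strand hits are reported in forward-strand, 0-based half-open
(BED-like) coordinates.
"""
from __future__ import annotations

import dataclasses
import io
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-value -> column index; 4 marks any non-ACGT symbol (N etc.)
_BYTE_CODE = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _BYTE_CODE[ord(_c)] = _i
    _BYTE_CODE[ord(_c.lower())] = _i

# floor applied to probabilities when taking logs for scoring, so that a
# zero-pseudocount matrix with structural zeros still yields finite scores
_LOG_FLOOR = 1e-12


class DegenerateMatrixError(ValueError):
    """A matrix position has no positive count even after pseudocounts."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def _uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


@dataclasses.dataclass
class PWM:
    """Positional nucleotide count model with background distribution.

    Parameters
    ----------
    id : str
        Matrix identifier, e.g. ``"V$AP1_01"``.
    counts : (L, 4) array_like
        Non-negative counts per position in A, C, G, T order.
    pseudocount : float or None
        Scalar added to every cell before normalization.  ``None`` (the
        default) uses 1% of each position's total count, which keeps
        probabilities strictly positive for any non-degenerate matrix.
    background : (4,) array_like
        Background nucleotide probabilities; must sum to 1.
    """

    id: str
    counts: np.ndarray
    pseudocount: float | None = None
    background: np.ndarray = dataclasses.field(default_factory=_uniform_background)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"{self.id}: counts must be an (L, 4) array")
        if self.counts.shape[0] < 1:
            raise ValueError(f"{self.id}: matrix length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.id}: counts must be non-negative")
        if self.pseudocount is not None and self.pseudocount < 0:
            raise ValueError(f"{self.id}: pseudocount must be non-negative")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,):
            raise ValueError(f"{self.id}: background must have length 4")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def _per_position_pseudocount(self) -> np.ndarray:
        if self.pseudocount is None:
            return 0.01 * self.counts.sum(axis=1)
        return np.full(self.length, float(self.pseudocount))

    def probabilities(self) -> np.ndarray:
        """Per-position probability matrix; rows sum to 1."""
        return normalize_pwm(self)

    def information_content(self) -> float:
        return information_content(self)

    def consensus(self) -> str:
        """Highest-probability letter at every position."""
        return "".join(ALPHABET[i] for i in np.argmax(self.probabilities(), axis=1))

    def log_probabilities(self) -> np.ndarray:
        """log2 probabilities used for scoring, floored to stay finite."""
        return np.log2(np.maximum(self.probabilities(), _LOG_FLOOR))

    def score_bounds(self) -> tuple[float, float]:
        """(S_min, S_max): worst and best achievable summed log2 probability."""
        logp = self.log_probabilities()
        return float(logp.min(axis=1).sum()), float(logp.max(axis=1).sum())


@dataclasses.dataclass(frozen=True)
class ScoredSite:
    """A motif match on one strand, in forward-strand half-open coordinates."""

    pwm_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("require 0 <= start < end")
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError("score must lie in [0, 1]")

    def overlaps(self, other: "ScoredSite") -> bool:
        return self.start < other.end and other.start < self.end


def normalize_pwm(pwm: PWM) -> np.ndarray:
    """Convert counts (+ pseudocount) into per-position probabilities.

    Raises
    ------
    DegenerateMatrixError
        if some position is all-zero and the pseudocount is zero.
    """
    pc = pwm._per_position_pseudocount()
    totals = pwm.counts.sum(axis=1) + 4.0 * pc
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise DegenerateMatrixError(
            f"{pwm.id}: position {bad} has zero total count and zero pseudocount"
        )
    return (pwm.counts + pc[:, None]) / totals[:, None]


def information_content(pwm: PWM) -> float:
    """Kullback-Leibler divergence from background, in bits, summed over positions.

    IC = sum_i sum_b p_ib * log2(p_ib / q_b).  Zero-probability cells
    contribute zero.  Invariant under permutation of positions.
    """
    if np.any(pwm.background <= 0):
        raise ValueError(f"{pwm.id}: background must be strictly positive")
    p = normalize_pwm(pwm)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / pwm.background[None, :]), 0.0)
    return float(terms.sum())


def score_site(pwm: PWM, sequence: str, pos: int, strand: str = "+") -> float:
    """Min-max-normalized match score of one window in [0, 1].

    The window is ``sequence[pos:pos+L]``; for the minus strand its reverse
    complement is scored against the matrix.  Any window containing a non-ACGT
    letter (N) scores 0.
    """
    L = pwm.length
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if pos < 0 or pos + L > len(sequence):
        raise ValueError(
            f"window [{pos}, {pos + L}) out of bounds for sequence of length {len(sequence)}"
        )
    window = sequence[pos : pos + L].upper()
    if strand == "-":
        window = reverse_complement(window)
    if any(c not in _CODE for c in window):
        if all(c in "ACGTN" for c in window):
            return 0.0
        raise ValueError(f"sequence contains non-nucleotide letters: {window!r}")
    logp = pwm.log_probabilities()
    s = sum(logp[i, _CODE[c]] for i, c in enumerate(window))
    s_min, s_max = pwm.score_bounds()
    if s_max - s_min <= 0:
        return 1.0  # fully uniform matrix: every word is optimal
    return float((s - s_min) / (s_max - s_min))


def _window_scores(logp: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed log-probabilities for all windows; second array flags N windows."""
    L = logp.shape[0]
    # pad a fifth column so code 4 (N) indexes harmlessly
    padded = np.hstack([logp, np.zeros((L, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = padded[np.arange(L), windows].sum(axis=1)
    has_n = (windows == 4).any(axis=1)
    return scores, has_n


def scan(pwm: PWM, seq_id: str, sequence: str, threshold: float) -> list[ScoredSite]:
    """All windows on either strand scoring >= threshold.

    Minus-strand hits are reported in forward-strand coordinates; output is
    sorted by (start, strand).  An empty or too-short sequence yields [].
    The threshold comparison carries a 1e-9 tolerance so the hit set is
    stable under floating-point summation order (strand symmetry).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    L = pwm.length
    n = len(sequence)
    if n < L:
        return []
    codes = _BYTE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    s_min, s_max = pwm.score_bounds()
    span = s_max - s_min
    logp = pwm.log_probabilities()

    hits: list[ScoredSite] = []
    for strand, mat in (("+", logp), ("-", logp[::-1, ::-1])):
        raw, has_n = _window_scores(mat, codes)
        if span > 0:
            norm = (raw - s_min) / span
        else:
            norm = np.ones_like(raw)
        norm = np.where(has_n, 0.0, norm)
        for pos in np.nonzero(norm >= threshold - 1e-9)[0]:
            hits.append(
                ScoredSite(
                    pwm_id=pwm.id,
                    seq_id=seq_id,
                    start=int(pos),
                    end=int(pos) + L,
                    strand=strand,
                    score=float(min(norm[pos], 1.0)),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# TRANSFAC-style flat-file I/O
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^(\d+)\s+(.*)$")


def read_transfac(source: str | Path | io.TextIOBase) -> list[PWM]:
    """Parse a TRANSFAC-style flat file into PWMs.

    Records are delimited by ``//``; the ``ID`` line carries the matrix
    identifier; numbered rows (``01`` .. ``NN``) carry four whitespace-
    separated counts in A C G T order (integer or real), optionally followed
    by a consensus letter which is ignored.  Other tags (P0, XX, BF, ...) are
    skipped.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()

    pwms: list[PWM] = []
    current_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal current_id, rows
        if current_id is not None and rows:
            pwms.append(PWM(id=current_id, counts=np.array(rows)))
        current_id, rows = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("//"):
            flush()
            continue
        if line.startswith("ID"):
            current_id = line[2:].strip()
            continue
        m = _ROW_RE.match(line)
        if m:
            fields = m.group(2).split()
            if len(fields) >= 4:
                try:
                    rows.append([float(x) for x in fields[:4]])
                except ValueError:
                    pass
    flush()
    return pwms


def write_transfac(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write PWMs in the TRANSFAC-style dialect accepted by read_transfac."""
    lines: list[str] = []
    for pwm in pwms:
        lines.append(f"ID {pwm.id}")
        lines.append("P0      A      C      G      T")
        for i, row in enumerate(pwm.counts, start=1):
            cells = "  ".join(f"{v:g}" for v in row)
            lines.append(f"{i:02d}  {cells}")
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")
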