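# Methods

## Model and procedure

The pipeline treats a developmental time course as five stages bounded by
six timepoints (days 0, 3, 8, 13, 29, 60 by default). Per stage it asks
which TFBS pairs co-occur in the promoters of that stage's unique
differentially expressed genes, and which of those pairs survive network
clustering as members of a hub-centered cluster.

**Differential expression (stand-in).** The reference analysis this package
emulates fits a moderated linear model per gene; that fit is deliberately
out of scope. The pluggable stand-in is a per-gene two-sample pooled-variance
t-test between a stage's two bounding timepoints on log2(FPKM + 1) across
replicates, with Benjamini–Hochberg FDR within the stage. The pooled
(equal-variance) form was chosen over Welch because it mirrors the
common-variance assumption of the moderated fit it replaces and keeps the
full n₁+n₂−2 degrees of freedom, which matters at 3 replicates. Rows with
zero variance in both groups take the limiting p-value (1 when the means
agree, 0 otherwise). A gene is a *unique* DEG of stage s when it passes
p ≤ 0.05 and FDR ≤ 0.01 in s and in no other stage (same thresholds on both
sides of the comparison — the simplest symmetric reading), is
protein-coding, and is not itself a TF gene.

**Promoters.** For a window (a, b) relative to the TSS — default (−1000, 0);
(−500, 0) and (−500, +100) are supported configuration values — a
plus-strand gene yields [tss+a, tss+b) and a minus-strand gene the mirrored
interval [tss−b, tss−a), reverse-complemented. Coordinates are 0-based
half-open (BED). Windows truncated at chromosome edges keep their achieved
length. Any promoter that shares ≥ 1 base with another promoter
(strand-agnostic) is removed, along with the promoter it overlaps: redundant
windows would overweight the TFBSs they contain. The operation is
idempotent.

**PWM scoring.** Matrices are count-based with an additive pseudocount
(default 1% of each position's total). A window's score is the summed
per-position log2 probability, min–max normalized so the best achievable
word scores 1 and the worst 0 ("MATCH-style"); bounded scores make library
thresholds portable across matrices. The exact scoring function of the
original composite-detection tool is unpublished, so this normalized scheme
is the package's own choice. Windows containing N score 0. Scanning
evaluates both strands (the minus strand via the reverse-complemented
matrix) and reports minus-strand hits in forward coordinates; the threshold
comparison carries a 1e-9 tolerance so hit sets are invariant to
floating-point summation order between strands. Information content is the
Kullback–Leibler divergence from background in bits summed over positions,
computed from the same smoothed probabilities used for scoring.

**Composite detection.** A library entry pairs two PWMs with per-side score
thresholds, an edge-to-edge gap window [min_gap, max_gap] in nucleotides
(the field's usual convention; overlapping site spans never form a
composite), and an orientation rule (same / opposite / any strands). Both
positional orders (A upstream of B or vice versa) count as the same pair
unless the entry is flagged `ordered`. Pair frequencies over a promoter set
default to counting distinct promoters with ≥ 1 occurrence; total-occurrence
counting is a switch. Promoter counting was made the default because a pair
occurring twice in one promoter is weaker evidence of set-wide co-occurrence
than a pair found in two promoters.

**Networks and MCL.** Nodes are TFBS identifiers; an edge carries the pair
frequency w(vᵢ, vⱼ); pairs mapping to the same unordered node pair sum;
homotypic pairs would be self-edges and are dropped with a warning. The
adjacency matrix is row-normalized, M = Δ⁻¹·A. The literal Δ⁻¹·A has no
self-loops, but classic MCL needs them to converge on bipartite-like
structures, so the default adds a per-node self-loop equal to the node's
maximum incident edge weight before normalization; `self_loop_weight=0`
restores the loop-free formula. The MCL loop alternates Expand (M ← M·M)
and Inflate (entrywise power r, default 2.0, then row renormalization,
zeroing entries below a 1e-9 pruning floor) until the maximum absolute
entrywise change falls below 1e-6 (cap 200 iterations; non-convergence is
logged and the last iterate is used). Clusters are read off attractors
(positive diagonal entries): each node joins the attractor it sends maximal
flow to, with ties broken toward the lexicographically smaller attractor id
(logged), and attractors that share a supporter merge — yielding a
partition. Singleton clusters are retained but flagged; the stage analysis
filters them.

**Stage analysis.** A cluster's hub is its node of maximal within-cluster
weighted degree (lexicographic tie-break) — the formalization of a binding
site "in the center" of a cluster. Only clusters whose induced subgraph has
≥ 3 edges (three interactions) are reported. A hub's presence table has one
row per partner ever adjacent to the hub inside the hub's cluster; the row's
five-stage boolean vector is true exactly where that hub–partner edge lies
inside the hub's cluster. Temporal categories: all five stages true →
`all_stages`; any true–false–true pattern (presence, absence, re-occurrence)
→ `interrupted`; exactly one true → `stage_specific`; the remainder
(contiguous multi-stage blocks) → `other`. A pair's expression annotation
computes, per side, the timepoints where the replicate-mean FPKM of any
mapped TF gene reaches the threshold (default 10, inclusive); the pair is a
`synergistic_candidate` if the two sides' expressed sets share a timepoint
inside every stage where the pair is present, an `antagonistic_candidate` if
both sets are non-empty yet disjoint within every present stage, and
`indeterminate` otherwise. This rule is the package's formalization of a
qualitative reading; the raw expressed sets are always reported alongside
it. The hourglass profile returns the (1-based) stage of the minimum of a
five-stage count vector (first occurrence on ties) and whether it is
interior (stages 2–4).

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, not
real sequencing data. Defaults, fixed once as the study conditions:

| parameter | default | role |
|---|---|---|
| genes | 300 | 5 × 40 stage-unique DE, 6 DE-in-two-stages, 1 non-coding DE decoy, 2 overlapping-promoter decoys, rest null |
| replicates | 3 | per timepoint |
| effect size | log2 FC 4 | step at the stage boundary, direction random |
| noise | lognormal, sd 0.25 on log2 | multiplicative per cell |
| baselines | 2^U(1, 5.6) FPKM | straddle the threshold of 10 |
| promoter length | 1000 nt | iid background, configurable GC (default 0.5) |
| hubs | 4, with 3–6 partners each | per-partner stage patterns: one all-stages, one interrupted, one stage-specific or early/late antagonistic, rest random |
| pair frequency | 4–7 promoters per present pair per stage | intra-hub edges ≥ 4 |
| cross-hub bridges | weight 1 | hub–hub pairs present at all stages |
| PWMs | length 10–12, IC 12–16 bits | pseudocount 0; planted-site score floor 0.97 |
| composite models | thresholds 0.95, gap 5–20 nt, orientation any | one per hub–partner and per bridge |

Planted sites are sampled from the PWM distribution with a floor on the
realized score (falling back to the consensus), so scanner thresholds are
exercised by near-optimal but not identical words. Each promoter hosts up to
four planting blocks spaced ≥ 190 nt apart — far beyond the gap window — so
co-planted pairs cannot cross-match; a stage whose planting demand exceeds
this capacity raises an error rather than silently truncating. Two
safeguards keep the ground-truth bookkeeping exact. First, generated
consensi share no 6-mer with one another or with each other's reverse
complements (rejection sampling): curated motif libraries keep their
matrices distinguishable, and without the constraint a coincidental shared
word between two random motifs lets one pair's planted site cross-match
another matrix. Second, each planted promoter's background is
rejection-sampled — with the planted layout held fixed — until the emitted
sequence contains exactly the recorded pair occurrences, since a handful of
background letters adjacent to a planted site can otherwise complete another
motif's consensus and fabricate a co-located pair. TF genes get designed
FPKM profiles: one hub/partner pair expressed at every timepoint (the
synergistic archetype), one pair split early-only vs late-only (the
antagonistic archetype, with the pair planted only in the first and last
stages), one TF gene with a genuine expression step that must still be
excluded from DEG sets by its TF flag, and a low-expressed second gene on
one mapping to exercise the max-over-genes rule. All randomness flows
through a single seeded generator; a fixed seed reproduces every emitted
file byte for byte.

What the generator does **not** emulate: read-level sequencing and FPKM
normalization from counts, replicate correlation structure, Markov (dinucleotide)
background composition, overlapping motif occurrences, indirect (tethered)
binding, and the curation biases of a real composite library. Passing tests
therefore demonstrate that the pipeline recovers structure of this idealized
kind; they do not certify performance on real promoter sequence, where
false-positive motif hits are substantially more frequent.

## Numerical choices and degenerate inputs

- Probabilities are floored at 1e-12 before taking logs, so zero-pseudocount
  matrices with structural zeros still score finitely.
- A fully uniform matrix has S_max = S_min; every window scores 1 by
  convention.
- An all-zero matrix position with zero pseudocount raises a
  degenerate-matrix error; a zero background entry rejects IC computation.
- Markov rows are validated to sum to 1 within 1e-6 on input and preserved
  within 1e-9 through Expand/Inflate; an all-zero row after pruning raises.
- A lone network node receives a unit self-loop (M = [1]) even in the
  loop-free mode, since an all-zero row cannot be normalized.
- extract_clusters falls back to row-argmax grouping if a (non-converged)
  matrix has no positive diagonal entries.
- Flow ties in cluster assignment and degree ties in hub selection break
  lexicographically and are logged, so re-runs are reproducible.

## Problem sizes

The default synthetic study (300 genes × 6 timepoints × 3 replicates, ~25
PWMs, ~200 scanned promoters of 1 kb per run) runs end to end in a few
seconds; the acceptance script's 20-replicate sweep completes in about two
minutes on one CPU, and the test suite in about ninety seconds. These sizes were
chosen so that planted-structure recovery is measured over many seeds while
iteration stays interactive.

## Known limitations

- The DEG stand-in has no variance moderation; at 2 replicates it is legal
  but underpowered.
- MCL is dense-matrix (O(n³) per iteration); fine for TFBS networks
  (tens–hundreds of nodes), not for genome-scale graphs.
- Overlapping promoter removal drops both members of a pair, as specified;
  no merging of overlapping windows is attempted.
- The synergistic/antagonistic annotation is a coarse threshold rule on
  marginal expression; it ignores protein-level regulation and is reported
  as candidate status only.
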