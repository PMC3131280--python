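"""Emergence-constrained progressive folding.

A scanning ribosome exposes a 5' leader gradually at its mRNA exit channel,
so the leader does not fold as a rigid standalone molecule: upstream sequence
folds (or fails to fold) before downstream sequence exists. This module
models that by folding a growing prefix of the leader segment by segment.
A segment that emerges without internal structure is assumed to stay
available for protein contacts and is blocked from pairing with anything
downstream; pairs formed in earlier rounds are frozen (forced) in later
rounds. With a single segment and a permissive policy the procedure reduces
exactly to a plain MFE fold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold_engine import (
    ConstraintSet,
    EnergyModel,
    FoldResult,
    default_model,
    mfe_fold,
)
from .seqio import RnaSequence, SeqFormatError

__all__ = [
    "SegmentationPlan",
    "EmergencePolicy",
    "FoldRound",
    "ProgressiveFoldResult",
    "segment",
    "classify_segment",
    "progressive_fold",
]

STRUCTURED = "structured"
UNSTRUCTURED = "unstructured"


@dataclass(frozen=True)
class SegmentationPlan:
    """Ordered segment lengths covering the fold region exactly."""

    segment_lengths: tuple[int, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        lengths = tuple(int(x) for x in self.segment_lengths)
        object.__setattr__(self, "segment_lengths", lengths)
        if not lengths or any(x <= 0 for x in lengths):
            raise SeqFormatError("segment lengths must be positive")
        if self.labels is not None and len(self.labels) != len(lengths):
            raise SeqFormatError("labels must match segment count")

    @classmethod
    def parse(cls, text: str) -> "SegmentationPlan":
        """Parse e.g. ``"66,81,73"``."""
        return cls(tuple(int(x) for x in text.split(",")))

    @property
    def total(self) -> int:
        return sum(self.segment_lengths)


@dataclass(frozen=True)
class EmergencePolicy:
    """What emergence implies for later folding rounds.

    cross_block_unstructured:
        Block all pairs between a segment classified unstructured at its
        emergence and every downstream position (internal pairing within the
        segment stays permitted).
    freeze_pairs:
        Carry each round's pairs into later rounds as forced pairs ("refold"
        mode when False, kept for sensitivity analysis).
    """

    cross_block_unstructured: bool = True
    freeze_pairs: bool = True


@dataclass(frozen=True)
class FoldRound:
    region: tuple[int, int]
    constraints: ConstraintSet
    result: FoldResult


@dataclass(frozen=True)
class ProgressiveFoldResult:
    rounds: tuple[FoldRound, ...]
    final: FoldResult
    segment_status: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]


def segment(seq: RnaSequence, plan: SegmentationPlan) -> list[tuple[int, int]]:
    """Contiguous, non-overlapping closed intervals covering ``seq`` in order."""
    if plan.total != len(seq):
        raise SeqFormatError(
            f"plan lengths sum to {plan.total}, sequence is {len(seq)} nt"
        )
    intervals, start = [], 1
    for length in plan.segment_lengths:
        intervals.append((start, start + length - 1))
        start += length
    return intervals


def classify_segment(
    result: FoldResult, region: tuple[int, int], threshold: int = 0
) -> str:
    """``unstructured`` iff at most ``threshold`` pairs lie entirely inside
    ``region`` (default 0: a single internal pair already counts as structure)."""
    lo, hi = region
    if not (1 <= lo <= hi <= result.structure.length):
        raise SeqFormatError(f"region {region} outside structure")
    internal = sum(1 for i, j in result.structure.pairs if lo <= i and j <= hi)
    return STRUCTURED if internal > threshold else UNSTRUCTURED


def progressive_fold(
    seq: RnaSequence,
    plan: SegmentationPlan,
    model: EnergyModel | None = None,
    policy: EmergencePolicy | None = None,
) -> ProgressiveFoldResult:
    """Fold ``seq`` as it progressively emerges, segment by segment.

    Round r folds the concatenation of segments 1..r. Each round applies:
    a block between every earlier segment classified unstructured and all
    downstream sequence (policy permitting), and the previous round's pairs
    as forced pairs (policy permitting). The final round covers the whole
    region; each segment's structured/unstructured status is fixed at the
    round in which it first emerges.
    """
    model = model or default_model()
    policy = policy or EmergencePolicy()
    intervals = segment(seq, plan)

    rounds: list[FoldRound] = []
    statuses: list[str] = []
    frozen: frozenset[tuple[int, int]] = frozenset()

    for r, (_, end) in enumerate(intervals):
        blocks = []
        if policy.cross_block_unstructured:
            for s in range(r):
                if statuses[s] == UNSTRUCTURED:
                    s_lo, s_hi = intervals[s]
                    if s_hi + 1 <= end:
                        blocks.append(((s_lo, s_hi), (s_hi + 1, end)))
        constraints = ConstraintSet(
            forced_pairs=frozen if policy.freeze_pairs else frozenset(),
            blocks=tuple(blocks),
        )
        prefix = seq.subsequence(1, end, id=f"{seq.id}|1-{end}")
        result = mfe_fold(prefix, constraints, model)
        rounds.append(FoldRound((1, end), constraints, result))
        statuses.append(classify_segment(result, intervals[r]))
        frozen = result.structure.pairs

    return ProgressiveFoldResult(
        rounds=tuple(rounds),
        final=rounds[-1].result,
        segment_status=tuple(statuses),
        intervals=tuple(intervals),
    )
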