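"""Synthetic leader generation.

Short-uORF 5' leaders of the kind this package analyses are strongly AU-rich
and G-poor (the default background composition is A 0.40 / C 0.22 / G 0.07 /
U 0.31), with their few G residues concentrated in compact GC-rich stems.
The generator emulates that: an i.i.d. AU-rich background with *planted*
GC-rich motifs — double-circle hairpins and bulged stems — whose local MFE
under the default energy model is verified (by folding) to equal the planted
geometry, resampling stem sequences up to a retry cap. The planted ground
truth is returned alongside the sequence, so every downstream stage can be
tested without any external data.

All randomness flows through one documented PRNG (numpy's PCG64 via
``numpy.random.default_rng``) seeded explicitly, so output is reproducible
across platforms.

:func:`gcn4_like_leader` builds a *synthetic stand-in* for the GCN4 uORF1
leader studied in the reinitiation literature: the real yeast sequence is
not distributed here, but the stand-in reproduces the published study
conditions exactly — a 229-nt anchored leader whose composition rounds to
A 40 / C 22 / G 7 / U 31 integer percent, a double-circle hairpin occupying
-129..-83 (outer stem at probe nt 3-7:45-49, inner stem at 22-24:31-33), and
a 9-bp bulged stem starting 6 nt downstream of the hairpin (probe nt
56-64:68-77, 3-nt apical loop, 1-nt bulge near the 3' base).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .fold_engine import EnergyModel, default_model, mfe_fold
from .motif_scan import RegionAnnotation
from .probing import ProbingDataset, read_probing_tsv
from .progressive_fold import ProgressiveFoldResult, SegmentationPlan, progressive_fold
from .seqio import RnaSequence, SecondaryStructure, SeqFormatError

__all__ = [
    "PlantedMotif",
    "SyntheticLeaderSpec",
    "generate_leader",
    "generate_caa_linker",
    "Gcn4LikeFixture",
    "gcn4_like_leader",
    "gcn4_like_probing",
]

DEFAULT_COMPOSITION = {"A": 0.40, "C": 0.22, "G": 0.07, "U": 0.31}

DOUBLE_CIRCLE_DEFAULTS = {
    "outer": 5,       # outer stem pairs
    "inner": 3,       # inner stem pairs
    "loop5": 4,       # internal loop, 5' side
    "loop3": 4,       # internal loop, 3' side
    "hairpin": 4,     # hairpin loop
}
BULGED_STEM_DEFAULTS = {
    "stem": 9,         # base pairs
    "apical": 3,       # apical loop nt
    "bulge": 1,        # bulge size (3' strand)
    "bulge_after": 3,  # pairs between helix base and the bulge; deep enough
                       # that the bulge bridge sits between stacked pairs
}


@dataclass(frozen=True)
class PlantedMotif:
    """A motif to embed: class, 1-based start offset, geometry overrides."""

    motif_class: str  # double_circle_hairpin | bulged_stem
    offset: int
    geometry: dict = field(default_factory=dict)

    def resolved_geometry(self) -> dict:
        if self.motif_class == "double_circle_hairpin":
            return {**DOUBLE_CIRCLE_DEFAULTS, **self.geometry}
        if self.motif_class == "bulged_stem":
            return {**BULGED_STEM_DEFAULTS, **self.geometry}
        raise SeqFormatError(f"unknown motif class {self.motif_class!r}")

    @property
    def span_length(self) -> int:
        g = self.resolved_geometry()
        if self.motif_class == "double_circle_hairpin":
            return 2 * (g["outer"] + g["inner"]) + g["loop5"] + g["loop3"] + g["hairpin"]
        return 2 * g["stem"] + g["apical"] + g["bulge"]


@dataclass(frozen=True)
class SyntheticLeaderSpec:
    length: int = 220
    composition: tuple[float, float, float, float] = (0.40, 0.22, 0.07, 0.31)  # A C G U
    planted_motifs: tuple[PlantedMotif, ...] = ()
    linker_style: str = "random"  # random | CAA-repeat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SeqFormatError("length must be >= 1")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise SeqFormatError("composition fractions must sum to 1")
        if self.linker_style not in ("random", "CAA-repeat"):
            raise SeqFormatError(f"unknown linker style {self.linker_style!r}")
        spans = []
        for m in self.planted_motifs:
            end = m.offset + m.span_length - 1
            if m.offset < 1 or end > self.length:
                raise SeqFormatError(
                    f"motif at offset {m.offset} (span {m.span_length} nt) does "
                    f"not fit in a {self.length}-nt leader"
                )
            spans.append((m.offset - 1, end + 1))  # include 1-nt guard margins
        spans.sort()
        for a, b in zip(spans, spans[1:]):
            if b[0] <= a[1]:
                raise SeqFormatError("planted motifs (plus guard nt) overlap")


def _motif_layout(motif: PlantedMotif) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Relative (1-based) pair list, 5'-strand stem positions, loop positions."""
    g = motif.resolved_geometry()
    if motif.motif_class == "double_circle_hairpin":
        o, i, l5, l3, h = g["outer"], g["inner"], g["loop5"], g["loop3"], g["hairpin"]
        span = 2 * (o + i) + l5 + l3 + h
        pairs = [(t, span - t + 1) for t in range(1, o + 1)]
        in5 = o + l5
        in3 = in5 + i + h
        pairs += [(in5 + t, in3 + i - t + 1) for t in range(1, i + 1)]
        stem5 = list(range(1, o + 1)) + list(range(in5 + 1, in5 + i + 1))
        loops = [p for p in range(1, span + 1) if p not in {x for pr in pairs for x in pr}]
        return pairs, stem5, loops
    g5 = g["stem"]
    span = 2 * g["stem"] + g["apical"] + g["bulge"]
    pairs = []
    for t in range(1, g["stem"] + 1):
        i = t
        j = span - t + 1 if t <= g["bulge_after"] else span - t + 1 - g["bulge"]
        pairs.append((i, j))
    stem5 = list(range(1, g5 + 1))
    loops = [p for p in range(1, span + 1) if p not in {x for pr in pairs for x in pr}]
    return pairs, stem5, loops


def _design_motif(
    motif: PlantedMotif,
    rng: np.random.Generator,
    model: EnergyModel,
    retries: int = 50,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Sequence-design a motif so its local MFE equals the planted geometry."""
    pairs, stem5, loops = _motif_layout(motif)
    span = motif.span_length
    for _ in range(retries):
        letters = [""] * (span + 1)
        for p in loops:
            letters[p] = "A"  # A-only loops cannot pair among themselves
        for i, j in pairs:
            if rng.random() < 0.5:
                letters[i], letters[j] = "G", "C"
            else:
                letters[i], letters[j] = "C", "G"
        seq = RnaSequence(id="motif", residues="".join(letters[1:]))
        fold = mfe_fold(seq, model=model)
        if set(fold.structure.pairs) == set(pairs):
            return letters[1:], pairs
    raise SeqFormatError(
        f"could not design a {motif.motif_class} with geometry "
        f"{motif.resolved_geometry()} in {retries} attempts"
    )


def generate_leader(
    spec: SyntheticLeaderSpec,
    model: EnergyModel | None = None,
    verify_flanks: bool = True,
    max_attempts: int = 100,
) -> tuple[RnaSequence, SecondaryStructure, list[RegionAnnotation]]:
    """Generate a synthetic leader with planted, fold-verified motifs.

    Returns the sequence (anchored at ``length + 1``, i.e. the uORF AUG abuts
    the 3' end), the planted ground-truth structure, and one
    :class:`RegionAnnotation` per planted motif. Deterministic given
    ``spec.seed``.

    Background bases immediately flanking each motif are set to ``A`` as part
    of the planting, so a planted helix cannot be stacked onto directly. When
    motifs are planted and ``verify_flanks`` is on, the background is redrawn
    until the whole-leader MFE equals the planted ground truth exactly — the
    "unstructured flanks" property of the natural G-poor leaders this module
    emulates. Motif-free leaders are plain i.i.d. draws (their background
    keeps the full G budget and folds whatever it folds).
    """
    model = model or default_model()
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    letters: list[str | None] = [None] * (n + 1)
    all_pairs: set[tuple[int, int]] = set()

    for motif in spec.planted_motifs:
        designed, rel_pairs = _design_motif(motif, rng, model)
        off = motif.offset
        for k, b in enumerate(designed):
            letters[off + k] = b
        all_pairs.update((off + i - 1, off + j - 1) for i, j in rel_pairs)
        for guard in (off - 1, off + len(designed)):
            if 1 <= guard <= n:
                letters[guard] = "A"

    background = [p for p in range(1, n + 1) if letters[p] is None]
    truth = SecondaryStructure(n, frozenset(all_pairs))

    # The planted GC-rich stems consume the leader's scarce G/C budget; the
    # background is drawn i.i.d. from the *residual* composition so the
    # overall leader keeps the target base frequencies and, like the natural
    # G-poor leaders this emulates, its flanks stay AU-dominated.
    budget = {b: spec.composition[k] * n for k, b in enumerate("ACGU")}
    for p in range(1, n + 1):
        if letters[p] is not None:
            budget[letters[p]] -= 1
    residual = {b: max(v, 0.0) for b, v in budget.items()}
    total = sum(residual.values()) or 1.0
    freqs = [residual[b] / total for b in "ACGU"]

    def draw_background() -> list[str]:
        filled = list(letters)
        if spec.linker_style == "CAA-repeat":
            pattern = "CAA"
            for k, p in enumerate(background):
                filled[p] = pattern[k % 3]
        else:
            draws = rng.choice(list("ACGU"), size=len(background), p=freqs)
            for p, b in zip(background, draws):
                filled[p] = str(b)
        return filled

    verify = verify_flanks and bool(spec.planted_motifs)
    seq = None
    for _ in range(max_attempts if verify else 1):
        filled = draw_background()
        candidate = RnaSequence(
            id=f"synthetic_leader_seed{spec.seed}",
            residues="".join(filled[1:]),
            anchor_index=n + 1,
        )
        if not verify:
            seq = candidate
            break
        if mfe_fold(candidate, model=model).structure.pairs == truth.pairs:
            seq = candidate
            break
    if seq is None:
        raise SeqFormatError(
            f"no background kept the flanks unstructured in {max_attempts} "
            f"attempts (seed {spec.seed})"
        )
    annotations = []
    for k, motif in enumerate(spec.planted_motifs, start=1):
        lo, hi = motif.offset, motif.offset + motif.span_length - 1
        annotations.append(
            RegionAnnotation(
                name=f"planted_{k}_{motif.motif_class}",
                span_neg=(lo - seq.anchor_index, hi - seq.anchor_index),
                status="structured",
            )
        )
    return seq, truth, annotations


def generate_caa_linker(n_triplets: int) -> RnaSequence:
    """``CAA`` repeated n times — the classic structure-free spacer (no allowed
    pair exists over {C, A}, so its MFE fold has zero pairs)."""
    if n_triplets < 1:
        raise SeqFormatError("n_triplets must be >= 1")
    return RnaSequence(id=f"caa_{n_triplets}", residues="CAA" * n_triplets)


# ---------------------------------------------------------------------------
# The synthetic GCN4-uORF1-like study fixture

# Fixed motif letters (leader coordinates). The double-circle hairpin occupies
# -129..-83 (indices 101..147 with the AUG anchored at 230); the 9-bp bulged
# stem starts 6 nt downstream at -76 (index 154). G/C placement puts a paired
# G at probe positions 23, 31, 48 and 75 (probe offset 98), the four sites the
# probing fixture scores.
_GCN4_MOTIF_LETTERS: dict[int, str] = {}
_GCN4_PLANTED_PAIRS: list[tuple[int, int]] = []


def _build_gcn4_layout() -> None:
    put = _GCN4_MOTIF_LETTERS.__setitem__
    # double-circle hairpin: outer stem 101-105 : 143-147
    for pos, b in zip(range(101, 106), "GCGCC"):
        put(pos, b)
    for pos, b in zip(range(143, 148), "GGCGC"):
        put(pos, b)
    # inner stem 120-122 : 129-131
    for pos, b in zip(range(120, 123), "CGC"):
        put(pos, b)
    for pos, b in zip(range(129, 132), "GCG"):
        put(pos, b)
    # A-only loops: internal 106-119 / 132-142, hairpin 123-128
    for pos in (*range(106, 120), *range(123, 129), *range(132, 143)):
        put(pos, "A")
    _GCN4_PLANTED_PAIRS.extend((100 + t, 148 - t) for t in range(1, 6))
    _GCN4_PLANTED_PAIRS.extend([(120, 131), (121, 130), (122, 129)])
    # bulged stem: 5' strand 154-162, apical loop 163-165, 3' strand 166-175
    # with a 1-nt bulge at 172 (probe 74), three pairs from the helix base —
    # deep enough that the bulge bridge sits between stacked pairs
    for pos, b in zip(range(154, 163), "GCCAGCUCG"):
        put(pos, b)
    for pos in range(163, 166):
        put(pos, "A")
    for pos, b in zip(range(166, 176), "CGAGCUAGGC"):
        put(pos, b)
    stem_pairs = [
        (154, 175), (155, 174), (156, 173), (157, 171), (158, 170),
        (159, 169), (160, 168), (161, 167), (162, 166),
    ]
    _GCN4_PLANTED_PAIRS.extend(stem_pairs)


_build_gcn4_layout()

_GCN4_LENGTH = 229          # leader -229..-1; the AUG A is index 230
_GCN4_FOLD_END = 220        # fold region -229..-10 (3'-terminal 9 nt excluded:
                            # they sit in the ribosome's mRNA channel)
_GCN4_PLAN = (66, 81, 73)
_GCN4_GUARDS = (100, 148, 153, 176)  # background A's flanking the motifs
# exact leader counts: A 92 / C 50 / G 16 / U 71 -> 40/22/7/31 integer percent
_GCN4_TARGET_COUNTS = {"A": 92, "C": 50, "G": 16, "U": 71}
_GCN4_PROBE_OFFSET = 98     # probe nt p sits at leader index p + 98
_GCN4_PROBE_SPAN = (99, 177)  # 79-mer: 2 nt before the hairpin .. 2 nt after the stem

_GCN4_RPE_TEMPLATES = (
    RegionAnnotation("RPE i", (-51, -31)),
    RegionAnnotation("RPE ii", (-61, -51)),
    RegionAnnotation("RPE iii", (-181, -143)),
    RegionAnnotation("RPE iv", (-129, -83)),
)


@dataclass(frozen=True)
class Gcn4LikeFixture:
    """Synthetic stand-in for the GCN4 uORF1 leader and its analysis inputs."""

    leader: RnaSequence                  # 229 nt, anchor_index 230
    fold_region: RnaSequence             # -229..-10 (220 nt)
    plan: SegmentationPlan
    planted: SecondaryStructure          # ground truth on the fold region
    result: ProgressiveFoldResult        # progressive fold of the region
    rpe_templates: tuple[RegionAnnotation, ...]
    probe: RnaSequence                   # the 79-mer probing substrate
    probe_offset: int
    attempts: int


def gcn4_like_leader(
    seed: int = 0, model: EnergyModel | None = None, max_attempts: int = 200
) -> Gcn4LikeFixture:
    """Construct the synthetic GCN4-uORF1-like leader (see module docstring).

    The motif letters and coordinates are fixed; the AU-rich background is
    drawn (exact letter counts, shuffled) from ``seed`` and resampled until
    the progressive fold of the 220-nt region under the (66, 81, 73) plan
    reproduces exactly the planted structure — in particular the emerged
    5' 66-mer stays pair-free. Deterministic given ``seed``.
    """
    model = model or default_model()
    rng = np.random.default_rng(seed)

    counts = dict(_GCN4_TARGET_COUNTS)
    for b in _GCN4_MOTIF_LETTERS.values():
        counts[b] -= 1
    for _ in _GCN4_GUARDS:
        counts["A"] -= 1
    if min(counts.values()) < 0:  # pragma: no cover - layout arithmetic guard
        raise AssertionError("motif letters exceed composition budget")
    pool = "".join(b * c for b, c in sorted(counts.items()))
    free = [
        p
        for p in range(1, _GCN4_LENGTH + 1)
        if p not in _GCN4_MOTIF_LETTERS and p not in _GCN4_GUARDS
    ]
    assert len(pool) == len(free)

    plan = SegmentationPlan(_GCN4_PLAN)
    planted = SecondaryStructure(_GCN4_FOLD_END, frozenset(_GCN4_PLANTED_PAIRS))

    for attempt in range(1, max_attempts + 1):
        shuffled = rng.permutation(list(pool))
        letters = [""] * (_GCN4_LENGTH + 1)
        for p, b in _GCN4_MOTIF_LETTERS.items():
            letters[p] = b
        for p in _GCN4_GUARDS:
            letters[p] = "A"
        for p, b in zip(free, shuffled):
            letters[p] = str(b)
        leader = RnaSequence(
            id=f"gcn4_like_synthetic_seed{seed}",
            residues="".join(letters[1:]),
            anchor_index=_GCN4_LENGTH + 1,
        )
        region = leader.subsequence(1, _GCN4_FOLD_END, id=f"{leader.id}|enhancer")
        result = progressive_fold(region, plan, model=model)
        if result.final.structure.pairs == planted.pairs:
            probe = leader.subsequence(*_GCN4_PROBE_SPAN, id=f"{leader.id}|probe79")
            return Gcn4LikeFixture(
                leader=leader,
                fold_region=region,
                plan=plan,
                planted=planted,
                result=result,
                rpe_templates=_GCN4_RPE_TEMPLATES,
                probe=probe,
                probe_offset=_GCN4_PROBE_OFFSET,
                attempts=attempt,
            )
    raise SeqFormatError(
        f"no background arrangement reproduced the planted fold in "
        f"{max_attempts} attempts (seed {seed})"
    )


def gcn4_like_probing() -> ProbingDataset:
    """The curated synthetic probing cut table for the 79-mer substrate."""
    ref = importlib.resources.files("reifold").joinpath(
        "data/probing_79mer_synthetic.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_probing_tsv(path)
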