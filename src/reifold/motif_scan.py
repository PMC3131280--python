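"""Detection of reinitiation-relevant structural features.

The features of interest in short-uORF leaders are: *double-circle hairpins*
(an outer helix and exactly one nested inner helix separated by an internal
loop — two "circles" in the planar drawing, the inner one closing the hairpin
loop), *bulged stems* (a helix interrupted by short single-stranded bulges),
and unstructured stretches. Candidate reinitiation-promoting element (RPE)
spans, given in AUG-relative negative coordinates, are annotated as
structured or unstructured against a predicted fold.

Motif calls are meant to single out the compact, GC-rich, thermodynamically
stable elements these leaders use as cis-signals, not every marginal helix
an AU-rich background improvises. When the sequence is supplied, a hit must
therefore (i) draw at least half of its stem pairs from G-C (``min_gc``) and
(ii) be at least as stable as the worst-case all-GC motif of the target
geometry (``max_energy``: -6 kcal/mol for a 5+3-pair double circle, -10 for
a 9-pair bulged stem, under the default parameter set). Without a sequence
only the geometric criteria apply.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seqio import (
    RnaSequence,
    SecondaryStructure,
    SeqFormatError,
    neg_to_index,
)

__all__ = [
    "Helix",
    "MotifHit",
    "RegionAnnotation",
    "enumerate_helices",
    "find_double_circle_hairpins",
    "find_bulged_stems",
    "annotate_rpes",
]


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs, merged across interruptions of at most
    ``max_interruption`` unpaired nt per side.

    ``pairs`` runs outermost to innermost; ``interruptions`` holds
    ``(after_pair_index, gap5, gap3)`` for every non-contiguous step.
    """

    pairs: tuple[tuple[int, int], ...]
    interruptions: tuple[tuple[int, int, int], ...]
    closes_hairpin: bool
    apical_loop: int | None  # hairpin-loop size if closes_hairpin

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def span(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[0][1]

    @property
    def strand5(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[-1][0]

    @property
    def strand3(self) -> tuple[int, int]:
        return self.pairs[-1][1], self.pairs[0][1]

    @property
    def bulges(self) -> tuple[tuple[str, int], ...]:
        """(side, size) per interruption: '5p'/'3p' bulges, 'internal' loops."""
        out = []
        for _, g5, g3 in self.interruptions:
            if g3 == 0:
                out.append(("5p", g5))
            elif g5 == 0:
                out.append(("3p", g3))
            else:
                out.append(("internal", g5 + g3))
        return tuple(out)

    def positions(self) -> set[int]:
        return {p for ij in self.pairs for p in ij}


@dataclass(frozen=True)
class MotifHit:
    motif_class: str  # double_circle_hairpin | bulged_stem | unstructured_run
    span: tuple[int, int]
    components: tuple[Helix, ...]
    score: dict
    span_neg: tuple[int, int] | None = None


@dataclass(frozen=True)
class RegionAnnotation:
    """An RPE (or custom) span in negative coordinates, with derived status."""

    name: str
    span_neg: tuple[int, int]  # (more negative, less negative), e.g. (-51, -31)
    status: str | None = None
    motifs: tuple[MotifHit, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.span_neg
        if lo > hi:
            object.__setattr__(self, "span_neg", (hi, lo))


def _children_map(structure: SecondaryStructure):
    """Direct child pairs of every pair (and of the exterior, key ``None``)."""
    table = structure.pair_table

    def children(lo: int, hi: int):
        kids, p = [], lo
        while p <= hi:
            q = table.get(p)
            if q is not None and q > p:
                kids.append((p, q))
                p = q + 1
            else:
                p += 1
        return kids

    out = {None: children(1, structure.length)}
    agenda = list(out[None])
    while agenda:
        i, j = agenda.pop()
        out[(i, j)] = children(i + 1, j - 1)
        agenda.extend(out[(i, j)])
    return out


def enumerate_helices(
    structure: SecondaryStructure, max_interruption: int = 3
) -> list[Helix]:
    """Partition the pair set into helices.

    Stacked runs are merged across a bulge or internal loop when the
    interruption is at most ``max_interruption`` nt on each side (so a 9-bp
    stem with a 1-nt bulge counts as a single helix); every pair belongs to
    exactly one helix. Helices are returned 5'->3' by outer pair.
    """
    kids = _children_map(structure)

    def continuation(pair):
        ch = kids[pair]
        if len(ch) != 1:
            return None
        (k, l) = ch[0]
        i, j = pair
        g5, g3 = k - i - 1, j - l - 1
        if g5 <= max_interruption and g3 <= max_interruption:
            return (k, l), g5, g3
        return None

    continued_into = set()
    for pair in list(kids):
        if pair is None:
            continue
        cont = continuation(pair)
        if cont:
            continued_into.add(cont[0])

    helices = []
    heads = sorted(p for p in kids if p is not None and p not in continued_into)
    for head in heads:
        chain = [head]
        interruptions = []
        cur = head
        while True:
            cont = continuation(cur)
            if cont is None:
                break
            nxt, g5, g3 = cont
            if (g5, g3) != (0, 0):
                interruptions.append((len(chain) - 1, g5, g3))
            chain.append(nxt)
            cur = nxt
        inner = chain[-1]
        inner_kids = kids[inner]
        closes = len(inner_kids) == 0
        apical = (inner[1] - inner[0] - 1) if closes else None
        helices.append(
            Helix(tuple(chain), tuple(interruptions), closes, apical)
        )
    return helices


def _attach_neg(hit: MotifHit, seq: RnaSequence | None) -> MotifHit:
    if seq is None or seq.anchor_index is None:
        return hit
    lo, hi = hit.span
    return replace(hit, span_neg=(lo - seq.anchor_index, hi - seq.anchor_index))


def _hit_quality(seq: RnaSequence, components, span, model) -> tuple[float, float]:
    """Stability (kcal/mol, substructure over the span) and GC pair fraction."""
    from .fold_engine import default_model, evaluate_energy

    model = model or default_model()
    lo, hi = span
    pairs = [(i, j) for c in components for (i, j) in c.pairs]
    gc = sum(1 for i, j in pairs if {seq.base(i), seq.base(j)} == {"G", "C"})
    sub = seq.subsequence(lo, hi)
    structure = SecondaryStructure(
        hi - lo + 1, frozenset((i - lo + 1, j - lo + 1) for i, j in pairs)
    )
    return evaluate_energy(sub, structure, model), gc / len(pairs)


def find_double_circle_hairpins(
    structure: SecondaryStructure,
    min_outer: int = 3,
    min_inner: int = 2,
    max_interruption: int = 3,
    seq: RnaSequence | None = None,
    max_energy: float = -6.0,
    min_gc: float = 0.5,
    model=None,
) -> list[MotifHit]:
    """Outer helix enclosing exactly one inner helix across an internal loop,
    the inner helix closing the hairpin loop (the two "circles").

    With ``seq`` given, hits must also pass the stability (``max_energy``)
    and GC-fraction (``min_gc``) quality thresholds (see module docstring).
    """
    kids = _children_map(structure)
    helices = enumerate_helices(structure, max_interruption)
    by_head = {h.pairs[0]: h for h in helices}
    hits = []
    for outer in helices:
        if outer.n_pairs < min_outer or outer.closes_hairpin:
            continue
        i, j = outer.pairs[-1]
        inner_pairs = kids[(i, j)]
        if len(inner_pairs) != 1:
            continue
        (k, l) = inner_pairs[0]
        g5, g3 = k - i - 1, j - l - 1
        if g5 < 1 or g3 < 1:  # the separating loop must be a true internal loop
            continue
        inner = by_head.get((k, l))
        if inner is None or not inner.closes_hairpin or inner.n_pairs < min_inner:
            continue
        score = {
            "outer_pairs": outer.n_pairs,
            "inner_pairs": inner.n_pairs,
            "internal_loop": (g5, g3),
            "hairpin_loop": inner.apical_loop,
        }
        if seq is not None:
            energy, gc = _hit_quality(seq, (outer, inner), outer.span, model)
            if energy > max_energy or gc < min_gc:
                continue
            score["energy"] = energy
            score["gc_fraction"] = gc
        hit = MotifHit(
            motif_class="double_circle_hairpin",
            span=outer.span,
            components=(outer, inner),
            score=score,
        )
        hits.append(_attach_neg(hit, seq))
    return hits


def find_bulged_stems(
    structure: SecondaryStructure,
    min_pairs: int = 5,
    max_interruption: int = 3,
    seq: RnaSequence | None = None,
    max_energy: float = -10.0,
    min_gc: float = 0.5,
    model=None,
) -> list[MotifHit]:
    """Helices with >= ``min_pairs`` pairs and at least one single-strand
    interruption; a perfect uninterrupted stem is not reported here.

    With ``seq`` given, hits must also pass the stability (``max_energy``)
    and GC-fraction (``min_gc``) quality thresholds (see module docstring).
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    hits = []
    for helix in enumerate_helices(structure, max_interruption):
        if helix.n_pairs < min_pairs or not helix.interruptions:
            continue
        score = {
            "n_pairs": helix.n_pairs,
            "apical_loop": helix.apical_loop,
            "bulges": helix.bulges,
        }
        if seq is not None:
            energy, gc = _hit_quality(seq, (helix,), helix.span, model)
            if energy > max_energy or gc < min_gc:
                continue
            score["energy"] = energy
            score["gc_fraction"] = gc
        hit = MotifHit(
            motif_class="bulged_stem",
            span=helix.span,
            components=(helix,),
            score=score,
        )
        hits.append(_attach_neg(hit, seq))
    return hits


def annotate_rpes(
    structure: SecondaryStructure,
    seq: RnaSequence,
    regions: list[RegionAnnotation],
    hits: list[MotifHit] | None = None,
) -> list[RegionAnnotation]:
    """Label each candidate RPE span structured/unstructured and link motifs.

    A span counts as *structured* when any paired position falls inside it
    (a stem whose partner strand lies outside the span still structures it).
    ``structure`` must be a 5'-anchored prefix of ``seq``'s coordinate system.
    """
    if hits is None:
        hits = find_double_circle_hairpins(structure, seq=seq) + find_bulged_stems(
            structure, seq=seq
        )
    paired = set(structure.pair_table)
    out = []
    for region in regions:
        lo = neg_to_index(region.span_neg[0], seq)
        hi = neg_to_index(region.span_neg[1], seq)
        if hi > structure.length:
            raise SeqFormatError(
                f"region {region.name} span {region.span_neg} extends past the "
                f"folded region ({structure.length} nt)"
            )
        status = (
            "structured"
            if any(lo <= p <= hi for p in paired)
            else "unstructured"
        )
        overlapping = tuple(
            h for h in hits if not (h.span[1] < lo or h.span[0] > hi)
        )
        out.append(replace(region, status=status, motifs=overlapping))
    return out
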