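"""Sequence perturbation: construct-style substitutions and stem disruption.

Variants use the construct notation of the uORF literature —
``<ref><negative position><alt>``, e.g. ``C-129A`` — with positions counted
upstream from the uORF AUG. Disruption is judged on the *refolded* mutant
structure, not on nominal complementarity, because substitutions can create
compensatory pairings.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Callable, Sequence

from .fold_engine import mfe_fold
from .motif_scan import Helix
from .seqio import RnaSequence, SecondaryStructure, SeqFormatError, neg_to_index

__all__ = [
    "VariantSpec",
    "parse_variant",
    "parse_variant_list",
    "apply_variants",
    "disruption_report",
    "design_disruptors",
]

_VARIANT_RE = re.compile(r"^([ACGUT])(-\d+)([ACGUT])$")

Folder = Callable[[RnaSequence], SecondaryStructure]


def _default_folder(seq: RnaSequence) -> SecondaryStructure:
    return mfe_fold(seq).structure


@dataclass(frozen=True)
class VariantSpec:
    """A single substitution at a negative coordinate."""

    ref: str
    position: int  # negative, AUG-relative
    alt: str

    def __post_init__(self) -> None:
        ref = self.ref.upper().replace("T", "U")
        alt = self.alt.upper().replace("T", "U")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        for b in (ref, alt):
            if b not in "ACGU":
                raise SeqFormatError(f"variant base {b!r} not in ACGU")
        if ref == alt:
            raise SeqFormatError(f"variant {self} does not change the base")
        if self.position > -1:
            raise SeqFormatError(f"variant position {self.position} must be negative")

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"

    def swapped(self) -> "VariantSpec":
        return VariantSpec(self.alt, self.position, self.ref)


def parse_variant(text: str) -> VariantSpec:
    """Parse construct notation, e.g. ``C-129A``."""
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise SeqFormatError(f"malformed variant {text!r} (expected e.g. C-129A)")
    return VariantSpec(m.group(1), int(m.group(2)), m.group(3))


def parse_variant_list(text: str) -> list[VariantSpec]:
    """Parse a comma-separated variant list, e.g. ``"C-129A,G-128A,G-109C"``."""
    return [parse_variant(tok) for tok in text.split(",") if tok.strip()]


def apply_variants(seq: RnaSequence, variants: Sequence[VariantSpec]) -> RnaSequence:
    """Apply substitutions; length and all unlisted positions are preserved.

    Reference bases are checked against the sequence and duplicates rejected.
    """
    positions = [v.position for v in variants]
    dupes = {p for p in positions if positions.count(p) > 1}
    if dupes:
        raise SeqFormatError(f"duplicate variant position(s): {sorted(dupes)}")
    residues = list(seq.residues)
    for v in variants:
        idx = neg_to_index(v.position, seq)
        found = seq.base(idx)
        if found != v.ref:
            raise SeqFormatError(
                f"variant {v}: expected {v.ref} at position {v.position} "
                f"(index {idx}), found {found}"
            )
        residues[idx - 1] = v.alt
    return RnaSequence(
        id=seq.id if not variants else f"{seq.id}|{','.join(map(str, variants))}",
        residues="".join(residues),
        anchor_index=seq.anchor_index,
    )


def disruption_report(
    seq: RnaSequence,
    variants: Sequence[VariantSpec],
    target_helices: Sequence[Helix],
    folder: Folder | None = None,
) -> dict:
    """Refold the mutant and count, per wild-type helix, the pairs retained.

    ``target_helices`` are defined on the wild-type fold; ``folder`` must
    apply the identical plan/model used for the wild type (defaults to a
    plain MFE fold). A helix is *disrupted* when zero of its pairs survive.
    """
    folder = folder or _default_folder
    mutant = apply_variants(seq, variants)
    mutant_structure = folder(mutant)
    mutant_pairs = set(mutant_structure.pairs)
    helices = []
    for k, helix in enumerate(target_helices):
        retained = sorted(set(helix.pairs) & mutant_pairs)
        helices.append(
            {
                "helix": k,
                "span": helix.span,
                "pairs_total": helix.n_pairs,
                "pairs_retained": len(retained),
                "retained": retained,
                "disrupted": not retained,
            }
        )
    return {
        "variants": [str(v) for v in variants],
        "mutant_structure": mutant_structure,
        "helices": helices,
        "all_disrupted": all(h["disrupted"] for h in helices),
    }


def _candidate_positions(
    seq: RnaSequence, target_helices: Sequence[Helix]
) -> list[int]:
    pos = sorted({p for h in target_helices for p in h.positions()})
    return pos


def design_disruptors(
    seq: RnaSequence,
    target_helices: Sequence[Helix],
    max_subs: int,
    folder: Folder | None = None,
    candidate_positions: Sequence[int] | None = None,
    exhaustive_cap: int = 200_000,
) -> list[tuple[VariantSpec, ...]]:
    """Minimal substitution sets whose refolded mutant retains zero target pairs.

    Candidate positions default to the target helices' strand positions (a
    substitution elsewhere cannot remove a pair directly, only via competing
    structure). Subset sizes are searched smallest first; each size is
    exhaustive while the combination count stays below ``exhaustive_cap``,
    then greedy (seeded with the best smaller-size partial solutions). All
    minimal sets found at the smallest achieving size are returned, in
    deterministic sorted order. An empty list means no solution within
    ``max_subs``; an empty tuple inside the list means the targets are
    already unpaired in the refold.
    """
    if max_subs < 1:
        raise ValueError("max_subs must be >= 1")
    folder = folder or _default_folder
    positions = list(candidate_positions or _candidate_positions(seq, target_helices))
    target_pairs = {p for h in target_helices for p in h.pairs}

    def retained(variants: tuple[VariantSpec, ...]) -> int:
        structure = folder(apply_variants(seq, variants))
        return len(target_pairs & set(structure.pairs))

    def variants_at(pos_neg: int):
        ref = seq.base(neg_to_index(pos_neg, seq))
        return [VariantSpec(ref, pos_neg, alt) for alt in "ACGU" if alt != ref]

    neg_positions = [p - seq.anchor_index for p in positions]
    if retained(()) == 0:
        return [()]

    best_partial: tuple[int, tuple[VariantSpec, ...]] | None = None
    for size in range(1, max_subs + 1):
        n_combos = math.comb(len(neg_positions), size) * 3**size
        if n_combos <= exhaustive_cap:
            solutions = []
            for pos_set in itertools.combinations(neg_positions, size):
                for combo in itertools.product(*(variants_at(p) for p in pos_set)):
                    r = retained(combo)
                    if r == 0:
                        solutions.append(tuple(combo))
                    elif best_partial is None or r < best_partial[0]:
                        best_partial = (r, tuple(combo))
            if solutions:
                return sorted(solutions, key=lambda c: [(v.position, v.alt) for v in c])
        else:
            # greedy completion from the best partial solution seen so far
            seed = best_partial[1] if best_partial else ()
            current = seed
            while len(current) < size:
                best = None
                used = {v.position for v in current}
                for p in neg_positions:
                    if p in used:
                        continue
                    for v in variants_at(p):
                        cand = current + (v,)
                        r = retained(cand)
                        if best is None or r < best[0]:
                            best = (r, cand)
                if best is None:
                    break
                current = best[1]
                if best[0] == 0:
                    return [tuple(sorted(current, key=lambda v: (v.position, v.alt)))]
    return []
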