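"""Constrained minimum-free-energy secondary-structure prediction.

An exact Zuker-style dynamic program over a nearest-neighbor energy model,
with hard constraints: forbidden pairs, forced-unpaired positions, forced
pairs, and range blocks (no pair between two index ranges). The model is
driven entirely by a text parameter file (see ``data/nn_params.yaml``), so
alternative parameter sets can be swapped in.

Energy bookkeeping is integral (0.01 kcal/mol units); the public interface
speaks kcal/mol floats. ``evaluate_energy`` recomputes the energy of any
structure by loop decomposition, independently of the DP fill, and the two
paths are held together by the test-suite's enumeration oracle.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
import numpy as np
import yaml

from ._dp import INF, fill_tables
from .seqio import RnaSequence, SecondaryStructure

__all__ = [
    "EnergyModel",
    "ConstraintSet",
    "FoldResult",
    "FoldError",
    "ConstraintError",
    "default_model",
    "evaluate_energy",
    "mfe_fold",
    "parse_constraint_file",
]

PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_CODE = {p: k for k, p in enumerate(PAIR_ORDER)}


class FoldError(ValueError):
    """Raised for structures or inputs the energy model cannot score."""


class ConstraintError(FoldError):
    """Raised for invalid or unsatisfiable constraint sets."""


def pair_code(b1: str, b2: str) -> int:
    """Pair-type code for bases (5' base, 3' base); -1 if not an allowed pair."""
    return PAIR_CODE.get(b1 + b2, -1)


def _to_int(x: float) -> int:
    return int(round(100 * x))


@dataclass(frozen=True)
class EnergyModel:
    """Turner-style nearest-neighbor model, file-driven.

    ``stack[c1][c2]`` scores the stack of inner pair ``c2`` on closing pair
    ``c1`` (codes follow :data:`PAIR_ORDER`). Loop tables hold initiation
    penalties by loop size and are extrapolated logarithmically past their
    tabulated range with coefficient ``lxc``. All energies kcal/mol at 37 C.
    """

    stack: tuple[tuple[float, ...], ...]
    hairpin: tuple[float, ...]            # sizes min_hairpin..
    bulge: tuple[float, ...]              # sizes 1..
    internal: tuple[float, ...]           # total sizes 2..
    lxc: float = 1.08
    ninio_per_nt: float = 0.6
    ninio_max: float = 3.0
    ml_closing: float = 9.3
    ml_branch: float = -0.9
    ml_unpaired: float = 0.0
    terminal_nonGC: float = 0.5
    min_hairpin: int = 3
    max_loop: int = 30

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyModel":
        raw = yaml.safe_load(Path(path).read_text())
        order = raw.get("pair_order", list(PAIR_ORDER))
        if tuple(order) != PAIR_ORDER:
            raise FoldError(f"parameter file pair_order must be {list(PAIR_ORDER)}")
        stack = tuple(tuple(float(v) for v in raw["stack"][p]) for p in PAIR_ORDER)
        return cls(
            stack=stack,
            hairpin=tuple(float(v) for v in raw["hairpin"]),
            bulge=tuple(float(v) for v in raw["bulge"]),
            internal=tuple(float(v) for v in raw["internal"]),
            lxc=float(raw.get("lxc", 1.08)),
            ninio_per_nt=float(raw["ninio"]["per_nt"]),
            ninio_max=float(raw["ninio"]["max"]),
            ml_closing=float(raw["multiloop"]["closing"]),
            ml_branch=float(raw["multiloop"]["branch"]),
            ml_unpaired=float(raw["multiloop"]["unpaired"]),
            terminal_nonGC=float(raw.get("terminal_nonGC_penalty", 0.5)),
            min_hairpin=int(raw.get("min_hairpin", 3)),
            max_loop=int(raw.get("max_loop", 30)),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "min_hairpin": self.min_hairpin,
            "max_loop": self.max_loop,
            "terminal_nonGC_penalty": self.terminal_nonGC,
            "lxc": self.lxc,
            "ninio": {"per_nt": self.ninio_per_nt, "max": self.ninio_max},
            "multiloop": {
                "closing": self.ml_closing,
                "branch": self.ml_branch,
                "unpaired": self.ml_unpaired,
            },
            "pair_order": list(PAIR_ORDER),
            "stack": {p: list(self.stack[k]) for k, p in enumerate(PAIR_ORDER)},
            "hairpin": list(self.hairpin),
            "bulge": list(self.bulge),
            "internal": list(self.internal),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    # -- integer tables -----------------------------------------------------

    def _extrapolated(self, tab: tuple[float, ...], first_size: int, n: int) -> np.ndarray:
        """Integer table indexed by loop size 0..n (unused slots = INF)."""
        out = np.full(n + 2, INF, np.int64)
        last_size = first_size + len(tab) - 1
        for k, v in enumerate(tab):
            size = first_size + k
            if size <= n + 1:
                out[size] = _to_int(v)
        base = _to_int(tab[-1])
        for size in range(last_size + 1, n + 2):
            out[size] = base + _to_int(self.lxc * np.log(size / last_size))
        return out

    def int_tables(self, n: int) -> dict:
        """All integer tables needed by the DP kernel / evaluator, for length n."""
        return {
            "stack": np.array(
                [[_to_int(v) for v in row] for row in self.stack], np.int64
            ),
            "hp_tab": self._extrapolated(self.hairpin, self.min_hairpin, n),
            "bg_tab": self._extrapolated(self.bulge, 1, n),
            "il_tab": self._extrapolated(self.internal, 2, n),
            "ninio_m": np.int64(_to_int(self.ninio_per_nt)),
            "ninio_max": np.int64(_to_int(self.ninio_max)),
            "ml_a": np.int64(_to_int(self.ml_closing)),
            "ml_b": np.int64(_to_int(self.ml_branch)),
            "ml_c": np.int64(_to_int(self.ml_unpaired)),
            "term": np.array(
                [0, 0] + [_to_int(self.terminal_nonGC)] * 4, np.int64
            ),
        }

    # -- loop energies (integer, shared by evaluator and traceback) ---------

    def _two_loop_int(self, t: dict, c: int, c2: int, s1: int, s2: int) -> int:
        if s1 == 0 and s2 == 0:
            return int(t["stack"][c, c2])
        if s1 == 0 or s2 == 0:
            s = s1 + s2
            if s == 1:
                return int(t["bg_tab"][1] + t["stack"][c, c2])
            return int(t["bg_tab"][s] + t["term"][c] + t["term"][c2])
        pen = min(int(t["ninio_max"]), int(t["ninio_m"]) * abs(s1 - s2))
        return int(t["il_tab"][s1 + s2] + pen + t["term"][c] + t["term"][c2])


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    """The packaged parameter set (``data/nn_params.yaml``)."""
    ref = importlib.resources.files("reifold").joinpath("data/nn_params.yaml")
    with importlib.resources.as_file(ref) as path:
        return EnergyModel.from_yaml(path)


# ---------------------------------------------------------------------------
# Constraints

@dataclass(frozen=True)
class ConstraintSet:
    """Hard folding constraints.

    ``blocks`` are pairs of closed index ranges; all pairs with one partner in
    each range are forbidden (the emergence model's "no contact between an
    emerged segment and downstream sequence").
    """

    forbidden_pairs: frozenset[tuple[int, int]] = frozenset()
    forced_unpaired: frozenset[int] = frozenset()
    forced_pairs: frozenset[tuple[int, int]] = frozenset()
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "forbidden_pairs",
            frozenset(tuple(sorted(p)) for p in self.forbidden_pairs),
        )
        object.__setattr__(
            self,
            "forced_pairs",
            frozenset(tuple(sorted(p)) for p in self.forced_pairs),
        )
        object.__setattr__(self, "forced_unpaired", frozenset(self.forced_unpaired))
        fp = sorted(self.forced_pairs)
        seen: set[int] = set()
        for i, j in fp:
            if i in seen or j in seen:
                raise ConstraintError(f"position in forced pair ({i}, {j}) forced twice")
            seen.update((i, j))
            if (i, j) in self.forbidden_pairs:
                raise ConstraintError(f"pair ({i}, {j}) both forced and forbidden")
            if i in self.forced_unpaired or j in self.forced_unpaired:
                raise ConstraintError(
                    f"forced pair ({i}, {j}) conflicts with forced-unpaired position"
                )
        for a in range(len(fp)):
            i1, j1 = fp[a]
            for b in range(a + 1, len(fp)):
                i2, j2 = fp[b]
                if i1 < i2 < j1 < j2:
                    raise ConstraintError(
                        f"forced pairs ({i1}, {j1}) and ({i2}, {j2}) cross"
                    )

    def validate_for_length(self, n: int) -> None:
        for i, j in self.forbidden_pairs | self.forced_pairs:
            if not 1 <= i < j <= n:
                raise ConstraintError(f"pair ({i}, {j}) outside [1, {n}]")
        for p in self.forced_unpaired:
            if not 1 <= p <= n:
                raise ConstraintError(f"position {p} outside [1, {n}]")
        for (a1, b1), (a2, b2) in self.blocks:
            for a, b in ((a1, b1), (a2, b2)):
                if not 1 <= a <= b <= n:
                    raise ConstraintError(f"block range ({a}, {b}) outside [1, {n}]")

    def allows(self, i: int, j: int) -> bool:
        """Whether pair (i, j) survives this constraint set (model aside)."""
        i, j = min(i, j), max(i, j)
        if (i, j) in self.forbidden_pairs:
            return False
        if i in self.forced_unpaired or j in self.forced_unpaired:
            return False
        for (a1, b1), (a2, b2) in self.blocks:
            if (a1 <= i <= b1 and a2 <= j <= b2) or (a1 <= j <= b1 and a2 <= i <= b2):
                return False
        partner = {}
        for a, b in self.forced_pairs:
            partner[a] = b
            partner[b] = a
        if i in partner and partner[i] != j:
            return False
        if j in partner and partner[j] != i:
            return False
        return True

    def merged_with(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(
            forbidden_pairs=self.forbidden_pairs | other.forbidden_pairs,
            forced_unpaired=self.forced_unpaired | other.forced_unpaired,
            forced_pairs=self.forced_pairs | other.forced_pairs,
            blocks=self.blocks + other.blocks,
        )


def parse_constraint_file(path: str | Path) -> ConstraintSet:
    """Parse a constraint file: ``F i j`` forced, ``P i j`` prohibited,
    ``X i`` unpaired, ``B i1 i2 j1 j2`` block between ranges."""
    forced, forbidden, unpaired, blocks = set(), set(), set(), []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0] == "F" and len(tok) == 3:
                forced.add((int(tok[1]), int(tok[2])))
            elif tok[0] == "P" and len(tok) == 3:
                forbidden.add((int(tok[1]), int(tok[2])))
            elif tok[0] == "X" and len(tok) == 2:
                unpaired.add(int(tok[1]))
            elif tok[0] == "B" and len(tok) == 5:
                blocks.append(
                    ((int(tok[1]), int(tok[2])), (int(tok[3]), int(tok[4])))
                )
            else:
                raise ValueError
        except ValueError as exc:
            raise ConstraintError(f"{path}:{lineno}: malformed constraint {raw!r}") from exc
    return ConstraintSet(
        forbidden_pairs=frozenset(forbidden),
        forced_unpaired=frozenset(unpaired),
        forced_pairs=frozenset(forced),
        blocks=tuple(blocks),
    )


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    energy: float
    constraints_used: ConstraintSet


# ---------------------------------------------------------------------------
# Energy evaluation by loop decomposition

def _decompose(structure: SecondaryStructure):
    """Yield (closing pair or None, direct child pairs, unpaired count) per loop.

    ``None`` closing pair denotes the exterior loop.
    """
    table = structure.pair_table
    n = structure.length

    def children_of(lo: int, hi: int):
        kids, unpaired, p = [], 0, lo
        while p <= hi:
            q = table.get(p)
            if q is not None and q > p:
                kids.append((p, q))
                p = q + 1
            else:
                unpaired += 1
                p += 1
        return kids, unpaired

    kids, unpaired = children_of(1, n)
    yield None, kids, unpaired
    agenda = list(kids)
    while agenda:
        i, j = agenda.pop()
        kids, unpaired = children_of(i + 1, j - 1)
        yield (i, j), kids, unpaired
        agenda.extend(kids)


def evaluate_energy(
    seq: RnaSequence,
    structure: SecondaryStructure,
    model: EnergyModel | None = None,
) -> float:
    """Free energy (kcal/mol) of ``structure`` on ``seq`` by loop decomposition.

    The open chain scores 0. Raises :class:`FoldError` for pairs the model
    disallows or hairpin loops shorter than the model minimum.
    """
    model = model or default_model()
    if structure.length != len(seq):
        raise FoldError("structure length does not match sequence length")
    t = model.int_tables(len(seq))
    code: dict[tuple[int, int], int] = {}
    for i, j in structure.pairs:
        c = pair_code(seq.base(i), seq.base(j))
        if c < 0:
            raise FoldError(
                f"pair ({i}, {j}) = {seq.base(i)}-{seq.base(j)} is not an allowed pair"
            )
        if j - i - 1 < model.min_hairpin:
            raise FoldError(
                f"pair ({i}, {j}) closes a loop shorter than {model.min_hairpin} nt"
            )
        code[(i, j)] = c

    total = 0
    for closing, kids, unpaired in _decompose(structure):
        if closing is None:  # exterior loop: unpaired free, terminal penalties
            for k in kids:
                total += int(t["term"][code[k]])
            continue
        c = code[closing]
        if not kids:  # hairpin
            total += int(t["hp_tab"][unpaired] + t["term"][c])
        elif len(kids) == 1:  # stack / bulge / internal
            (k, l) = kids[0]
            i, j = closing
            total += model._two_loop_int(t, c, code[(k, l)], k - i - 1, j - l - 1)
        else:  # multiloop
            total += int(t["ml_a"]) + int(t["term"][c])
            for kid in kids:
                total += int(t["ml_b"]) + int(t["term"][code[kid]])
            total += int(t["ml_c"]) * unpaired
    return total / 100.0


# ---------------------------------------------------------------------------
# MFE fold

def _pair_matrix(
    seq: RnaSequence,
    constraints: ConstraintSet,
    model: EnergyModel,
    no_lonely_pairs: bool,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(seq)
    pcode = np.full((n + 2, n + 2), -1, np.int8)
    for i in range(1, n + 1):
        for j in range(i + model.min_hairpin + 1, n + 1):
            c = pair_code(seq.base(i), seq.base(j))
            if c >= 0 and constraints.allows(i, j):
                pcode[i, j] = c
    if no_lonely_pairs:
        # canonical-pair heuristic: keep (i, j) only if it could stack on a
        # neighboring pair (mirrors the reference tool's --noLP filter)
        base = pcode.copy()
        for i in range(1, n + 1):
            for j in range(i + model.min_hairpin + 1, n + 1):
                if base[i, j] < 0:
                    continue
                inner = base[i + 1, j - 1] >= 0
                outer = i > 1 and j < n and base[i - 1, j + 1] >= 0
                if not (inner or outer) and (i, j) not in constraints.forced_pairs:
                    pcode[i, j] = -1
    can_unpair = np.ones(n + 2, bool)
    for i, j in constraints.forced_pairs:
        can_unpair[i] = can_unpair[j] = False
    return pcode, can_unpair


def _traceback(n, V, WM, W, pcode, can_unpair, t, model: EnergyModel):
    min_hp, max_loop = model.min_hairpin, model.max_loop
    stack_t, term = t["stack"], t["term"]
    ml_a, ml_b, ml_c = int(t["ml_a"]), int(t["ml_b"]), int(t["ml_c"])
    pairs: list[tuple[int, int]] = []
    agenda: list[tuple] = [("W", n)]

    def unpairable_free(lo: int, hi: int) -> bool:
        return all(can_unpair[p] for p in range(lo, hi + 1))

    while agenda:
        task = agenda.pop()
        if task[0] == "W":
            j = task[1]
            while j > 0:
                if can_unpair[j] and W[j] == W[j - 1]:
                    j -= 1
                    continue
                hit = False
                for i in range(1, j - min_hp):
                    c = pcode[i, j]
                    if c >= 0 and V[i, j] < INF and W[i - 1] + V[i, j] + term[c] == W[j]:
                        pairs.append((i, j))
                        agenda.append(("V", i, j))
                        j = i - 1
                        hit = True
                        break
                if not hit:  # pragma: no cover - DP/traceback mismatch
                    raise AssertionError("exterior traceback failed")
        elif task[0] == "V":
            _, i, j = task
            c = pcode[i, j]
            e = V[i, j]
            if unpairable_free(i + 1, j - 1) and e == t["hp_tab"][j - i - 1] + term[c]:
                continue
            hit = False
            kmax = min(i + max_loop + 1, j - min_hp - 2)
            for k in range(i + 1, kmax + 1):
                s1 = k - i - 1
                if not unpairable_free(i + 1, k - 1):
                    break
                for l in range(j - 1, k + min_hp, -1):
                    s2 = j - l - 1
                    if s1 + s2 > max_loop:
                        break
                    c2 = pcode[k, l]
                    if c2 < 0 or V[k, l] >= INF:
                        continue
                    if not unpairable_free(l + 1, j - 1):
                        continue
                    le = model._two_loop_int(t, c, c2, s1, s2)
                    if V[k, l] + le == e:
                        pairs.append((k, l))
                        agenda.append(("V", k, l))
                        hit = True
                        break
                if hit:
                    break
            if hit:
                continue
            for k in range(i + 1, j - 1):
                if (
                    WM[i + 1, k] < INF
                    and WM[k + 1, j - 1] < INF
                    and WM[i + 1, k] + WM[k + 1, j - 1] + ml_a + term[c] == e
                ):
                    agenda.append(("WM", i + 1, k))
                    agenda.append(("WM", k + 1, j - 1))
                    hit = True
                    break
            if not hit:  # pragma: no cover
                raise AssertionError(f"V traceback failed at ({i}, {j})")
        else:  # WM
            _, i, j = task
            while True:
                e = WM[i, j]
                if can_unpair[i] and WM[i + 1, j] < INF and e == WM[i + 1, j] + ml_c:
                    i += 1
                    continue
                if can_unpair[j] and WM[i, j - 1] < INF and e == WM[i, j - 1] + ml_c:
                    j -= 1
                    continue
                c = pcode[i, j]
                if c >= 0 and V[i, j] < INF and e == V[i, j] + ml_b + term[c]:
                    pairs.append((i, j))
                    agenda.append(("V", i, j))
                    break
                hit = False
                for k in range(i, j):
                    if WM[i, k] < INF and WM[k + 1, j] < INF and e == WM[i, k] + WM[k + 1, j]:
                        agenda.append(("WM", i, k))
                        agenda.append(("WM", k + 1, j))
                        hit = True
                        break
                if not hit:  # pragma: no cover
                    raise AssertionError(f"WM traceback failed at ({i}, {j})")
                break
    return pairs


def mfe_fold(
    seq: RnaSequence,
    constraints: ConstraintSet | None = None,
    model: EnergyModel | None = None,
    no_lonely_pairs: bool = False,
) -> FoldResult:
    """Minimum-free-energy structure of ``seq`` under hard constraints.

    Exact DP; the returned structure is optimal among all nested structures
    satisfying the constraints, with a fixed deterministic traceback for
    reproducible tie-breaking. Raises :class:`ConstraintError` if the forced
    constraints cannot be satisfied.
    """
    model = model or default_model()
    constraints = constraints or ConstraintSet.empty()
    n = len(seq)
    constraints.validate_for_length(n)
    pcode, can_unpair = _pair_matrix(seq, constraints, model, no_lonely_pairs)
    for i, j in constraints.forced_pairs:
        if pcode[i, j] < 0:
            raise ConstraintError(
                f"forced pair ({i}, {j}) = {seq.base(i)}-{seq.base(j)} is not "
                "admissible under the model/constraints"
            )
    t = model.int_tables(n)
    if n <= model.min_hairpin:
        if constraints.forced_pairs:
            raise ConstraintError("sequence too short for any pair")
        structure = SecondaryStructure(n, frozenset(), 0.0, model.min_hairpin)
        return FoldResult(structure, 0.0, constraints)
    V, WM, W = fill_tables(
        n,
        pcode,
        can_unpair,
        t["stack"],
        t["hp_tab"],
        t["bg_tab"],
        t["il_tab"],
        t["ninio_m"],
        t["ninio_max"],
        t["ml_a"],
        t["ml_b"],
        t["ml_c"],
        t["term"],
        np.int64(model.min_hairpin),
        np.int64(model.max_loop),
    )
    if W[n] >= INF:
        raise ConstraintError("constraints unsatisfiable: no valid structure exists")
    pairs = _traceback(n, V, WM, W, pcode, can_unpair, t, model)
    energy = float(W[n]) / 100.0
    structure = SecondaryStructure(n, frozenset(pairs), energy, model.min_hairpin)
    return FoldResult(structure, energy, constraints)
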