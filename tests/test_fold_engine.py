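"""Constrained MFE folding: energy evaluation, DP optimality, constraints."""

import numpy as np
import pytest

from reifold.fold_engine import (
    ConstraintSet,
    ConstraintError,
    EnergyModel,
    FoldError,
    default_model,
    evaluate_energy,
    mfe_fold,
    parse_constraint_file,
)
from reifold.seqio import RnaSequence, SecondaryStructure

from oracles import oracle_mfe, random_sequence


class TestEvaluateEnergy:
    def test_open_chain_scores_zero(self, model):
        seq = RnaSequence("x", "ACGUACGUAC")
        s = SecondaryStructure(10, frozenset())
        assert evaluate_energy(seq, s, model) == 0.0

    def test_hand_sum_of_parameter_entries(self, model):
        # three stacked GC pairs closing a 4-nt hairpin: two GC-on-GC stack
        # terms plus the size-4 hairpin initiation, straight from the tables
        seq = RnaSequence("x", "GGGAAAACCC")
        s = SecondaryStructure(10, frozenset({(1, 10), (2, 9), (3, 8)}))
        gc = 1  # pair code of GC in the documented pair order
        expected = 2 * model.stack[gc][gc] + model.hairpin[1]  # size-4 entry
        assert evaluate_energy(seq, s, model) == pytest.approx(expected, abs=1e-9)

    def test_terminal_penalty_on_au_closed_hairpin(self, model):
        seq = RnaSequence("x", "AGGAAAACCU")
        s = SecondaryStructure(10, frozenset({(1, 10), (2, 9), (3, 8)}))
        # closing pair AU pays the non-GC term once (helix end at the exterior)
        expected = (
            model.stack[4][1]  # AU on GC
            + model.stack[1][1]  # GC on GC
            + model.hairpin[1]
            + model.terminal_nonGC
        )
        assert evaluate_energy(seq, s, model) == pytest.approx(expected, abs=1e-9)

    def test_disallowed_pair_rejected(self, model):
        seq = RnaSequence("x", "AGGAAAACCG")
        s = SecondaryStructure(10, frozenset({(1, 10)}))  # A-G
        with pytest.raises(FoldError):
            evaluate_energy(seq, s, model)

    def test_short_hairpin_rejected_upstream(self):
        with pytest.raises(Exception):
            SecondaryStructure(4, frozenset({(1, 3)}))


class TestMfeFold:
    def test_poly_a_is_open(self, model):
        res = mfe_fold(RnaSequence("x", "A" * 10), model=model)
        assert res.structure.pairs == frozenset()
        assert res.energy == 0.0

    def test_canonical_hairpin(self, model):
        res = mfe_fold(RnaSequence("x", "GGGAAAACCC"), model=model)
        assert res.structure.dot_bracket == "(((....)))"
        e, pairs = oracle_mfe(RnaSequence("x", "GGGAAAACCC"), model)
        assert res.energy == pytest.approx(e, abs=1e-9)

    def test_matches_enumeration_oracle(self, model):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = random_sequence(rng, int(rng.integers(8, 21)))
            res = mfe_fold(seq, model=model)
            e, _ = oracle_mfe(seq, model)
            assert res.energy == pytest.approx(e, abs=1e-9), seq.residues

    def test_energy_equals_its_own_evaluation(self, model):
        rng = np.random.default_rng(6)
        for _ in range(25):
            seq = random_sequence(rng, int(rng.integers(10, 40)))
            res = mfe_fold(seq, model=model)
            assert evaluate_energy(seq, res.structure, model) == pytest.approx(
                res.energy, abs=1e-6
            )

    def test_deterministic(self, model):
        seq = random_sequence(np.random.default_rng(9), 50)
        a = mfe_fold(seq, model=model)
        b = mfe_fold(seq, model=model)
        assert a.structure.pairs == b.structure.pairs

    def test_no_lonely_pairs_flag(self, model):
        rng = np.random.default_rng(12)
        for _ in range(10):
            seq = random_sequence(rng, 40)
            res = mfe_fold(seq, model=model, no_lonely_pairs=True)
            base = mfe_fold(seq, model=model)
            assert res.energy >= base.energy - 1e-9  # restriction never helps


class TestConstraints:
    def _random_constraints(self, rng, n):
        forb = set()
        for _ in range(int(rng.integers(0, 4))):
            i, j = sorted(rng.integers(1, n + 1, 2).tolist())
            if i < j:
                forb.add((i, j))
        unp = {int(x) for x in rng.integers(1, n + 1, int(rng.integers(0, 3)))}
        blocks = ()
        if n >= 8 and rng.random() < 0.5:
            mid = int(rng.integers(3, n - 3))
            blocks = (((1, mid), (mid + 1, n)),)
        return ConstraintSet(
            forbidden_pairs=frozenset(forb),
            forced_unpaired=frozenset(unp),
            blocks=blocks,
        )

    def test_soundness_and_oracle_under_constraints(self, model):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(10, 19))
            seq = random_sequence(rng, n)
            cons = self._random_constraints(rng, n)
            res = mfe_fold(seq, cons, model)
            for i, j in res.structure.pairs:
                assert cons.allows(i, j)
            e, _ = oracle_mfe(seq, model, cons)
            assert res.energy == pytest.approx(e, abs=1e-9)

    def test_adding_constraints_never_improves_mfe(self, model):
        rng = np.random.default_rng(22)
        for _ in range(20):
            n = int(rng.integers(12, 25))
            seq = random_sequence(rng, n)
            base = mfe_fold(seq, model=model)
            cons = self._random_constraints(rng, n)
            res = mfe_fold(seq, cons, model)
            assert res.energy >= base.energy - 1e-9

    def test_forced_pair_appears(self, model):
        seq = RnaSequence("x", "GCAAAAAAGC")
        cons = ConstraintSet(forced_pairs=frozenset({(1, 10)}))
        res = mfe_fold(seq, cons, model)
        assert (1, 10) in res.structure.pairs
        assert res.energy >= mfe_fold(seq, model=model).energy - 1e-9

    def test_unsatisfiable_forced_pair_rejected(self, model):
        seq = RnaSequence("x", "AAAAAAAAAA")
        cons = ConstraintSet(forced_pairs=frozenset({(1, 10)}))  # A-A
        with pytest.raises(ConstraintError):
            mfe_fold(seq, cons, model)

    def test_crossing_forced_pairs_rejected(self):
        with pytest.raises(ConstraintError):
            ConstraintSet(forced_pairs=frozenset({(1, 10), (5, 15)}))

    def test_block_forbids_cross_pairs(self, model):
        rng = np.random.default_rng(23)
        for _ in range(10):
            seq = random_sequence(rng, 30)
            cons = ConstraintSet(blocks=(((1, 15), (16, 30)),))
            res = mfe_fold(seq, cons, model)
            for i, j in res.structure.pairs:
                assert not (i <= 15 < j)

    def test_constraint_file_parsing(self, tmp_path, model):
        p = tmp_path / "c.txt"
        p.write_text("# test\nF 1 10\nP 2 9\nX 5\nB 1 3 8 10\n")
        cons = parse_constraint_file(p)
        assert (1, 10) in cons.forced_pairs
        assert (2, 9) in cons.forbidden_pairs
        assert 5 in cons.forced_unpaired
        assert cons.blocks == (((1, 3), (8, 10)),)
        with pytest.raises(ConstraintError):
            bad = tmp_path / "bad.txt"
            bad.write_text("Z 1 2\n")
            parse_constraint_file(bad)


class TestParameterFile:
    def test_yaml_roundtrip(self, tmp_path, model):
        p = tmp_path / "params.yaml"
        model.to_yaml(p)
        back = EnergyModel.from_yaml(p)
        assert back == model

    def test_swapping_parameters_changes_the_fold_energy(self, tmp_path, model):
        doubled = EnergyModel(
            stack=tuple(tuple(2 * v for v in row) for row in model.stack),
            hairpin=model.hairpin,
            bulge=model.bulge,
            internal=model.internal,
        )
        seq = RnaSequence("x", "GGGAAAACCC")
        assert mfe_fold(seq, model=doubled).energy < mfe_fold(seq, model=model).energy
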