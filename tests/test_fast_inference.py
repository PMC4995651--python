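"""Move catalogue, class machinery and the efficient p-value algorithm."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from causalq import (
    ClassKey,
    InfeasibleTableError,
    MarginSet,
    StatisticKind,
    ThresholdPolicy,
    enumerate_tables,
    generate_minimal_moves,
    generate_transpositions,
    max_dvalue_reference,
    max_probability_table,
    min_score_table,
    principal_moves,
    pvalue_exact,
    pvalue_fast,
    score,
    score_distribution,
    score_probability,
    score_steps,
)
from causalq.tables import EmptyClassError, log_dvalue, max_score_table

from conftest import kind_for, random_margins

CS, ES, QS = (StatisticKind.CORRECTNESS, StatisticKind.ENRICHMENT,
              StatisticKind.QUATERNARY)

TAU_EXAMPLE = (-1, 0, 1, 0, 1, -1, 0, 0, 0)   # (q+,+,q-)(q-,0,q+)
TAU1 = (-1, 0, 0, 1, 0, 0, 1, -1, 0)          # (q0,-,q+)(q+,+,q0)
TAU2 = (-1, 0, -2, 1, 0, 2, 3, -1, -2)        # repeated-transposition product
SIGMA1 = (0, 0, -1, 1, -1, 1, 1, -1, 0)


class TestTranspositions:
    def test_counts(self):
        assert len(generate_transpositions("3x3")) == 18
        assert len(generate_transpositions("4x3")) == 36

    @pytest.mark.parametrize("shape", ["3x3", "4x3"])
    def test_margin_preservation(self, shape):
        for mv in generate_transpositions(shape):
            d = mv.cell_deltas
            rows = ["p", "m", "0"] if shape == "3x3" else ["p", "m", "r", "0"]
            for r in rows:
                assert sum(d[f"n_{r}{c}"] for c in "pm0") == 0
            for c in "pm0":
                assert sum(d[f"n_{r}{c}"] for r in rows) == 0

    def test_contains_printed_example_matrix(self):
        deltas = {mv.deltas for mv in generate_transpositions("3x3")}
        assert TAU_EXAMPLE in deltas


class TestMinimalMoves:
    def test_includes_tau1(self):
        deltas = {mv.deltas for mv in generate_minimal_moves("3x3")}
        assert TAU1 in deltas

    def test_excludes_tau2_and_identity(self):
        deltas = {mv.deltas for mv in generate_minimal_moves("3x3")}
        assert TAU2 not in deltas
        assert (0,) * 9 not in deltas

    def test_decompositions_are_witnesses(self):
        taus = {t.deltas: t for t in generate_transpositions("3x3")}
        for mv in generate_minimal_moves("3x3"):
            total = [0] * 9
            seen = set()
            for pair in mv.decomposition:
                assert pair not in seen  # distinct transpositions
                seen.add(pair)
                tau = next(t for t in generate_transpositions("3x3")
                           if t.decomposition == (pair,))
                total = [a + b for a, b in zip(total, tau.deltas)]
            assert tuple(total) == mv.deltas

    def test_move_roundtrip_preserves_probability(self, rng):
        moves = generate_minimal_moves("3x3")
        for _ in range(5):
            m = random_margins(rng, mixed=False)
            for t in list(enumerate_tables(m))[:10]:
                for mv in moves[:40]:
                    try:
                        t2 = mv.apply(t)
                    except InfeasibleTableError:
                        continue
                    assert (-mv).apply(t2) == t


class TestPrincipalMoves:
    def test_inner_family_moves_are_sigma1_pair(self):
        inner = principal_moves("3x3", "inner")
        assert {mv.deltas for mv in inner} == {
            SIGMA1, tuple(-d for d in SIGMA1)}

    def test_score_steps_are_1_2_4(self):
        assert score_steps("3x3") == (1, 2, 4)
        assert score_steps("4x3") == (1, 2, 4)

    def test_no_principal_move_for_unattainable_step(self):
        assert principal_moves("3x3", "score +3") == ()

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_score_increasing_signatures(self, k):
        moves = principal_moves("3x3", f"score +{k}")
        assert moves
        assert all(mv.delta_score() == k for mv in moves)

    def test_decrease_n_pp_signature_and_applicability(self, rng):
        moves = principal_moves("3x3", "decrease n_pp")
        assert moves
        for mv in moves:
            assert mv.delta_score() == 0 and mv.delta("n_pp") == -1
        m = random_margins(rng, mixed=False)
        for t in enumerate_tables(m):
            for mv in moves:
                try:
                    t2 = mv.apply(t)
                except InfeasibleTableError:
                    # a recorded constraint cell was too small
                    assert any(getattr(t, c) + mv.delta(c) < 0
                               for c in mv.constraints)
                    continue
                assert t2.n_pp == t.n_pp - 1
                assert score(t2, CS) == score(t, CS)

    def test_unknown_transition_rejected(self):
        with pytest.raises(ValueError, match="transition"):
            principal_moves("3x3", "sideways")

    @pytest.mark.parametrize("shape,coord", [
        ("4x3", "n_rp"), ("4x3", "n_rm"), ("4x3", "n_mm")])
    def test_4x3_coordinate_transitions_exist(self, shape, coord):
        moves = principal_moves(shape, f"decrease {coord}")
        assert moves
        for mv in moves:
            assert mv.delta_score() == 0
            assert mv.delta(coord) < 0


class TestReachability:
    """Iterated principal moves visit every nonempty score class."""

    @pytest.mark.parametrize("mixed", [False, True])
    def test_all_score_classes_reached(self, rng, mixed):
        for _ in range(8):
            m = random_margins(rng, n_max=10, mixed=mixed)
            kind = kind_for(m)
            shape = m.shape
            moves = []
            for k in score_steps(shape):
                moves += list(principal_moves(shape, f"score +{k}"))
            coords = (("n_pp", "n_mm") if shape == "3x3"
                      else ("n_pp", "n_mm", "n_rp", "n_rm"))
            for c in coords:
                moves += list(principal_moves(shape, f"decrease {c}"))
                moves += list(principal_moves(shape, f"increase {c}"))
            moves += list(principal_moves(shape, "inner"))
            start = min_score_table(m, kind)[0]
            seen = {start.as_vector(): start}
            frontier = [start]
            while frontier:
                t = frontier.pop()
                for mv in moves:
                    try:
                        t2 = mv.apply(t)
                    except InfeasibleTableError:
                        continue
                    key = t2.as_vector()
                    if key not in seen:
                        seen[key] = t2
                        frontier.append(t2)
            reached = {score(t, kind) for t in seen.values()}
            expected = set(score_distribution(m, kind).support)
            assert expected <= reached


class TestMaxProbabilityTable:
    def test_min_score_class_is_its_unique_table(self, rng):
        for _ in range(10):
            m = random_margins(rng, mixed=False)
            (tmin,) = min_score_table(m, CS)
            got = max_probability_table(
                m, CS, ClassKey(CS, (score(tmin, CS),)))
            assert got == tmin

    def test_single_table_margins(self):
        m = MarginSet(0, 0, 0, 4, 0, 0, 4)
        got = max_probability_table(m, CS, ClassKey(CS, (0,)))
        assert got.n_00 == 4

    def test_empty_class_signals(self):
        m = MarginSet(0, 0, 0, 4, 0, 0, 4)
        with pytest.raises(EmptyClassError):
            max_probability_table(m, CS, ClassKey(CS, (1,)))

    def test_matches_bruteforce_class_maximum(self, rng):
        for _ in range(8):
            m = random_margins(rng, n_max=10)
            kind = kind_for(m)
            best: dict[tuple, float] = {}
            for t in enumerate_tables(m):
                for depth in (1, 2, 3):
                    key = (score(t, kind), t.n_pp, t.n_mm)[:depth]
                    best[key] = max(best.get(key, -math.inf), log_dvalue(t))
            for key, target in best.items():
                got = max_probability_table(m, kind, ClassKey(kind, key))
                assert log_dvalue(got) == pytest.approx(target, abs=1e-9)


class TestScoreProbability:
    def test_single_table_margins(self):
        m = MarginSet(0, 0, 0, 4, 0, 0, 4)
        assert score_probability(m, CS, 0) == pytest.approx(1.0)
        assert score_probability(m, CS, 1) == 0.0

    def test_two_table_margins(self):
        m = MarginSet(1, 1, 0, 0, 1, 1, 0)
        assert score_probability(m, CS, 2,
                                 ThresholdPolicy.exact()) == pytest.approx(0.5)

    def test_matches_bruteforce_pmf(self, rng):
        for _ in range(20):
            m = random_margins(rng)
            kind = kind_for(m)
            dist = score_distribution(m, kind)
            for s, p in dist.pmf.items():
                got = score_probability(m, kind, s, ThresholdPolicy.exact())
                assert got == pytest.approx(p, rel=1e-12, abs=1e-15)


class TestPvalueFast:
    def test_boundaries(self):
        m = MarginSet(1, 1, 0, 0, 1, 1, 0)
        assert pvalue_fast(m, CS, -2) == 1.0
        assert pvalue_fast(m, CS, 3) == 0.0

    def test_max_score_pvalue_is_unique_table_probability(self, rng):
        from causalq.tables import table_log_probability
        for _ in range(5):
            m = random_margins(rng, mixed=False)
            t = max_score_table(m, CS)
            assert pvalue_fast(m, CS, score(t, CS),
                               ThresholdPolicy.exact()) == pytest.approx(
                math.exp(table_log_probability(t)), rel=1e-12)

    def test_exact_mode_equals_bruteforce(self, rng):
        for _ in range(30):
            m = random_margins(rng)
            kind = kind_for(m)
            for s in score_distribution(m, kind).support:
                pe = pvalue_exact(m, kind, s)
                pf = pvalue_fast(m, kind, s, ThresholdPolicy.exact())
                assert pf == pytest.approx(pe, rel=1e-12, abs=1e-300)

    def test_matches_bruteforce_at_moderate_scale(self):
        # margins large enough that the vectorised class sweep batches
        # and prunes, but still enumerable
        cases = [
            MarginSet(12, 10, 0, 30, 14, 11, 27),
            MarginSet(8, 6, 9, 30, 16, 12, 25),
        ]
        for m in cases:
            kind = QS if m.q_r else CS
            dist = score_distribution(m, kind, n_cap=60)
            for s in dist.support:
                pe = dist.pvalue(s)
                assert pvalue_fast(m, kind, s, ThresholdPolicy.exact()) \
                    == pytest.approx(pe, rel=1e-11)
                assert pvalue_fast(m, kind, s, ThresholdPolicy(1e-16)) \
                    == pytest.approx(pe, rel=1e-8)

    def test_default_threshold_accuracy(self, rng):
        for _ in range(20):
            m = random_margins(rng)
            kind = kind_for(m)
            for s in score_distribution(m, kind).support:
                pe = pvalue_exact(m, kind, s)
                pf = pvalue_fast(m, kind, s, ThresholdPolicy(1e-16))
                assert pf == pytest.approx(pe, rel=1e-8)

    def test_enrichment_equals_fisher_tail(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            qr = int(rng.integers(0, n + 1))
            nde = int(rng.integers(0, n + 1))
            npl = int(rng.integers(0, nde + 1))
            m = MarginSet(0, 0, qr, n - qr, npl, nde - npl, n - nde)
            for s in range(0, min(qr, nde) + 2):
                expect = float(hypergeom.sf(s - 1, n, nde, qr))
                got = pvalue_fast(m, ES, s, ThresholdPolicy.exact())
                assert got == pytest.approx(expect, rel=1e-10, abs=1e-14)

    def test_limit_reductions(self, rng):
        for _ in range(10):
            m = random_margins(rng, mixed=False)
            for s in score_distribution(m, CS).support:
                assert pvalue_fast(m, QS, s) == pvalue_fast(m, CS, s)
        for _ in range(10):
            n = int(rng.integers(1, 12))
            qr = int(rng.integers(0, n + 1))
            c2 = sorted(int(v) for v in rng.integers(0, n + 1, size=2))
            m = MarginSet(0, 0, qr, n - qr, c2[0], c2[1] - c2[0], n - c2[1])
            for s in range(0, qr + 1):
                assert pvalue_fast(m, QS, s) == pvalue_fast(m, ES, s)


class TestMaxDvalueReference:
    def test_single_table_margins(self):
        m = MarginSet(0, 0, 0, 6, 0, 0, 6)
        t = max_score_table(m, CS)
        assert max_dvalue_reference(m) == pytest.approx(log_dvalue(t))

    def test_dominates_every_enumerated_dvalue(self):
        m = MarginSet(15, 15, 0, 15, 15, 15, 15)
        ref = max_dvalue_reference(m)
        worst = max(log_dvalue(t) for t in enumerate_tables(m))
        assert ref >= worst - 1e-9

    def test_policy_cutoff(self):
        m = MarginSet(15, 15, 0, 15, 15, 15, 15)
        pol = ThresholdPolicy(1e-16)
        assert pol.log_cutoff(m) == pytest.approx(
            max_dvalue_reference(m) + math.log(1e-16))
        assert ThresholdPolicy.exact().log_cutoff(m) == -math.inf
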