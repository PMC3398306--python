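import math

import numpy as np
import pytest

from oracle_prw import oracle_log_score, oracle_log_scores, ranking_agrees
from targetfish import AssociationTable, PRWModel, log_kernel
from targetfish.prw import LOG_SQRT_2PI, scores_from_disagreement

from conftest import make_toy_table


class TestLogKernel:
    def test_closed_form_at_origin(self):
        assert log_kernel(0, 1.0, 1) == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    @pytest.mark.parametrize("h", [2.0**-3, 0.5, 1.0, 4.0])
    def test_successive_m_log_ratio(self, h):
        """Each extra disagreeing bit costs exactly 1/(2 h^2) in log space."""
        step = log_kernel(3, h, 16) - log_kernel(2, h, 16)
        assert step == pytest.approx(-1.0 / (2 * h * h), abs=1e-12)

    def test_maximized_at_zero_disagreement(self):
        vals = [log_kernel(m, 0.7, 8) for m in range(9)]
        assert vals[0] == max(vals) and vals == sorted(vals, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            log_kernel(0, 0.0, 4)
        with pytest.raises(ValueError):
            log_kernel(5, 1.0, 4)


class TestClassLogScore:
    def test_single_member_closed_form(self):
        """One class, one member equal to the query: ln score = -d*ln(sqrt(2pi))."""
        x = np.array([1, 0], dtype=np.uint8)
        table = AssociationTable(instances=(("c0", "t0"),), fingerprints={"c0": x})
        model = PRWModel(table, h=1.0)
        assert model.class_log_score(x, "t0") == pytest.approx(-2 * LOG_SQRT_2PI, abs=1e-12)

    def test_duplicating_members_adds_log2(self, rng):
        """N_a cancels between prior and likelihood, so doubling a class's
        membership (same vectors twice) raises its log score by ln 2."""
        d = 8
        fps = {f"c{i}": rng.integers(0, 2, d).astype(np.uint8) for i in range(4)}
        fps.update({f"e{i}": fps[f"c{i}"] for i in range(2)})
        base = AssociationTable(
            instances=(("c0", "a"), ("c1", "a"), ("c2", "b"), ("c3", "b")), fingerprints=fps
        )
        doubled = AssociationTable(
            instances=base.instances + (("e0", "a"), ("e1", "a")), fingerprints=fps
        )
        x = rng.integers(0, 2, d).astype(np.uint8)
        # same N in both tables so only the kernel sum changes
        s_base = PRWModel(base, h=0.5).class_log_score(x, "a") + math.log(base.N)
        s_doub = PRWModel(doubled, h=0.5).class_log_score(x, "a") + math.log(doubled.N)
        assert s_doub - s_base == pytest.approx(math.log(2), abs=1e-9)

    def test_matches_plain_arithmetic_oracle(self, rng):
        """Log-space result equals literal evaluation where no underflow occurs."""
        table = make_toy_table(rng, d=8, n_classes=2, members=5)
        model = PRWModel(table, h=0.5)
        x = rng.integers(0, 2, 8).astype(np.uint8)
        for tid in table.class_ids:
            members = [
                table.fingerprints[c].tolist() for c, t in table.instances if t == tid
            ]
            expected = oracle_log_score(x.tolist(), members, 0.5, 8, table.N)
            assert model.class_log_score(x, tid) == pytest.approx(expected, rel=1e-9)

    def test_unknown_class_errors(self, toy_table):
        model = PRWModel(toy_table, h=1.0)
        with pytest.raises(KeyError):
            model.class_log_score(np.zeros(8, np.uint8), "nope")


class TestRanking:
    def test_single_class_rank_one(self):
        x = np.ones(4, dtype=np.uint8)
        table = AssociationTable(instances=(("c0", "only"),), fingerprints={"c0": x})
        ranking = PRWModel(table, h=1.0).rank_classes(x)
        assert ranking.entries[0].class_id == "only" and ranking.entries[0].rank == 1

    def test_identical_classes_tie_by_class_id(self, rng):
        fp = rng.integers(0, 2, 8).astype(np.uint8)
        fps = {"c0": fp, "c1": fp.copy()}
        table = AssociationTable(
            instances=(("c0", "zz"), ("c1", "aa")), fingerprints=fps
        )
        ranking = PRWModel(table, h=1.0).rank_classes(rng.integers(0, 2, 8).astype(np.uint8))
        assert [e.class_id for e in ranking.entries] == ["aa", "zz"]

    def test_ranks_contiguous_and_scores_sorted(self, toy_table, rng):
        ranking = PRWModel(toy_table, h=0.25).rank_classes(
            rng.integers(0, 2, 8).astype(np.uint8)
        )
        ranks = [e.rank for e in ranking.entries]
        scores = [e.log_score for e in ranking.entries]
        assert ranks == list(range(1, toy_table.M + 1))
        assert scores == sorted(scores, reverse=True)

    def test_large_h_limit_orders_by_class_size(self, rng):
        """As h grows the kernel flattens and the prior N_a dominates."""
        table = make_toy_table(rng, d=16, n_classes=4, members=3)  # sizes 3,4,5,6
        sizes = table.class_sizes
        x = rng.integers(0, 2, 16).astype(np.uint8)
        ranking = PRWModel(table, h=2.0**15).rank_classes(x)
        observed = [e.class_id for e in ranking.entries]
        assert observed == sorted(sizes, key=lambda t: (-sizes[t], t))

    def test_small_h_exact_duplicate_dominates(self, rng):
        table = make_toy_table(rng, d=16, n_classes=4, members=3)
        target_cid, target_tid = table.instances[-1]
        x = table.fingerprints[target_cid]
        ranking = PRWModel(table, h=2.0**-15).rank_classes(x)
        assert ranking.entries[0].class_id == target_tid

    def test_monotone_in_disagreement_single_member(self):
        """A lone class's score never increases as its member drifts from x."""
        x = np.zeros(16, dtype=np.uint8)
        scores = []
        for m in range(0, 17, 4):
            member = x.copy()
            member[:m] = 1
            table = AssociationTable(instances=(("c", "t"),), fingerprints={"c": member})
            scores.append(PRWModel(table, h=0.5).class_log_score(x, "t"))
        assert scores == sorted(scores, reverse=True)

    def test_permuting_instances_bit_identical(self, rng):
        table = make_toy_table(rng, d=12, n_classes=3, members=4)
        shuffled = AssociationTable(
            instances=tuple(reversed(table.instances)), fingerprints=table.fingerprints
        )
        x = rng.integers(0, 2, 12).astype(np.uint8)
        a = PRWModel(table, h=0.3).score_rows(x)
        b = PRWModel(shuffled, h=0.3).score_rows(x)
        assert np.array_equal(a, b)

    def test_dimension_mismatch_errors(self, toy_table):
        with pytest.raises(ValueError, match="dimension"):
            PRWModel(toy_table, h=1.0).rank_classes(np.zeros(9, np.uint8))


class TestTopK:
    def test_k_at_least_m_returns_all(self, toy_table, rng):
        model = PRWModel(toy_table, h=1.0)
        x = rng.integers(0, 2, 8).astype(np.uint8)
        assert set(model.predict_top_k(x, k=100)) == set(toy_table.class_ids)

    def test_k_one_is_top_ranked(self, toy_table, rng):
        model = PRWModel(toy_table, h=1.0)
        x = rng.integers(0, 2, 8).astype(np.uint8)
        assert model.predict_top_k(x, k=1) == [model.rank_classes(x).entries[0].class_id]

    def test_prefix_of_full_ranking(self, rng):
        table = make_toy_table(rng, d=10, n_classes=5, members=3)
        model = PRWModel(table, h=0.5)
        x = rng.integers(0, 2, 10).astype(np.uint8)
        full = [e.class_id for e in model.rank_classes(x).entries]
        assert model.predict_top_k(x, k=3) == full[:3]


def test_prior_cancellation_identity(rng):
    """Ranking by the full Bayes product equals ranking by the bare
    log-sum-exp of kernel exponents: the class-independent constant and the
    cancelling N_a never affect order."""
    table = make_toy_table(rng, d=12, n_classes=5, members=4)
    model = PRWModel(table, h=0.5)
    x = rng.integers(0, 2, (6, 12)).astype(np.uint8)
    full = model.score_rows(x)
    m = model.disagreements(x)
    bare = np.empty_like(full)
    from scipy.special import logsumexp

    for j, idx in enumerate(model._groups):
        bare[:, j] = logsumexp(-m[:, idx] / (2 * 0.5**2), axis=1)
    assert np.array_equal(np.argsort(-full, axis=1, kind="stable"),
                          np.argsort(-bare, axis=1, kind="stable"))


def test_oracle_equivalence_on_seeded_toys():
    """Log-space rankings agree with a literal extended-precision evaluation
    of the prior x kernel-sum product on many random small problems, including
    bandwidths where direct double-precision evaluation would underflow.
    Score gaps below double-precision resolution count as ties."""
    rng = np.random.default_rng(2024)
    h_values = [2.0**-15, 2.0**-3, 0.5, 2.0, 8.0]
    for trial in range(20):
        d = int(rng.integers(4, 17))
        n_classes = int(rng.integers(2, 11))
        members = int(rng.integers(2, 5))
        table = make_toy_table(rng, d=d, n_classes=n_classes, members=members)
        assert table.N <= 100
        by_class = {
            tid: [table.fingerprints[c].tolist() for c, t in table.instances if t == tid]
            for tid in table.class_ids
        }
        x = rng.integers(0, 2, d).astype(np.uint8)
        h = h_values[trial % len(h_values)]
        fast = [
            e.class_id for e in PRWModel(table, h=h).rank_classes(x).entries
        ]
        exact = oracle_log_scores(x.tolist(), by_class, h, d, table.N)
        assert ranking_agrees(fast, exact)
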