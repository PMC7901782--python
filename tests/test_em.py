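"""EM quantification: compatibility weighting, naive baseline, EM fixed
points vs a brute-force oracle, cutoff and taxonomy collapse."""

import numpy as np
import pandas as pd
import pytest

from aquamicrobe.em import (
    QuantParams,
    apply_cutoff,
    build_compatibility,
    collapse_taxonomy,
    em_quantify,
    naive_count,
)
from aquamicrobe.io_formats import AlignmentRecord, TaxonomyEntry


def aln(read, ref, identity, block=1000, score=None):
    return AlignmentRecord(read, ref, block, int(round(identity * block)), block, 0,
                           align_score=score)


def dense_em_oracle(w, tol=1e-12, iters=100_000):
    """Literal dense fixed-point iteration, independent of the sparse path."""
    n, m = w.shape
    theta = np.full(m, 1.0 / m)
    active = w.sum(axis=0) > 0
    theta = np.where(active, 1.0 / active.sum(), 0.0)
    for _ in range(iters):
        gamma = theta * w
        gamma /= gamma.sum(axis=1, keepdims=True)
        new = gamma.sum(axis=0) / n
        if np.abs(new - theta).max() < tol:
            theta = new
            break
        theta = new
    return theta


def matrix_from_dense(w, refs=None):
    refs = refs or [chr(ord("A") + j) for j in range(w.shape[1])]
    alns = []
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if w[i, j] > 0:
                alns.append(aln(f"r{i}", refs[j], w[i, j]))
    return build_compatibility(alns, QuantParams())


class TestCompatibility:
    def test_single_alignment_weight_one(self):
        m = build_compatibility([aln("r1", "A", 0.9)])
        assert m.weights.toarray().tolist() == [[1.0]]

    def test_equal_identities_split_evenly(self):
        m = build_compatibility([aln("r1", "A", 0.9), aln("r1", "B", 0.9)])
        np.testing.assert_allclose(m.weights.toarray()[0], [0.5, 0.5])

    def test_unequal_identities_proportional(self):
        m = build_compatibility([aln("r1", "A", 0.9), aln("r1", "B", 0.3)])
        np.testing.assert_allclose(m.weights.toarray()[0], [0.75, 0.25])

    def test_as_score_preferred_over_identity(self):
        m = build_compatibility(
            [aln("r1", "A", 0.5, score=300), aln("r1", "B", 0.9, score=100)]
        )
        np.testing.assert_allclose(m.weights.toarray()[0], [0.75, 0.25])

    def test_uniform_weights_flag(self):
        m = build_compatibility(
            [aln("r1", "A", 0.9), aln("r1", "B", 0.3)],
            QuantParams(uniform_weights=True),
        )
        np.testing.assert_allclose(m.weights.toarray()[0], [0.5, 0.5])

    def test_max_alignments_cap(self):
        alns = [aln("r1", f"ref{j:03d}", 0.5 + j * 1e-4) for j in range(120)]
        m = build_compatibility(alns, QuantParams(max_alignments=100))
        assert m.weights.getnnz() == 100

    def test_unknown_reference_with_bound_taxonomy(self):
        with pytest.raises(ValueError, match="unknown reference"):
            build_compatibility([aln("r1", "X", 0.9)], ref_ids=["A", "B"])

    def test_rows_normalized(self, rng):
        w = rng.random((20, 5)) * (rng.random((20, 5)) < 0.5)
        w[w.sum(axis=1) == 0, 0] = 0.5
        m = matrix_from_dense(w)
        np.testing.assert_allclose(np.asarray(m.weights.sum(axis=1)).ravel(), 1.0)


class TestNaive:
    def test_all_best_to_one_ref(self):
        alns = [aln(f"r{i}", "A", 0.9) for i in range(10)]
        alns += [aln(f"r{i}", "B", 0.5) for i in range(10)]
        counts = naive_count(build_compatibility(alns))
        assert counts["A"] == 10 and counts["B"] == 0

    def test_tie_breaks_lexicographically(self):
        counts = naive_count(build_compatibility([aln("r1", "B", 0.9), aln("r1", "A", 0.9)]))
        assert counts["A"] == 1 and counts["B"] == 0

    def test_matches_argmax_oracle(self, rng):
        w = rng.random((50, 6)) * (rng.random((50, 6)) < 0.6)
        w[w.sum(axis=1) == 0, 0] = 0.3
        m = matrix_from_dense(w)
        counts = naive_count(m)
        oracle = np.zeros(6, dtype=int)
        for i in range(50):
            row = np.round(w[i] * 1000) / 1000  # identity rounding in aln()
            oracle[np.argmax(row)] += 1
        np.testing.assert_array_equal(counts.to_numpy(), oracle)


class TestEM:
    def test_unique_reads_recover_proportions(self):
        alns = [aln(f"a{i}", "A", 0.9) for i in range(7)]
        alns += [aln(f"b{i}", "B", 0.9) for i in range(3)]
        est = em_quantify(build_compatibility(alns))
        np.testing.assert_allclose(est.theta[["A", "B"]], [0.7, 0.3], atol=1e-9)

    def test_symmetric_ambiguity_splits_evenly(self):
        alns = [aln(f"a{i}", "A", 0.9) for i in range(3)]
        alns += [aln(f"b{i}", "B", 0.9) for i in range(3)]
        for i in range(4):
            alns += [aln(f"x{i}", "A", 0.8), aln(f"x{i}", "B", 0.8)]
        est = em_quantify(build_compatibility(alns))
        np.testing.assert_allclose(est.theta[["A", "B"]], [0.5, 0.5], atol=1e-6)

    def test_analytic_fixed_point_winner_takes_all(self):
        # 6 unique to A, 4 ambiguous -> fixed point a = (6 + 4a)/10 => a = 1
        alns = [aln(f"a{i}", "A", 0.9) for i in range(6)]
        for i in range(4):
            alns += [aln(f"x{i}", "A", 0.8), aln(f"x{i}", "B", 0.8)]
        est = em_quantify(
            build_compatibility(alns), QuantParams(tolerance=1e-12, max_iterations=5000)
        )
        np.testing.assert_allclose(est.theta[["A", "B"]], [1.0, 0.0], atol=1e-8)

    def test_loglik_monotone_and_theta_normalized(self, rng):
        w = rng.random((30, 5)) * (rng.random((30, 5)) < 0.5)
        w[w.sum(axis=1) == 0, 0] = 0.4
        est = em_quantify(matrix_from_dense(w))
        ll = est.log_likelihood
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))
        assert est.theta.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle_small_instances(self, trial):
        """m <= 4 refs, n <= 12 reads: sparse EM equals dense fixed-point
        iteration to 1e-8."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 13))
        m = int(rng.integers(2, 5))
        w = rng.random((n, m)) * (rng.random((n, m)) < 0.7)
        w[w.sum(axis=1) == 0, 0] = 0.5
        w = np.round(w * 1000) / 1000  # match identity rounding
        refs = [chr(ord("A") + j) for j in range(m)]
        est = em_quantify(
            matrix_from_dense(w), QuantParams(tolerance=1e-12, max_iterations=200_000)
        )
        theta = est.theta.reindex(refs, fill_value=0.0)  # refs with no hits drop out
        oracle = dense_em_oracle(w / w.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(theta.to_numpy(), oracle, atol=1e-8)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            em_quantify(build_compatibility([]))


class TestCutoffAndCollapse:
    @staticmethod
    def estimate(counts: dict, n=None):
        from aquamicrobe.em import AbundanceEstimate

        total = sum(counts.values()) if n is None else n
        theta = pd.Series({k: v / total for k, v in counts.items()})
        return AbundanceEstimate(theta=theta, n_reads=total)

    def test_threshold_drops_low(self):
        est = apply_cutoff(self.estimate({"A": 500, "B": 100}), 300)
        assert list(est.expected_counts.index) == ["A"]
        assert est.expected_counts["A"] == pytest.approx(500)

    def test_boundary_inclusive(self):
        est = apply_cutoff(self.estimate({"A": 300}), 300)
        assert list(est.theta.index) == ["A"]

    def test_cutoff_zero_is_identity(self):
        est = apply_cutoff(self.estimate({"A": 5, "B": 1}), 0)
        assert list(est.theta.index) == ["A", "B"]

    def test_no_renormalization(self):
        est = apply_cutoff(self.estimate({"A": 400, "B": 100}), 300)
        assert est.expected_counts["A"] == pytest.approx(400)

    def test_collapse_additive(self):
        tax = {
            "A1": TaxonomyEntry("A1", ("B", "P", "C", "O", "F", "G")),
            "A2": TaxonomyEntry("A2", ("B", "P", "C", "O", "F", "G")),
        }
        out = collapse_taxonomy(pd.Series({"A1": 200.0, "A2": 100.0}), tax, "genus")
        assert out["G"] == pytest.approx(300)

    def test_unassigned_pooled(self):
        tax = {"X": TaxonomyEntry("X", ("B", "P", "C", "O", "F"))}
        out = collapse_taxonomy(pd.Series({"X": 50.0}), tax, "genus")
        assert out["unclassified"] == pytest.approx(50)

    def test_total_conserved_across_ranks(self, ref_db):
        counts = pd.Series(
            {r: float(i + 1) for i, r in enumerate(ref_db.ref_ids)}
        )
        g = collapse_taxonomy(counts, ref_db.taxonomy, "genus")
        p = collapse_taxonomy(counts, ref_db.taxonomy, "phylum")
        assert g.sum() == pytest.approx(p.sum()) == pytest.approx(counts.sum())

    def test_missing_taxonomy_entry_named(self):
        with pytest.raises(KeyError, match="refZ"):
            collapse_taxonomy(pd.Series({"refZ": 1.0}), {}, "genus")
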