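"""Topology selection, shared-path WLS and the branch-covariance pipeline."""

import numpy as np
import pytest

from branchcov.covariance import (
    InfoTable,
    QuartetDistances,
    branch_covariance,
    build_info_table,
    covariance_matrix,
    estimate_shared_path,
    general_covariance,
    nr_covariance,
    select_topology,
    triplet_shared_path,
)
from branchcov.distances import nr_delta_variance, pairwise_distance_table
from branchcov.models import make_nr_model
from branchcov.simulate import Quartet, sample_quartet

# Design matrices mapping the five branch lengths (b_i, b_j, b_k, b_l, b_m)
# to the six path lengths in order (ij, ik, il, jk, jl, kl), per topology.
_DESIGNS = {
    "T1": np.array(
        [[1, 1, 0, 0, 1], [1, 0, 1, 0, 0], [1, 0, 0, 1, 1],
         [0, 1, 1, 0, 1], [0, 1, 0, 1, 0], [0, 0, 1, 1, 1]], float),
    "T2": np.array(
        [[1, 1, 0, 0, 1], [1, 0, 1, 0, 1], [1, 0, 0, 1, 0],
         [0, 1, 1, 0, 0], [0, 1, 0, 1, 1], [0, 0, 1, 1, 1]], float),
    "T3": np.array(
        [[1, 1, 0, 0, 0], [1, 0, 1, 0, 1], [1, 0, 0, 1, 1],
         [0, 1, 1, 0, 1], [0, 1, 0, 1, 1], [0, 0, 1, 1, 0]], float),
}


def wls_oracle(d6, v6, topology):
    """Independent constrained-WLS oracle: fit all five branch lengths.

    Returns the minimized weighted sum of squares and the fitted middle
    branch length.
    """
    X = _DESIGNS[topology]
    w = np.sqrt(1.0 / np.asarray(v6))
    sol, *_ = np.linalg.lstsq(w[:, None] * X, w * np.asarray(d6), rcond=None)
    resid = w * (np.asarray(d6) - X @ sol)
    return float(resid @ resid), float(sol[4])


def quartet_distances(q, noise=None, v=1e-3, n=1000):
    d6 = np.asarray(q.true_distances(), dtype=float)
    if noise is not None:
        d6 = d6 + noise
    return QuartetDistances.from_arrays(q.labels, d6, [v] * 6, [n] * 6)


class TestTopologySelection:
    def test_noiseless_t1(self):
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T1")
        fit = select_topology(quartet_distances(q))
        assert fit.topology == "T1"
        assert fit.scores["T1"] == pytest.approx(0.0, abs=1e-20)

    def test_noiseless_t3(self):
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T3")
        fit = select_topology(quartet_distances(q))
        assert fit.topology == "T3"
        assert fit.scores["T3"] == pytest.approx(0.0, abs=1e-20)

    def test_all_equal_distances_tie_to_t3(self):
        qd = QuartetDistances.from_arrays(
            "abcd", [0.3] * 6, [1e-3] * 6, [1000] * 6
        )
        fit = select_topology(qd)
        assert fit.topology == "T3" and fit.tied

    def test_nonpositive_variance_rejected(self):
        qd = QuartetDistances.from_arrays(
            "abcd", [0.3] * 6, [1e-3] * 5 + [0.0], [1000] * 6
        )
        with pytest.raises(ValueError):
            select_topology(qd)

    def test_scores_match_full_wls_oracle(self, rng):
        """Each S(T) equals the minimized weighted SS of the five-branch WLS
        fit under that topology, on noisy random quartets."""
        for _ in range(30):
            b = rng.uniform(0.05, 0.5, 5)
            q = Quartet(delta=tuple(b), topology="T1")
            noise = rng.normal(0, 0.02, 6)
            v6 = rng.uniform(5e-4, 5e-3, 6)
            d6 = np.asarray(q.true_distances()) + noise
            qd = QuartetDistances.from_arrays(q.labels, d6, v6, [1000] * 6)
            fit = select_topology(qd)
            for topo in ("T1", "T2", "T3"):
                ss, _ = wls_oracle(d6, v6, topo)
                assert fit.scores[topo] == pytest.approx(ss, abs=1e-12)
            best = min(fit.scores, key=fit.scores.get)
            assert fit.topology == best


class TestSharedPath:
    def test_noiseless_value(self):
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T1")
        qd = quartet_distances(q)
        sp = estimate_shared_path(qd, select_topology(qd))
        assert sp.raw == pytest.approx(0.05, abs=1e-12)
        assert sp.clamped == sp.raw

    def test_negative_raw_value_clamped(self):
        # d_ik = d_jl exceed the other four equal distances: T1 is selected
        # with a zero score but its fitted middle branch is negative
        d6 = [0.30, 0.33, 0.30, 0.30, 0.33, 0.30]  # ij, ik, il, jk, jl, kl
        qd = QuartetDistances.from_arrays("abcd", d6, [1e-3] * 6, [1000] * 6)
        fit = select_topology(qd)
        assert fit.topology == "T1"
        sp = estimate_shared_path(qd, fit)
        assert sp.raw < 0 and sp.clamped == 0.0

    def test_t3_is_a_contract_violation(self):
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T3")
        qd = quartet_distances(q)
        with pytest.raises(ValueError):
            estimate_shared_path(qd, select_topology(qd))

    def test_matches_wls_oracle_with_unequal_weights(self, rng):
        for _ in range(30):
            b = rng.uniform(0.05, 0.5, 5)
            q = Quartet(delta=tuple(b), topology="T1")
            d6 = np.asarray(q.true_distances()) + rng.normal(0, 0.02, 6)
            v6 = rng.uniform(5e-4, 5e-3, 6)
            qd = QuartetDistances.from_arrays(q.labels, d6, v6, [1000] * 6)
            _, bm = wls_oracle(d6, v6, "T1")
            fit = select_topology(qd)
            if fit.topology != "T1":
                continue
            sp = estimate_shared_path(qd, fit)
            assert sp.raw == pytest.approx(bm, abs=1e-12)

    def test_reweighting_moves_estimate(self):
        """Halving the cross-pair variances pulls the estimate toward the
        within-pair distance sums."""
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T1")
        d6 = np.asarray(q.true_distances())
        d6[0] += 0.02  # perturb d_ij so the weighting matters
        base = QuartetDistances.from_arrays(q.labels, d6, [1e-3] * 6, [1000] * 6)
        v_low_cross = [1e-3, 1e-3, 5e-4, 5e-4, 1e-3, 1e-3]  # halve v_il, v_jk
        relow = QuartetDistances.from_arrays(q.labels, d6, v_low_cross, [1000] * 6)
        fit = select_topology(base)
        sp_base = estimate_shared_path(base, fit)
        sp_low = estimate_shared_path(relow, select_topology(relow))
        # giving the unperturbed cross paths more weight dilutes the
        # perturbed d_ij, so the estimate moves back toward the truth
        assert sp_low.raw != sp_base.raw
        assert abs(sp_low.raw - 0.05) < abs(sp_base.raw - 0.05)


class TestTripletSharedPath:
    @pytest.mark.parametrize(
        "d_ij,d_jk,d_ik,expect",
        [(0.3, 0.4, 0.5, 0.1), (0.3, 0.4, 0.7, 0.0), (0.1, 0.1, 0.5, 0.0)],
    )
    def test_three_point_formula(self, d_ij, d_jk, d_ik, expect):
        assert triplet_shared_path(d_ij, d_jk, d_ik) == pytest.approx(expect, abs=1e-15)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            triplet_shared_path(-0.1, 0.2, 0.3)


class TestCovarianceFormulas:
    def test_nr_covariance_is_variance_at_shared_path(self):
        for dm in np.linspace(0.0, 2.0, 21):
            assert nr_covariance(4, dm, 500) == nr_delta_variance(4, dm, 500)

    def test_nr_worked_value(self):
        assert nr_covariance(4, 0.2, 500) == pytest.approx(4.934e-4, rel=2e-4)

    def test_general_matches_nr_closed_form(self, nr4):
        for dm in np.linspace(0.01, 2.0, 50):
            assert general_covariance(nr4, dm, 1000) == pytest.approx(
                nr_covariance(4, dm, 1000), rel=1e-8
            )

    def test_zero_shared_path(self, nr4, general_model):
        assert general_covariance(nr4, 0.0, 1000) == 0.0
        assert general_covariance(general_model, 1e-12, 1000) == 0.0

    def test_continuous_increasing_in_shared_path(self, general_model):
        dm = np.linspace(0.01, 3.0, 100)
        cov = np.array([general_covariance(general_model, x, 1000) for x in dm])
        assert np.all(np.diff(cov) > 0)
        # smooth on the log scale: the covariance is ~linear in delta_m near
        # zero and exponential at large delta_m, so per-step log increments
        # are bounded by the log increments of the grid plus a growth term
        log_step = np.diff(np.log(cov))
        bound = 2 * np.diff(np.log(dm)) + 0.25
        assert np.all(log_step < bound)


class TestInfoTable:
    def test_grid_values_positive_decreasing(self, nr4):
        t = build_info_table(nr4, 0.05, 2.0, 0.05)
        assert np.all(t.values > 0)
        assert np.all(np.diff(t.values) < 0)

    def test_grid_point_equals_direct_evaluation(self, nr4):
        t = build_info_table(nr4, 0.05, 2.0, 0.05)
        for g, val in zip(t.grid[::8], t.values[::8]):
            direct = 1.0 / general_covariance(nr4, float(g), 1)
            assert val == pytest.approx(direct, rel=1e-12)

    def test_tsv_round_trip(self, nr4, tmp_path):
        t = build_info_table(nr4, 0.05, 1.0, 0.05)
        p = tmp_path / "info.tsv"
        t.to_tsv(p)
        back = InfoTable.from_tsv(p)
        assert back.model_id == t.model_id
        assert np.allclose(back.grid, t.grid, atol=1e-12)
        assert np.allclose(back.values, t.values, rtol=1e-12)

    def test_interpolation_accuracy_at_midpoints(self, nr4):
        t = build_info_table(nr4, 0.001, 2.0, 0.001)
        mids = np.arange(0.05, 2.0, 0.0373) + 0.0005
        for dm in mids:
            direct = general_covariance(nr4, float(dm), 1000)
            interp = general_covariance(nr4, float(dm), 1000, table=t)
            assert interp == pytest.approx(direct, rel=1e-5)

    def test_out_of_range_rejected(self, nr4):
        t = build_info_table(nr4, 0.1, 1.0, 0.1)
        with pytest.raises(ValueError):
            general_covariance(nr4, 1.5, 1000, table=t)

    def test_bad_grid_config_rejected(self, nr4):
        with pytest.raises(ValueError):
            build_info_table(nr4, 0.5, 1.0, 0.6)


class TestBranchCovariancePipeline:
    def test_independent_topology_gives_exact_zero(self, nr4):
        q = Quartet(delta=(0.2, 0.3, 0.25, 0.15, 0.1), topology="T3")
        est = branch_covariance(nr4, quartet_distances(q))
        assert est.cov == 0.0 and est.zero_reason == "independent-topology"

    def test_noiseless_dependence_equals_closed_form(self, nr4):
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T1")
        est = branch_covariance(nr4, quartet_distances(q, n=1000))
        assert est.zero_reason == "none"
        assert est.delta_m_hat == pytest.approx(0.05, abs=1e-12)
        assert est.cov == pytest.approx(nr_covariance(4, 0.05, 1000), rel=1e-8)

    def test_negative_delta_reported_as_zero(self, nr4):
        # d_ac = d_bd exceed the other four equal distances, so the best
        # WLS topology is T1 but its fitted middle branch is negative
        d6 = [0.30, 0.33, 0.30, 0.30, 0.33, 0.30]
        qd = QuartetDistances.from_arrays("abcd", d6, [1e-3] * 6, [1000] * 6)
        est = branch_covariance(nr4, qd)
        assert est.cov == 0.0 and est.zero_reason == "negative-delta"

    def test_bounded_by_either_variance_on_noiseless_input(self, rng):
        nr4 = make_nr_model(4)
        for _ in range(50):
            q = sample_quartet(rng)
            n = 1000
            d6 = q.true_distances()
            v6 = [nr_delta_variance(4, d, n) for d in d6]
            qd = QuartetDistances.from_arrays(q.labels, d6, v6, [n] * 6)
            est = branch_covariance(nr4, qd)
            assert 0.0 <= est.cov <= min(v6[0], v6[5]) + 1e-15

    def test_geomean_vs_min_effective_n(self, nr4):
        q = Quartet(delta=(0.1, 0.1, 0.1, 0.1, 0.05), topology="T1")
        d6 = q.true_distances()
        qd = QuartetDistances.from_arrays(
            q.labels, d6, [1e-3] * 6, [400, 1000, 1000, 1000, 1000, 900]
        )
        geo = branch_covariance(nr4, qd, n_effective="geomean")
        mn = branch_covariance(nr4, qd, n_effective="min")
        assert geo.n_effective == 600  # sqrt(400 * 900)
        assert mn.n_effective == 400
        assert mn.cov > geo.cov  # smaller n, larger covariance

    def test_wls_recovery_on_random_noiseless_quartets(self, rng):
        """Topology and middle branch recovered exactly on additive input."""
        hits = 0
        for _ in range(200):
            q = sample_quartet(rng)
            n = 1000
            d6 = q.true_distances()
            v6 = [max(nr_delta_variance(4, d, n), 1e-12) for d in d6]
            qd = QuartetDistances.from_arrays(q.labels, d6, v6, [n] * 6)
            fit = select_topology(qd)
            assert fit.topology == "T1"
            sp = estimate_shared_path(qd, fit)
            assert sp.clamped == pytest.approx(q.delta_m, abs=1e-10)
            hits += 1
        assert hits == 200


class TestCovarianceMatrix:
    def make_additive_tree_distances(self, nr4, n=1000):
        # caterpillar 6-taxon tree; distances from summed branch lengths
        import itertools
        import pandas as pd

        # node chain: internal nodes x1..x4; leaves a..f hang off the chain
        leaf_attach = {"a": 0, "b": 0, "c": 1, "d": 2, "e": 3, "f": 3}
        leaf_edge = {"a": 0.10, "b": 0.12, "c": 0.08, "d": 0.09, "e": 0.11, "f": 0.13}
        chain = [0.05, 0.07, 0.06]  # internal edges x1-x2, x2-x3, x3-x4
        rows = []
        for x, y in itertools.combinations(sorted(leaf_attach), 2):
            i, j = leaf_attach[x], leaf_attach[y]
            d = leaf_edge[x] + leaf_edge[y] + sum(chain[min(i, j) : max(i, j)])
            rows.append(
                dict(
                    taxon_a=x,
                    taxon_b=y,
                    d_hat=d,
                    variance=nr_delta_variance(4, d, n),
                    n=n,
                    saturated=False,
                )
            )
        return pd.DataFrame(rows), leaf_attach, chain, leaf_edge

    def test_four_taxon_combinatorics(self, nr4, tmp_path):
        fasta = tmp_path / "four.fa"
        fasta.write_text(
            ">a\nACGTACGTACGTACGTACGT\n>b\nACGTACGTACGTACGTACGA\n"
            ">c\nACGTACGAACGTACGTACGT\n>d\nACGAACGTACGTACTTACGT\n"
        )
        from branchcov.distances import read_fasta

        table = pairwise_distance_table(nr4, read_fasta(fasta))
        out = covariance_matrix(nr4, table)
        assert len(out) == 21  # 6 variances + 15 pair-of-pair records
        assert (out.pair_a == out.pair_b).sum() == 6
        diag = out[out.pair_a == out.pair_b]
        assert np.allclose(np.sort(diag["covariance"]), np.sort(table.variance))

    def test_t3_pairs_are_exact_zero(self, nr4):
        table, *_ = self.make_additive_tree_distances(nr4)
        out = covariance_matrix(nr4, table)
        t3 = out[out.topology == "T3"]
        assert len(t3) > 0
        assert np.all(t3["covariance"] == 0.0)
        assert np.all(t3.zero_reason == "independent-topology")

    def test_disjoint_pairs_recover_true_shared_path(self, nr4):
        table, leaf_attach, chain, leaf_edge = self.make_additive_tree_distances(nr4)
        out = covariance_matrix(nr4, table)
        # paths a-d and c-f overlap on the spine edge between the
        # attachment points of c and d (length 0.07)
        row = out[(out.pair_a == "a-d") & (out.pair_b == "c-f")].iloc[0]
        assert row.topology in ("T1", "T2")
        assert row.delta_m_hat == pytest.approx(0.07, abs=1e-10)
        assert row["covariance"] == pytest.approx(
            general_covariance(nr4, 0.07, 1000), rel=1e-8
        )

    def test_triplet_pairs_use_three_point_formula(self, nr4):
        table, *_ = self.make_additive_tree_distances(nr4)
        out = covariance_matrix(nr4, table)
        row = out[(out.pair_a == "a-b") & (out.pair_b == "a-c")].iloc[0]
        assert row.topology == "triplet"
        assert row.delta_m_hat == pytest.approx(0.10, abs=1e-12)  # a's edge

    def test_missing_pair_rejected(self, nr4):
        table, *_ = self.make_additive_tree_distances(nr4)
        with pytest.raises(ValueError):
            covariance_matrix(nr4, table.iloc[:-1])

    def test_symmetric_by_construction(self, nr4):
        """Each unordered pair of pairs appears once; swapping the target
        pair roles leaves the estimate unchanged."""
        table, *_ = self.make_additive_tree_distances(nr4)
        out = covariance_matrix(nr4, table)
        keys = set(zip(out.pair_a, out.pair_b))
        assert all((b, a) not in keys or a == b for a, b in keys)
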