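"""TCR, resampling comparisons, and Fisher exact tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, kstest

from regnetopo import (
    Direction,
    GeneClass,
    GeneClassPartition,
    class_association,
    compare_sets,
    connected_tf_count,
    neighbor_enrichment,
    tcr,
)
from regnetopo.network import NodeType
from regnetopo.stats import _fisher

from _oracles import tcr_from_target_sets
from conftest import build_net


def mirna_net(target_sets: dict[str, set[str]]):
    """Network of miRNAs with given non-TF target sets."""
    nodes = {m: "MIRNA" for m in target_sets}
    for targets in target_sets.values():
        for t in targets:
            nodes[t] = "NONTF"
    edges = [
        (m, t) for m, targets in target_sets.items() for t in sorted(targets)
    ]
    return build_net(nodes, edges)


class TestTCR:
    def test_disjoint_targets_give_one(self):
        net = mirna_net(
            {"m1": {"a", "b"}, "m2": {"c", "d"}, "m3": {"e", "f"}}
        )
        res = tcr(net, {"m1", "m2", "m3"})
        assert res.tcr == pytest.approx(1.0)
        assert res.n_mir == 3
        assert res.mean_out_degree == pytest.approx(2.0)
        assert res.mean_target_number == pytest.approx(2.0)

    def test_identical_targets_give_zero(self):
        net = mirna_net({"m1": {"a", "b"}, "m2": {"a", "b"}, "m3": {"a", "b"}})
        assert tcr(net, {"m1", "m2", "m3"}).tcr == pytest.approx(0.0)

    def test_partial_overlap(self):
        # targets {a,b} and {b,c}: <N_targ>=3/2, <K_out>=2, TCR=0.5
        net = mirna_net({"m1": {"a", "b"}, "m2": {"b", "c"}})
        res = tcr(net, {"m1", "m2"})
        assert res.mean_target_number == pytest.approx(1.5)
        assert res.mean_out_degree == pytest.approx(2.0)
        assert res.tcr == pytest.approx(0.5)

    def test_fewer_than_two_mirnas_errors(self):
        net = mirna_net({"m1": {"a"}})
        with pytest.raises(ValueError, match="at least 2"):
            tcr(net, {"m1"})

    def test_zero_out_degree_member_errors(self):
        net = build_net(
            {"m1": "MIRNA", "m2": "MIRNA", "a": "NONTF"}, [("m1", "a")]
        )
        with pytest.raises(ValueError, match="out-degree 0"):
            tcr(net, {"m1", "m2"})

    def test_non_mirna_member_errors(self):
        net = build_net({"t": "TF", "m": "MIRNA", "a": "NONTF"},
                        [("t", "a"), ("m", "a")])
        with pytest.raises(ValueError, match="not a miRNA"):
            tcr(net, {"t", "m"})

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10**6),
        n_mir=st.integers(2, 6),
        scenario=st.sampled_from(["disjoint", "identical", "random"]),
    )
    def test_boundaries_and_oracle_equivalence(self, seed, n_mir, scenario):
        """Disjoint sets => TCR 1, identical => 0, and for arbitrary
        random target sets the value equals the union-count oracle."""
        rng = np.random.default_rng(seed)
        universe = [f"t{i}" for i in range(12)]
        if scenario == "disjoint":
            sizes = rng.integers(1, 3, size=n_mir)
            cursor = 0
            sets = []
            for k in sizes:
                sets.append(set(universe[cursor:cursor + int(k)]))
                cursor += int(k)
        elif scenario == "identical":
            shared = set(
                rng.choice(universe, size=int(rng.integers(1, 5)),
                           replace=False)
            )
            sets = [set(shared) for _ in range(n_mir)]
        else:
            sets = [
                set(rng.choice(universe, size=int(rng.integers(1, 6)),
                               replace=False))
                for _ in range(n_mir)
            ]
        net = mirna_net({f"m{i}": s for i, s in enumerate(sets)})
        value = tcr(net, [f"m{i}" for i in range(n_mir)]).tcr
        assert value == pytest.approx(
            tcr_from_target_sets(sets), abs=1e-12
        )
        if scenario == "disjoint":
            assert value == pytest.approx(1.0, abs=1e-12)
        if scenario == "identical":
            assert value == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_relabeling(self):
        net1 = mirna_net({"m1": {"a", "b"}, "m2": {"b", "c"}})
        net2 = mirna_net({"zz": {"x", "y"}, "aa": {"y", "w"}})
        assert tcr(net1, {"m1", "m2"}).tcr == pytest.approx(
            tcr(net2, {"zz", "aa"}).tcr
        )


class TestConnectedTFCount:
    def test_counts_in_and_out_tf_neighbors(self):
        net = build_net(
            {"m": "MIRNA", "t1": "TF", "t2": "TF", "t3": "TF",
             "g": "NONTF"},
            [("t1", "m"), ("t2", "m"), ("m", "t3"), ("m", "g")],
        )
        assert connected_tf_count(net, {"m"}) == pytest.approx(3.0)

    def test_no_tf_neighbors(self):
        net = build_net(
            {"m": "MIRNA", "g": "NONTF"}, [("m", "g")]
        )
        assert connected_tf_count(net, {"m"}) == 0.0

    def test_bidirectional_tf_counts_once(self):
        net = build_net(
            {"m": "MIRNA", "t": "TF", "g": "NONTF", "g2": "NONTF"},
            [("t", "m"), ("m", "t"), ("m", "g")],
        )
        assert connected_tf_count(net, {"m"}) == pytest.approx(1.0)

    def test_empty_set_errors(self, mixed_net):
        with pytest.raises(ValueError, match="empty"):
            connected_tf_count(mixed_net, set())


def make_profile(values: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"out_degree": pd.Series(values, dtype=float)}
    ).rename_axis("node_id")


class TestCompareSets:
    def test_constant_values_are_never_significant(self):
        profile = make_profile({f"n{i}": 5.0 for i in range(30)})
        res = compare_sets(
            profile, {f"n{i}" for i in range(5)},
            {f"n{i}" for i in range(5, 30)}, "out_degree",
            n_resamples=200, seed=0,
        )
        assert res.p_greater == 1.0 and res.p_less == 1.0
        assert res.significant_direction is Direction.NONE

    def test_exhaustive_singleton_max(self):
        """Small set holds the largest of 10 strictly ordered values:
        full enumeration of the 9 singleton null sets plus add-one
        smoothing gives exactly 1/10."""
        profile = make_profile({f"n{i}": float(i) for i in range(10)})
        res = compare_sets(
            profile, {"n9"}, {f"n{i}" for i in range(9)}, "out_degree",
            method="exhaustive",
        )
        assert res.p_greater == pytest.approx(1 / 10)
        assert res.n_resamples == 9

    def test_resample_reproducible_with_seed(self):
        rng = np.random.default_rng(4)
        profile = make_profile(
            {f"n{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        )
        small = {f"n{i}" for i in range(8)}
        bg = {f"n{i}" for i in range(8, 50)}
        a = compare_sets(profile, small, bg, "out_degree", seed=42,
                         n_resamples=500)
        b = compare_sets(profile, small, bg, "out_degree", seed=42,
                         n_resamples=500)
        assert np.array_equal(a.null_means, b.null_means)
        assert (a.p_greater, a.p_less) == (b.p_greater, b.p_less)

    def test_monotone_in_small_set_shift(self):
        rng = np.random.default_rng(9)
        values = {f"n{i}": float(v) for i, v in
                  enumerate(rng.normal(size=60))}
        small = {f"n{i}" for i in range(10)}
        bg = {f"n{i}" for i in range(10, 60)}
        base = compare_sets(make_profile(values), small, bg, "out_degree",
                            seed=3, n_resamples=400)
        shifted = dict(values)
        for nid in small:
            shifted[nid] += 1.5
        after = compare_sets(make_profile(shifted), small, bg, "out_degree",
                             seed=3, n_resamples=400)
        assert after.p_greater <= base.p_greater

    def test_p_floor(self):
        profile = make_profile(
            {f"n{i}": float(i) for i in range(40)}
        )
        small = {f"n{i}" for i in range(36, 40)}
        bg = {f"n{i}" for i in range(36)}
        res = compare_sets(profile, small, bg, "out_degree",
                           n_resamples=100, seed=0)
        assert res.p_greater >= 1 / 101
        assert res.significant_direction is Direction.HIGHER

    def test_background_smaller_than_small_set_errors(self):
        profile = make_profile({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError, match="smaller"):
            compare_sets(profile, {"a", "b"}, {"c"}, "out_degree")

    def test_overlapping_sets_error(self):
        profile = make_profile({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError, match="disjoint"):
            compare_sets(profile, {"a"}, {"a", "b", "c"}, "out_degree")

    def test_nonfinite_values_error(self):
        profile = make_profile({"a": 1.0, "b": math.nan, "c": 3.0})
        with pytest.raises(ValueError, match="non-finite"):
            compare_sets(profile, {"a"}, {"b", "c"}, "out_degree")

    def test_recompute_p_matches(self):
        rng = np.random.default_rng(12)
        profile = make_profile(
            {f"n{i}": float(v) for i, v in enumerate(rng.normal(size=40))}
        )
        res = compare_sets(
            profile, {f"n{i}" for i in range(6)},
            {f"n{i}" for i in range(6, 40)}, "out_degree",
            n_resamples=300, seed=77,
        )
        assert res.recompute_p() == (res.p_greater, res.p_less)

    def test_null_calibration_uniformity(self):
        """Exchangeable small sets give p_greater no smaller than
        uniform: the ECDF stays within 3 binomial SEs of the diagonal."""
        master = np.random.default_rng(2024)
        n_rep = 200
        p_values = np.empty(n_rep)
        ids = [f"n{i}" for i in range(120)]
        for rep in range(n_rep):
            vals = master.normal(size=120)
            profile = make_profile(dict(zip(ids, vals)))
            picks = master.choice(120, size=10, replace=False)
            small = {ids[i] for i in picks}
            bg = set(ids) - small
            res = compare_sets(profile, small, bg, "out_degree",
                               n_resamples=500,
                               seed=int(master.integers(2**31)))
            p_values[rep] = res.p_greater
        for q in (0.05, 0.1, 0.25, 0.5, 0.75):
            ecdf = np.mean(p_values <= q)
            tol = 3 * math.sqrt(q * (1 - q) / n_rep)
            assert ecdf <= q + tol  # never anti-conservative beyond noise
            assert ecdf >= q - tol - 0.02  # and close to uniform


class TestFisher:
    def test_perfect_association(self):
        res = _fisher(np.array([[10, 0], [0, 10]]))
        assert math.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(2 / math.comb(20, 10))

    def test_no_association(self):
        res = _fisher(np.array([[5, 5], [5, 5]]))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_sum(self):
        """Two-sided P equals the brute-force sum of hypergeometric
        probabilities not exceeding the observed table's."""
        table = np.array([[1, 9], [9, 1]])
        res = _fisher(table)
        m = 10  # row-1 total
        n = 10  # row-2 total
        k = 10  # column-1 total
        p_obs = hypergeom.pmf(1, m + n, m, k)
        total = sum(
            hypergeom.pmf(x, m + n, m, k)
            for x in range(max(0, k - n), min(m, k) + 1)
            if hypergeom.pmf(x, m + n, m, k) <= p_obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(total, rel=1e-9)

    def test_degenerate_margin_flagged(self):
        res = _fisher(np.array([[3, 0], [7, 0]]))
        assert res.degenerate and res.p_value == 1.0
        assert math.isnan(res.odds_ratio)


class TestNeighborEnrichment:
    def test_table_construction(self):
        """Focal TF with one TF neighbor; one TF and two non-TFs
        unconnected."""
        net = build_net(
            {"f": "TF", "t1": "TF", "t2": "TF", "g1": "NONTF",
             "g2": "NONTF"},
            [("f", "t1")],
        )
        res = neighbor_enrichment(net, {"f"}, NodeType.TF)
        assert res.contingency == ((1, 0), (1, 2))

    def test_empty_focal_errors(self, mixed_net):
        with pytest.raises(ValueError, match="nonempty"):
            neighbor_enrichment(mixed_net, set(), NodeType.TF)

    def test_degenerate_class_margin(self):
        net = build_net(
            {"f": "TF", "g1": "NONTF", "g2": "NONTF"}, [("f", "g1")]
        )
        res = neighbor_enrichment(net, {"f"}, NodeType.MIRNA)
        assert res.degenerate and res.p_value == 1.0


class TestClassAssociation:
    def _partition(self, cls, ids):
        return GeneClassPartition(cls, frozenset(ids))

    def test_identical_partitions_maximal_association(self):
        universe = {f"n{i}" for i in range(20)}
        part = self._partition(GeneClass.DISEASE_TF, list(universe)[:10])
        res = class_association(part, part, universe)
        # the two equally extreme diagonal tables for these margins
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_disjoint_halves_negative_association(self):
        ids = [f"n{i}" for i in range(20)]
        a = self._partition(GeneClass.DISEASE_TF, ids[:10])
        b = self._partition(GeneClass.TS_TF, ids[10:])
        res = class_association(a, b, set(ids))
        assert res.odds_ratio == 0.0
        assert res.p_value < 0.05

    def test_empty_universe_errors(self):
        a = self._partition(GeneClass.DISEASE_TF, [])
        with pytest.raises(ValueError, match="empty universe"):
            class_association(a, a, set())

    def test_null_calibration(self):
        """Independent random labels: P-values are not left-skewed
        (conservative discrete uniform)."""
        rng = np.random.default_rng(5)
        pvals = []
        ids = [f"n{i}" for i in range(200)]
        for _ in range(100):
            lab_a = rng.random(200) < 0.5
            lab_b = rng.random(200) < 0.5
            a = self._partition(
                GeneClass.DISEASE_TF,
                [i for i, keep in zip(ids, lab_a) if keep],
            )
            b = self._partition(
                GeneClass.TS_TF,
                [i for i, keep in zip(ids, lab_b) if keep],
            )
            pvals.append(class_association(a, b, set(ids)).p_value)
        # Fisher's exact P is conservative; check no excess of small Ps
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.05 + 3 * math.sqrt(
            0.05 * 0.95 / 100
        )
        assert kstest(pvals, "uniform", alternative="greater").pvalue > 0.01
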