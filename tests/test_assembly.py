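import numpy as np
import pytest

from comecol.assembly import (
    bmntd,
    bnti,
    classify_processes,
    cophenetic,
    pnst,
    raup_crick_bray,
)
from comecol.core_io import DistanceMatrix, OtuTable, PhyloTree
from comecol.synthetic_data import (
    simulate_dispersal_limited,
    simulate_neutral,
    simulate_selection,
    simulate_tree,
)

from oracles import bmntd_brute, bray_curtis_brute


class TestCophenetic:
    def test_hand_path_sums(self, caterpillar_tree):
        d = cophenetic(caterpillar_tree)
        assert d[("B", "C")] == pytest.approx(2.0)
        assert d[("A", "C")] == pytest.approx(3.0)

    def test_zero_diagonal(self, caterpillar_tree):
        d = cophenetic(caterpillar_tree)
        assert np.all(np.diag(d.data) == 0)

    def test_ultrametric_bound(self):
        tree = simulate_tree(30, seed=5)
        d = cophenetic(tree)
        assert d.data.max() <= 2.0 + 1e-6  # unit height -> max tip-tip 2

    def test_missing_tip_named(self, caterpillar_tree):
        with pytest.raises(Exception, match="ZZZ"):
            cophenetic(caterpillar_tree, ["A", "ZZZ"])


class TestBmntd:
    def test_identical_communities_zero(self, star_tree_4):
        t = OtuTable(
            np.array([[5, 5], [3, 3], [2, 2], [1, 1]]),
            ["t0", "t1", "t2", "t3"],
            ["s1", "s2"],
        )
        d = bmntd(t, cophenetic(star_tree_4))
        assert d[("s1", "s2")] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_hand_case(self, star_tree_4):
        # A = {t0}, B = {t1} on a unit-branch star: nearest distance is 2
        # in both directions, so the weighted average is 2
        t = OtuTable(np.array([[7, 0], [0, 9]]), ["t0", "t1"], ["s1", "s2"])
        d = bmntd(t, cophenetic(star_tree_4))
        assert d[("s1", "s2")] == pytest.approx(2.0)

    def test_adding_shared_taxon_cannot_increase(self, star_tree_4):
        rng = np.random.default_rng(0)
        pd_ = cophenetic(star_tree_4)
        for _ in range(20):
            counts = rng.integers(0, 9, size=(4, 2))
            counts[rng.integers(4), 0] += 1  # keep rows nonzero-ish
            counts = counts + (counts.sum(axis=1, keepdims=True) == 0)
            t = OtuTable(counts.copy(), ["t0", "t1", "t2", "t3"], ["A", "B"])
            base = bmntd(t, pd_)[("A", "B")]
            # add to B a taxon already present in A
            in_a = np.flatnonzero(t.counts[:, 0] > 0)
            i = int(rng.choice(in_a))
            counts2 = t.counts.copy()
            counts2[i, 1] += 5
            t2 = OtuTable(counts2, list(t.taxon_ids), ["A", "B"])
            assert bmntd(t2, pd_)[("A", "B")] <= base + 1e-12

    def test_matches_brute_force_random_instances(self):
        rng = np.random.default_rng(42)
        tree = simulate_tree(5, seed=1)
        pd_ = cophenetic(tree)
        dist = {
            (a, b): pd_[(a, b)] for a in pd_.ids for b in pd_.ids if a != b
        }
        for _ in range(25):
            counts = rng.integers(0, 6, size=(5, 4))
            counts[:, counts.sum(axis=0) == 0] += 1
            counts[counts.sum(axis=1) == 0, 0] += 1
            t = OtuTable(counts, list(pd_.ids), [f"s{j}" for j in range(4)])
            d = bmntd(t, pd_)
            rel = t.relative_abundance()
            for i in range(4):
                for j in range(i + 1, 4):
                    wk = {
                        tax: rel[ti, i]
                        for ti, tax in enumerate(t.taxon_ids)
                        if t.counts[ti, i] > 0
                    }
                    wl = {
                        tax: rel[ti, j]
                        for ti, tax in enumerate(t.taxon_ids)
                        if t.counts[ti, j] > 0
                    }
                    expected = bmntd_brute(wk, wl, dist)
                    assert d.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unweighted_variant(self, star_tree_4):
        t = OtuTable(
            np.array([[7, 0], [3, 0], [0, 9], [0, 1]]),
            ["t0", "t1", "t2", "t3"],
            ["s1", "s2"],
        )
        d = bmntd(t, cophenetic(star_tree_4), weighted=False)
        assert d[("s1", "s2")] == pytest.approx(2.0)


class TestBnti:
    def test_zero_variance_null_flagged(self, star_tree_4):
        t = OtuTable(
            np.array([[7, 0], [0, 9]]), ["t0", "t1"], ["s1", "s2"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            z = bnti(t, star_tree_4, n_null=101, seed=0)
        assert np.isnan(z[("s1", "s2")])

    def test_neutral_calibration(self):
        tree = simulate_tree(100, seed=2)
        table, _ = simulate_neutral(100, 12, 2000, Nm_true=500.0, seed=3)
        z = bnti(table, tree, n_null=199, seed=4)
        iu = np.triu_indices(z.n, 1)
        assert np.nanmean(np.abs(z.data[iu])) <= 2.0

    def test_selection_recovery(self):
        tree = simulate_tree(150, seed=5)
        table, meta = simulate_selection(tree, 12, 2000, niche_sd=0.5, seed=6)
        labels = meta.groups(table, "group")
        z = bnti(table, tree, n_null=199, seed=7)
        between = [
            z.data[i, j]
            for i in range(12)
            for j in range(i + 1, 12)
            if labels[i] != labels[j]
        ]
        assert np.nanmean(between) > 2.0

    def test_seed_stability_of_null_mean(self):
        # two seeds should agree within ~3 null standard errors
        from comecol.assembly import (
            _abundance_weights,
            _bmntd_from_arrays,
            _null_bmntd_stack,
        )

        tree = simulate_tree(40, seed=8)
        table, _ = simulate_neutral(40, 6, 500, Nm_true=200.0, seed=9)
        pd_ = tree.cophenetic(table.taxon_ids)
        w = _abundance_weights(table, True)
        pres = table.presence()
        n_null = 199
        s1 = _null_bmntd_stack(w, pres, pd_.data, n_null, np.random.default_rng(1))
        s2 = _null_bmntd_stack(w, pres, pd_.data, n_null, np.random.default_rng(2))
        m1, m2 = s1.mean(axis=0), s2.mean(axis=0)
        se = s1.std(axis=0) / np.sqrt(n_null)
        iu = np.triu_indices(table.n_samples, 1)
        assert (np.abs(m1 - m2)[iu] <= 3 * np.sqrt(2) * se[iu] + 1e-12).all()


class TestRaupCrick:
    def test_identical_samples_minus_one(self):
        counts = np.array([[10, 10], [5, 5], [3, 3], [2, 2]])
        t = OtuTable(counts, list("abcd"), ["s1", "s2"])
        rc = raup_crick_bray(t, n_null=199, seed=0)
        assert rc[("s1", "s2")] == pytest.approx(-1.0, abs=0.02)

    def test_disjoint_samples_plus_one(self):
        rng = np.random.default_rng(1)
        n_taxa = 40
        counts = np.zeros((n_taxa, 6), dtype=int)
        # a large shared pool, but the two focal samples use disjoint halves
        counts[:20, 0] = rng.integers(1, 20, 20)
        counts[20:, 1] = rng.integers(1, 20, 20)
        counts[:, 2:] = rng.integers(1, 20, (n_taxa, 4))
        t = OtuTable(counts, [f"t{i}" for i in range(n_taxa)], [f"s{j}" for j in range(6)])
        rc = raup_crick_bray(t, n_null=199, seed=2)
        assert rc[("s0", "s1")] > 0.9

    def test_bounded(self):
        table, _ = simulate_neutral(50, 8, 500, Nm_true=100.0, seed=3)
        rc = raup_crick_bray(table, n_null=99, seed=4)
        assert (np.abs(rc.data) <= 1.0).all()

    def test_null_preserves_richness_and_totals(self):
        from comecol.assembly import _null_communities

        table, _ = simulate_neutral(30, 6, 300, Nm_true=100.0, seed=5)
        rng = np.random.default_rng(6)
        null = _null_communities(
            table.presence().sum(axis=0),
            table.sample_totals(),
            table.presence().sum(axis=1).astype(float),
            table.taxon_totals().astype(float),
            rng,
        )
        assert np.array_equal((null > 0).sum(axis=1), table.presence().sum(axis=0))
        assert np.array_equal(null.sum(axis=1), table.sample_totals())

    def test_bray_curtis_matches_brute(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, size=(5, 4))
        counts[counts.sum(axis=1) == 0, 0] += 1
        obs = squareform(pdist(counts.T.astype(float), metric="braycurtis"))
        for i in range(4):
            for j in range(i + 1, 4):
                assert obs[i, j] == pytest.approx(
                    bray_curtis_brute(counts[:, i], counts[:, j]), abs=1e-12
                )


class TestClassify:
    @pytest.mark.parametrize(
        "b,r,expected",
        [
            (2.5, 0.99, "HeS"),
            (-2.5, -0.99, "HoS"),
            (1.0, 0.97, "DL"),
            (0.0, -0.99, "HD"),
            (0.0, 0.2, "DR"),
            # boundary conventions: exactly +/-2 and +/-0.95 are not selection/dispersal
            (2.0, 0.0, "DR"),
            (-2.0, 0.0, "DR"),
            (0.0, 0.95, "DR"),
            (0.0, -0.95, "DR"),
            (2.0 + 1e-9, 0.0, "HeS"),
            (-2.0 - 1e-9, 0.0, "HoS"),
            (0.0, 0.95 + 1e-9, "DL"),
            (0.0, -0.95 - 1e-9, "HD"),
        ],
    )
    def test_thresholds(self, b, r, expected):
        bm = DistanceMatrix.unchecked(np.array([[0.0, b], [b, 0.0]]), ["x", "y"])
        rm = DistanceMatrix.unchecked(np.array([[0.0, r], [r, 0.0]]), ["x", "y"])
        res = classify_processes(bm, rm)
        assert res.pairs["process"][0] == expected
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_nan_pairs_excluded(self):
        data_b = np.array([[0, np.nan, 1.0], [np.nan, 0, 0.5], [1.0, 0.5, 0]])
        data_r = np.zeros((3, 3))
        bm = DistanceMatrix.unchecked(data_b, list("xyz"))
        rm = DistanceMatrix.unchecked(data_r, list("xyz"))
        res = classify_processes(bm, rm)
        assert res.n_excluded == 1
        assert sum(res.counts.values()) == 2

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        n = 8
        b = rng.normal(0, 3, (n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r = np.clip(rng.normal(0, 1, (n, n)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        ids = [f"s{i}" for i in range(n)]
        res = classify_processes(
            DistanceMatrix.unchecked(b, ids), DistanceMatrix.unchecked(r, ids)
        )
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-12)


class TestPnst:
    def test_neutral_above_half(self):
        tree = simulate_tree(100, seed=10)
        table, _ = simulate_neutral(100, 12, 2000, Nm_true=500.0, seed=11)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = pnst(table, tree, groups, n_null=199, seed=12)
        for v in res.group_pnst.values():
            assert 0.5 < v <= 1.0

    def test_strong_selection_below_half(self):
        tree = simulate_tree(200, seed=13)
        # groups mixing both environmental extremes: heterogeneous selection
        # inside each group drives stochasticity down
        env = np.array(([-3.0] * 5 + [3.0] * 5) * 2)
        table, _ = simulate_selection(
            tree, 20, 2000, niche_sd=0.3, seed=14, env_values=env,
            sample_noise_sd=1.0,
        )
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = pnst(table, tree, groups, n_null=199, seed=15)
        for v in res.group_pnst.values():
            assert v < 0.5

    def test_bounded(self):
        tree = simulate_tree(50, seed=16)
        table, _ = simulate_neutral(50, 9, 500, Nm_true=100.0, seed=17)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = pnst(table, tree, groups, n_null=99, seed=18)
        assert ((res.pair_stochasticity["mst"] >= 0) & (res.pair_stochasticity["mst"] <= 1)).all()
        for v in res.group_pnst.values():
            assert 0 <= v <= 1

    def test_small_group_rejected(self):
        tree = simulate_tree(30, seed=19)
        table, _ = simulate_neutral(30, 5, 300, Nm_true=100.0, seed=20)
        groups = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match="b"):
            pnst(table, tree, groups, n_null=99, seed=21)


class TestEndToEndRecovery:
    def test_neutral_scenario_stochastic_dominant(self):
        tree = simulate_tree(100, seed=22)
        table, _ = simulate_neutral(100, 12, 2000, Nm_true=500.0, seed=23)
        z = bnti(table, tree, n_null=199, seed=24)
        rc = raup_crick_bray(table, n_null=199, seed=25)
        res = classify_processes(z, rc)
        stochastic = res.fractions["DR"] + res.fractions["DL"] + res.fractions["HD"]
        assert stochastic > 0.7

    def test_selection_elevates_selected_fractions(self):
        tree = simulate_tree(100, seed=26)
        neutral_table, _ = simulate_neutral(100, 12, 2000, Nm_true=500.0, seed=27)
        sel_table, _ = simulate_selection(tree, 12, 2000, niche_sd=0.5, seed=28)
        out = {}
        for name, tab in [("neutral", neutral_table), ("selection", sel_table)]:
            z = bnti(tab, tree, n_null=199, seed=29)
            rc = raup_crick_bray(tab, n_null=199, seed=30)
            res = classify_processes(z, rc)
            out[name] = res.fractions
        sel = out["selection"]["HeS"] + out["selection"]["HoS"]
        neu = out["neutral"]["HeS"] + out["neutral"]["HoS"]
        assert sel > neu

    def test_dispersal_scenario_between_block_dl(self):
        table, meta = simulate_dispersal_limited(
            100, 2, 6, 2000, drift_strength=3.0, seed=31
        )
        labels = meta.groups(table, "block")
        rc = raup_crick_bray(table, n_null=199, seed=32)
        n = table.n_samples
        between = [
            rc.data[i, j]
            for i in range(n)
            for j in range(i + 1, n)
            if labels[i] != labels[j]
        ]
        within = [
            rc.data[i, j]
            for i in range(n)
            for j in range(i + 1, n)
            if labels[i] == labels[j]
        ]
        assert np.mean(np.asarray(between) > 0.95) > 0.5
        assert np.mean(np.asarray(within) < -0.95) > 0.5

    def test_homogenization_limit(self):
        table, _ = simulate_dispersal_limited(
            100, 2, 6, 2000, drift_strength=1e-3, seed=33
        )
        rc = raup_crick_bray(table, n_null=199, seed=34)
        iu = np.triu_indices(table.n_samples, 1)
        assert np.mean(rc.data[iu] < -0.95) > 0.5
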