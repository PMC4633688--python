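import numpy as np
import pytest
from scipy.stats import pearsonr

from nmfselect import nmf, sampling, screening
from nmfselect.dataset import ClinicalDataset
from nmfselect.exceptions import ConfigError, DegenerateInputError, ValidationError
from nmfselect.redundancy import (
    RedundancyGroups,
    RedundantGroup,
    assemble_subset,
    build_mixed_feature,
    combined_similarity,
    find_redundant_groups,
    sim_corr_matrix,
    sim_dist_matrix,
    similarity_matrices,
)
from nmfselect.synthetic import generate, paper_shape_preset


class TestSimDist:
    def test_hand_case(self):
        W = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        sd, max_d = sim_dist_matrix(W)
        assert max_d == pytest.approx(9.0)
        assert sd[0, 1] == pytest.approx(1 - 1 / 9)
        assert sd[0, 2] == pytest.approx(0.0)  # the MaxD pair
        assert np.allclose(np.diag(sd), 1.0)

    def test_identical_rows_give_one(self):
        W = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]])
        sd, _ = sim_dist_matrix(W)
        assert sd[0, 1] == pytest.approx(1.0)

    def test_degenerate_geometry(self):
        with pytest.raises(DegenerateInputError):
            sim_dist_matrix(np.ones((4, 3)))

    def test_loop_oracle(self, rng):
        W = rng.uniform(0, 2, size=(6, 4))
        sd, max_d = sim_dist_matrix(W)
        n = 6
        d2 = [[sum((W[i, k] - W[j, k]) ** 2 for k in range(4)) for j in range(n)]
              for i in range(n)]
        exp_max = max(d2[i][j] for i in range(n) for j in range(n))
        assert max_d == pytest.approx(exp_max, rel=1e-12)
        for i in range(n):
            for j in range(n):
                if i != j:
                    assert sd[i, j] == pytest.approx(1 - d2[i][j] / exp_max, abs=1e-12)


class TestSimCorr:
    def test_scalar_multiple(self):
        W = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [1.0, 0.0, 0.0]])
        sc = sim_corr_matrix(W)
        assert sc[0, 1] == pytest.approx(1.0)

    def test_reversal(self):
        W = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        sc = sim_corr_matrix(W)
        assert sc[0, 1] == pytest.approx(-1.0)

    def test_textbook_oracle(self):
        # note: these two rows are exactly uncorrelated
        a, b = [1.0, 0.0, 2.0], [0.0, 1.0, 1.0]
        sc = sim_corr_matrix(np.array([a, b]))
        assert sc[0, 1] == pytest.approx(pearsonr(a, b).statistic, abs=1e-12)
        assert sc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_random_oracle(self, rng):
        W = rng.uniform(0, 2, size=(5, 6))
        sc = sim_corr_matrix(W)
        for i in range(5):
            for j in range(i + 1, 5):
                assert sc[i, j] == pytest.approx(
                    pearsonr(W[i], W[j]).statistic, abs=1e-10
                )

    def test_constant_row_warns_and_nans(self):
        W = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        with pytest.warns(RuntimeWarning):
            sc = sim_corr_matrix(W)
        assert np.isnan(sc[0, 1]) and np.isnan(sc[1, 0])
        assert sc[0, 0] == 1.0
        assert not np.isnan(sc[1, 2])


class TestCombined:
    @pytest.mark.parametrize(
        "sd,sc,expected",
        [(1.0, 1.0, 1.0), (0.9672, 1.0, 0.9836), (0.5, -0.5, 0.0)],
    )
    def test_values(self, sd, sc, expected):
        out = combined_similarity(np.array([[sd]]), np.array([[sc]]))
        assert out[0, 0] == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            combined_similarity(np.ones((2, 2)), np.ones((3, 3)))

    def test_matrix_invariants(self, rng):
        W = rng.uniform(0, 2, size=(7, 4))
        sims = similarity_matrices(W, [f"V{i}" for i in range(7)])
        assert np.allclose(sims.smx, sims.smx.T)
        assert np.allclose(np.diag(sims.smx), 1.0)
        assert np.all(sims.sim_dist <= 1.0 + 1e-12)
        assert np.all(sims.sim_corr >= -1 - 1e-12) and np.all(sims.sim_corr <= 1 + 1e-12)


def _sims_for(W, ids=None):
    ids = ids or [f"V{i + 1}" for i in range(len(W))]
    return similarity_matrices(np.asarray(W, dtype=float), ids)


def _pairs(groups):
    out = set()
    for g in groups:
        for i, a in enumerate(g.members):
            for b in g.members[i + 1:]:
                out.add(frozenset((a, b)))
    return out


class TestGrouping:
    def test_chain_forms_single_group(self):
        # a-b and b-c close, a-c merged transitively
        W = np.array([[1.0, 0.0], [1.05, 0.0], [1.10, 0.0], [0.0, 5.0]])
        sims = _sims_for(W)
        groups = find_redundant_groups(sims, np.zeros(4, dtype=int), 0.95,
                                       same_basis=False)
        assert len(groups) == 1
        assert groups.groups[0].members == ["V1", "V2", "V3"]

    def test_no_pairs_above_theta(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 3.0]])
        sims = _sims_for(W)
        groups = find_redundant_groups(sims, np.zeros(3, dtype=int), 0.99,
                                       same_basis=False)
        assert len(groups) == 0

    def test_planted_duplicates_with_noise(self, rng):
        base = rng.uniform(0.5, 2.0, size=(8, 3))
        W = np.vstack([base, base[2] * 1.01, base[2] * 0.99])
        ids = [f"V{i + 1}" for i in range(10)]
        sims = _sims_for(W, ids)
        groups = find_redundant_groups(sims, np.zeros(10, dtype=int), 0.95,
                                       same_basis=False)
        planted = {frozenset(p) for p in (("V3", "V9"), ("V3", "V10"), ("V9", "V10"))}
        # brute-force oracle: edges by dual rule, components by closure
        sd, sc = sims.sim_dist, sims.sim_corr
        import itertools
        adj = {i: set() for i in range(10)}
        for i, j in itertools.combinations(range(10), 2):
            if sd[i, j] >= 0.95 and sc[i, j] >= 0.95:
                adj[i].add(j)
                adj[j].add(i)
        seen, comps = set(), []
        for i in range(10):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k])
            seen |= comp
            if len(comp) >= 2:
                comps.append({ids[k] for k in comp})
        assert [set(g.members) for g in groups] == sorted(comps, key=min)
        assert _pairs(groups) == planted

    def test_same_basis_constraint(self):
        W = np.array([[1.0, 0.0], [1.01, 0.0], [0.0, 9.0]])
        sims = _sims_for(W)
        both = find_redundant_groups(sims, np.array([0, 1, 1]), 0.95)
        assert len(both) == 0  # near-identical rows split across bases
        free = find_redundant_groups(sims, np.array([0, 1, 1]), 0.95, same_basis=False)
        assert len(free) == 1

    def test_smx_rule(self):
        W = np.array([[1.0, 0.0], [1.01, 0.0], [0.0, 9.0]])
        sims = _sims_for(W)
        groups = find_redundant_groups(sims, np.zeros(3, dtype=int), 0.9,
                                       rule="smx", same_basis=False)
        assert _pairs(groups) == {frozenset(("V1", "V2"))}

    def test_theta_monotonicity(self, rng):
        W = rng.uniform(0, 2, size=(12, 3))
        sims = _sims_for(W)
        for t1, t2 in [(0.5, 0.7), (0.7, 0.9), (0.9, 0.97)]:
            g1 = find_redundant_groups(sims, np.zeros(12, int), t1, same_basis=False)
            g2 = find_redundant_groups(sims, np.zeros(12, int), t2, same_basis=False)
            for high in g2:
                assert any(set(high.members) <= set(low.members) for low in g1)

    def test_mixed_ids_per_basis_scheme(self):
        W = np.array(
            [[1.0, 0.0], [1.001, 0.0], [5.0, 0.0], [5.005, 0.0],
             [0.0, 3.0], [0.0, 3.003], [9.0, 11.0]]
        )
        sims = _sims_for(W)
        groups = find_redundant_groups(sims, nmf.assign_feature_basis(W), 0.95)
        assert [g.mixed_id for g in groups] == ["M11", "M12", "M21"]

    def test_theta_validation(self):
        sims = _sims_for(np.array([[1.0, 0.0], [0.0, 1.0]]))
        for theta in (0.0, 1.0, -1.0):
            with pytest.raises(ConfigError):
                find_redundant_groups(sims, np.zeros(2, int), theta)

    def test_group_mean_similarities(self):
        W = np.array([[1.0, 0.0], [1.01, 0.0], [0.99, 0.0], [0.0, 9.0]])
        sims = _sims_for(W)
        g = find_redundant_groups(sims, np.zeros(4, int), 0.95, same_basis=False).groups[0]
        idx = [0, 1, 2]
        exp_sd = np.mean([sims.sim_dist[i, j] for k, i in enumerate(idx) for j in idx[k + 1:]])
        exp_sc = np.mean([sims.sim_corr[i, j] for k, i in enumerate(idx) for j in idx[k + 1:]])
        assert g.mean_sim_dist == pytest.approx(exp_sd)
        assert g.mean_sim_corr == pytest.approx(exp_sc)


def _dataset(n_features, p=4, seed=0):
    rng = np.random.default_rng(seed)
    return ClinicalDataset(
        values=rng.integers(0, 4, size=(p, n_features)),
        symptom_ids=[f"V{j + 1}" for j in range(n_features)],
        sample_ids=[f"s{i}" for i in range(p)],
        stage=np.ones(p, dtype=int),
    )


class TestMixedFeature:
    def test_mean_of_two_columns(self):
        ds = ClinicalDataset(
            values=np.array([[0, 2], [2, 0], [4, 4]]),
            symptom_ids=["V1", "V2"],
            sample_ids=["a", "b", "c"],
            stage=np.array([1, 1, 1]),
        )
        vec, mid = build_mixed_feature(ds, ["V1", "V2"], "mean", mixed_id="M11")
        assert np.allclose(vec, [1, 1, 4])
        assert mid == "M11"

    def test_representative_is_member(self):
        ds = _dataset(3, p=6, seed=1)
        vec, _ = build_mixed_feature(ds, ["V1", "V3"], "representative", seed=9)
        assert any(np.array_equal(vec, ds.column(g)) for g in ("V1", "V3"))

    def test_mean_loop_oracle(self):
        ds = _dataset(4, p=5, seed=2)
        group = ["V1", "V2", "V4"]
        vec, _ = build_mixed_feature(ds, group, "mean")
        for i in range(5):
            assert vec[i] == pytest.approx(
                sum(ds.column(g)[i] for g in group) / 3
            )

    def test_unknown_strategy(self):
        ds = _dataset(2)
        with pytest.raises(ConfigError):
            build_mixed_feature(ds, ["V1", "V2"], "median")

    def test_group_too_small(self):
        ds = _dataset(2)
        with pytest.raises(ValidationError):
            build_mixed_feature(ds, ["V1"], "mean")


def _groups(member_lists, bases):
    groups = []
    counters = {}
    for members, b in zip(member_lists, bases):
        counters[b] = counters.get(b, 0) + 1
        groups.append(
            RedundantGroup(
                members=members, basis=b, mean_sim_dist=1.0, mean_sim_corr=1.0,
                mixed_id=f"M{b + 1}{counters[b]}",
            )
        )
    return RedundancyGroups(groups=groups)


class TestAssembleSubset:
    def test_table_shaped_counts(self):
        # 49 features, six groups of sizes 3/2/2/5/2/2 -> 33 kept + 6 mixed = 39
        ds = _dataset(49, p=10)
        ids = ds.symptom_ids
        member_lists = [
            ids[0:3], ids[3:5], ids[5:7], ids[7:12], ids[12:14], ids[14:16]
        ]
        groups = _groups(member_lists, [0, 0, 1, 1, 2, 2])
        subset = assemble_subset(ds, groups)
        assert len(subset.kept_ids) == 33
        assert len(subset.mixed_ids) == 6
        assert len(subset.feature_ids) == 39
        assert subset.values.shape == (10, 39)

    def test_empty_groups_identity(self):
        ds = _dataset(5, p=4)
        subset = assemble_subset(ds, RedundancyGroups())
        assert subset.feature_ids == ds.symptom_ids
        assert np.allclose(subset.values, ds.values)

    def test_hand_case_five_features(self):
        ds = _dataset(5, p=4, seed=3)
        groups = _groups([["V2", "V4"]], [0])
        subset = assemble_subset(ds, groups)
        assert subset.feature_ids == ["V1", "V3", "V5", "M11"]
        assert np.allclose(
            subset.values[:, 3], (ds.column("V2") + ds.column("V4")) / 2
        )

    def test_overlapping_groups_rejected(self):
        ds = _dataset(5)
        groups = _groups([["V1", "V2"], ["V2", "V3"]], [0, 0])
        with pytest.raises(ValidationError):
            assemble_subset(ds, groups)

    def test_count_invariant(self):
        ds = _dataset(20, p=6)
        groups = _groups([["V1", "V2", "V3"], ["V5", "V9"]], [0, 1])
        subset = assemble_subset(ds, groups)
        n_grouped = 5
        assert len(subset.feature_ids) == 20 - n_grouped + 2

    def test_transform_other_dataset(self):
        train = _dataset(6, p=8, seed=4)
        test = _dataset(6, p=5, seed=5)
        groups = _groups([["V1", "V6"]], [0])
        subset = assemble_subset(train, groups)
        out = subset.transform(test)
        assert out.shape == (5, 5)
        assert np.allclose(out[:, -1], (test.column("V1") + test.column("V6")) / 2)

    def test_transform_representative_uses_stored_member(self):
        train = _dataset(6, p=8, seed=4)
        test = _dataset(6, p=5, seed=5)
        groups = _groups([["V1", "V6"]], [0])
        subset = assemble_subset(train, groups, strategy="representative", seed=3)
        pick = subset.representative_choice["M11"]
        out = subset.transform(test)
        assert np.allclose(out[:, -1], test.column(pick))

    def test_transform_missing_column(self):
        train = _dataset(6, p=8)
        test = _dataset(4, p=5)
        groups = _groups([["V1", "V6"]], [0])
        subset = assemble_subset(train, groups)
        with pytest.raises(ValidationError):
            subset.transform(test)


class TestPlantedRecovery:
    def test_exact_duplicate_limit(self):
        # duplicated columns (zero noise) -> basis rows similar above 0.999
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0.5, 2.0, size=(8, 3))
        W0 = np.vstack([W0, W0[0]])
        H0 = rng.uniform(0.2, 2.0, size=(3, 30))
        X = W0 @ H0
        fac = nmf.factorize(X, nmf.NMFConfig(rank=3, max_iter=2000, tol=1e-10, seed=1))
        sims = similarity_matrices(fac.W, [f"V{i}" for i in range(9)])
        assert sims.sim_dist[0, 8] >= 0.999
        assert sims.sim_corr[0, 8] >= 0.999

    def test_pipeline_recovery_on_preset(self):
        # copies with flip noise 0.02; NMF at the generator's latent rank
        precs, recs = [], []
        for seed in range(10):
            ds, truth = generate(paper_shape_preset(seed=seed))
            ft = screening.positive_frequencies(ds)
            scr = screening.remove_features(ds, screening.find_irrelevant(ft, 0.10))
            rep = sampling.select_representatives(
                scr, 40, balance="sex", ratio={0: 20, 1: 20}
            )
            X = rep.subset.values.T.astype(float)
            best, best_obj = None, np.inf
            for k in range(8):
                fac = nmf.factorize(
                    X, nmf.NMFConfig(rank=6, max_iter=1500, seed=100 * seed + k)
                )
                if fac.objective_trace[-1] < best_obj:
                    best_obj, best = fac.objective_trace[-1], fac
            sims = similarity_matrices(best.W, scr.symptom_ids)
            basis = nmf.assign_feature_basis(best.W)
            groups = find_redundant_groups(sims, basis, 0.95)
            found = _pairs(groups)
            truth_pairs = truth.redundant_pairs
            tp = len(found & truth_pairs)
            precs.append(tp / max(1, len(found)))
            recs.append(tp / len(truth_pairs))
        assert np.mean(precs) >= 0.9
        assert np.mean(recs) >= 0.9
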