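"""Voxel-wise GLM, cluster forming, and permutation cluster-FWE inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metalesion import (
    CohortStack,
    GLMDesign,
    GreyMatterMask,
    ScoreTable,
    build_design,
    cluster_forming,
    fit_glm,
    peak_table,
    permutation_cluster_fwe,
)
from metalesion.massuni import T_SENTINEL, LesionDeficitModel


def design_from_matrix(X, names=None, score_index=-1):
    X = np.asarray(X, dtype=float)
    names = names or [f"c{j}" for j in range(X.shape[1])]
    si = score_index % X.shape[1]
    return GLMDesign(X=X, column_names=names, score_index=si, score_name=names[si])


def stack_from(data, shape=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if shape is None:
        shape = (data.shape[1], 1, 1)
    grid = np.ones(shape, dtype=bool)
    mask = GreyMatterMask(grid, np.eye(4), 1.0)
    return CohortStack(data, [f"s{i}" for i in range(data.shape[0])], mask)


def ols_oracle(X, y, c_idx):
    """Normal-equations oracle: beta, se, t for one coefficient."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[c_idx, c_idx])
    return beta[c_idx], se, beta[c_idx] / se


class TestGLM:
    def test_tiny_worked_case_matches_hand_normal_equations(self):
        """n=6, intercept + score: solved by hand via the normal equations."""
        score = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8, 12.2])
        X = np.column_stack([np.ones(6), score])
        pos, _ = fit_glm(stack_from(y[:, None]), design_from_matrix(X))
        b, se, t = ols_oracle(X, y, 1)
        assert pos.beta[0] == pytest.approx(b, abs=1e-10)
        assert pos.se[0] == pytest.approx(se, abs=1e-10)
        assert pos.t[0] == pytest.approx(t, abs=1e-10)
        assert pos.df == 4

    def test_random_designs_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, p, v = 20, 4, 6
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            Y = rng.standard_normal((n, v))
            design = design_from_matrix(X)
            pos, neg = fit_glm(stack_from(Y), design)
            for j in range(v):
                b, se, t = ols_oracle(X, Y[:, j], p - 1)
                assert pos.beta[j] == pytest.approx(b, abs=1e-8)
                assert pos.se[j] == pytest.approx(se, abs=1e-8)
                assert pos.t[j] == pytest.approx(t, abs=1e-8)
            assert np.array_equal(pos.t, neg.t)  # shared statistics

    def test_null_t_follows_student_distribution(self):
        rng = np.random.default_rng(1)
        n, v = 40, 4000
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        Y = rng.standard_normal((n, v))
        pos, _ = fit_glm(stack_from(Y, (v, 1, 1)), design_from_matrix(X))
        ks = stats.kstest(pos.t, stats.t(df=n - 3).cdf)
        assert ks.pvalue > 0.01

    def test_perfect_fit_reports_capped_sentinel(self):
        score = np.linspace(-1, 1, 10)
        X = np.column_stack([np.ones(10), score])
        Y = np.column_stack([3.0 * score, np.random.default_rng(2).standard_normal(10)])
        pos, _ = fit_glm(stack_from(Y), design_from_matrix(X))
        assert pos.perfect_fit[0] and not pos.perfect_fit[1]
        assert pos.t[0] == T_SENTINEL

    def test_zero_variance_voxel_flagged_undefined(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        Y = np.column_stack([np.full(12, 5.0), rng.standard_normal(12)])
        pos, _ = fit_glm(stack_from(Y), design_from_matrix(X))
        assert pos.undefined[0] and not pos.undefined[1]
        assert np.isnan(pos.t[0])

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(ValueError, match="rank deficient"):
            design_from_matrix(X)

    def test_higher_is_worse_score_sign_flipped_in_design(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame({"hads_depression": rng.random(10)})
        scores = ScoreTable(vals, {"hads_depression": True})
        conf = pd.DataFrame(index=range(10))
        design = build_design(scores, "hads_depression", conf)
        assert np.allclose(
            design.score_column(), -vals["hads_depression"].to_numpy()
        )


def flood_fill_oracle(grid):
    """Brute-force BFS 6-connected labelling oracle."""
    labels = np.zeros(grid.shape, dtype=int)
    current = 0
    for start in np.argwhere(grid):
        if labels[tuple(start)]:
            continue
        current += 1
        queue = [tuple(start)]
        labels[tuple(start)] = current
        while queue:
            i, j, k = queue.pop()
            for di, dj, dk in [(1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)]:
                ni, nj, nk = i+di, j+dj, k+dk
                if (0 <= ni < grid.shape[0] and 0 <= nj < grid.shape[1]
                        and 0 <= nk < grid.shape[2] and grid[ni,nj,nk]
                        and not labels[ni,nj,nk]):
                    labels[ni,nj,nk] = current
                    queue.append((ni,nj,nk))
    return labels


class TestClusterForming:
    def _statmap(self, t_grid, df=20):
        from metalesion.massuni import StatMap

        grid = np.ones(t_grid.shape, dtype=bool)
        mask = GreyMatterMask(grid, np.eye(4), 1.0)
        t = t_grid.ravel()
        return StatMap(
            beta=t.copy(), se=np.ones_like(t), t=t, df=df, direction="positive",
            undefined=np.zeros(t.size, bool), perfect_fit=np.zeros(t.size, bool),
            mask=mask,
        )

    def test_single_suprathreshold_voxel_single_cluster(self):
        t_grid = np.zeros((3, 3, 3))
        t_grid[1, 1, 1] = 10.0
        labels = cluster_forming(self._statmap(t_grid), 1e-4)
        assert labels.max() == 1 and labels[1, 1, 1] == 1

    def test_face_neighbours_merge_edge_neighbours_do_not(self):
        t_grid = np.zeros((4, 4, 4))
        t_grid[1, 1, 1] = t_grid[2, 1, 1] = 10.0  # share a face
        labels = cluster_forming(self._statmap(t_grid), 1e-4)
        assert labels.max() == 1
        t_grid = np.zeros((4, 4, 4))
        t_grid[1, 1, 1] = t_grid[2, 2, 1] = 10.0  # share only an edge
        labels = cluster_forming(self._statmap(t_grid), 1e-4)
        assert labels.max() == 2

    def test_random_map_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        t_grid = rng.standard_normal((6, 6, 6)) * 3
        statmap = self._statmap(t_grid)
        labels = cluster_forming(statmap, 0.01)
        t_star = stats.t.ppf(0.99, statmap.df)
        oracle = flood_fill_oracle(t_grid >= t_star)
        # same partition (label ids may differ)
        assert (labels > 0).sum() == (oracle > 0).sum()
        for lab in range(1, labels.max() + 1):
            members = labels == lab
            oracle_ids = np.unique(oracle[members])
            assert len(oracle_ids) == 1 and oracle_ids[0] != 0

    def test_lower_threshold_never_shrinks_clusters(self):
        rng = np.random.default_rng(6)
        t_grid = rng.standard_normal((5, 5, 5)) * 2.5
        statmap = self._statmap(t_grid)
        strict = cluster_forming(statmap, 1e-4)
        loose = cluster_forming(statmap, 1e-2)
        assert ((strict > 0) & ~(loose > 0)).sum() == 0

    def test_no_suprathreshold_voxels_empty_labelling(self):
        labels = cluster_forming(self._statmap(np.zeros((3, 3, 3))), 1e-4)
        assert labels.max() == 0


def make_effect_cohort(n=60, seed=0, effect=0.0):
    """Small cohort: 5x5x5 grid, optional implanted score effect in a corner."""
    rng = np.random.default_rng(seed)
    v = 125
    score = rng.standard_normal(n)
    age = rng.normal(40, 10, n)
    Y = rng.standard_normal((n, v)) + 0.3 * age[:, None] / 10
    region = np.zeros(v, dtype=bool)
    region[:8] = True  # a 2x2x2 face-connected corner block in C order
    region_grid = np.zeros((5, 5, 5), dtype=bool)
    region_grid[:2, :2, :2] = True
    region = region_grid.ravel()
    Y[:, region] += effect * score[:, None]
    stack = stack_from(Y, (5, 5, 5))
    scores = ScoreTable(pd.DataFrame({"s": score}, index=stack.subject_ids))
    conf = pd.DataFrame({"age": age}, index=stack.subject_ids)
    return stack, scores, conf, region


class TestPermutationFWE:
    def test_implanted_effect_detected_with_valid_p(self):
        stack, scores, conf, region = make_effect_cohort(seed=7, effect=1.2)
        design = build_design(scores, "s", conf)
        clusters = permutation_cluster_fwe(
            stack, design, p_uncorrected=1e-3, n_perm=200, seed=1
        )
        sig = clusters.significant()
        assert len(sig) >= 1
        assert sig.iloc[0]["direction"] == "positive"
        # extreme rank: observed beats every permutation maximum
        assert sig.iloc[0]["p_fwe"] == pytest.approx(1 / 201)

    def test_reproducible_given_seed(self):
        stack, scores, conf, _ = make_effect_cohort(seed=8, effect=0.8)
        design = build_design(scores, "s", conf)
        a = permutation_cluster_fwe(stack, design, n_perm=150, seed=3)
        b = permutation_cluster_fwe(stack, design, n_perm=150, seed=3)
        assert a.table.equals(b.table)

    def test_sign_equivariance_swaps_tails(self):
        stack, scores, conf, _ = make_effect_cohort(seed=9, effect=1.0)
        design = build_design(scores, "s", conf)
        flipped = ScoreTable(-scores.values)
        design_f = build_design(flipped, "s", conf)
        a = permutation_cluster_fwe(stack, design, p_uncorrected=1e-3, n_perm=120, seed=4)
        b = permutation_cluster_fwe(stack, design_f, p_uncorrected=1e-3, n_perm=120, seed=4)
        pos_a = a.table[a.table.direction == "positive"].drop(columns="direction")
        neg_b = b.table[b.table.direction == "negative"].drop(columns="direction")
        pd.testing.assert_frame_equal(
            pos_a.reset_index(drop=True), neg_b.reset_index(drop=True)
        )

    def test_p_values_respect_resolution_floor(self):
        stack, scores, conf, _ = make_effect_cohort(seed=10, effect=1.5)
        design = build_design(scores, "s", conf)
        clusters = permutation_cluster_fwe(stack, design, n_perm=100, seed=5)
        if len(clusters.table):
            assert (clusters.table["p_fwe"] >= 1 / 101 - 1e-12).all()

    def test_too_few_permutations_rejected(self):
        stack, scores, conf, _ = make_effect_cohort(seed=11)
        design = build_design(scores, "s", conf)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_cluster_fwe(stack, design, n_perm=50, seed=0)


class TestPeaks:
    def test_single_voxel_cluster_peak_is_that_voxel(self):
        stack, scores, conf, _ = make_effect_cohort(seed=12, effect=1.5)
        design = build_design(scores, "s", conf)
        clusters = permutation_cluster_fwe(stack, design, n_perm=100, seed=6)
        for i in range(len(clusters.table)):
            if clusters.table.iloc[i]["size"] == 1:
                members = clusters.voxel_lists[i]
                coords = stack.mask.coordinates()[members[0]]
                assert clusters.table.iloc[i]["peak_i"] == coords[0]

    def test_peak_tie_breaks_to_lowest_linear_index(self):
        from metalesion.massuni import StatMap, _assemble_cluster_frame

        grid = np.ones((2, 1, 1), dtype=bool)
        mask = GreyMatterMask(grid, np.eye(4), 1.0)
        rows = [{
            "direction": "positive", "size": 2, "p_fwe": 0.5,
            "p_uncorrected_cluster": 0.5,
            "_members": np.array([0, 1]), "_tail_t": np.array([4.0, 4.0]),
        }]
        frame = _assemble_cluster_frame(rows, mask, None, None)
        assert frame.iloc[0]["peak_i"] == 0

    def test_world_coordinates_through_affine(self):
        stack, scores, conf, _ = make_effect_cohort(seed=13, effect=1.5)
        # non-trivial affine: 3 mm voxels with an offset
        stack.mask.affine = np.diag([3.0, 3.0, 3.0, 1.0])
        stack.mask.affine[:3, 3] = [-10.0, 5.0, 0.0]
        design = build_design(scores, "s", conf)
        clusters = permutation_cluster_fwe(stack, design, n_perm=100, seed=7)
        for i in range(len(clusters.table)):
            row = clusters.table.iloc[i]
            assert row["peak_x_mm"] == pytest.approx(row["peak_i"] * 3.0 - 10.0)

    def test_label_volume_mismatch_rejected(self):
        stack, scores, conf, _ = make_effect_cohort(seed=14, effect=1.5)
        design = build_design(scores, "s", conf)
        with pytest.raises(ValueError, match="label volume"):
            permutation_cluster_fwe(
                stack, design, n_perm=100, seed=8,
                label_volume=np.zeros((2, 2, 2), dtype=int),
            )


def test_model_results_summary_runs(default_cohort, default_confounds):
    stack, scores, truth = default_cohort
    from metalesion import fit_ppca

    completed = fit_ppca(scores, k=3).impute(scores)
    model = LesionDeficitModel(stack, completed, "verbal_iq", default_confounds)
    res = model.fit(n_perm=120, seed=1)
    text = res.summary()
    assert "verbal_iq" in text and "clusters" in text
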