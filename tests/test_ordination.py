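"""Proximity ordination, environmental vector fitting, rank correlations."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from microtnt.forest import ProximityMatrix
from microtnt.io_model import ValidationError
from microtnt.ordination import (
    fit_environment_vectors,
    ordinate_from_proximity,
    spearman_correlation_cluster,
)


def _proximity(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return ProximityMatrix(values, ids)


def _block_proximity(n_per_block=5, within=0.9, between=0.1):
    n = 2 * n_per_block
    P = np.full((n, n), between)
    P[:n_per_block, :n_per_block] = within
    P[n_per_block:, n_per_block:] = within
    np.fill_diagonal(P, 1.0)
    return _proximity(P)


class TestOrdination:
    def test_identical_samples_coincide(self):
        P = _proximity([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        result = ordinate_from_proximity(P)
        assert np.allclose(
            result.scores.iloc[0].to_numpy(), result.scores.iloc[1].to_numpy(), atol=1e-8
        )

    def test_axis1_separates_two_blocks(self):
        result = ordinate_from_proximity(_block_proximity())
        pc1 = result.scores["PC1"].to_numpy()
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()  # blocks on opposite sides
        assert np.sign(pc1[:5]).std() == 0 and np.sign(pc1[5:]).std() == 0

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.uniform(0.0, 1.0, (8, 8))
            P = (A + A.T) / 2
            np.fill_diagonal(P, 1.0)
            result = ordinate_from_proximity(_proximity(P), n_axes=4)
            ex = result.explained.to_numpy()
            assert (np.diff(ex) <= 1e-9).all()
            assert ex.sum() <= 1 + 1e-9

    def test_inter_point_distances_recover_dissimilarity_structure(self):
        # rotation/sign indeterminacy: compare distances, not coordinates
        result = ordinate_from_proximity(_block_proximity(), n_axes=2)
        d = pdist(result.scores.to_numpy())
        # 2 blocks: within-block pair distances must all be smaller than
        # between-block ones
        labels = [0] * 5 + [1] * 5
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        within = [dist for dist, (i, j) in zip(d, pairs) if labels[i] == labels[j]]
        between = [dist for dist, (i, j) in zip(d, pairs) if labels[i] != labels[j]]
        assert max(within) < min(between)

    def test_identity_proximity_degenerates_gracefully(self):
        # a forest that always separates all samples: P = I
        P = _proximity(np.eye(6))
        result = ordinate_from_proximity(P, n_axes=2)
        assert np.isfinite(result.scores.to_numpy()).all()
        assert np.allclose(result.explained, result.explained.iloc[0], atol=1e-9)

    def test_requested_axes_beyond_rank_truncated(self):
        P = _proximity([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        with pytest.warns(UserWarning, match="rank"):
            result = ordinate_from_proximity(P, n_axes=3)
        assert result.scores.shape[1] < 3

    def test_sign_convention_deterministic(self):
        result = ordinate_from_proximity(_block_proximity())
        anchor = result.scores.index[0]  # lexicographically smallest id
        assert result.scores.loc[anchor, "PC1"] >= 0


class TestEnvfit:
    def _ordination(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, (n, n))
        P = (A + A.T) / 2
        np.fill_diagonal(P, 1.0)
        return ordinate_from_proximity(_proximity(P))

    def test_axis_aligned_variable_fits_perfectly(self):
        ordn = self._ordination()
        env = pd.DataFrame({"v": ordn.scores["PC1"]}, index=ordn.scores.index)
        fit = fit_environment_vectors(ordn, env, n_perm=99, seed=1)
        assert fit.table.loc["v", "r2"] == pytest.approx(1.0, abs=1e-10)
        assert fit.table.loc["v", "p_value"] == pytest.approx(1 / 100)

    def test_constant_variable_flagged_inert(self):
        ordn = self._ordination()
        env = pd.DataFrame({"c": 3.0}, index=ordn.scores.index)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_environment_vectors(ordn, env, n_perm=49, seed=2)
        assert fit.table.loc["c", "r2"] == 0.0
        assert fit.table.loc["c", "p_value"] == 1.0

    def test_null_variable_p_values_spread_uniformly(self):
        ordn = self._ordination(n=40, seed=3)
        rng = np.random.default_rng(4)
        pvals = []
        for k in range(60):
            env = pd.DataFrame(
                {"noise": rng.normal(size=40)}, index=ordn.scores.index
            )
            fit = fit_environment_vectors(ordn, env, n_perm=199, seed=int(rng.integers(2**31 - 1)))
            pvals.append(fit.table.loc["noise", "p_value"])
        pvals = np.asarray(pvals)
        assert 0.25 < pvals.mean() < 0.75
        assert (pvals < 0.05).mean() < 0.15

    def test_display_rule_filters_on_p_and_r2(self):
        ordn = self._ordination()
        rng = np.random.default_rng(5)
        env = pd.DataFrame(
            {
                "strong": ordn.scores["PC1"] + rng.normal(0, 0.05, 30) * ordn.scores["PC1"].std(),
                "noise": rng.normal(size=30),
            },
            index=ordn.scores.index,
        )
        fit = fit_environment_vectors(ordn, env, n_perm=1999, seed=6)
        shown = fit.significant(p_cutoff=0.001, r2_cutoff=0.3)
        assert "strong" in shown.index
        assert "noise" not in shown.index

    def test_direction_cosines_unit_length(self):
        ordn = self._ordination()
        rng = np.random.default_rng(7)
        env = pd.DataFrame({"v": rng.normal(size=30)}, index=ordn.scores.index)
        fit = fit_environment_vectors(ordn, env, n_perm=49, seed=8)
        assert np.hypot(fit.table.loc["v", "axis1"], fit.table.loc["v", "axis2"]) == pytest.approx(1.0)

    def test_matches_vegan_envfit_r2(self, tmp_path):
        """Independent oracle: vegan's envfit on the same scores and variable."""
        ordn = self._ordination(n=25, seed=9)
        rng = np.random.default_rng(10)
        env = pd.DataFrame(
            {"v1": rng.normal(size=25), "v2": ordn.scores["PC2"] + rng.normal(0, 0.1, 25)},
            index=ordn.scores.index,
        )
        fit = fit_environment_vectors(ordn, env, n_perm=99, seed=11)
        scores_path = tmp_path / "scores.tsv"
        env_path = tmp_path / "env.tsv"
        out_path = tmp_path / "r2.tsv"
        ordn.scores.to_csv(scores_path, sep="\t")
        env.to_csv(env_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            scores <- as.matrix(read.delim("{scores_path}", row.names = 1))
            env <- read.delim("{env_path}", row.names = 1)
            fit <- envfit(scores, env, permutations = 99)
            write.table(data.frame(variable = names(fit$vectors$r),
                                   r2 = fit$vectors$r),
                        "{out_path}", sep = "\t", row.names = FALSE)
        """)
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        vegan = pd.read_csv(out_path, sep="\t").set_index("variable")
        for var in env.columns:
            assert fit.table.loc[var, "r2"] == pytest.approx(
                vegan.loc[var, "r2"], abs=1e-6
            )


class TestSpearmanCluster:
    def _env(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return pd.DataFrame(
            {
                "x": x,
                "expx": np.exp(x),  # monotone transform
                "noise": rng.normal(size=n),
                "mud": rng.uniform(0, 100, n),
            },
            index=[f"s{i:03d}" for i in range(n)],
        )

    def test_self_correlation_is_one(self):
        result = spearman_correlation_cluster(self._env())
        assert result.rho.loc["x", "x"] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        result = spearman_correlation_cluster(self._env())
        assert result.rho.loc["x", "expx"] == pytest.approx(1.0)

    def test_independent_columns_weakly_correlated(self):
        rng = np.random.default_rng(1)
        hits = 0
        for k in range(20):
            env = pd.DataFrame(
                rng.normal(size=(150, 2)), columns=["a", "b"]
            )
            result = spearman_correlation_cluster(env)
            if abs(result.rho.loc["a", "b"]) < 0.3:
                hits += 1
        assert hits >= 19

    def test_zero_variance_column_flagged_na(self):
        env = self._env(n=20)
        env["flat"] = 1.0
        result = spearman_correlation_cluster(env)
        assert np.isnan(result.rho.loc["flat", "x"])
        assert not result.significant.loc["flat", "x"]

    def test_significance_flags_and_ordering(self):
        result = spearman_correlation_cluster(self._env(), p_flag=0.01)
        assert bool(result.significant.loc["x", "expx"])
        assert sorted(result.order) == sorted(result.rho.columns)
        # correlated pair should be adjacent in the hierarchical ordering
        ix, iexp = result.order.index("x"), result.order.index("expx")
        assert abs(ix - iexp) == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            spearman_correlation_cluster(self._env(n=2))
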