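"""Correlation, PCA with varimax rotation, and Ward variable clustering."""

import numpy as np
import pandas as pd
import pytest

from hydrochem.errors import UndefinedQuantityError, ValidationError
from hydrochem.multivariate import (
    hca_ward,
    pca_varimax,
    pearson_matrix,
    varimax,
    zscore_table,
)
from hydrochem.samples import samples_to_frame
from hydrochem.synthetic import CampaignConfig, DEFAULT_CV, _FIXTURE_ROWS, generate_campaign


def campaign_table(config, columns):
    frame = samples_to_frame(generate_campaign(config))
    return frame[list(columns)].astype(float)


def block_config(blocks: dict[str, tuple[str, ...]], loading=0.9, seed=2):
    """Campaign config with disjoint planted latent factors and no
    electroneutrality coupling (it would re-tie HCO3 to the cations)."""
    loadings = {name: {p: loading for p in params} for name, params in blocks.items()}
    return CampaignConfig(seed=seed, loadings=loadings, balance_adjust=False)


class TestZscore:
    def test_simple_column(self):
        z = zscore_table(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert z["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = zscore_table(pd.DataFrame(rng.normal(5, 3, size=(40, 4))))
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        base = pd.DataFrame({"a": [1.0, 4.0, 2.0, 8.0]})
        assert np.allclose(zscore_table(base * 10.0), zscore_table(base))

    def test_constant_column_names_the_variable(self):
        with pytest.raises(ValidationError, match="flat"):
            zscore_table(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestPearson:
    def test_duplicated_column_has_r_one(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 5.0, 3.0], "b": [1.0, 2.0, 5.0, 3.0]})
        c = pearson_matrix(t)
        assert c.r.loc["a", "b"] == pytest.approx(1.0)
        assert c.sig.loc["a", "b"] == "**"

    def test_constructed_anticorrelation(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 3.0, 2.0, 1.0]})
        assert pearson_matrix(t).r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        c = pearson_matrix(t)
        z = zscore_table(t)
        for i in t.columns:
            for j in t.columns:
                brute = float((z[i] * z[j]).sum() / (len(t) - 1))
                assert c.r.loc[i, j] == pytest.approx(min(max(brute, -1), 1), abs=1e-12)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(5)
        c = pearson_matrix(pd.DataFrame(rng.normal(size=(9, 4))))
        assert np.allclose(c.r, c.r.T)
        assert np.allclose(np.diag(c.r), 1.0)

    def test_needs_three_samples(self):
        with pytest.raises(UndefinedQuantityError):
            pearson_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))

    def test_na_cl_association_on_fixture_site_means(self):
        t = pd.DataFrame({"Na": _FIXTURE_ROWS["Na"], "Cl": _FIXTURE_ROWS["Cl"]})
        r = pearson_matrix(t).r.loc["Na", "Cl"]
        assert r == pytest.approx(0.95, abs=0.01)


class TestPca:
    def test_analytic_spectrum_of_duplicated_variable(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        y = pd.Series([1.0, -1.0, -1.0, 1.0])  # exactly uncorrelated with x
        t = pd.DataFrame({"a": x, "b": 2 * x, "c": y})
        r = pca_varimax(t)
        assert r.eigenvalues[:3] == pytest.approx([2.0, 1.0, 0.0], abs=1e-10)

    def test_rotation_preserves_communalities(self):
        rng = np.random.default_rng(6)
        lam = rng.normal(size=(10, 3))
        rot = varimax(lam)
        assert np.allclose((rot**2).sum(axis=1), (lam**2).sum(axis=1), atol=1e-9)

    def test_eigenvalues_sum_to_variable_count(self):
        cfg = CampaignConfig(seed=9)
        t = campaign_table(cfg, ("Ca", "Mg", "Na", "Cl", "SO4", "HCO3", "NO3", "Fe"))
        r = pca_varimax(t)
        assert r.eigenvalues.sum() == pytest.approx(t.shape[1], rel=1e-9)
        assert r.cum_pct[-1] == pytest.approx(100.0)

    def test_reconstruction_residual_decreases_with_components(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(60, 2))
        t = pd.DataFrame(
            np.hstack([base, base @ rng.normal(size=(2, 3)) + 0.3 * rng.normal(size=(60, 3))])
        )
        z = zscore_table(t)
        corr = np.asarray(z.T @ z / (len(t) - 1))
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        residuals = []
        for k in (1, 2, 3):
            load = eigvec[:, :k] * np.sqrt(eigval[:k])
            recon = load @ load.T
            np.fill_diagonal(recon, 1.0)
            residuals.append(np.linalg.norm(corr - recon))
        assert residuals[0] > residuals[1] > residuals[2]

    def test_planted_four_factor_recovery(self):
        """A campaign built from four disjoint latent factors yields four
        retained components whose rotated loadings recover the blocks."""
        blocks = {
            "A": ("Ca", "Mg", "Na", "Cl"),
            "B": ("SO4", "HCO3", "NO3"),
            "C": ("Fe", "Mn"),
            "D": ("K", "CO3"),
        }
        cfg = block_config(blocks, seed=12)
        t = campaign_table(cfg, [p for ps in blocks.values() for p in ps])
        r = pca_varimax(t)
        assert r.n_retained == 4
        for params in blocks.values():
            # one rotated component must load |.| > 0.7 on the whole block
            hits = (r.loadings.loc[list(params)].abs() > 0.7).all(axis=0)
            assert hits.any(), params

    def test_deterministic_sign_convention(self):
        cfg = CampaignConfig(seed=9)
        t = campaign_table(cfg, ("Ca", "Mg", "Na", "Cl", "SO4"))
        a = pca_varimax(t).loadings
        b = pca_varimax(t).loadings
        assert np.allclose(a, b)
        for col in a.columns:
            assert a[col].abs().max() == pytest.approx(a[col].max())


class TestHca:
    def test_identical_variables_merge_first_at_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        t = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        tree = hca_ward(t)
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-10)
        assert {int(tree.linkage[0, 0]), int(tree.linkage[0, 1])} == {0, 1}

    def test_heights_non_decreasing(self):
        cfg = CampaignConfig(seed=13)
        t = campaign_table(cfg, ("Ca", "Mg", "Na", "Cl", "SO4", "HCO3", "Fe", "Mn"))
        tree = hca_ward(t)
        heights = tree.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_planted_three_cluster_recovery(self):
        blocks = {
            "A": ("Ca", "Mg", "Na", "Cl"),
            "B": ("SO4", "HCO3", "NO3"),
            "C": ("Fe", "Mn"),
        }
        cfg = block_config(blocks, seed=14)
        t = campaign_table(cfg, [p for ps in blocks.values() for p in ps])
        assignment = hca_ward(t).cut(k=3)
        for params in blocks.values():
            ids = {assignment[p] for p in params}
            assert len(ids) == 1, (params, assignment)

    def test_single_variable_degenerate_tree(self):
        tree = hca_ward(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert tree.linkage.shape[0] == 0

    def test_newick_export_parses(self):
        import dendropy

        cfg = CampaignConfig(seed=15)
        t = campaign_table(cfg, ("Ca", "Mg", "Na", "Cl", "Fe"))
        nwk = hca_ward(t).to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(t.columns)
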