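"""Combined ANOVA, AMMI decomposition, Gollob tests and biplot coordinates."""

import numpy as np
import pandas as pd
import pytest

from metstab import (
    METDataset,
    SimulationSpec,
    ammi1_coords,
    ammi2_coords,
    ammi_analysis,
    ammi_decompose,
    combined_anova,
    compute_ge_means,
    generate_met,
    gollob_test,
)
from conftest import met_from_means


def brute_force_anova(frame):
    """Sums of squares straight from the textbook definitions."""
    y = frame["yield"].to_numpy()
    grand = y.mean()
    ss = {"total": ((y - grand) ** 2).sum()}
    env = frame.groupby("environment")["yield"]
    ss["environment"] = sum(len(s) * (s.mean() - grand) ** 2 for _, s in env)
    rep = frame.groupby(["environment", "replicate"])["yield"]
    envmean = env.mean()
    ss["replicate_within_environment"] = sum(
        len(s) * (s.mean() - envmean[e]) ** 2 for (e, _), s in rep
    )
    gen = frame.groupby("genotype")["yield"]
    ss["genotype"] = sum(len(s) * (s.mean() - grand) ** 2 for _, s in gen)
    cell = frame.groupby(["genotype", "environment"])["yield"]
    genmean = gen.mean()
    ss["genotype_x_environment"] = sum(
        len(s) * (s.mean() - genmean[g] - envmean[e] + grand) ** 2 for (g, e), s in cell
    )
    ss["error"] = ss["total"] - sum(v for k, v in ss.items() if k not in ("total", "error"))
    return ss


class TestCombinedAnova:
    def test_constant_response_all_zero(self):
        data = met_from_means(np.full((3, 3), 5.0), r=1)
        table = combined_anova(data).table
        np.testing.assert_allclose(table["SS"], 0, atol=1e-12)

    def test_toy_2x2x2_matches_brute_force(self):
        rng = np.random.default_rng(11)
        rows = [
            (f"G{i}", f"E{j}", f"R{k}", rng.uniform(10, 100))
            for i in (1, 2) for j in (1, 2) for k in (1, 2)
        ]
        data = METDataset.from_frame(
            pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "yield"])
        )
        res = combined_anova(data)
        expect = brute_force_anova(data.frame)
        for source, ss in expect.items():
            assert res.table.loc[source, "SS"] == pytest.approx(ss, rel=1e-10, abs=1e-10)
        assert res.table.loc["error", "df"] == 2
        assert res.table.loc["total", "df"] == 7

    def test_ss_conservation_and_percent(self, default_trial):
        data, _ = default_trial
        table = combined_anova(data).table
        parts = table.loc[table.index != "total", "SS"].sum()
        assert parts == pytest.approx(table.loc["total", "SS"], rel=1e-8)
        assert table.loc[table.index != "total", "percent_of_total"].sum() == pytest.approx(100.0, abs=1e-8)

    def test_unequal_replicates_across_environments_still_partition(self):
        # E1 has 3 reps, E2 has 2: proportional cell counts keep sources orthogonal
        rng = np.random.default_rng(5)
        rows = []
        for i in range(1, 5):
            for j, r in (("E1", 3), ("E2", 2)):
                for k in range(1, r + 1):
                    rows.append((f"G{i}", j, f"R{k}", rng.uniform(500, 1500)))
        data = METDataset.from_frame(pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "yield"]))
        res = combined_anova(data)
        expect = brute_force_anova(data.frame)
        for source in ("environment", "genotype", "genotype_x_environment"):
            assert res.table.loc[source, "SS"] == pytest.approx(expect[source], rel=1e-9)
        assert res.table.loc["error", "SS"] >= 0

    def test_single_replicate_has_no_f_tests(self):
        data = met_from_means(np.arange(12.0).reshape(3, 4) ** 1.3, r=1)
        res = combined_anova(data)
        assert not res.has_error_term
        assert res.table["F"].isna().all()


class TestDecomposition:
    def test_additive_means_give_zero_axes(self):
        means = compute_ge_means(met_from_means([[10, 20, 30], [20, 30, 40], [5, 15, 25]]))
        res = ammi_decompose(means)
        np.testing.assert_allclose(res.singular_values, 0, atol=1e-9)
        assert res.zero_interaction
        np.testing.assert_array_equal(res.percent_explained, 0)

    def test_2x2_interaction_oracle(self):
        # means with interaction [[1,-1],[-1,1]]: single axis, lambda = 2
        means = compute_ge_means(met_from_means([[11, 9], [9, 11]]))
        np.testing.assert_allclose(means.interaction, [[1, -1], [-1, 1]], atol=1e-12)
        res = ammi_decompose(means)
        np.testing.assert_allclose(res.singular_values, [2.0], rtol=1e-12)
        assert res.percent_explained[0] == pytest.approx(100.0)

    def test_svd_identities_and_reconstruction(self, default_trial):
        data, _ = default_trial
        means = compute_ge_means(data)
        res = ammi_decompose(means, replicate_count=3)
        # eigenvalue sum equals interaction Frobenius norm squared
        assert (res.singular_values**2).sum() == pytest.approx((means.interaction**2).sum(), rel=1e-10)
        # symmetric scaling: per-axis score SS equals the singular value on both sides
        np.testing.assert_allclose((res.genotype_scores**2).sum(axis=0), res.singular_values, rtol=1e-9)
        np.testing.assert_allclose((res.environment_scores**2).sum(axis=0), res.singular_values, rtol=1e-9)
        # full reconstruction with all axes
        recon = (
            means.grand_mean
            + means.genotype_effects[:, None]
            + means.environment_effects[None, :]
            + res.genotype_scores @ res.environment_scores.T
        )
        assert np.abs(recon - means.means).max() < 1e-8 * means.grand_mean
        # genotype scores orthogonal across axes
        cross = res.genotype_scores.T @ res.genotype_scores
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8 * res.singular_values[0]
        # theta sums to 100
        assert res.percent_explained.sum() == pytest.approx(100.0, abs=1e-8)

    def test_sign_convention_dominant_genotype_positive(self, default_trial):
        data, _ = default_trial
        res = ammi_decompose(compute_ge_means(data))
        for n in range(res.n_axes):
            i = np.argmax(np.abs(res.genotype_vectors[:, n]))
            assert res.genotype_vectors[i, n] > 0


class TestGollob:
    def test_df_formula(self, default_trial):
        data, _ = default_trial
        _, anova, res = ammi_analysis(data)
        # g=16, e=8: df = g + e - 1 - 2n
        assert res.gollob.loc[1, "df"] == 21
        assert res.gollob.loc[2, "df"] == 19
        assert res.gollob.loc[3, "df"] == 17

    def test_zero_interaction_floor_one(self):
        data = met_from_means([[10, 20, 30], [20, 30, 40], [30, 40, 50]], r=2)
        means, anova, res = ammi_analysis(data)
        assert res.n_significant == 1
        assert not res.gollob["significant"].any()

    def test_rank1_signal_detected_as_one_axis(self):
        """Strong rank-1 interaction plus noise: N' lands on 1 axis.

        A small design is used because Gollob's F-test is liberal: in
        large tables the leading noise axis concentrates enough SS to be
        declared significant at well above the nominal rate.
        """
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            spec = SimulationSpec(
                g=5, e=3, r=3, interaction_singular_values=(300.0,), plot_noise_sd=100.0,
                genotype_effect_sd=90.0, environment_effect_sd=170.0, seed=seed,
            )
            data, _ = generate_met(spec)
            _, _, res = ammi_analysis(data, alpha=0.05)
            hits += res.n_significant == 1
        assert hits >= int(0.95 * n_seeds)

    def test_alpha_validated(self, default_trial):
        data, _ = default_trial
        means = compute_ge_means(data)
        anova = combined_anova(data)
        res = ammi_decompose(means, 3)
        with pytest.raises(ValueError):
            gollob_test(res, anova, alpha=1.5)


class TestBiplots:
    def test_ammi1_genotype_rows_are_row_means(self, default_trial):
        data, _ = default_trial
        means, _, res = ammi_analysis(data)
        coords = ammi1_coords(means, res)
        grows = coords[coords.kind == "genotype"].set_index("name")
        np.testing.assert_allclose(grows.loc[means.genotypes, "mean"], means.genotype_means())
        np.testing.assert_allclose(grows.loc[means.genotypes, "IPC1"], res.genotype_scores[:, 0])
        assert coords.attrs["grand_mean"] == pytest.approx(means.grand_mean)

    def test_ammi1_additive_data_zero_ordinates(self):
        means = compute_ge_means(met_from_means([[10, 20], [30, 40], [50, 60]]))
        res = ammi_decompose(means)
        coords = ammi1_coords(means, res)
        np.testing.assert_allclose(coords["IPC1"], 0, atol=1e-9)

    def test_ammi2_matches_oracle_svd_on_toy(self):
        m = np.array([[12.0, 7.0, 5.0], [6.0, 11.0, 7.0], [6.0, 6.0, 12.0]])
        means = compute_ge_means(met_from_means(m))
        res = ammi_decompose(means)
        coords = ammi2_coords(res)
        u, s, vt = np.linalg.svd(means.interaction)
        expected = np.abs(u[:, :2] * np.sqrt(s[:2]))
        got = coords[coords.kind == "genotype"][["IPC1", "IPC2"]].to_numpy()
        np.testing.assert_allclose(np.abs(got), expected, atol=1e-10)

    def test_ammi2_distance_and_rank1_degeneracy(self):
        means = compute_ge_means(met_from_means([[11, 9], [9, 11]]))
        res = ammi_decompose(means)
        with pytest.raises(Exception, match="ammi1"):
            ammi2_coords(res)

    def test_distance_is_euclidean(self, default_trial):
        data, _ = default_trial
        _, _, res = ammi_analysis(data)
        coords = ammi2_coords(res)
        np.testing.assert_allclose(
            coords["distance_from_origin"],
            np.hypot(coords["IPC1"], coords["IPC2"]),
        )
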