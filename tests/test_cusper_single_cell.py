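"""Reproductive-success pipeline: correction, LOD, binning, reconstruction,
Bray-Curtis and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest

from phyllocomp import cusper_single_cell as cu
from phyllocomp import synthetic_data as sd


def cells_frame(green, bg, fov=None):
    n = len(green)
    return pd.DataFrame({
        "cell_id": range(n),
        "fov": fov if fov is not None else [0] * n,
        "green_intensity": green,
        "bg_green": bg,
    })


class TestBackgroundCorrect:
    def test_subtracts_fov_mean(self):
        out = cu.background_correct(cells_frame([500.0], [100.0]))
        assert out["green_corrected"].iloc[0] == 400.0
        assert not out["floor_censored"].iloc[0]

    def test_cell_at_background_floors_and_flags(self):
        out = cu.background_correct(cells_frame([100.0], [100.0]))
        assert out["green_corrected"].iloc[0] == cu.INTENSITY_FLOOR
        assert out["floor_censored"].iloc[0]

    def test_fovs_corrected_independently(self):
        out = cu.background_correct(
            cells_frame([500.0, 500.0], [100.0, 300.0], fov=[0, 1]))
        np.testing.assert_allclose(out["green_corrected"], [400.0, 200.0])

    def test_missing_background_rejected(self):
        with pytest.raises(ValueError):
            cu.background_correct(cells_frame([500.0], [np.nan]))


class TestReproductiveSuccess:
    def test_closed_forms(self):
        assert cu.reproductive_success(1000.0, [1000.0])[0] == 0.0
        assert cu.reproductive_success(1000.0, [250.0])[0] == 2.0
        assert cu.reproductive_success(1000.0, [1000.0 / 32])[0] == pytest.approx(5.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            cu.reproductive_success(0.0, [100.0])
        with pytest.raises(ValueError):
            cu.reproductive_success(100.0, [0.0])


class TestLOD:
    def test_uniform_background_quantile(self, rng):
        bg_rs = rng.uniform(4.0, 6.0, 100000)
        assert cu.lod_from_background(bg_rs) == pytest.approx(4.1, abs=0.02)

    def test_matches_sorting_oracle(self, rng):
        bg_rs = rng.normal(5.0, 0.5, 501)
        # oracle: linear ECDF interpolation on the sorted sample
        s = np.sort(bg_rs)
        expected = np.interp(0.05 * (len(s) - 1), np.arange(len(s)), s)
        assert cu.lod_from_background(bg_rs) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_background(self):
        assert cu.lod_from_background(np.full(50, 5.0)) == 5.0

    def test_snap_truncates_to_bin_edge(self):
        # a raw quantile of 4.58 must yield the working LOD 4.5
        bg_rs = np.linspace(4.58, 8.0, 100)
        assert cu.lod_from_background(bg_rs, snap_to_bin_edge=True) == 4.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cu.lod_from_background(np.ones(5))


class TestBinning:
    @pytest.mark.parametrize("rs,expected", [
        (0.49, "RS_0"), (0.5, "RS_1"), (1.49, "RS_1"), (1.5, "RS_2"),
        (2.49, "RS_2"), (3.5, "RS_4"), (4.49, "RS_4"), (4.5, "RS_>4"),
    ])
    def test_half_open_edges(self, rs, expected):
        assert cu.bin_rs([rs])["bin"].iloc[0] == expected

    def test_above_lod_censored(self):
        out = cu.bin_rs([7.2])
        assert out["bin"].iloc[0] == "RS_>4"
        assert out["censored"].iloc[0]

    def test_negative_rs_to_first_bin_and_counted(self):
        out = cu.bin_rs([-0.2])
        assert out["bin"].iloc[0] == "RS_0"
        assert out.attrs["n_negative_rs"] == 1

    def test_lod_must_align_with_edges(self):
        with pytest.raises(ValueError):
            cu.bin_rs([1.0], lod=4.2)

    def test_fractions_sum_to_one(self, rng):
        out = cu.bin_rs(rng.uniform(-0.5, 6.0, 500))
        assert cu.fractions_from_bins(out).sum() == pytest.approx(1.0)


class TestFounderReconstruction:
    def test_all_divided_twice(self):
        g, fold = cu.founder_reconstruction({"RS_2": 1.0})
        assert g["RS_2"] == 1.0
        assert fold == 4.0

    def test_mixed_bins_match_explicit_founder_list(self):
        # 1 founder with 0 divisions and 1 with 1 division leave 1 + 2 cells:
        # observed fractions (1/3, 2/3) must invert to founders (1/2, 1/2)
        # and here the observed fractions (0.5, 0.5) invert to (2/3, 1/3)
        g, fold = cu.founder_reconstruction({"RS_0": 0.5, "RS_1": 0.5})
        assert g["RS_0"] == pytest.approx(2 / 3)
        assert g["RS_1"] == pytest.approx(1 / 3)
        assert fold == pytest.approx(4 / 3)

    def test_no_growth_population(self):
        g, fold = cu.founder_reconstruction({"RS_0": 1.0})
        assert fold == 1.0

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            cu.founder_reconstruction({})

    def test_founder_fractions_sum_to_one(self, rng):
        f = rng.dirichlet(np.ones(6))
        g, _ = cu.founder_reconstruction(dict(zip(cu.BIN_LABELS, f)))
        assert g.sum() == pytest.approx(1.0)

    def test_noise_free_round_trip_is_exact(self):
        pmf = {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}
        pop = sd.gen_cusper_population(400, pmf, gfp_mean=4096, gfp_cv=0.0, seed=6)
        corrected = cu.background_correct(pop.cells)
        rs = cu.reproductive_success(4096.0, corrected["green_corrected"])
        fractions = cu.fractions_from_bins(cu.bin_rs(rs))
        g, fold = cu.founder_reconstruction(fractions)
        assert fold == pytest.approx(len(pop.cells) / 400, abs=1e-12)
        # exact founder recovery: weight each observed class back by 2^-k
        founder_k = np.array([0, 1, 2, 3])
        counts = pd.Series(pop.truth.division_counts).value_counts()
        founders = np.array([counts.get(k, 0) / 2**k for k in founder_k])
        np.testing.assert_allclose(g.values[:4], founders / founders.sum())

    def test_deep_divisions_always_censored_without_noise(self):
        pop = sd.gen_cusper_population(50, {5: 0.5, 6: 0.5}, gfp_mean=4096,
                                       gfp_cv=0.0, seed=1)
        corrected = cu.background_correct(pop.cells)
        rs = cu.reproductive_success(4096.0, corrected["green_corrected"])
        binned = cu.bin_rs(rs)
        assert (binned["bin"] == "RS_>4").all()
        assert binned["censored"].all()


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        D = cu.bray_curtis(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert D[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        D = cu.bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D[0, 1] == 1.0

    def test_hand_computed_value(self):
        D = cu.bray_curtis(np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]]))
        assert D[0, 1] == pytest.approx(0.5)

    def test_negative_fractions_rejected(self):
        with pytest.raises(ValueError):
            cu.bray_curtis(np.array([[0.5, -0.1], [0.5, 0.5]]))


class TestPermanova:
    @staticmethod
    def two_group_data(rng, n_per=8, shift=False):
        alpha_a = np.ones(6) * 4
        alpha_b = np.array([12.0, 4, 1, 1, 1, 1]) if shift else alpha_a
        X = np.vstack([rng.dirichlet(alpha_a, n_per), rng.dirichlet(alpha_b, n_per)])
        factors = pd.DataFrame({"group": ["a"] * n_per + ["b"] * n_per})
        return cu.bray_curtis(X), factors

    def test_detects_planted_composition_shift(self, rng):
        D, factors = self.two_group_data(rng, shift=True)
        res = cu.permanova(D, factors, n_permutations=999, seed=1)[0]
        assert res.p_value <= 0.05
        assert 0 < res.r_squared < 1

    def test_p_resolution(self, rng):
        D, factors = self.two_group_data(rng)
        res = cu.permanova(D, factors, n_permutations=99, seed=0)[0]
        assert res.p_value >= 1 / 100
        assert res.n_permutations == 99

    def test_identical_compositions_degenerate(self):
        X = np.tile([0.25, 0.25, 0.25, 0.25], (8, 1))
        factors = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4})
        res = cu.permanova(cu.bray_curtis(X), factors, n_permutations=99)[0]
        assert res.pseudo_F == 0.0
        assert res.p_value == 1.0

    def test_singleton_groups_rejected(self, rng):
        D, _ = self.two_group_data(rng, n_per=2)
        factors = pd.DataFrame({"group": ["a", "a", "a", "b"]})
        with pytest.raises(ValueError):
            cu.permanova(D, factors)

    def test_one_way_f_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        D, factors = self.two_group_data(rng, shift=True)
        ours = cu.permanova(D, factors, n_permutations=99, seed=0)[0]
        theirs = skbio_permanova(DistanceMatrix(D), factors["group"].values,
                                 permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_sequential_two_factor_partition(self, rng):
        n = 16
        X = rng.dirichlet(np.ones(6) * 2, n)
        factors = pd.DataFrame({
            "time": (["t0"] * 8 + ["t1"] * 8),
            "treatment": (["mono", "comp"] * 8),
        })
        results = cu.permanova(cu.bray_curtis(X), factors, n_permutations=99, seed=2)
        assert [r.factor for r in results] == ["time", "treatment"]
        assert all(0 <= r.r_squared <= 1 for r in results)
        assert sum(r.r_squared for r in results) <= 1.0 + 1e-9
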