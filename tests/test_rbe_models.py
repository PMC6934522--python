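import math

import numpy as np
import pytest

from protonrbe import (
    LetWeightParams,
    MMParams,
    McNamaraParams,
    ModelName,
    ModelParams,
    Quantity,
    RBEModelError,
    ROIMask,
    TissueParams,
    VoxelGrid,
    alpha_beta_grid,
    apply_model,
    dose_constant,
    dose_let_weighted,
    load_params,
    ratio_map,
    rbe_combined,
    rbe_mcnamara,
    rbe_misrepair,
    rbe_residual,
    residual_misrepair_ratio,
)

LETS = np.linspace(0.0, 20.0, 81)


def mcnamara_oracle(D, L, ab, p=McNamaraParams()):
    """Independently coded closed form of the LQ-based RBE."""
    rbe_max = p.z1 + p.z2 * L / ab
    rbe_min = p.z3 - p.z4 * math.sqrt(ab)
    return (math.sqrt(ab * ab + 4 * D * ab * rbe_max + 4 * D * D * rbe_min * rbe_min)
            - ab) / (2 * D)


class TestConstantAndLetWeighted:
    def test_constant_is_1p1_times_dose(self):
        assert dose_constant(1.8) == pytest.approx(1.98)
        assert dose_constant(0.0) == 0.0
        with pytest.raises(RBEModelError):
            dose_constant(-1.0)

    def test_let_weighted_values_and_identity_at_zero_let(self):
        p = LetWeightParams(kappa=0.055)
        assert dose_let_weighted(2.0, 4.0, p) == pytest.approx(2.44)
        assert dose_let_weighted(1.7, 0.0, p) == pytest.approx(1.7)
        assert dose_let_weighted(0.0, 5.0, p) == 0.0

    def test_alternative_published_kappa_supported(self):
        assert dose_let_weighted(2.0, 4.0, LetWeightParams(kappa=0.0055)) == pytest.approx(2.044)


class TestMcNamara:
    def test_example_value_2Gy_zero_let(self):
        rbe = rbe_mcnamara(2.0, 0.0, 2.0)
        assert rbe == pytest.approx(1.0624, abs=2e-4)
        assert rbe == pytest.approx(mcnamara_oracle(2.0, 0.0, 2.0), rel=1e-12)

    def test_low_dose_limit_is_rbe_max(self):
        # D -> 0 with LET_d = 2, alpha/beta = 2: Z1 + Z2 * 2/2
        assert rbe_mcnamara(0.0, 2.0, 2.0) == pytest.approx(1.3467, abs=2e-4)
        assert rbe_mcnamara(1e-9, 2.0, 2.0) == pytest.approx(1.3467, abs=2e-4)

    def test_high_dose_limit_is_rbe_min(self):
        assert rbe_mcnamara(1e6, 0.0, 2.0) == pytest.approx(1.0957, abs=2e-4)

    def test_matches_independent_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            D = float(rng.uniform(0.01, 5.0))
            L = float(rng.uniform(0.0, 15.0))
            ab = float(rng.uniform(1.0, 12.0))
            assert rbe_mcnamara(D, L, ab) == pytest.approx(
                mcnamara_oracle(D, L, ab), rel=1e-12)

    def test_reduces_to_unity_with_trivial_fit(self):
        p = McNamaraParams(z1=1.0, z2=0.0, z3=1.0, z4=0.0)
        for D in (0.5, 2.0, 10.0):
            assert rbe_mcnamara(D, 7.0, 3.0, p) == pytest.approx(1.0, rel=1e-12)

    def test_strictly_increasing_in_let(self):
        rbe = rbe_mcnamara(np.full_like(LETS, 2.0), LETS, 2.0)
        assert (np.diff(rbe) > 0).all()

    def test_invalid_alpha_beta(self):
        with pytest.raises(RBEModelError):
            rbe_mcnamara(2.0, 1.0, 0.0)


class TestMechanisticCorrelations:
    def test_residual_floor_at_zero_let(self):
        # e*c/gamma_r: the minimum of any residual-RBE map.
        assert rbe_residual(0.0) == pytest.approx(1.0277, abs=5e-4)
        assert round(rbe_residual(0.0), 2) == 1.03

    def test_residual_example_and_slope(self):
        assert rbe_residual(2.0) == pytest.approx(1.1257, abs=5e-4)
        p = MMParams()
        fd_slope = (rbe_residual(5.001) - rbe_residual(4.999)) / 0.002
        assert fd_slope == pytest.approx(p.d * p.c / p.gamma_r, rel=1e-6)
        assert p.d * p.c / p.gamma_r == pytest.approx(0.0490, abs=1e-4)

    def test_misrepair_examples(self):
        assert rbe_misrepair(0.0) == pytest.approx(9.456, abs=5e-3)
        assert rbe_misrepair(2.0) == pytest.approx(11.22, abs=5e-3)
        assert rbe_misrepair(5.0) == pytest.approx(15.07, abs=5e-3)

    def test_combined_examples_via_pooling_identity(self):
        p = MMParams()
        for L, expected in ((0.0, 1.231), (2.0, 1.369)):
            pooled = (p.gamma_r * rbe_residual(L) + p.gamma_m * rbe_misrepair(L)) / (
                p.gamma_r + p.gamma_m)
            assert rbe_combined(L) == pytest.approx(pooled, rel=1e-12)
            assert rbe_combined(L) == pytest.approx(expected, abs=2e-3)

    def test_pooling_identity_exact_on_random_lets(self):
        p = MMParams()
        rng = np.random.default_rng(3)
        lets = rng.uniform(0.0, 20.0, 100)
        lhs = (p.gamma_r + p.gamma_m) * rbe_combined(lets)
        rhs = p.gamma_r * rbe_residual(lets) + p.gamma_m * rbe_misrepair(lets)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-14)

    def test_monotone_increasing_in_let(self):
        for fn in (rbe_residual, rbe_misrepair, rbe_combined):
            assert (np.diff(fn(LETS)) > 0).all()

    def test_endpoint_ordering_misrepair_above_combined_above_residual(self):
        r, m, c = rbe_residual(LETS), rbe_misrepair(LETS), rbe_combined(LETS)
        assert (m > c).all() and (c > r).all()
        # pooled endpoint sits near the residual one (gamma_m << gamma_r)
        assert (c - r).max() < (m - c).min()

    def test_ratio_examples_decreasing_and_above_unity(self):
        assert residual_misrepair_ratio(0.0) == pytest.approx(4.39, abs=5e-3)
        assert residual_misrepair_ratio(2.0) == pytest.approx(4.06, abs=5e-3)
        vals = residual_misrepair_ratio(LETS)
        assert (np.diff(vals) < 0).all()
        assert (vals > 1).all()

    def test_ratio_is_dose_free_consequence(self):
        # both yields carry D*(d*L+e); their ratio must equal r/m scaled by photon yields
        p = MMParams()
        L = 3.7
        assert residual_misrepair_ratio(L) == pytest.approx(
            (rbe_residual(L) * p.gamma_r) / (rbe_misrepair(L) * p.gamma_m), rel=1e-12)

    def test_negative_let_rejected(self):
        for fn in (rbe_residual, rbe_misrepair, rbe_combined, residual_misrepair_ratio):
            with pytest.raises(RBEModelError):
                fn(-0.1)


class TestParameterLoading:
    def test_defaults_match_published_set(self, params):
        assert params.mm.gamma_r == 1.726
        assert params.mcnamara.z2 == 0.35605
        assert params.let_weighted.kappa == 0.055
        assert params.uncertainty_pct == {}

    def test_packaged_file_and_overrides(self, tmp_path):
        loaded = load_params()
        assert loaded.mm == MMParams()
        assert loaded.uncertainty_pct["gamma_m"] == 16.7
        override = tmp_path / "p.json"
        override.write_text('{"let_weighted": {"kappa": 0.0055}, "mm": {"e": 25.0}}')
        custom = load_params(override)
        assert custom.let_weighted.kappa == 0.0055
        assert custom.mm.e == 25.0
        assert custom.mm.d == 1.149  # untouched keys keep defaults

    def test_invalid_parameter_sets_rejected(self):
        with pytest.raises(RBEModelError):
            MMParams(c=1.5)
        with pytest.raises(RBEModelError):
            MMParams(gamma_r=0.01, gamma_m=0.02)
        with pytest.raises(RBEModelError):
            McNamaraParams(z1=-1.0)


def _uniform_bundle_pieces(dose_val, let_val, let_quantity):
    dims = (2, 2, 2)
    dose = VoxelGrid(dims, (2, 2, 2), (0, 0, 0), np.full(dims, dose_val), Quantity.DOSE)
    let = dose.with_values(np.full(dims, let_val), let_quantity)
    return dose, let


class TestGridApplication:
    def test_uniform_residual_map_matches_scalar(self):
        dose, let = _uniform_bundle_pieces(2.0, 2.0, Quantity.LET_T)
        weighted, rbe = apply_model(dose, let, ModelName.MM_RESIDUAL)
        assert rbe.values == pytest.approx(rbe_residual(2.0))
        assert weighted.values == pytest.approx(2.0 * rbe_residual(2.0))
        assert weighted.values == pytest.approx(2.2513, abs=1e-3)

    def test_constant_model_map(self):
        dose, _ = _uniform_bundle_pieces(1.0, 1.0, Quantity.LET_T)
        _, rbe = apply_model(dose, None, "constant")
        assert (rbe.values == 1.1).all()

    def test_sentinel_in_zero_dose_voxels(self):
        dims = (1, 1, 2)
        dose = VoxelGrid(dims, (2, 2, 2), (0, 0, 0), [0.0, 2.0], Quantity.DOSE)
        let = dose.with_values([1.0, 1.0], Quantity.LET_D)
        weighted, rbe = apply_model(dose, let, ModelName.LET_WEIGHTED)
        assert np.isnan(rbe.values[0, 0, 0]) and weighted.values[0, 0, 0] == 0.0
        assert rbe.values[0, 0, 1] == pytest.approx(1.055)

    def test_wrong_let_flavour_is_an_error(self):
        dose, let_d = _uniform_bundle_pieces(2.0, 2.0, Quantity.LET_D)
        with pytest.raises(RBEModelError, match="let_t"):
            apply_model(dose, let_d, ModelName.MM_RESIDUAL)
        _, let_t = _uniform_bundle_pieces(2.0, 2.0, Quantity.LET_T)
        with pytest.raises(RBEModelError, match="let_d"):
            apply_model(dose, let_t, ModelName.MCNAMARA, alpha_beta=2.0)
        with pytest.raises(RBEModelError, match="requires"):
            apply_model(dose, None, ModelName.MM_RESIDUAL)

    def test_mcnamara_needs_alpha_beta_source(self):
        dose, let_d = _uniform_bundle_pieces(2.0, 2.0, Quantity.LET_D)
        with pytest.raises(RBEModelError, match="alpha_beta"):
            apply_model(dose, let_d, ModelName.MCNAMARA)

    def test_alpha_beta_grid_priority_most_specific_wins(self, small_grid):
        ptv = np.zeros(small_grid.dims, dtype=bool)
        ptv[:, :, :2] = True
        cord = np.zeros(small_grid.dims, dtype=bool)
        cord[:, :, 1:3] = True  # overlaps ptv in column 1
        masks = {"ptv": ROIMask.from_grid("ptv", small_grid, ptv),
                 "spinal_cord": ROIMask.from_grid("spinal_cord", small_grid, cord)}
        ab = alpha_beta_grid(small_grid, masks, TissueParams())
        assert ab[0, 0, 0] == 10.0   # ptv only
        assert ab[0, 0, 1] == 2.0    # overlap: cord wins
        assert ab[0, 0, 3] == 2.0    # body default

    def test_ratio_map_requires_track_averaged_let(self):
        dose, let_d = _uniform_bundle_pieces(2.0, 2.0, Quantity.LET_D)
        with pytest.raises(RBEModelError):
            ratio_map(dose, let_d)
        _, let_t = _uniform_bundle_pieces(2.0, 2.0, Quantity.LET_T)
        ratio = ratio_map(dose, let_t)
        assert ratio.values == pytest.approx(residual_misrepair_ratio(2.0))
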