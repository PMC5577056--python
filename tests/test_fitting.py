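"""Global cluster fitting: exclusion rule, recovery, diagnostics, model choice."""

import numpy as np
import pytest

from fluctedit.fitting import (DispersionCurve, InvalidComparisonError,
                               cluster_search, ensure_sigma, exclude_flat_curves,
                               f_test_select, fit_cluster, reduced_chi2)
from fluctedit.models import (DEFAULT_GRID, ExchangeParams, InvalidInputError,
                              luz_meiboom_r2eff)
from fluctedit.synth import ClusterScenario, gen_dispersion_dataset


def make_curve(rid, field, nu, r2, sigma=0.3):
    return DispersionCurve(rid, field, nu, np.asarray(r2, dtype=float),
                           np.full(len(nu), sigma))


def ramp_curve(rid, field, nu, r2_range):
    """Curve whose R2eff decreases linearly by exactly ``r2_range``."""
    r2 = 15.0 + np.linspace(r2_range, 0.0, nu.size)
    return make_curve(rid, field, nu, r2)


class TestExclusionRule:
    @pytest.mark.parametrize("r2_range, kept", [
        (0.8, False),    # below the 1 s^-1 rule -> excluded
        (1.0, True),     # boundary: rule excludes strictly-below only
        (0.0, False),    # perfectly flat
        (2.5, True),
    ])
    def test_threshold(self, field600, nu_grid, r2_range, kept):
        curves = [ramp_curve("H:R71", field600, nu_grid, r2_range)]
        kept_c, excl_c = exclude_flat_curves(curves)
        assert (len(kept_c) == 1) is kept
        assert len(kept_c) + len(excl_c) == 1

    def test_residue_kept_if_any_field_dispersive(self, field600, field750, nu_grid):
        curves = [ramp_curve("H:R71", field600, nu_grid, 0.4),
                  ramp_curve("H:R71", field750, nu_grid, 1.6)]
        kept_c, excl_c = exclude_flat_curves(curves)
        assert len(kept_c) == 2 and not excl_c

    def test_partition_exhaustive_disjoint_and_idempotent(self, field600, nu_grid):
        curves = [ramp_curve(f"H:K{i}", field600, nu_grid, rng)
                  for i, rng in enumerate([0.2, 0.9, 1.0, 3.0])]
        kept_c, excl_c = exclude_flat_curves(curves)
        assert len(kept_c) + len(excl_c) == len(curves)
        assert not {id(c) for c in kept_c} & {id(c) for c in excl_c}
        kept2, excl2 = exclude_flat_curves(kept_c)
        assert kept2 == kept_c and not excl2
        # order independence
        kept_r, _ = exclude_flat_curves(curves[::-1])
        assert {c.residue_id for c in kept_r} == {c.residue_id for c in kept_c}

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            exclude_flat_curves([])


class TestFitCluster:
    def test_noiseless_single_residue_exact_recovery(self, field600, nu_grid):
        p = ExchangeParams(r2_0=12.0, k_ex=1200.0, phi_ppm2=0.06)
        clean = luz_meiboom_r2eff(nu_grid, p, field600)
        fit = fit_cluster([make_curve("H:R71", field600, nu_grid, clean)],
                          model="luz_meiboom")
        assert fit.chi2 < 1e-6
        assert fit.k_ex == pytest.approx(1200.0, rel=1e-3)
        assert fit.per_residue["H:R71"]["phi_ppm2"] == pytest.approx(0.06, rel=1e-3)

    def test_duplicating_curves_doubles_chi2_not_estimates(self, field600, nu_grid):
        rng = np.random.default_rng(3)
        p = ExchangeParams(r2_0=12.0, k_ex=900.0, phi_ppm2=0.05)
        noisy = luz_meiboom_r2eff(nu_grid, p, field600) + rng.normal(0, 0.3, nu_grid.size)
        one = [make_curve("H:R71", field600, nu_grid, noisy)]
        fit1 = fit_cluster(one, model="luz_meiboom")
        fit2 = fit_cluster(one + [make_curve("H:R71", field600, nu_grid, noisy)],
                           model="luz_meiboom")
        assert fit2.k_ex == pytest.approx(fit1.k_ex, rel=1e-3)
        assert fit2.chi2 == pytest.approx(2.0 * fit1.chi2, rel=1e-3)

    def test_cluster_recovery_at_wild_type_rate(self):
        """Two-field 10-residue cluster generated at the slower wild-type rate."""
        scen = ClusterScenario(name="c1", k_ex=840.0, model="carver_richards",
                               n_residues=10, p_minor=0.03, dw_range=(0.5, 2.0))
        curves, truth = gen_dispersion_dataset(11, clusters=(scen,), n_decoys=0)
        fit = fit_cluster(curves, model="carver_richards")
        assert abs(fit.k_ex - truth["clusters"][0]["k_ex"]) <= 2.0 * fit.k_ex_se

    def test_single_residue_global_equals_single_fit(self, field600, nu_grid):
        rng = np.random.default_rng(5)
        p = ExchangeParams(r2_0=12.0, k_ex=700.0, phi_ppm2=0.07)
        noisy = luz_meiboom_r2eff(nu_grid, p, field600) + rng.normal(0, 0.3, nu_grid.size)
        c = make_curve("H:R71", field600, nu_grid, noisy)
        alone = fit_cluster([c], model="luz_meiboom")
        again = fit_cluster([c], model="luz_meiboom")
        assert again.k_ex == pytest.approx(alone.k_ex, rel=1e-9)  # deterministic
        assert again.chi2 == pytest.approx(alone.chi2, abs=1e-12)

    def test_releasing_shared_p_minor_never_raises_chi2(self):
        scen = ClusterScenario(name="s", k_ex=300.0, model="carver_richards",
                               n_residues=3, p_minor=0.05, dw_range=(1.5, 3.0))
        curves, _ = gen_dispersion_dataset(7, clusters=(scen,), n_decoys=0)
        shared = fit_cluster(curves, model="carver_richards", share_p_minor=True)
        released = fit_cluster(curves, model="carver_richards", share_p_minor=False,
                               kex_starts=(shared.k_ex,))
        assert released.chi2 <= shared.chi2 + 1e-6

    def test_dof_guard(self, field600):
        nu = np.array([25.0, 50.0, 100.0, 200.0])
        c = make_curve("H:R71", field600, nu, [15, 14, 13, 12])
        with pytest.raises(InvalidInputError):
            # 4 points, but k_ex + phi + r2_0 = 3 parameters and 4 - 3 = 1 > 0,
            # so shrink to the degenerate case via duplicated parameters:
            fit_cluster([c], model="carver_richards", share_p_minor=False)

    def test_sigma_floor_and_duplicate_estimate(self, field600, nu_grid):
        c = DispersionCurve("H:R71", field600, nu_grid,
                            15.0 - np.linspace(0, 2, nu_grid.size))
        ensure_sigma([c], floor=0.2)
        assert np.all(c.sigma == 0.2)
        nu_dup = np.array([25.0, 25.0, 100.0, 100.0, 500.0, 500.0])
        r2 = np.array([15.0, 15.4, 13.0, 13.4, 12.0, 12.4])
        c2 = DispersionCurve("H:K5", field600, nu_dup, r2)
        ensure_sigma([c2])
        assert c2.sigma[0] == pytest.approx(np.std([0.0, 0.4], ddof=1), rel=1e-9)


class TestReducedChi2:
    def test_ratio(self, field600, nu_grid):
        fit = fit_cluster([ramp_curve("H:R71", field600, nu_grid, 3.0)],
                          model="luz_meiboom")
        assert reduced_chi2(fit) == pytest.approx(fit.chi2 / fit.dof)

    def test_matches_noise_level_on_large_sample(self, field600):
        """With sigma equal to the true noise SD, reduced chi2 is near 1."""
        rng = np.random.default_rng(17)
        nu = np.linspace(25, 1000, 40)
        p = ExchangeParams(r2_0=12.0, k_ex=800.0, phi_ppm2=0.06)
        curves = [make_curve(f"H:R{i}", field600, nu,
                             luz_meiboom_r2eff(nu, p, field600)
                             + rng.normal(0, 0.3, nu.size))
                  for i in range(4)]   # 160 points
        fit = fit_cluster(curves, model="luz_meiboom")
        assert 0.5 <= fit.reduced_chi2 <= 1.5


class TestFTest:
    def test_equal_chi2_keeps_simple(self, field600, nu_grid):
        p = ExchangeParams(r2_0=12.0, k_ex=2000.0, phi_ppm2=0.05)
        clean = luz_meiboom_r2eff(nu_grid, p, field600)
        curves = [make_curve("H:R71", field600, nu_grid, clean),
                  make_curve("H:K72", field600, nu_grid, clean)]
        simple = fit_cluster(curves, model="luz_meiboom")
        complex_ = fit_cluster(curves, model="carver_richards")
        res = f_test_select(simple, complex_)
        assert res.selected == "simple"

    def test_different_data_rejected(self, field600, nu_grid):
        a = fit_cluster([ramp_curve("H:R71", field600, nu_grid, 3.0)],
                        model="luz_meiboom")
        b = fit_cluster([ramp_curve("H:K72", field600, nu_grid, 2.0)],
                        model="luz_meiboom")
        with pytest.raises(InvalidComparisonError):
            f_test_select(a, b)

    @pytest.mark.parametrize("scen, expect", [
        (ClusterScenario(name="fast", k_ex=2000.0, model="luz_meiboom",
                         n_residues=2, phi_range=(0.02, 0.08)), "luz_meiboom"),
        (ClusterScenario(name="slow", k_ex=200.0, model="carver_richards",
                         n_residues=2, p_minor=0.05, dw_range=(2.0, 3.0)), "carver_richards"),
    ])
    def test_regime_selection_small_sample(self, scen, expect):
        """Fast-exchange data prefer the fast closed form; slow data the full one."""
        hits = 0
        for seed in range(5):
            curves, _ = gen_dispersion_dataset(seed, clusters=(scen,), n_decoys=0)
            lm = fit_cluster(curves, model="luz_meiboom")
            cr = fit_cluster(curves, model="carver_richards")
            hits += f_test_select(lm, cr).selected_model == expect
        assert hits >= 4


class TestClusterSearch:
    def test_two_true_clusters_beat_forced_single(self):
        clusters = (
            ClusterScenario(name="c1", k_ex=840.0, model="luz_meiboom", n_residues=3,
                            chain="H", phi_range=(0.03, 0.1)),
            ClusterScenario(name="c2", k_ex=2033.0, model="luz_meiboom", n_residues=3,
                            chain="L", phi_range=(0.03, 0.1)),
        )
        curves, truth = gen_dispersion_dataset(23, clusters=clusters, n_decoys=0)
        h_res = sorted({c.residue_id for c in curves if c.residue_id.startswith("H")})
        l_res = sorted({c.residue_id for c in curves if c.residue_id.startswith("L")})
        result = cluster_search(curves, [[h_res + l_res], [h_res, l_res]],
                                model="luz_meiboom")
        assert result.best.partition == (tuple(h_res), tuple(l_res))
        # recovered rates near the generating 840 / 2033 within 2 SE
        for fit, want in zip(result.best.fits, (840.0, 2033.0)):
            assert abs(fit.k_ex - want) <= 2.0 * fit.k_ex_se
        # the nested pair got an F test and it favours the refinement
        assert any(p < 0.05 for _, _, _, p in result.f_tests)

    def test_identical_curves_tie(self, field600, nu_grid):
        p = ExchangeParams(r2_0=12.0, k_ex=900.0, phi_ppm2=0.05)
        clean = luz_meiboom_r2eff(nu_grid, p, field600)
        curves = [make_curve(rid, field600, nu_grid, clean)
                  for rid in ("H:R1", "H:R2", "H:R3")]
        res = cluster_search(curves, [[["H:R1", "H:R2", "H:R3"]],
                                      [["H:R1"], ["H:R2", "H:R3"]]],
                             model="luz_meiboom")
        assert all(r.chi2 == pytest.approx(0.0, abs=1e-6) for r in res.ranked)

    def test_empty_partition_list_rejected(self, field600, nu_grid):
        with pytest.raises(InvalidInputError):
            cluster_search([ramp_curve("H:R71", field600, nu_grid, 3.0)], [])
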