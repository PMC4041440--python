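import math

import numpy as np
import pandas as pd
import pytest

from ensdyn.nmr_dynamics import (
    GAMMA_RATIO_15N,
    RelaxationRates,
    RelaxationSeries,
    csp,
    default_selection,
    fit_exponential_rate,
    het_noe,
    hotspot_call,
    sliding_mean,
    tau_c_from_r2_r1,
)
from ensdyn.synthetic_data import (
    R1_DELAYS,
    R2_DELAYS,
    SyntheticSpec,
    make_relaxation,
    make_titration,
    relaxation_truth,
)


class TestExponentialFit:
    def test_noiseless_exact(self):
        series = RelaxationSeries(1, R1_DELAYS, 100.0 * np.exp(-2.0 * R1_DELAYS))
        fit = fit_exponential_rate(series)
        assert fit.ok
        assert fit.rate == pytest.approx(2.0, rel=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)

    def test_noisy_recovery_r2_grid(self):
        """R2 = 15/s with 2% noise: mean recovered rate within 2% of truth."""
        rng = np.random.default_rng(12)
        rates = []
        for _ in range(200):
            clean = 100.0 * np.exp(-15.0 * R2_DELAYS)
            noisy = clean * (1 + rng.normal(0, 0.02, len(R2_DELAYS)))
            rates.append(fit_exponential_rate(
                RelaxationSeries(1, R2_DELAYS, noisy)).rate)
        assert np.mean(rates) == pytest.approx(15.0, rel=0.02)

    def test_constant_series_flagged(self):
        series = RelaxationSeries(1, R1_DELAYS, np.full(len(R1_DELAYS), 50.0))
        fit = fit_exponential_rate(series)
        assert not fit.ok

    def test_too_few_delays_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            RelaxationSeries(1, [0.1, 0.2, 0.3], [3, 2, 1])

    def test_duplicates_inform_errors(self):
        rng = np.random.default_rng(3)
        clean = 80.0 * np.exp(-10.0 * R2_DELAYS)
        s = RelaxationSeries(
            1, R2_DELAYS,
            clean * (1 + rng.normal(0, 0.03, len(R2_DELAYS))),
            duplicates=clean * (1 + rng.normal(0, 0.03, len(R2_DELAYS))),
        )
        fit = fit_exponential_rate(s)
        assert fit.ok and fit.err > 0


class TestHetNoe:
    def test_unity_and_ratio(self):
        assert het_noe(5.0, 5.0)[0] == pytest.approx(1.0)
        assert het_noe(0.78 * 3.0, 3.0)[0] == pytest.approx(0.78)

    def test_duplicate_half_range_error(self):
        noe, err = het_noe(0.8, 1.0, duplicates=(0.80, 0.76))
        assert noe == pytest.approx(0.78)
        assert err == pytest.approx(0.02)

    def test_zero_denominator(self):
        with pytest.raises(ValueError, match="zero"):
            het_noe(1.0, 0.0)


def _rates(ratios, noe=0.85):
    return [RelaxationRates(i + 1, 1.0, 0.01, r, 0.1, noe, 0.02)
            for i, r in enumerate(ratios)]


class TestTauC:
    def test_closed_form_value(self):
        """<R2/R1> = 10 at nu_N = 50 MHz: tau_c = sqrt(53)/(4 pi nu_N)."""
        est = tau_c_from_r2_r1(_rates([10.0] * 10), 50.0 / GAMMA_RATIO_15N)
        assert est.nu_n_hz == pytest.approx(50e6)
        assert est.tau_c_ns == pytest.approx(11.59, abs=0.01)

    def test_boundary_root_raises(self):
        with pytest.raises(ValueError, match="7/6"):
            tau_c_from_r2_r1(_rates([7.0 / 6.0] * 10), 599.78)

    def test_monotone_in_ratio_and_inverse_in_frequency(self):
        t1 = tau_c_from_r2_r1(_rates([15.0] * 10), 599.78).tau_c_s
        t2 = tau_c_from_r2_r1(_rates([25.0] * 10), 599.78).tau_c_s
        assert t2 > t1
        ta = tau_c_from_r2_r1(_rates([20.0] * 10), 500.0).tau_c_s
        tb = tau_c_from_r2_r1(_rates([20.0] * 10), 1000.0).tau_c_s
        assert ta == pytest.approx(2.0 * tb, rel=1e-9)

    def test_selection_excludes_mobile_residues(self):
        rigid = _rates([23.7] * 20)
        mobile = [RelaxationRates(100 + i, 1.5, 0.01, 10.0, 0.1, 0.3, 0.02)
                  for i in range(5)]
        sel = default_selection(rigid + mobile)
        assert all(r.noe >= 0.65 for r in sel)
        assert {r.residue for r in sel} <= {r.residue for r in rigid}

    def test_synthetic_profile_recovery(self):
        """Full pipeline on generated decays reproduces the generator's
        rigid-core R2/R1 and a tumbling time near 15 ns."""
        spec = SyntheticSpec(seed=41)
        r1df, r2df, noedf, truth = make_relaxation(spec)
        import ensdyn.nmr_dynamics as nd

        def fits(df):
            out = {}
            for res, grp in df.groupby("residue"):
                g1 = grp[grp.replicate == 1].sort_values("delay_s")
                g2 = grp[grp.replicate == 2].sort_values("delay_s")
                out[res] = fit_exponential_rate(RelaxationSeries(
                    int(res), g1.delay_s.to_numpy(), g1.intensity.to_numpy(),
                    g2.intensity.to_numpy()))
            return out

        f1, f2 = fits(r1df), fits(r2df)
        rates = []
        for _, t in truth.iterrows():
            res = int(t.residue)
            rates.append(RelaxationRates(res, f1[res].rate, f1[res].err,
                                         f2[res].rate, f2[res].err,
                                         t.noe, 0.02))
        # fitted rates track the ground-truth profile
        for col, fit_map in (("r1", f1), ("r2", f2)):
            fitted = np.array([fit_map[int(r)].rate for r in truth.residue])
            r = np.corrcoef(fitted, truth[col].to_numpy())[0, 1]
            assert r > 0.95
        est = tau_c_from_r2_r1(rates, 599.78)
        truth_ratio = spec.r2_core / spec.r1_core
        assert est.mean_r2_over_r1 == pytest.approx(truth_ratio, rel=0.02)


class TestCSP:
    @pytest.mark.parametrize(
        "dh,dn,expected",
        [(0.0, 0.0, 0.0), (0.0, 6.51, 1.0), (0.10, 0.651, 0.1414)],
    )
    def test_combined_shift(self, dh, dn, expected):
        free = pd.DataFrame({"residue": [1], "h_ppm": [8.0],
                             "n_ppm": [120.0], "intensity": [1.0]})
        bound = pd.DataFrame({"residue": [1], "h_ppm": [8.0 + dh],
                              "n_ppm": [120.0 + dn], "intensity": [0.5]})
        prof = csp(free, bound)
        assert prof.dd_combined[0] == pytest.approx(expected, abs=1e-4)

    def test_swap_invariance(self):
        rng = np.random.default_rng(5)
        free = pd.DataFrame({"residue": np.arange(10), "h_ppm": rng.normal(8, 0.5, 10),
                             "n_ppm": rng.normal(120, 5, 10), "intensity": np.ones(10)})
        bound = free.copy()
        bound["h_ppm"] += rng.normal(0, 0.05, 10)
        bound["n_ppm"] += rng.normal(0, 0.3, 10)
        a = csp(free, bound).dd_combined
        b = csp(bound, free).dd_combined
        assert np.allclose(a, b)

    def test_missing_residue_is_nan(self):
        free = pd.DataFrame({"residue": [1, 2], "h_ppm": [8.0, 8.5],
                             "n_ppm": [120.0, 121.0], "intensity": [1.0, 1.0]})
        bound = pd.DataFrame({"residue": [1], "h_ppm": [8.1],
                              "n_ppm": [120.5], "intensity": [0.4]})
        prof = csp(free, bound)
        i = list(prof.residues).index(2)
        assert np.isnan(prof.dd_combined[i])
        assert np.isnan(prof.intensity_ratio[i])

    def test_sliding_mean_constant_including_edges(self):
        vals = np.full(20, 0.7)
        assert np.allclose(sliding_mean(vals, 5), 0.7)

    def test_hotspot_flat_profile_empty(self):
        free = pd.DataFrame({"residue": np.arange(20), "h_ppm": 8.0,
                             "n_ppm": 120.0, "intensity": 1.0})
        prof = csp(free, free)
        assert hotspot_call(prof) == set()

    def test_hotspot_all_missing_errors(self):
        free = pd.DataFrame({"residue": [1], "h_ppm": [8.0],
                             "n_ppm": [120.0], "intensity": [1.0]})
        bound = pd.DataFrame({"residue": [2], "h_ppm": [8.0],
                              "n_ppm": [120.0], "intensity": [1.0]})
        prof = csp(free, bound)
        with pytest.raises(ValueError, match="no valid"):
            hotspot_call(prof)

    def test_binding_site_recovered(self):
        """Injected site called back with Jaccard >= 0.5 (shift metric)."""
        spec = SyntheticSpec(seed=42)
        free, steps, truth = make_titration(spec)
        prof = csp(free, steps[truth["analysis_step"] - 1])
        called = hotspot_call(prof)
        site = set(truth["site_residues"])
        jaccard = len(called & site) / len(called | site)
        assert jaccard >= 0.5
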