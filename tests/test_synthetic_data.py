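import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tpod
from tpod.synthetic_data import ResponseCurve, log2_noise_sd


class TestMakeDesign:
    @pytest.mark.parametrize("args,expected", [
        ((2.92, 3, 10, 3), [0, 0.00292, 0.0292, 0.292, 2.92]),
        ((48.3, 0, 10, 3), [0, 48.3]),
        ((1.0, 2, 2, 3), [0, 0.25, 0.5, 1.0]),
    ])
    def test_dilution_series(self, args, expected):
        d = tpod.make_design(*args)
        assert np.allclose(d.concentrations, expected, rtol=1e-12)

    @pytest.mark.parametrize("args", [
        (-1.0, 3, 10, 3),     # negative anchor
        (0.0, 3, 10, 3),      # zero anchor
        (1.0, 3, 1.0, 3),     # dilution factor not > 1
        (1.0, 3, 10, 1),      # too few replicates
    ])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            tpod.make_design(*args)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(anchor=st.floats(0.01, 100.0), n=st.integers(0, 4),
           factor=st.floats(1.5, 20.0))
    def test_series_invariants(self, anchor, n, factor):
        d = tpod.make_design(anchor, n, factor, 3)
        c = np.asarray(d.concentrations)
        assert c[0] == 0.0 and np.count_nonzero(c == 0) == 1
        assert np.all(np.diff(c) > 0)
        assert math.isclose(c[-1], anchor)
        nz = c[c > 0]
        assert np.allclose(nz[1:] / nz[:-1], factor, rtol=1e-9)


class TestSimulateCounts:
    def test_identical_seed_gives_identical_matrix(self, tbbpa_design):
        truth = tpod.make_truth(100, tbbpa_design, seed=3)
        a = tpod.simulate_counts(tbbpa_design, truth, 50_000, seed=1)
        b = tpod.simulate_counts(tbbpa_design, truth, 50_000, seed=1)
        c = tpod.simulate_counts(tbbpa_design, truth, 50_000, seed=2)
        assert a.counts.equals(b.counts)
        assert not a.counts.equals(c.counts)

    def test_null_gene_mean_flat_across_doses(self):
        # a non-responsive gene has the same expected count at every dose
        design = tpod.make_design(10.0, 2, 10, 100)
        truth = tpod.make_truth(5, design, seed=1, responsive_fraction=0.0,
                                dispersion=0.0)
        cm = tpod.simulate_counts(design, truth, 5_000, seed=4,
                                  library_size_log_sd=0.0)
        concs = cm.concentrations()
        for g in cm.counts.index:
            y = cm.counts.loc[g].to_numpy(float)
            gm = [y[concs == u].mean() for u in np.unique(concs)]
            se = y.std(ddof=1) / math.sqrt((concs == concs[0]).sum())
            assert max(gm) - min(gm) < 6 * se

    def test_poisson_limit_moments(self):
        # dispersion 0: variance equals the mean (checked over 1e4 draws)
        design = tpod.make_design(1.0, 0, 10, 5000)   # 2 concs x 5000 reps
        truth = tpod.make_truth(1, design, seed=1, responsive_fraction=0.0,
                                dispersion=0.0, baseline_log_sd=0.0)
        cm = tpod.simulate_counts(design, truth, truth.frame.baseline_mean
                                  .sum(), seed=7, library_size_log_sd=0.0)
        y = cm.counts.iloc[0].to_numpy(float)
        n, m, s2 = len(y), y.mean(), y.var(ddof=1)
        # Var(s2) for Poisson: (mu4 - sigma^4 (n-3)/(n-1)) / n, mu4 = l(1+3l)
        mu4 = m * (1 + 3 * m)
        se = math.sqrt((mu4 - m ** 2 * (n - 3) / (n - 1)) / n)
        assert abs(s2 - m) < 3 * se

    def test_nb_moments_match_dispersion(self):
        design = tpod.make_design(1.0, 0, 10, 5000)
        truth = tpod.make_truth(1, design, seed=1, responsive_fraction=0.0,
                                dispersion=0.1, baseline_log_sd=0.0)
        cm = tpod.simulate_counts(design, truth, truth.frame.baseline_mean
                                  .sum(), seed=8, library_size_log_sd=0.0)
        y = cm.counts.iloc[0].to_numpy(float)
        mu = y.mean()
        expected_var = mu + 0.1 * mu ** 2
        assert abs(y.var(ddof=1) / expected_var - 1) < 0.1

    def test_column_sums_track_library_size(self, tbbpa_design):
        truth = tpod.make_truth(5000, tbbpa_design, seed=5)
        cm = tpod.simulate_counts(tbbpa_design, truth, 300_000, seed=5,
                                  library_size_log_sd=0.0)
        sums = cm.counts.to_numpy().sum(axis=0)
        assert np.all(np.abs(sums / 300_000 - 1) < 0.05)

    def test_negative_dispersion_rejected(self, tbbpa_design):
        truth = tpod.make_truth(5, tbbpa_design, seed=1)
        truth.frame.loc[0, "dispersion"] = -0.1
        with pytest.raises(ValueError):
            tpod.simulate_counts(tbbpa_design, truth, 1000, seed=1)


class TestTrueBmd:
    def test_linear_closed_form(self):
        cv = ResponseCurve("linear", {"slope": 0.5})
        assert tpod.true_bmd_of(cv, 1.0, c_max=10.0) == pytest.approx(2.0,
                                                                      rel=1e-6)

    def test_hill_half_maximum(self):
        # amplitude 2, k=10, n=1: 2c/(10+c) = 1 at c = 10
        cv = ResponseCurve("hill", {"k": 10.0, "n": 1.0, "amplitude": 2.0})
        assert tpod.true_bmd_of(cv, 1.0, c_max=10.0) == pytest.approx(
            10.0, rel=1e-6)

    def test_flat_curve_unreachable(self):
        assert tpod.true_bmd_of(ResponseCurve("null"), 1.0, c_max=10.0) is None

    @pytest.mark.parametrize("curve,bmr", [
        (ResponseCurve("linear", {"slope": 0.3, "cap": 2.0}), 0.5),
        (ResponseCurve("hill", {"k": 0.2, "n": 2.0, "amplitude": -1.5}), 0.4),
        (ResponseCurve("exp", {"amplitude": 2.0, "rate": 0.8}), 0.7),
    ])
    def test_agrees_with_dense_grid_scan(self, curve, bmr):
        c_max = 3.0
        hi = 10 * c_max
        grid = np.linspace(0, hi, 10_000)
        dev = np.abs(curve(grid) - curve(0.0))
        idx = np.nonzero(dev >= bmr)[0]
        oracle = grid[idx[0]] if len(idx) else None
        got = tpod.true_bmd_of(curve, bmr, c_max=c_max)
        step = hi / 9_999
        assert got is not None and abs(got - oracle) <= step


class TestTruthTable:
    def test_invariants_and_roundtrip(self, tbbpa_design, tmp_path):
        truth = tpod.make_truth(300, tbbpa_design, seed=9)
        f = truth.frame
        assert (f.baseline_mean > 0).all()
        assert (f.dispersion >= 0).all()
        assert (f.responsive == f.true_bmd.notna()).all()
        bmds = f.loc[f.responsive, "true_bmd"]
        assert ((bmds > 0) & (bmds <= tbbpa_design.max_conc)).all()
        truth.to_tsv(tmp_path / "truth.tsv")
        back = tpod.TruthTable.from_tsv(tmp_path / "truth.tsv")
        assert back.frame["gene_id"].equals(f["gene_id"])
        assert np.allclose(back.frame["true_bmd"].fillna(-1),
                           f["true_bmd"].fillna(-1))

    def test_noise_sd_delta_method(self):
        # phi = 0.05, mu large: sd -> sqrt(phi)/ln2
        assert log2_noise_sd(1e9, 0.05) == pytest.approx(
            math.sqrt(0.05) / math.log(2), rel=1e-3)
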