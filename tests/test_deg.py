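import math

import numpy as np
import pytest

import tpod
from tpod.deg import LFC_CUTOFF, Q_CUTOFF

from conftest import make_count_matrix


class TestSizeFactors:
    def test_doubled_column(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        cm = make_count_matrix(np.column_stack([base, 2 * base]))
        sf = tpod.size_factors(cm)
        assert np.allclose(sf, [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_identical_columns(self):
        base = np.arange(1, 21)
        cm = make_count_matrix(np.column_stack([base] * 4))
        assert np.allclose(tpod.size_factors(cm), 1.0)

    def test_single_sample(self):
        cm = make_count_matrix(np.arange(1, 11)[:, None])
        assert np.allclose(tpod.size_factors(cm), 1.0)

    def test_no_common_gene_errors(self):
        cm = make_count_matrix(np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError):
            tpod.size_factors(cm)


class TestNormalize:
    @pytest.mark.parametrize("count,factor,pseudo,expected", [
        (0, 1.0, 1.0, 0.0),
        (7, 1.0, 1.0, 3.0),
        (10, 2.0, 1.0, math.log2(6)),
    ])
    def test_log2_transform(self, count, factor, pseudo, expected):
        cm = make_count_matrix(np.array([[count]]))
        import pandas as pd
        factors = pd.Series([factor], index=cm.counts.columns)
        norm = tpod.normalize_log2(cm, factors, pseudo)
        assert norm.log2.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_pseudocount(self):
        cm = make_count_matrix(np.array([[1, 2]]))
        with pytest.raises(ValueError):
            tpod.normalize_log2(cm, pseudocount=0.0)


def _two_arm_counts(rng, n_genes, base_mean, phi, shift_lfc=None, n_per=3):
    """NB counts for a control + treatment contrast, optional per-gene shift."""
    mu0 = rng.lognormal(math.log(base_mean), 0.5, n_genes)
    shift = np.zeros(n_genes) if shift_lfc is None else shift_lfc
    r = 1.0 / phi
    cols = []
    for arm, s in (("0", 0.0), ("1", 1.0)):
        for _ in range(n_per):
            mu = mu0 * 2.0 ** (shift * s)
            cols.append(rng.negative_binomial(r, r / (r + mu)))
    counts = np.column_stack(cols)
    concs = [0.0] * n_per + [1.0] * n_per
    reps = [f"rep{i + 1}" for i in range(n_per)] * 2
    return make_count_matrix(counts, concs, reps)


class TestNbTest:
    def test_identical_arms_are_null(self):
        base = np.arange(20, 40)
        counts = np.column_stack([base] * 6)
        cm = make_count_matrix(counts, [0, 0, 0, 1, 1, 1],
                               ["rep1", "rep2", "rep3"] * 2)
        res = tpod.nb_test(cm)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["p"] >= 0.5).all()

    def test_fourfold_shift_recovered(self):
        rng = np.random.default_rng(10)
        shift = np.zeros(400)
        shift[:20] = 2.0      # 4-fold up
        cm = _two_arm_counts(rng, 400, 100, 0.05, shift)
        res = tpod.nb_test(cm).set_index("gene_id")
        hits = res.loc[[f"g{i}" for i in range(20)]]
        assert hits["is_deg"].mean() >= 0.8
        assert (hits["log2fc"] - 2.0).abs().median() < 0.5

    def test_null_type1_error_calibrated(self):
        # fraction of null genes with p < 0.05 within 3 binomial SE of 0.05
        rng = np.random.default_rng(11)
        cm = _two_arm_counts(rng, 2000, 150, 0.05)
        res = tpod.nb_test(cm)
        rate = (res["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se

    def test_all_zero_gene_reported_untested(self):
        counts = np.vstack([np.zeros(6, dtype=int),
                            np.full(6, 50, dtype=int),
                            np.arange(6) + 30])
        cm = make_count_matrix(counts, [0, 0, 0, 1, 1, 1],
                               ["rep1", "rep2", "rep3"] * 2)
        res = tpod.nb_test(cm).set_index("gene_id")
        assert math.isnan(res.loc["g0", "p"])
        assert not res.loc["g0", "is_deg"]

    def test_depth_scaling_leaves_lfc_unchanged(self):
        rng = np.random.default_rng(12)
        shift = np.zeros(200)
        shift[:10] = 1.5
        cm = _two_arm_counts(rng, 200, 200, 0.05, shift)
        scaled = make_count_matrix(cm.counts.to_numpy() * 5,
                                   cm.samples["concentration_uM"],
                                   cm.samples["replicate"])
        a = tpod.nb_test(cm).set_index("gene_id")["log2fc"]
        b = tpod.nb_test(scaled).set_index("gene_id")["log2fc"]
        both = a.notna() & b.notna()
        assert (a[both] - b[both]).abs().max() < 0.05

    def test_bh_is_monotone_in_p(self):
        rng = np.random.default_rng(13)
        cm = _two_arm_counts(rng, 300, 100, 0.05)
        res = tpod.nb_test(cm).dropna(subset=["p"])
        by_p = res.sort_values(["p", "gene_id"])["gene_id"].tolist()
        by_q = res.sort_values(["q", "p", "gene_id"])["gene_id"].tolist()
        assert by_p == by_q


class TestCallDegs:
    @pytest.mark.parametrize("q,lfc,expected", [
        (0.04, 0.60, True),     # passes both gates
        (0.04, 0.50, False),    # fails the 1.5-fold cutoff
        (0.06, 3.00, False),    # fails the FDR gate
    ])
    def test_threshold_gates(self, q, lfc, expected):
        import pandas as pd
        rec = pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc],
                            "p": [q / 2], "q": [q]})
        assert tpod.call_degs(rec)["is_deg"].iloc[0] == expected

    def test_deg_set_shrinks_with_stricter_fold_cutoff(self,
                                                       simulated_dataset):
        _, counts = simulated_dataset
        res = tpod.nb_test(counts)
        n15 = tpod.call_degs(res, Q_CUTOFF, math.log2(1.5))["is_deg"].sum()
        n20 = tpod.call_degs(res, Q_CUTOFF, math.log2(2.0))["is_deg"].sum()
        assert n20 <= n15

    def test_default_cutoffs(self):
        assert Q_CUTOFF == 0.05
        assert round(LFC_CUTOFF, 3) == 0.585
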