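"""Normalization, differential expression, effect estimation and ddCt."""

import numpy as np
import pandas as pd
import pytest

from relocus import sim
from relocus.expression import (
    QpcrMeasurement,
    ddct,
    differential,
    induced_genes,
    mrna_share,
    normalize,
    percent_reduction,
    prefilter,
    remaining_fraction,
    size_factors,
)


def cdf(data, samples=None):
    df = pd.DataFrame(data).T
    if samples:
        df.columns = samples
    return df


class TestPrefilter:
    def test_threshold_boundary(self):
        counts = pd.DataFrame(
            {"s1": [4, 5, 0], "s2": [5, 5, 0]}, index=["g9", "g10", "g0"]
        )
        kept = prefilter(counts)
        assert list(kept.index) == ["g10"]  # total 9 dropped, 10 kept

    def test_all_zero_empty(self):
        counts = pd.DataFrame(np.zeros((5, 3), dtype=int))
        assert len(prefilter(counts)) == 0

    def test_matches_sum_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 6, size=(50, 4)))
        kept = prefilter(counts, min_total=10)
        for g in counts.index:
            assert (g in kept.index) == (counts.loc[g].sum() >= 10)


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_factor_ratio(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_matches_literal_median_of_ratios(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 500, size=(200, 6)))
        sf = size_factors(counts)
        # independent literal computation of the formula
        log_gm = np.log(counts.values).mean(axis=1)
        for j, col in enumerate(counts.columns):
            ratios = np.log(counts.values[:, j]) - log_gm
            assert np.isclose(sf[col], np.exp(np.median(ratios)))

    def test_all_genes_with_zero_raise(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-count"):
            size_factors(counts)


class TestDifferential:
    def test_identical_groups_zero_lfc(self):
        rng = np.random.default_rng(2)
        x = rng.integers(10, 100, size=(20, 2))
        counts = pd.DataFrame(
            np.hstack([x, x]), columns=["a1", "a2", "b1", "b2"]
        )
        res = differential(counts, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert (res["p_value"] == 1.0).all()

    def test_group_size_validation(self):
        counts = pd.DataFrame({"a1": [1], "b1": [1], "b2": [2]})
        with pytest.raises(ValueError):
            differential(counts, ["a1"], ["b1", "b2"])

    def test_bh_adjustment_matches_stepup_and_is_rank_monotone(self):
        rng = np.random.default_rng(3)
        r = 1 / 0.02
        means = np.full(300, 200.0)
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + means[:, None]), size=(300, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        res = differential(counts, [f"s{i}" for i in range(4)],
                           [f"s{i}" for i in range(4, 8)])
        p = res["p_value"].values
        padj = res["adjusted_p"].values
        # reference step-up computation
        m = len(p)
        order = np.argsort(p)
        ref = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        ref = np.minimum(ref, 1.0)
        assert np.allclose(padj[order], ref)
        # monotone in raw p-value ranks
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert ((padj >= p - 1e-12) & (padj <= 1.0)).all()

    def test_casein_stage_fold_change_near_100(self, annotation):
        """p6 -> L1 contrast recovers the ~100-fold casein induction."""
        fcs = []
        for seed in range(5):
            cfg = sim.SyntheticConfig(seed=seed)
            cnt, _ = sim.generate_expression(
                cfg, annotation,
                [("mammary", "p6", "WT", 3), ("mammary", "L1", "WT", 4)],
            )
            a = [c for c in cnt.columns if "p6" in c]
            b = [c for c in cnt.columns if "L1" in c]
            res = differential(prefilter(cnt), a, b)
            fcs.append(
                float((2 ** res.loc[sim.CASEIN_GENES, "log2_fold_change"]).mean())
            )
        assert 80 <= np.mean(fcs) <= 125

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        r = 1 / 0.02
        means = np.exp(rng.normal(np.log(300), 0.7, size=2000))
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + means[:, None]), size=(2000, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        res = differential(counts, [f"s{i}" for i in range(4)],
                           [f"s{i}" for i in range(4, 8)])
        rate = float((res["p_value"] < 0.05).mean())
        assert 0.02 < rate < 0.08


class TestInducedGenes:
    def test_all_caseins_induced_on_defaults(self, annotation):
        cfg = sim.SyntheticConfig(seed=0)
        cnt, meta = sim.generate_expression(cfg, annotation)
        ind = induced_genes(cnt, meta)
        assert set(sim.CASEIN_GENES) <= ind

    def test_infinite_threshold_empty(self, annotation):
        cfg = sim.SyntheticConfig(seed=0)
        cnt, meta = sim.generate_expression(cfg, annotation)
        assert induced_genes(cnt, meta, fc_threshold=1e12) == set()

    def test_missing_stage_errors(self, annotation):
        cfg = sim.SyntheticConfig(seed=0)
        cnt, meta = sim.generate_expression(
            cfg, annotation, [("mammary", "p6", "WT", 3)]
        )
        with pytest.raises(ValueError):
            induced_genes(cnt, meta)


class TestEffectEstimates:
    def test_percent_reduction_arithmetic(self):
        # several stable reference genes so size factors are all 1
        counts = pd.DataFrame(
            {"w1": [100, 7, 20, 55], "w2": [100, 7, 20, 55],
             "m1": [2, 7, 20, 55], "m2": [2, 7, 20, 55]},
            index=["g", "r1", "r2", "r3"],
        )
        assert np.isclose(
            percent_reduction(counts, "g", ["w1", "w2"], ["m1", "m2"]), 98.0
        )
        assert np.isclose(
            percent_reduction(counts, "r1", ["w1", "w2"], ["m1", "m2"]), 0.0
        )

    def test_wt_zero_errors(self):
        counts = pd.DataFrame(
            {"w1": [0, 5], "w2": [0, 5], "m1": [1, 5], "m2": [1, 5]},
            index=["g", "ref"],
        )
        with pytest.raises(ZeroDivisionError):
            percent_reduction(counts, "g", ["w1", "w2"], ["m1", "m2"])

    def test_invariant_to_library_scaling(self):
        rng = np.random.default_rng(5)
        base = rng.integers(50, 500, size=(40, 4)).astype(float)
        counts = pd.DataFrame(base, columns=["w1", "w2", "m1", "m2"])
        counts.iloc[0, 2:] = counts.iloc[0, 2:] * 0.1  # true reduction
        scaled = counts.copy()
        scaled[["m1", "m2"]] = (scaled[["m1", "m2"]] * 3).round()
        a = percent_reduction(counts.round(), 0, ["w1", "w2"], ["m1", "m2"])
        b = percent_reduction(scaled.round(), 0, ["w1", "w2"], ["m1", "m2"])
        assert abs(a - b) < 2.0

    def test_dse_mammary_csn3_recovery(self, annotation):
        """Super-enhancer deletion leaves ~2% of Csn3-like expression."""
        vals = []
        for seed in range(10):
            cfg = sim.SyntheticConfig(seed=seed)
            cnt, _ = sim.generate_expression(
                cfg, annotation,
                [("mammary", "p18", "WT", 4), ("mammary", "p18", "dSE", 4)],
            )
            wt = [c for c in cnt.columns if "_WT_" in c]
            mut = [c for c in cnt.columns if "dSE" in c]
            vals.append(percent_reduction(cnt, "Csn3", wt, mut))
        assert abs(np.mean(vals) - 98.0) < 5.0


class TestShareAndQpcr:
    def test_share_limits(self):
        counts = pd.DataFrame({"s": [10, 30]}, index=["g1", "g2"])
        assert mrna_share(counts, ["g1", "g2"], ["s"]) == 100.0
        assert mrna_share(counts, [], ["s"]) == 0.0

    def test_share_zero_total_errors(self):
        counts = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(ValueError):
            mrna_share(counts, [0], ["s"])

    @pytest.mark.parametrize(
        "shift, expected", [(0.0, 1.0), (5.0, 0.03125), (-1.0, 2.0)]
    )
    def test_ddct_closed_form(self, shift, expected):
        wt = QpcrMeasurement("wt", [20.0, 20.1, 19.9], [15.0, 15.1, 14.9])
        mut = QpcrMeasurement(
            "mut", [20.0 + shift, 20.1 + shift, 19.9 + shift],
            [15.0, 15.1, 14.9],
        )
        assert np.isclose(ddct(wt, mut), expected)

    def test_qpcr_validation(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("x", [], [15.0])
        with pytest.raises(ValueError):
            QpcrMeasurement("x", [0.0, 20.0], [15.0])
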