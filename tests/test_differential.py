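"""NB Wald test, TE shift test, dispersion estimation, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decaptools import (
    Contrast,
    bh_adjust,
    call_regulated_sets,
    estimate_dispersions,
    nb_wald_test,
    run_differential,
    te_shift_test,
)
from decaptools.differential import DifferentialResult
from decaptools.normalization import median_of_ratios_size_factors
from decaptools.synthetic_data import AssayCounts


def _null_counts(rng, mu, alpha, n_samples=4):
    k = 1.0 / alpha
    return np.column_stack(
        [rng.negative_binomial(k, k / (k + mu)) for _ in range(n_samples)]
    )


def _assay(counts, design, name="rna"):
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=design["sample_id"],
    )
    return AssayCounts(name, df, design)


class TestDispersions:
    def test_poisson_counts_give_near_floor(self, two_group_design):
        rng = np.random.default_rng(0)
        counts = rng.poisson(500.0, size=(500, 4))
        ac = _assay(counts, two_group_design)
        sf = median_of_ratios_size_factors(ac)
        disp = estimate_dispersions(ac, sf, two_group_design)
        assert disp.median() < 0.01

    def test_recovers_simulated_dispersion(self, two_group_design):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(np.log(400), 0.8, 500)
        counts = _null_counts(rng, mu, alpha=0.1)
        ac = _assay(counts, two_group_design)
        sf = median_of_ratios_size_factors(ac)
        disp = estimate_dispersions(ac, sf, two_group_design)
        assert 0.05 <= disp.median() <= 0.2

    def test_single_replicate_per_group_rejected(self):
        design = pd.DataFrame(
            {"sample_id": ["a", "b"], "genotype": ["WT", "mut"], "replicate": [1, 1]}
        )
        ac = _assay(np.ones((5, 2), dtype=int) * 10, design)
        sf = median_of_ratios_size_factors(ac)
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(ac, sf, design)


class TestWald:
    def test_identical_groups_null_result(self, two_group_design):
        counts = np.tile(np.array([[100], [40], [2000]]), (1, 4))
        ac = _assay(counts, two_group_design)
        sf = median_of_ratios_size_factors(ac)
        disp = estimate_dispersions(ac, sf, two_group_design)
        res = nb_wald_test(ac, sf, disp, Contrast("mut"), two_group_design)
        t = res.table[res.table.tested]
        assert np.allclose(t.log2_fc, 0.0)
        assert (t.p_value > 0.99).all()

    def test_fold_change_consistency_at_depth(self, two_group_design):
        # a true 4-fold gene at high depth -> log2_fc close to 2
        rng = np.random.default_rng(3)
        mu = np.full(200, 2000.0)
        counts = _null_counts(rng, mu, alpha=0.02)
        counts[0, 2:] = rng.negative_binomial(50, 50 / (50 + 8000.0), 2)
        ac = _assay(counts, two_group_design)
        res = run_differential(ac, Contrast("mut"))
        assert res.table.iloc[0]["log2_fc"] == pytest.approx(2.0, abs=0.3)
        assert res.table.iloc[0]["q_value"] < 0.01

    def test_low_count_genes_untested(self, two_group_design):
        counts = np.vstack([np.full((1, 4), 2), np.full((5, 4), 500)])
        ac = _assay(counts, two_group_design)
        res = run_differential(ac, Contrast("mut"))
        assert not res.table.iloc[0]["tested"]
        assert np.isnan(res.table.iloc[0]["p_value"])

    def test_estimated_lfc_unbiased_at_high_depth(self, two_group_design):
        rng = np.random.default_rng(9)
        n = 400
        mu_wt = np.full(n, 1e7 / n)
        fc = 2.0 ** rng.uniform(-1, 1, n)
        counts = np.column_stack(
            [
                *(rng.negative_binomial(100, 100 / (100 + mu_wt)) for _ in range(2)),
                *(rng.negative_binomial(100, 100 / (100 + mu_wt * fc)) for _ in range(2)),
            ]
        )
        ac = _assay(counts, two_group_design)
        res = run_differential(ac, Contrast("mut"))
        bias = (res.table["log2_fc"] - np.log2(fc)).mean()
        assert abs(bias) < 0.05


class TestTEShift:
    def test_parallel_changes_cancel(self, two_group_design):
        rng = np.random.default_rng(5)
        mu = np.full(300, 800.0)
        base = _null_counts(rng, mu, 0.02)
        doubled = base.copy()
        doubled[:, 2:] = _null_counts(rng, mu * 2, 0.02)[:, 2:]
        rna = _assay(doubled, two_group_design, "rna")
        rpf = _assay(
            np.column_stack([_null_counts(rng, mu, 0.02)[:, :2],
                             _null_counts(rng, mu * 2, 0.02)[:, 2:]]),
            two_group_design, "rpf",
        )
        res = te_shift_test(rpf, rna, Contrast("mut"))
        t = res.table[res.table.tested]
        assert abs(t.log2_fc.median()) < 0.1
        assert (t.q_value < 0.1).mean() < 0.02

    def test_rpf_only_doubling_gives_unit_te_shift(self, two_group_design):
        # RPF doubles for a 10% subset (a global doubling would rightly be
        # absorbed by relative normalization); mRNA is unchanged
        rng = np.random.default_rng(6)
        mu = np.full(300, 800.0)
        rna = _assay(_null_counts(rng, mu, 0.02), two_group_design, "rna")
        mu_mut = mu.copy()
        mu_mut[:30] *= 2
        rpf_counts = np.column_stack(
            [_null_counts(rng, mu, 0.02)[:, :2], _null_counts(rng, mu_mut, 0.02)[:, 2:]]
        )
        rpf = _assay(rpf_counts, two_group_design, "rpf")
        res = te_shift_test(rpf, rna, Contrast("mut"))
        t = res.table[res.table.tested]
        assert t.log2_fc.iloc[:30].median() == pytest.approx(1.0, abs=0.15)
        assert abs(t.log2_fc.iloc[30:].median()) < 0.1


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over j with p_j >= p_i of p_j*m/rank_j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


class TestBH:
    def test_hand_step_up(self):
        assert bh_adjust(np.array([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        assert bh_adjust(np.array([0.42])) == pytest.approx([0.42])

    def test_all_ones(self):
        assert bh_adjust(np.ones(5)) == pytest.approx(np.ones(5))

    def test_nan_excluded_from_m(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx([0.02, 0.04])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_brute_force(self, p):
        assert bh_adjust(np.array(p)) == pytest.approx(brute_force_bh(p))

    def test_matches_scipy_reference(self):
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        assert bh_adjust(p) == pytest.approx(false_discovery_control(p))


class TestSetCalling:
    def _result(self, rows):
        table = pd.DataFrame(
            rows,
            columns=["log2_fc", "se", "p_value", "q_value", "mean_expression", "tested"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        return DifferentialResult(measure="mRNA", contrast="mut_vs_WT", table=table)

    def test_threshold_inclusion_and_strict_boundary(self):
        res = self._result([
            [np.log2(1.6), 0.1, 1e-4, 0.01, 100, True],   # in
            [np.log2(1.5), 0.1, 1e-4, 0.01, 100, True],   # boundary: out
            [np.log2(1.6), 0.1, 0.2, 0.06, 100, True],    # q too high: out
            [np.log2(1.6), 0.1, 1e-4, 0.01, 100, False],  # untested: out
        ])
        s = call_regulated_sets(res, 1.5, 0.05, "up")
        assert s.members == frozenset({"g0"})

    def test_down_direction(self):
        res = self._result([[-1.0, 0.1, 1e-4, 0.001, 50, True]])
        assert len(call_regulated_sets(res, 1.5, 0.05, "down")) == 1
        assert len(call_regulated_sets(res, 1.5, 0.05, "up")) == 0
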