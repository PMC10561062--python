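"""bicor core, correlation p-values, stratified records, tissue screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endocor import (
    bicor,
    bicor_matrix,
    correlation_pvalue,
    cross_tissue_correlations,
    screen_tissues,
    simulate_cohort,
)
from endocor.correlate import RECORD_COLUMNS, empty_records
from endocor.estrogen import EstrogenState
from endocor.resources import GeneSet, TissueExpression
from helpers import build_records, oracle_bicor, oracle_t_sf, small_config

FROZEN_X = (0.2, 1.1, -0.7, 2.4, 0.9, -1.3, 0.4, 1.8)
FROZEN_Y = (0.5, 0.9, -1.1, 2.0, 1.2, -0.8, 0.0, 1.5)
FROZEN_BICOR = 0.9539423180438656  # oracle_bicor(FROZEN_X, FROZEN_Y)


finite_floats = st.floats(-50.0, 50.0, allow_nan=False, allow_infinity=False)


class TestBicor:
    def test_identity_is_one(self):
        assert bicor([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == (1.0, "bicor")

    def test_exact_antimonotone_is_minus_one(self):
        r, method = bicor([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0, abs=1e-12)
        assert method == "bicor"

    def test_frozen_oracle_value(self):
        r, method = bicor(FROZEN_X, FROZEN_Y)
        assert method == "bicor"
        assert r == pytest.approx(FROZEN_BICOR, abs=1e-10)
        # and the oracle itself still reproduces the frozen constant
        assert oracle_bicor(FROZEN_X, FROZEN_Y) == pytest.approx(
            FROZEN_BICOR, abs=1e-12
        )

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, method = bicor(x, y)
            if method == "bicor":
                assert r == pytest.approx(oracle_bicor(x, y), abs=1e-10)

    def test_robust_to_single_outlier(self):
        x = np.linspace(0.0, 1.0, 30)
        y = x.copy()
        x_out = x.copy()
        x_out[7] = 40.0  # one wild point in an otherwise perfect pair
        r_bicor, _ = bicor(x_out, y)
        r_pearson = float(np.corrcoef(x_out, y)[0, 1])
        assert abs(r_bicor - 1.0) < abs(r_pearson - 1.0)

    def test_mad_zero_falls_back_to_pearson(self):
        x = [0.0, 0.0, 0.0, 0.0, 5.0]  # MAD(x) = 0
        y = [0.1, 0.2, 0.4, 0.3, 9.0]
        r, method = bicor(x, y)
        assert method == "pearson_fallback"
        assert r == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-12)

    @pytest.mark.parametrize(
        ("x", "y", "message"),
        [
            ([1, 2, 3], [1, 2], "mismatch"),
            ([1, 2], [1, 2], "at least 3"),
            ([1, 2, np.nan], [1, 2, 3], "non-finite"),
            ([2, 2, 2, 2], [1, 2, 3, 4], "zero variance"),
        ],
    )
    def test_invalid_inputs(self, x, y, message):
        with pytest.raises(ValueError, match=message):
            bicor(x, y)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(finite_floats, min_size=5, max_size=25), st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, x, seed):
        y = np.random.default_rng(seed).normal(size=len(x))
        try:
            r_xy, _ = bicor(x, y)
            r_yx, _ = bicor(y, x)
        except ValueError:
            return  # degenerate draw
        assert -1.0 <= r_xy <= 1.0
        assert r_xy == pytest.approx(r_yx, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_positive_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(size=20)
        r_base, _ = bicor(x, y)
        r_affine, _ = bicor(scale * x + shift, y)
        assert r_base == pytest.approx(r_affine, abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(200):
            x = rng.normal(size=200)
            y = 0.5 * x + rng.normal(size=200)
            r, _ = bicor(x, y)
            agree += abs(r - float(np.corrcoef(x, y)[0, 1])) < 0.05
        assert agree >= 190

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 30))
        Y = rng.normal(size=(3, 30))
        R, fb_x, fb_y, deg_x, deg_y = bicor_matrix(X, Y)
        assert not fb_x.any() and not deg_x.any()
        for i in range(4):
            for j in range(3):
                r, _ = bicor(X[i], Y[j])
                assert R[i, j] == pytest.approx(r, abs=1e-12)


class TestCorrelationPvalue:
    def test_zero_r_is_one(self):
        assert correlation_pvalue(0.0, 25) == pytest.approx(1.0)

    def test_perfect_r_is_zero(self):
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 10) == 0.0

    def test_matches_t_tail_oracle(self):
        r, n = 0.5, 30
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2.0 * oracle_t_sf(t, n - 2)
        assert correlation_pvalue(r, n) == pytest.approx(expected, abs=1e-8)

    def test_needs_three_observations(self):
        with pytest.raises(ValueError, match="n >= 3"):
            correlation_pvalue(0.5, 2)

    def test_symmetric_in_sign(self):
        assert correlation_pvalue(0.3, 40) == pytest.approx(
            correlation_pvalue(-0.3, 40)
        )


def _two_gene_expression(tissue, genes, individuals, rng):
    data = pd.DataFrame(
        rng.normal(size=(len(genes), len(individuals))),
        index=genes, columns=individuals,
    )
    return TissueExpression(tissue=tissue, data=data)


class TestCrossTissueRecords:
    def _setup(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"I{i}" for i in range(n)]
        peripheral = _two_gene_expression("adipose", ["P1", "P2"], ids, rng)
        hypothalamus = _two_gene_expression("hypothalamus", ["T1", "T2"], ids, rng)
        states = [
            EstrogenState(individual=i, per_tissue_score={}, aggregate_score=0.0,
                          bin="high" if k < n // 2 else "low")
            for k, i in enumerate(ids)
        ]
        category = GeneSet("CAT", frozenset({"P1", "P2"}), "secreted")
        return peripheral, hypothalamus, category, states

    def test_record_invariants(self):
        peripheral, hypothalamus, category, states = self._setup()
        records = cross_tissue_correlations(
            peripheral, hypothalamus, category, ["T1", "T2"], states, min_n=10
        )
        assert list(records.columns) == list(RECORD_COLUMNS)
        assert len(records) == 8  # 2x2 pairs x 2 strata
        assert (records.r.abs() <= 1.0).all()
        assert (records.n >= 10).all()
        assert records.p.between(0.0, 1.0).all()
        assert set(records.stratum) == {"high", "low"}

    def test_deterministic(self):
        peripheral, hypothalamus, category, states = self._setup()
        a = cross_tissue_correlations(
            peripheral, hypothalamus, category, ["T1"], states, min_n=10
        )
        b = cross_tissue_correlations(
            peripheral, hypothalamus, category, ["T1"], states, min_n=10
        )
        pd.testing.assert_frame_equal(a, b)

    def test_disjoint_category_gives_empty(self):
        peripheral, hypothalamus, _, states = self._setup()
        other = GeneSet("OTHER", frozenset({"NOPE"}), "ligand")
        records = cross_tissue_correlations(
            peripheral, hypothalamus, other, ["T1"], states, min_n=10
        )
        assert len(records) == 0

    def test_all_high_states_error_names_stratum(self):
        peripheral, hypothalamus, category, states = self._setup()
        all_high = [
            EstrogenState(individual=s.individual, per_tissue_score={},
                          aggregate_score=0.0, bin="high")
            for s in states
        ]
        with pytest.raises(ValueError, match="low"):
            cross_tissue_correlations(
                peripheral, hypothalamus, category, ["T1"], all_high, min_n=10
            )

    def test_min_n_skips_stratum(self):
        peripheral, hypothalamus, category, states = self._setup(n=80)
        records = cross_tissue_correlations(
            peripheral, hypothalamus, category, ["T1", "T2"], states, min_n=200
        )
        assert len(records) == 0

    def test_max_pairs_cap_deterministic(self):
        peripheral, hypothalamus, category, states = self._setup()
        capped = cross_tissue_correlations(
            peripheral, hypothalamus, category, ["T1", "T2"], states,
            min_n=10, max_pairs=3,
        )
        # first 3 pairs in sorted order, both strata
        assert sorted(set(zip(capped.peripheral_gene, capped.target_gene))) == [
            ("P1", "T1"), ("P1", "T2"), ("P2", "T1")
        ]

    def test_explicit_pairs_only(self):
        peripheral, hypothalamus, category, states = self._setup()
        records = cross_tissue_correlations(
            peripheral, hypothalamus, category, ["T1", "T2"], states,
            min_n=10, pairs=[("P2", "T1")],
        )
        assert set(zip(records.peripheral_gene, records.target_gene)) == {
            ("P2", "T1")
        }

    def test_parameter_recovery_on_generating_pairs(self):
        """Median stratum bicor of adipose secreted pairs ~ generating rho."""
        medians_high, medians_low = [], []
        for seed in range(10):
            config = small_config(
                {"adipose_subcutaneous": (0.5, 0.0)}, n_individuals=300,
                seed=seed,
            )
            records, *_ = build_records(config, matched=True)
            sub = records[records.tissue == "adipose_subcutaneous"]
            medians_high.append(sub[sub.stratum == "high"].r.median())
            medians_low.append(sub[sub.stratum == "low"].r.median())
        assert abs(np.mean(medians_high) - 0.5) < 0.08
        assert abs(np.mean(medians_low) - 0.0) < 0.08


class TestScreen:
    def _records(self, tissue, n, p_values):
        return pd.DataFrame({
            "tissue": tissue, "category": "secreted",
            "peripheral_gene": [f"P{i}" for i in range(len(p_values))],
            "target_gene": "T", "stratum": "high",
            "r": 0.1, "n": n, "p": p_values, "method": "bicor",
        })

    def test_insufficient_matching_dropped_with_reason(self):
        records = {"small_intestine": self._records("small_intestine", 12, [0.001] * 10)}
        kept, dropped = screen_tissues(records, min_n=30)
        assert kept == []
        assert "insufficient matching" in dropped["small_intestine"]
        assert "12" in dropped["small_intestine"]

    def test_significant_tissue_kept(self):
        records = {"adipose": self._records("adipose", 100, [1e-8] * 20)}
        kept, dropped = screen_tissues(records, min_n=30, min_sig_fraction=0.05)
        assert kept == ["adipose"]
        assert dropped == {}

    def test_matched_n_used_for_empty_records(self):
        kept, dropped = screen_tissues(
            {"stomach": empty_records()},
            min_n=30, matched_n={"stomach": {"high": 5, "low": 40}},
        )
        assert "insufficient matching" in dropped["stomach"]

    def test_null_tissue_dropped_mostly(self):
        """All-null records (rho=0) are dropped under BH in most seeds."""
        n_dropped = 0
        n_seeds = 25
        for seed in range(n_seeds):
            config = small_config(
                {"stomach": (0.0, 0.0)}, n_individuals=120, seed=seed
            )
            records, *_ = build_records(config, matched=False)
            _, dropped = screen_tissues(
                {"stomach": records}, min_n=30, min_sig_fraction=0.05,
            )
            n_dropped += "stomach" in dropped
        assert n_dropped >= 0.8 * n_seeds

    def test_signal_tissue_kept_reliably(self):
        """rho=0.5 generating pairs keep the tissue in nearly every seed."""
        n_kept = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = small_config(
                {"stomach": (0.5, 0.5)}, n_individuals=120, seed=100 + seed
            )
            records, *_ = build_records(config, matched=True)
            kept, _ = screen_tissues(
                {"stomach": records}, min_n=30, min_sig_fraction=0.05,
            )
            n_kept += "stomach" in kept
        assert n_kept >= 0.95 * n_seeds

    def test_bh_adjustment_monotone(self):
        from statsmodels.stats.multitest import multipletests

        raw = np.sort(np.random.default_rng(0).uniform(size=30))
        _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
        assert (np.diff(adjusted) >= -1e-15).all()
        assert (adjusted >= raw - 1e-15).all()
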