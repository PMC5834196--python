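"""Generator correctness: distributional oracles, censoring mechanics,
piecewise continuity, determinism, summaries."""
import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import kstest

import allosurv as al
from allosurv.data_model import DAYS_PER_YEAR
from allosurv.synthetic_data import (
    DEFAULT_COVARIATE_FREQS,
    _patient_segments,
    inverse_transform_sample,
)


class TestInverseTransform:
    def test_exponential_closed_inversion(self):
        t = inverse_transform_sample(
            "weibull", [(0.0, {"lam": 1.0, "k": 1.0}, 1.0)], np.exp(-2.0)
        )
        assert t == pytest.approx(2.0, rel=1e-12)

    def test_weibull_closed_inversion(self):
        lam, k, scale, u = 0.03, 1.5, 1.7, 0.42
        t = inverse_transform_sample("weibull", [(0.0, {"lam": lam, "k": k}, scale)], u)
        assert t == pytest.approx((-np.log(u) / (lam * scale)) ** (1 / k), rel=1e-12)

    def test_u_domain(self):
        with pytest.raises(ValueError):
            inverse_transform_sample("weibull", [(0.0, {"lam": 1, "k": 1}, 1.0)], 0.0)

    def test_piecewise_matches_root_find(self):
        """Segment-wise inversion agrees with a numeric root-find on the
        accumulated cumulative hazard."""
        segs = [
            (30.0, {"lam": 0.8, "k": 1.1}, 1.3),
            (30.3, {"lam": 0.5, "k": 0.9}, 1.3),
            (31.0, {"lam": 0.02, "k": 1.4}, 1.3),
        ]

        def cum(t):
            total = 0.0
            for i, (lo, p, sc) in enumerate(segs):
                hi = segs[i + 1][0] if i + 1 < len(segs) else np.inf
                a, b = max(lo, 30.0), min(t, hi)
                if b > a:
                    total += sc * (
                        al.cumulative_hazard("weibull", p, b)
                        - al.cumulative_hazard("weibull", p, a)
                    )
            return total

        for u in (0.9, 0.5, 0.1, 0.01):
            t = inverse_transform_sample("weibull", segs, u, entry_age=30.0)
            t_oracle = brentq(lambda v: cum(v) + np.log(u), 30.0, 500.0, xtol=1e-10)
            assert t == pytest.approx(t_oracle, abs=1e-9)

    def test_cumulative_hazard_continuous_at_boundaries(self):
        """No probability mass sits on the 100/365-day or biennial edges."""
        cfg = al.GeneratorConfig(n_patients=1, seed=0, period_trend=-0.105)
        segs = _patient_segments(cfg, 40.0, "related", 2000, 1.0)
        starts = [s[0] for s in segs]
        for i in range(1, len(segs)):
            below = inverse_transform_sample("weibull", segs, 1.0 - 1e-12, entry_age=40.0)
            assert np.isfinite(below)
            # Lambda continuity: inverting at the boundary's own cumhaz level
            lam_at = 0.0
            for k in range(i):
                lo, p, sc = segs[k]
                hi = segs[k + 1][0]
                lam_at += sc * (
                    al.cumulative_hazard(cfg.family, p, hi)
                    - al.cumulative_hazard(cfg.family, p, lo)
                )
            t = inverse_transform_sample(
                "weibull", segs, float(np.exp(-lam_at)), entry_age=40.0
            )
            assert t == pytest.approx(starts[i], abs=1e-9)


class TestGenerateCohort:
    def test_determinism(self):
        cfg = al.GeneratorConfig(n_patients=300, seed=5)
        a, _ = al.generate_cohort(cfg)
        b, _ = al.generate_cohort(cfg)
        assert a.df.equals(b.df)

    def test_zero_hazard_config_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            al.GeneratorConfig.single_stratum(0.0, 1.0, n_patients=10)

    def test_exponential_mean_survival(self):
        """Uncensored exponential stratum: mean time-to-event is 1/lam."""
        lam = 0.4
        cfg = al.GeneratorConfig.single_stratum(
            lam, 1.0, n_patients=20000, seed=3, censor_year=2300
        )
        cohort, _ = al.generate_cohort(cfg)
        df = cohort.df
        assert df["event_theta"].all()
        times = (df["exit_age_x"] - df["transplant_age_j"]).to_numpy()
        mc_se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 1 / lam) < 3 * mc_se

    def test_uncensored_times_pass_ks(self):
        """Generated times match the analytic conditional law (KS test)."""
        lam, k = 0.15, 1.3
        cfg = al.GeneratorConfig.single_stratum(
            lam, k, n_patients=4000, seed=17, censor_year=2300
        )
        cohort, _ = al.generate_cohort(cfg)
        df = cohort.df
        j = df["transplant_age_j"].to_numpy()
        x = df["exit_age_x"].to_numpy()
        # S(x|j) = exp(-(Lambda(x) - Lambda(j))) is U(0,1) under the truth
        u = np.exp(-lam * (x**k - j**k))
        assert kstest(u, "uniform").pvalue > 0.01

    def test_censoring_is_administrative(self):
        cohort, _ = al.generate_cohort(al.GeneratorConfig(n_patients=3000, seed=8))
        df = cohort.df
        cens = df[df["event_theta"] == 0]
        expected_exit = cens["transplant_age_j"] + (
            2013.0 - (cens["transplant_year"] + 0.5)
        )
        np.testing.assert_allclose(cens["exit_age_x"], expected_exit, atol=1e-9)

    def test_covariate_frequencies_match_config(self):
        cohort, _ = al.generate_cohort(al.GeneratorConfig(n_patients=8000, seed=10))
        df = cohort.df
        for donor in ("related", "unrelated"):
            sub = df[df["donor_source"] == donor]
            p_cfg = DEFAULT_COVARIATE_FREQS["acute_gvhd"][donor][1]
            p_hat = sub["acute_gvhd"].mean()
            se = np.sqrt(p_cfg * (1 - p_cfg) / len(sub))
            assert abs(p_hat - p_cfg) < 3 * se

    def test_missingness_injected(self):
        cfg = al.GeneratorConfig(n_patients=2000, seed=4, missing_fraction=0.3)
        cohort, _ = al.generate_cohort(cfg)
        _, report = al.apply_eligibility_filters(cohort)
        assert 0.2 < report["excluded"]["missing"] / 2000 < 0.4

    def test_truth_record_carries_config(self):
        cfg = al.GeneratorConfig(n_patients=10, seed=99)
        _, truth = al.generate_cohort(cfg)
        assert truth["seed"] == 99
        assert truth["stratum_params"]["I1:unrelated"]["k"] == 0.96
        assert truth["frailty_true"] == {"distribution": "none", "variance": 0.0}


class TestSummaries:
    def test_frequencies_echo_table_structure(self):
        cohort, _ = al.generate_cohort(al.GeneratorConfig(n_patients=5000, seed=12))
        s = al.summarize_cohort(cohort)
        assert set(s.columns) == {"related", "unrelated"}
        # died % and interval mix approximate the published cohort profile
        assert abs(s.loc["died_pct", "related"] - 64.4) < 5
        assert abs(s.loc["died_pct", "unrelated"] - 71.3) < 5
        assert abs(s.loc["duration_I1_pct", "unrelated"] - 28.3) < 5

    def test_empty_cohort(self, tiny_cohort):
        empty = al.CohortTable(tiny_cohort.df.iloc[:0])
        s = al.summarize_cohort(empty)
        assert (s.loc["N"] == 0).all()

    def test_single_patient(self, tiny_cohort):
        one = al.CohortTable(tiny_cohort.df.iloc[:1])
        s = al.summarize_cohort(one)
        assert s.loc["N", "related"] == 1
        assert s.loc["died_pct", "related"] == 100.0
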