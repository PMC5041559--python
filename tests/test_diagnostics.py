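import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from promopanel.diagnostics import (
    ConfusionTable,
    clopper_pearson,
    confusion,
    performance,
    round_half_up,
)
from promopanel.ihc import MarkerDefinition
from promopanel.matrix import make_sample_table
from promopanel.reference import REFERENCE_MARKERS

# Published per-marker metrics: estimate and 95% CI for each of the five
# proportions, on the discovery (12 non-lepidic AD vs 3 PDSCC) and validation
# (16 non-lepidic AD vs 11 PDSCC) cohorts. ``None`` marks an undefined metric
# and the one known typographic CI error (discovery ST6GALNAC1 accuracy CI,
# which duplicates the NPV CI in print and is inconsistent with 11/15).
PUBLISHED = {
    ("discovery", "ST6GALNAC1"): {
        "sensitivity": (0.667, 0.349, 0.901),
        "specificity": (1.000, 0.292, 1.000),
        "ppv": (1.000, 0.631, 1.000),
        "npv": (0.429, 0.099, 0.816),
        "accuracy": (0.733, None, None),
    },
    ("discovery", "TTF-1"): {
        "sensitivity": (0.417, 0.152, 0.723),
        "specificity": (1.000, 0.292, 1.000),
        "ppv": (1.000, 0.478, 1.000),
        "npv": (0.300, 0.067, 0.652),
        "accuracy": (0.533, 0.266, 0.787),
    },
    ("discovery", "napsin A"): {
        "sensitivity": (0.167, 0.021, 0.484),
        "specificity": (1.000, 0.292, 1.000),
        "ppv": (1.000, 0.158, 1.000),
        "npv": (0.231, 0.050, 0.538),
        "accuracy": (0.333, 0.118, 0.616),
    },
    ("discovery", "SPATS2"): {
        "sensitivity": (0.667, 0.094, 0.992),
        "specificity": (1.000, 0.735, 1.000),
        "ppv": (1.000, 0.158, 1.000),
        "npv": (0.923, 0.640, 0.998),
        "accuracy": (0.933, 0.681, 0.998),
    },
    ("discovery", "CK5"): {
        "sensitivity": (0.333, 0.008, 0.906),
        "specificity": (1.000, 0.735, 1.000),
        "ppv": (1.000, 0.025, 1.000),
        "npv": (0.857, 0.572, 0.982),
        "accuracy": (0.867, 0.595, 0.983),
    },
    ("discovery", "DSG3"): {
        "sensitivity": (0.000, 0.000, 0.708),
        "specificity": (1.000, 0.735, 1.000),
        "ppv": None,
        "npv": (0.800, 0.519, 0.957),
        "accuracy": (0.800, 0.519, 0.957),
    },
    ("discovery", "p40"): {
        "sensitivity": (0.333, 0.008, 0.906),
        "specificity": (1.000, 0.735, 1.000),
        "ppv": (1.000, 0.025, 1.000),
        "npv": (0.857, 0.572, 0.982),
        "accuracy": (0.867, 0.595, 0.983),
    },
    ("discovery", "CK6"): {
        "sensitivity": (0.000, 0.000, 0.708),
        "specificity": (1.000, 0.735, 1.000),
        "ppv": None,
        "npv": (0.800, 0.519, 0.957),
        "accuracy": (0.800, 0.519, 0.957),
    },
    ("validation", "ST6GALNAC1"): {
        "sensitivity": (0.938, 0.698, 0.998),
        "specificity": (1.000, 0.715, 1.000),
        "ppv": (1.000, 0.782, 1.000),
        "npv": (0.917, 0.615, 0.998),
        "accuracy": (0.963, 0.810, 0.999),
    },
    ("validation", "TTF-1"): {
        "sensitivity": (0.625, 0.354, 0.848),
        "specificity": (1.000, 0.715, 1.000),
        "ppv": (1.000, 0.692, 1.000),
        "npv": (0.647, 0.383, 0.858),
        "accuracy": (0.778, 0.577, 0.914),
    },
    ("validation", "napsin A"): {
        "sensitivity": (0.750, 0.476, 0.927),
        "specificity": (1.000, 0.715, 1.000),
        "ppv": (1.000, 0.735, 1.000),
        "npv": (0.733, 0.449, 0.922),
        "accuracy": (0.852, 0.663, 0.958),
    },
    ("validation", "SPATS2"): {
        "sensitivity": (0.636, 0.308, 0.891),
        "specificity": (1.000, 0.794, 1.000),
        "ppv": (1.000, 0.590, 1.000),
        "npv": (0.800, 0.563, 0.943),
        "accuracy": (0.852, 0.663, 0.958),
    },
    ("validation", "CK5"): {
        "sensitivity": (0.636, 0.308, 0.891),
        "specificity": (1.000, 0.794, 1.000),
        "ppv": (1.000, 0.590, 1.000),
        "npv": (0.800, 0.563, 0.943),
        "accuracy": (0.852, 0.663, 0.958),
    },
    ("validation", "DSG3"): {
        "sensitivity": (0.545, 0.234, 0.833),
        "specificity": (1.000, 0.794, 1.000),
        "ppv": (1.000, 0.541, 1.000),
        "npv": (0.762, 0.528, 0.918),
        "accuracy": (0.815, 0.619, 0.937),
    },
    ("validation", "p40"): {
        "sensitivity": (0.636, 0.308, 0.891),
        "specificity": (1.000, 0.794, 1.000),
        "ppv": (1.000, 0.590, 1.000),
        "npv": (0.800, 0.563, 0.943),
        "accuracy": (0.852, 0.663, 0.958),
    },
    ("validation", "CK6"): {
        "sensitivity": (0.455, 0.167, 0.766),
        "specificity": (0.438, 0.198, 0.701),
        "ppv": (0.357, 0.128, 0.649),
        "npv": (0.538, 0.251, 0.808),
        "accuracy": (0.444, 0.255, 0.647),
    },
}


def _cp_bisection_oracle(x, n, conf=0.95):
    """Invert the binomial tails directly by bisection."""
    alpha = 1 - conf

    def solve(fn, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if (fn(mid) > target) == increasing:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    # P(X >= x | p) grows with p; P(X <= x | p) shrinks with p
    low = (
        0.0
        if x == 0
        else solve(lambda p: 1 - binom.cdf(x - 1, n, p), alpha / 2, True)
    )
    high = 1.0 if x == n else solve(lambda p: binom.cdf(x, n, p), alpha / 2, False)
    return low, high


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,expected",
        [(8, 12, (0.349, 0.901)), (0, 3, (0.000, 0.708)), (12, 12, (0.735, 1.000))],
    )
    def test_published_intervals(self, x, n, expected):
        low, high = clopper_pearson(x, n)
        assert round_half_up(low) == expected[0]
        assert round_half_up(high) == expected[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)
        with pytest.raises(ValueError):
            clopper_pearson(1, 3, conf=1.0)

    def test_agrees_with_bisection_oracle(self):
        for n in range(1, 51):
            for x in range(n + 1):
                got = clopper_pearson(x, n)
                expected = _cp_bisection_oracle(x, n)
                assert got[0] == pytest.approx(expected[0], abs=1e-9)
                assert got[1] == pytest.approx(expected[1], abs=1e-9)

    def test_agrees_with_statsmodels(self):
        for x, n in [(0, 5), (3, 10), (17, 20), (50, 120)]:
            expected = proportion_confint(x, n, alpha=0.05, method="beta")
            got = clopper_pearson(x, n)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_coverage_is_conservative(self):
        """MC coverage at 95% stays >= nominal - 2 MC-SE (exact CIs over-cover)."""
        rng = np.random.default_rng(123)
        reps = 10_000
        for p in (0.1, 0.5, 0.9):
            for n in (5, 20, 100):
                bounds = np.array([clopper_pearson(x, n) for x in range(n + 1)])
                xs = rng.binomial(n, p, size=reps)
                covered = (bounds[xs, 0] <= p) & (p <= bounds[xs, 1])
                cover = covered.mean()
                mc_se = np.sqrt(0.95 * 0.05 / reps)
                assert cover >= 0.95 - 2 * mc_se

    def test_width_shrinks_with_n(self):
        for ratio_num, ratio_den in [(1, 2), (1, 5), (4, 5)]:
            widths = []
            for scale in (4, 8, 16, 32):
                x, n = ratio_num * scale, ratio_den * scale
                low, high = clopper_pearson(x, n)
                widths.append(high - low)
            assert all(w2 <= w1 for w1, w2 in zip(widths, widths[1:]))


class TestPerformance:
    def test_published_tables_reproduced(self):
        """Every printed estimate and CI in both cohort tables, to 3 decimals."""
        for (cohort, name), metrics in PUBLISHED.items():
            _, disc, valid = REFERENCE_MARKERS[name]
            table = disc if cohort == "discovery" else valid
            perf = performance(table)
            for metric, expected in metrics.items():
                prop = getattr(perf, metric)
                if expected is None:
                    assert not prop.defined
                    continue
                est, lo, hi = expected
                assert round_half_up(prop.estimate) == est, (cohort, name, metric)
                if lo is not None:
                    assert round_half_up(prop.ci_low) == lo, (cohort, name, metric)
                    assert round_half_up(prop.ci_high) == hi, (cohort, name, metric)

    def test_undefined_ppv(self):
        perf = performance(ConfusionTable(0, 0, 3, 12))
        assert not perf.ppv.defined
        assert perf.npv.estimate == pytest.approx(0.8)

    def test_transposed_table_swaps_metrics(self):
        t = ConfusionTable(8, 2, 4, 3)
        p1, p2 = performance(t), performance(t.transpose())
        assert p2.sensitivity == p1.specificity
        assert p2.ppv == p1.npv

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(0, 0, 0, 0)


class TestConfusion:
    def _cohort(self):
        ids = [f"t{i}" for i in range(15)]
        subs = ["non-lepidic AD"] * 12 + ["PDSCC"] * 3
        return make_sample_table(ids, subs)

    def test_reproduces_published_counts(self):
        """Calls with 8/12 AD positive and 0/3 SCC positive give the published
        discovery 2x2 for the AD marker."""
        table = self._cohort()
        calls = pd.Series([True] * 8 + [False] * 7, index=table.index)
        marker = MarkerDefinition("ST6GALNAC1", "AD", "novel")
        t = confusion(calls, table, marker)
        assert (t.a, t.b, t.c, t.d) == (8, 0, 4, 3)

    def test_all_negative_calls(self):
        table = self._cohort()
        calls = pd.Series(False, index=table.index)
        t = confusion(calls, table, MarkerDefinition("X", "AD", "novel"))
        assert (t.a, t.b) == (0, 0)

    def test_marker_class_flip_transposes(self):
        table = self._cohort()
        rng = np.random.default_rng(0)
        calls = pd.Series(rng.uniform(size=15) < 0.5, index=table.index)
        t_ad = confusion(calls, table, MarkerDefinition("X", "AD", "novel"))
        t_scc = confusion(calls, table, MarkerDefinition("X", "SCC", "novel"))
        assert (t_scc.a, t_scc.b, t_scc.c, t_scc.d) == (t_ad.b, t_ad.a, t_ad.d, t_ad.c)

    def test_restriction_and_empty_cohort(self):
        table = self._cohort()
        calls = pd.Series(True, index=table.index)
        marker = MarkerDefinition("X", "AD", "novel")
        t = confusion(calls, table, marker, restrict_subtypes={"PDSCC"})
        assert t.total == 3
        with pytest.raises(ValueError):
            confusion(calls, table, marker, restrict_subtypes={"WDSCC"})
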