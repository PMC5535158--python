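"""RPKM arithmetic, A/T ratios, the median summary and the inclusion filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taclass.coverage_quant import (
    CountTable,
    at_ratio,
    coverage_filter,
    read_count_table,
    rpkm,
    summarize_ratios,
    write_count_table,
)
from taclass.synthetic_data import SimConfig, simulate


def make_table(n_a, n_t, total=1e6, dataset_id="d1"):
    return CountTable(dataset_id, "c1", "r1",
                      {"toy_antitoxin": n_a, "toy_toxin": n_t}, total)


def make_toy_operon():
    from taclass.operon_model import GeneModel, OperonModel
    return OperonModel("toy", [
        GeneModel("toy_antitoxin", "antitoxin", 100, 340),
        GeneModel("toy_toxin", "toxin", 337, 622),
    ])


@pytest.mark.parametrize(
    "n,L,T,expected",
    [
        (100, 1000, 1e6, 100.0),
        (0, 1000, 1e6, 0.0),
        (3.5, 700, 2e6, 2.5),  # 1e9*3.5/(700*2e6), seven multi-mapped half-reads
    ],
)
def test_rpkm_formula(n, L, T, expected):
    assert rpkm(n, L, T) == pytest.approx(expected)


@pytest.mark.parametrize("L,T", [(0, 1e6), (-5, 1e6), (1000, 0)])
def test_rpkm_rejects_degenerate_denominators(L, T):
    with pytest.raises(ValueError):
        rpkm(10, L, T)


@given(n=st.floats(0, 1e6), L=st.integers(30, 5000), T=st.floats(1, 1e9),
       k=st.floats(0.01, 100))
def test_rpkm_library_size_invariance(n, L, T, k):
    assert rpkm(k * n, L, k * T) == pytest.approx(rpkm(n, L, T), rel=1e-9)


def test_count_table_rejects_non_half_integers():
    with pytest.raises(ValueError):
        CountTable("d", "c", "r", {"g": 1.3}, 100)
    with pytest.raises(ValueError):
        CountTable("d", "c", "r", {"g": -1.0}, 100)


class TestAtRatio:
    @pytest.mark.parametrize(
        "n_a,L_a,n_t,L_t,expected",
        [
            (200, 250, 200, 250, 1.0),
            (400, 250, 100, 250, 4.0),
            (289, 258, 100, 258, 2.89),
        ],
    )
    def test_examples(self, n_a, L_a, n_t, L_t, expected, toy_operon):
        op = toy_operon
        # rebuild gene lengths to match the example
        from taclass.operon_model import GeneModel, OperonModel
        op = OperonModel("toy", [
            GeneModel("toy_antitoxin", "antitoxin", 0, L_a),
            GeneModel("toy_toxin", "toxin", L_a + 5, L_a + 5 + L_t),
        ])
        assert at_ratio(make_table(n_a, n_t), op) == pytest.approx(expected)

    @given(t1=st.floats(1e3, 1e9), t2=st.floats(1e3, 1e9),
           k=st.sampled_from([0.5, 1.0, 2.0, 8.0]))
    def test_independent_of_library_size_and_common_rescaling(self, t1, t2, k):
        op = make_toy_operon()
        r1 = at_ratio(make_table(100, 40, total=t1), op)
        r2 = at_ratio(make_table(100 * k, 40 * k, total=t2), op)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_zero_toxin_count_excludes_dataset(self, toy_operon):
        assert at_ratio(make_table(100, 0), toy_operon) is None


class TestSummarizeRatios:
    def test_constant_ratios(self, toy_operon):
        tables = [make_table(100, 100, dataset_id=f"d{i}") for i in range(3)]
        s = summarize_ratios(tables, toy_operon)
        # lengths differ (240 vs 285) so the constant ratio is L_T/L_A scaled
        assert s.sd_ratio == pytest.approx(0.0)
        assert s.n_datasets == 3

    def test_median_matches_brute_force_oracle(self, toy_operon):
        """Sort-and-middle median for every list length 1..13."""
        rng = np.random.default_rng(0)
        for m in range(1, 14):
            counts = rng.integers(1, 500, size=(m, 2))
            tables = [make_table(int(a), int(t), dataset_id=f"d{i}")
                      for i, (a, t) in enumerate(counts)]
            s = summarize_ratios(tables, toy_operon, apply_filter=False)
            vals = sorted(s.per_dataset_ratio.values())
            mid = len(vals) // 2
            oracle = vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2
            assert s.median_ratio == pytest.approx(oracle)

    def test_sample_sd(self, toy_operon):
        tables = [make_table(a, 100, dataset_id=f"d{i}")
                  for i, a in enumerate([100, 200, 400])]
        s = summarize_ratios(tables, toy_operon, apply_filter=False)
        vals = np.array(list(s.per_dataset_ratio.values()))
        assert s.sd_ratio == pytest.approx(np.std(vals, ddof=1))

    def test_no_usable_datasets(self, toy_operon):
        s = summarize_ratios([make_table(100, 0)], toy_operon)
        assert not s.included and s.n_datasets == 0

    def test_high_depth_simulation_recovers_truth(self):
        """Median over 13 low-noise datasets lands within 10% of the true ratio."""
        config = SimConfig(n_operons_per_class=1, depth_mean=500.0,
                           nb_dispersion=0.005, seed=11,
                           true_ratio_by_class={1: 2.89, 2: 1.0, 3: 2.9, 4: 1.0})
        data = simulate(config)
        op = next(o for o in data.operons if data.truths[o.operon_id].true_class == 1)
        s = summarize_ratios(data.count_tables, op)
        assert s.median_ratio == pytest.approx(2.89, rel=0.10)


class TestCoverageFilter:
    def _tables(self, low_count_datasets, n=13, L=240):
        # toy_antitoxin length 240, toy_toxin length 285 in the shared fixture
        tables = []
        for i in range(n):
            n_t = 100 if i < low_count_datasets else 400  # 100/285 < 1
            tables.append(make_table(500, n_t, dataset_id=f"d{i}"))
        return tables

    def test_excluded_when_low_in_seven_of_thirteen(self, toy_operon):
        assert coverage_filter(self._tables(7), toy_operon) is False

    def test_included_at_exactly_six_of_thirteen(self, toy_operon):
        assert coverage_filter(self._tables(6), toy_operon) is True

    def test_included_when_always_covered(self, toy_operon):
        assert coverage_filter(self._tables(0), toy_operon) is True


def test_count_table_tsv_round_trip(tmp_path):
    table = CountTable("ds01", "cond1", "rep2", {"gA": 120.5, "gT": 88.0}, 2.5e6)
    path = tmp_path / "ds01.tsv"
    write_count_table(path, table)
    back = read_count_table(path)
    assert back == table
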