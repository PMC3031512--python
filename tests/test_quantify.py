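import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

from translokin import quantify as qt
from translokin.errors import (
    InvalidArgumentError,
    MissingDataError,
    ParseError,
    UndefinedStatisticError,
)


def make_trace(ratios, cell_id="c0", region="CS", dt=10.0):
    ratios = np.asarray(ratios, dtype=float)
    times = np.arange(ratios.size) * dt
    return qt.CellTrace(
        cell_id=cell_id,
        explant_id="e0",
        region=region,
        times=times,
        i_nuc=ratios * 100.0,
        i_cyt=np.full(ratios.size, 100.0),
    )


class TestProjectStack:
    def test_single_slice_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(qt.project_stack(img[None]), img)

    def test_bright_voxel_per_column(self):
        stack = np.zeros((4, 3, 3))
        stack[2, 1, 1] = 9.0
        assert qt.project_stack(stack)[1, 1] == 9.0

    def test_random_stack_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 255, size=(5, 8, 8)).astype(float)
        out = qt.project_stack(stack)
        for i in range(8):
            for j in range(8):
                assert out[i, j] == max(stack[z, i, j] for z in range(5))

    def test_mean_mode(self):
        stack = np.stack([np.zeros((2, 2)), np.full((2, 2), 4.0)])
        np.testing.assert_array_equal(
            qt.project_stack(stack, method="mean"), np.full((2, 2), 2.0)
        )

    def test_empty_or_2d_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qt.project_stack(np.zeros((0, 4, 4)))
        with pytest.raises(InvalidArgumentError):
            qt.project_stack(np.zeros((4, 4)))


class TestIntensityRatio:
    def setup_method(self):
        self.nuc = np.zeros((6, 6), dtype=bool)
        self.nuc[2:4, 2:4] = True
        self.cyt = np.zeros((6, 6), dtype=bool)
        self.cyt[0, :] = True

    def test_uniform_image_gives_unity(self):
        assert qt.intensity_ratio(np.full((6, 6), 7.0), self.nuc, self.cyt) == 1.0

    def test_two_to_one(self):
        img = np.ones((6, 6))
        img[self.nuc] = 2.0
        assert qt.intensity_ratio(img, self.nuc, self.cyt) == pytest.approx(2.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st_.floats(1e-3, 1e3))
    def test_illumination_invariance(self, scale):
        rng = np.random.default_rng(1)
        img = rng.uniform(1.0, 10.0, size=(6, 6))
        r1 = qt.intensity_ratio(img, self.nuc, self.cyt)
        r2 = qt.intensity_ratio(img * scale, self.nuc, self.cyt)
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_overlapping_masks_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qt.intensity_ratio(np.ones((6, 6)), self.nuc, self.nuc)

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qt.intensity_ratio(np.ones((6, 6)), np.zeros((6, 6), bool), self.cyt)

    def test_zero_cytoplasm_undefined(self):
        img = np.ones((6, 6))
        img[self.cyt] = 0.0
        with pytest.raises(UndefinedStatisticError):
            qt.intensity_ratio(img, self.nuc, self.cyt)


class TestNormalizeTrace:
    def test_normalization_is_to_initial_ratio(self):
        tr = qt.normalize_trace(make_trace([0.8, 1.2]))
        np.testing.assert_allclose(tr.ratio_norm, [1.0, 1.5])
        np.testing.assert_allclose(tr.y, [0.0, 0.5])

    def test_constant_trace_is_flat(self):
        tr = qt.normalize_trace(make_trace([1.3, 1.3, 1.3]))
        np.testing.assert_allclose(tr.ratio_norm, 1.0)
        np.testing.assert_allclose(tr.y, 0.0)

    def test_unit_baseline_identity(self):
        tr = make_trace([1.0, 1.5, 2.0])
        np.testing.assert_allclose(tr.ratio_norm, [1.0, 1.5, 2.0])

    def test_initial_ratio_exactly_one_after_normalization(self):
        tr = make_trace([0.77, 0.9, 1.4])
        assert tr.ratio_norm[0] == 1.0
        assert tr.y[0] == 0.0


def mann_whitney_enumeration(a, b):
    """Brute-force two-sided Mann-Whitney p-value by full rank enumeration."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u_obs = sum(
        (x > y) + 0.5 * (x == y) for x in a for y in b
    )
    pooled = np.concatenate([a, b])
    n_a = a.size
    mu = n_a * b.size / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(pooled.size), n_a):
        xa = pooled[list(idx)]
        xb = np.delete(pooled, list(idx))
        u = sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCompareRegions:
    def test_separated_samples_exact_p(self):
        res = qt.compare_regions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.u_statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)
        assert not res.significant

    def test_identical_samples_not_significant(self):
        res = qt.compare_regions([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.9
        assert res.u_statistic == pytest.approx(8.0)  # n^2/2 under full ties

    def test_exact_mode_matches_full_enumeration(self):
        rng = np.random.default_rng(42)
        for n_a in range(1, 6):
            for n_b in range(1, min(9, 11 - n_a)):
                a = rng.normal(0, 1, n_a)
                b = rng.normal(0.8, 1, n_b)
                res = qt.compare_regions(a, b)
                assert res.p_value == pytest.approx(
                    mann_whitney_enumeration(a, b), abs=1e-10
                ), (n_a, n_b)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(2, 1, 20)
        res = qt.compare_regions(a, b)
        assert res.significant
        assert 0 <= res.u_statistic <= res.n_a * res.n_b

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qt.compare_regions([], [1.0])


class TestRegionSummary:
    def test_two_cell_mean_and_sd(self):
        traces = [
            make_trace([1.0, 1.0], cell_id="a"),
            make_trace([1.0, 2.0], cell_id="b"),
        ]
        out = qt.region_summary(traces, 10.0)
        row = out[out.region == "CS"].iloc[0]
        assert row["mean"] == pytest.approx(1.5)
        assert row["sd"] == pytest.approx(np.std([1.0, 2.0], ddof=1))
        assert row["n"] == 2

    def test_single_cell_sd_zero_with_n_flag(self):
        out = qt.region_summary([make_trace([1.0, 1.4])], 10.0)
        assert out.iloc[0]["sd"] == 0.0
        assert out.iloc[0]["n"] == 1

    def test_identical_cells_have_zero_sd(self):
        traces = [make_trace([1.0, 1.7], cell_id=f"c{i}") for i in range(5)]
        assert qt.region_summary(traces, 10.0).iloc[0]["sd"] == 0.0

    def test_missing_time_point_names_offenders(self):
        traces = [make_trace([1.0, 1.2], cell_id="good"),
                  make_trace([1.0], cell_id="short")]
        with pytest.raises(MissingDataError) as exc:
            qt.region_summary(traces, 10.0)
        assert "short" in exc.value.offenders


class TestTraceCsv:
    def test_round_trip(self, tmp_path):
        traces = [make_trace([1.0, 1.5, 1.9], cell_id="a"),
                  make_trace([1.1, 1.0, 0.9], cell_id="b", region="NS")]
        path = tmp_path / "traces.csv"
        qt.write_traces_csv(traces, path)
        back = qt.read_traces_csv(path)
        assert [tr.cell_id for tr in back] == ["a", "b"]
        np.testing.assert_allclose(back[0].ratio, traces[0].ratio)
        assert back[1].region == "NS"

    def test_missing_column_named_in_error(self, tmp_path):
        df = pd.DataFrame({"cell_id": ["a"], "explant_id": ["e"], "region": ["CS"],
                           "time_min": [0.0], "i_nuc": [1.0]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match="i_cyt"):
            qt.read_traces_csv(path)

    def test_derived_columns_present_on_write(self, tmp_path):
        path = tmp_path / "traces.csv"
        qt.write_traces_csv([make_trace([1.0, 2.0])], path)
        cols = pd.read_csv(path).columns.tolist()
        assert cols == ["cell_id", "explant_id", "region", "time_min",
                        "i_nuc", "i_cyt", "ratio", "ratio_norm", "y"]
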