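"""eDots arithmetic, classification rules, cohort summaries and co-expression
correlation, checked against constructions with known areas and counts."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acidoquant.image_segmentation import SegmentationResult
from acidoquant.images import Image2D, LabelMap
from acidoquant.spot_quantification import (
    CellProfile,
    SpotQuantConfig,
    classify_cells,
    coexpression_correlation,
    count_signal_components,
    quantify_spots,
    summarize_cohort,
)
from acidoquant.synthetic_data import simulate_coexpression_counts
from acidoquant.synthetic_data._placement import BlurredDiskProfile, add_disk_spot


def _one_cell_seg(shape=(100, 100), px=0.5):
    labels = np.zeros(shape, np.int32)
    labels[10:90, 10:90] = 1
    cells = LabelMap(labels, px)
    return SegmentationResult(cells, cells, 1, [])


def _profile(cell_id, edots_by_channel):
    p = CellProfile(cell_id=cell_id, cell_area_um2=100.0)
    for ch, e in edots_by_channel.items():
        p.eDots[ch] = float(e)
        p.eDots_int[ch] = int(np.floor(e + 0.5))
        p.signal_area_um2[ch] = float(e) * 6.0
        p.positive[ch] = p.eDots_int[ch] >= 1
    return p


class TestQuantifySpots:
    def test_single_unit_dot_yields_one_edot(self):
        seg = _one_cell_seg()
        img = np.zeros((100, 100))
        add_disk_spot(img, (50.0, 50.0), BlurredDiskProfile(24.0, 1.3), 1.0)
        cfg = SpotQuantConfig(threshold_spec=0.5)
        [p] = quantify_spots({"PACC1": Image2D(img, 0.5)}, seg, cfg, preprocessed=True)
        assert p.eDots_int["PACC1"] == 1
        assert p.eDots["PACC1"] == pytest.approx(1.0, abs=0.15)

    def test_twelve_um2_of_signal_is_exactly_two_edots(self):
        seg = _one_cell_seg()
        img = np.zeros((100, 100))
        img[40:46, 40:48] = 1.0  # 48 px * 0.25 um^2 = 12 um^2
        cfg = SpotQuantConfig(threshold_spec=0.5)
        [p] = quantify_spots({"PACC1": Image2D(img, 0.5)}, seg, cfg, preprocessed=True)
        assert p.eDots["PACC1"] == pytest.approx(2.0, abs=1e-12)
        assert p.eDots_int["PACC1"] == 2

    def test_specks_below_min_dot_size_are_discarded(self):
        seg = _one_cell_seg()
        img = np.zeros((100, 100))
        img[20, 20:24] = 1.0  # 4 px = 1 um^2, far below the 6 um^2 minimum
        cfg = SpotQuantConfig(threshold_spec=0.5)
        [p] = quantify_spots({"PACC1": Image2D(img, 0.5)}, seg, cfg, preprocessed=True)
        assert p.eDots["PACC1"] == 0.0
        assert not p.positive["PACC1"]

    def test_edots_additive_over_cells(self, small_tissue_field):
        """Total eDots equals total surviving in-cell area / unit area."""
        from acidoquant.evaluation import run_tissue_pipeline

        profiles, _, _ = run_tissue_pipeline(small_tissue_field)
        total_edots = sum(p.eDots["PACC1"] for p in profiles)
        total_area = sum(p.signal_area_um2["PACC1"] for p in profiles)
        assert total_edots == pytest.approx(total_area / 6.0, abs=1e-9)

    def test_shape_mismatch_signaled(self):
        seg = _one_cell_seg()
        with pytest.raises(ValueError):
            quantify_spots({"PACC1": Image2D(np.zeros((64, 64)), 0.5)}, seg)

    @given(st.floats(min_value=0.5, max_value=0.95))
    def test_raising_threshold_never_increases_edots(self, higher):
        seg = _one_cell_seg()
        rng = np.random.default_rng(7)
        img = np.zeros((100, 100))
        prof = BlurredDiskProfile(24.0, 1.3)
        for _ in range(6):
            add_disk_spot(img, tuple(rng.uniform(20, 80, 2)), prof, 1.0)
        channel = Image2D(img, 0.5)
        lo = quantify_spots(
            {"c": channel}, seg, SpotQuantConfig(threshold_spec=0.5), preprocessed=True
        )[0].eDots["c"]
        hi = quantify_spots(
            {"c": channel}, seg, SpotQuantConfig(threshold_spec=higher), preprocessed=True
        )[0].eDots["c"]
        assert hi <= lo + 1e-12

    def test_component_counting_merges_fused_dots(self):
        seg = _one_cell_seg()
        img = np.zeros((100, 100))
        prof = BlurredDiskProfile(24.0, 1.3)
        add_disk_spot(img, (50.0, 50.0), prof, 1.0)
        add_disk_spot(img, (50.0, 54.0), prof, 1.0)  # fused pair
        add_disk_spot(img, (30.0, 30.0), prof, 1.0)  # isolated
        cfg = SpotQuantConfig(threshold_spec=0.5)
        counts = count_signal_components({"c": Image2D(img, 0.5)}, seg, cfg, preprocessed=True)
        assert counts.loc[0, "components_c"] == 2  # three dots, two blobs


class TestClassification:
    CFG = SpotQuantConfig()
    MARKERS = {"neuron": "RBFOX3", "astrocyte": "S100B"}

    def test_zero_target_edots_is_negative(self):
        p = _profile(1, {"PACC1": 0, "RBFOX3": 0, "S100B": 0})
        classify_cells([p], self.CFG, self.MARKERS, "PACC1")
        assert not p.positive["PACC1"]
        assert p.expression_bin is None

    @pytest.mark.parametrize(
        "marker_dots,expected_class",
        [(10, "neuron"), (9, "unclassified")],
    )
    def test_marker_threshold_is_ten_dots(self, marker_dots, expected_class):
        p = _profile(1, {"PACC1": 3, "RBFOX3": marker_dots, "S100B": 0})
        classify_cells([p], self.CFG, self.MARKERS, "PACC1")
        assert p.cell_class == expected_class

    def test_double_marker_positive_is_unclassified_with_reason(self):
        p = _profile(1, {"PACC1": 3, "RBFOX3": 15, "S100B": 12})
        classify_cells([p], self.CFG, self.MARKERS, "PACC1")
        assert p.cell_class == "unclassified"
        assert "multiple markers" in p.class_reason

    @pytest.mark.parametrize(
        "edots,expected_bin",
        [(1, "1-9"), (9, "1-9"), (10, "10-30"), (30, "10-30"), (31, ">30")],
    )
    def test_expression_bins_follow_configured_edges(self, edots, expected_bin):
        p = _profile(1, {"PACC1": edots, "RBFOX3": 0, "S100B": 0})
        classify_cells([p], self.CFG, self.MARKERS, "PACC1")
        assert p.expression_bin == expected_bin

    def test_bins_must_be_contiguous(self):
        with pytest.raises(ValueError):
            SpotQuantConfig(bins=((1, 9), (11, 30), (31, None)))


class TestCohortSummary:
    def test_fraction_positive_is_count_ratio(self):
        profiles = [_profile(i, {"PACC1": 2 if i < 8 else 0}) for i in range(10)]
        s = summarize_cohort(profiles, "PACC1")
        assert s.fraction_positive == pytest.approx(0.8)
        assert s.n_positive == 8

    def test_all_low_expressors_fill_first_bin(self):
        profiles = [_profile(i, {"PACC1": 3}) for i in range(5)]
        s = summarize_cohort(profiles, "PACC1")
        assert s.bin_histogram == {"1-9": 1.0, "10-30": 0.0, ">30": 0.0}
        assert sum(s.bin_histogram.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_cells_signaled(self):
        with pytest.raises(ValueError):
            summarize_cohort([], "PACC1")

    def test_no_positive_cells_reports_absent_mean(self):
        profiles = [_profile(i, {"PACC1": 0}) for i in range(4)]
        s = summarize_cohort(profiles, "PACC1")
        assert s.mean_dots_per_positive_cell is None
        assert s.fraction_positive == 0.0


class TestCoexpression:
    def test_self_correlation_is_one(self):
        profiles = [_profile(i, {"a": i + 1, "b": i + 1}) for i in range(10)]
        assert coexpression_correlation(profiles, "a", "b")["r"] == pytest.approx(1.0)

    def test_latent_factor_correlation_recovered(self):
        a, b, rho = simulate_coexpression_counts(2000, 8.0, 6.0, 1.0, seed=4)
        profiles = [_profile(i, {"a": ai, "b": bi}) for i, (ai, bi) in enumerate(zip(a, b))]
        r = coexpression_correlation(profiles, "a", "b")["r"]
        assert r == pytest.approx(rho, abs=0.05)

    def test_independent_channels_near_zero(self):
        a, b, _ = simulate_coexpression_counts(2000, 8.0, 6.0, None, seed=5)
        profiles = [_profile(i, {"a": ai, "b": bi}) for i, (ai, bi) in enumerate(zip(a, b))]
        assert abs(coexpression_correlation(profiles, "a", "b")["r"]) < 0.05

    def test_zero_variance_signaled(self):
        profiles = [_profile(i, {"a": 5, "b": i}) for i in range(5)]
        with pytest.raises(ValueError):
            coexpression_correlation(profiles, "a", "b")

    def test_too_few_cells_signaled(self):
        profiles = [_profile(i, {"a": i, "b": i}) for i in range(2)]
        with pytest.raises(ValueError):
            coexpression_correlation(profiles, "a", "b")
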