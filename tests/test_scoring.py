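import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cacskit.core_io import CtVolume, VesselLabelMask
from cacskit.scoring import (
    ScoringConfig,
    ThicknessWarning,
    agatston_score,
    agatston_weight,
    cac_drs,
    count_calcified_vessels,
    extract_lesions,
    mass_score,
    score_case,
    volume_score,
)


def _case(hu_values, labels, spacing=(3.0, 0.5, 0.5)):
    vol = CtVolume(voxels=np.asarray(hu_values, dtype=float), spacing=spacing)
    mask = VesselLabelMask(labels=np.asarray(labels, dtype=np.int64),
                           spacing=spacing)
    return vol, mask


@pytest.mark.parametrize("hu, weight", [
    (130, 1), (199, 1), (200, 2), (299, 2), (300, 3), (399, 3), (400, 4),
    (250, 2), (1200, 4),
])
def test_agatston_density_weight_table(hu, weight):
    assert agatston_weight(hu) == weight


def test_agatston_weight_below_threshold_is_a_domain_error():
    with pytest.raises(ValueError, match="130"):
        agatston_weight(129.9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=130, max_value=3000),
       st.floats(min_value=0, max_value=500))
def test_weight_is_monotone_in_peak_hu(hu, bump):
    assert agatston_weight(hu + bump) >= agatston_weight(hu)


@pytest.mark.parametrize("total_as, a_cat", [
    (0.0, "A0"), (0.5, "A1"), (99.9, "A1"), (100.0, "A2"),
    (299.9, "A2"), (300.0, "A3"), (535.3, "A3"),
])
def test_cac_drs_a_stratification(total_as, a_cat):
    assert cac_drs(total_as, 0)[0] == a_cat


@pytest.mark.parametrize("n", range(5))
def test_cac_drs_n_category_counts_vessels(n):
    assert cac_drs(0.0, n)[1] == f"N{n}"


def test_cac_drs_rejects_negative_score_and_bad_counts():
    with pytest.raises(ValueError):
        cac_drs(-1.0, 0)
    with pytest.raises(ValueError):
        cac_drs(0.0, 5)


class TestExtractLesions:
    def test_all_zero_volume_yields_no_lesions(self, flat_volume):
        assert extract_lesions(*flat_volume) == []

    def test_five_labeled_voxels_make_one_lesion(self):
        hu = np.zeros((1, 8, 8))
        lab = np.zeros((1, 8, 8))
        for r, c in [(3, 3), (3, 4), (3, 5), (4, 3), (4, 4)]:
            hu[0, r, c] = 450.0
            lab[0, r, c] = 2
        (lesion,) = extract_lesions(*_case(hu, lab))
        assert lesion.area_mm2 == pytest.approx(1.25)
        assert lesion.peak_hu == 450.0
        assert lesion.vessel == 2

    def test_diagonal_voxels_connectivity_convention(self):
        hu = np.zeros((1, 8, 8))
        lab = np.zeros((1, 8, 8))
        hu[0, 2, 2] = hu[0, 3, 3] = 200.0
        lab[0, 2, 2] = lab[0, 3, 3] = 1
        vol, mask = _case(hu, lab)
        # 8-connectivity joins the diagonal pair into one component
        joined = extract_lesions(vol, mask,
                                 ScoringConfig(connectivity_2d=8, min_area_mm2=0))
        assert len(joined) == 1 and joined[0].area_mm2 == pytest.approx(0.5)
        # 4-connectivity splits it into two 1-voxel components
        split = extract_lesions(vol, mask,
                                ScoringConfig(connectivity_2d=4, min_area_mm2=0))
        assert len(split) == 2
        # the default 1 mm^2 minimum area discards it either way
        assert extract_lesions(vol, mask, ScoringConfig(connectivity_2d=8)) == []

    def test_threshold_sharpness_at_130_hu(self):
        hu = np.zeros((1, 8, 8))
        lab = np.zeros((1, 8, 8))
        hu[0, 2, 2:7] = 129.0
        lab[0, 2, 2:7] = 1
        vol, mask = _case(hu, lab)
        assert extract_lesions(vol, mask) == []
        hu[0, 2, 2:7] = 130.0
        vol, mask = _case(hu, lab)
        (lesion,) = extract_lesions(vol, mask)
        assert lesion.peak_hu == 130.0

    def test_label_5_voxels_are_never_lesions(self):
        hu = np.full((1, 8, 8), 0.0)
        lab = np.zeros((1, 8, 8))
        hu[0, 2:5, 2:5] = 600.0
        lab[0, 2:5, 2:5] = 5
        assert extract_lesions(*_case(hu, lab)) == []


def test_agatston_score_hand_arithmetic():
    hu = np.zeros((2, 16, 16))
    lab = np.zeros((2, 16, 16))
    hu[0, 2:4, 2:6] = 210.0  # LAD, 8 voxels = 2 mm^2, weight 2
    lab[0, 2:4, 2:6] = 2
    hu[1, 8:11, 8:12] = 130.0  # RCA, 12 voxels = 3 mm^2, weight 1
    lab[1, 8:11, 8:12] = 4
    scores = agatston_score(extract_lesions(*_case(hu, lab)))
    assert scores["LAD"] == pytest.approx(4.0)
    assert scores["RCA"] == pytest.approx(3.0)
    assert scores["Total"] == pytest.approx(7.0)
    assert scores["LM"] == scores["LCX"] == 0.0


def test_empty_lesion_list_scores_zero():
    scores = agatston_score([])
    assert all(v == 0.0 for v in scores.values())


def test_volume_score_counts_supra_threshold_voxels():
    hu = np.zeros((1, 8, 8))
    lab = np.zeros((1, 8, 8))
    for r, c in [(3, 3), (3, 4), (3, 5), (4, 3), (4, 4)]:
        hu[0, r, c] = 450.0
        lab[0, r, c] = 3
    scores = volume_score(*_case(hu, lab))
    assert scores["LCX"] == pytest.approx(5 * 3.0 * 0.5 * 0.5)
    assert scores["Total"] == pytest.approx(3.75)


def test_mass_score_hand_arithmetic_and_calibration_linearity():
    hu = np.zeros((1, 8, 8))
    lab = np.zeros((1, 8, 8))
    for r, c in [(3, 3), (3, 4), (3, 5), (4, 3), (4, 4)]:
        hu[0, r, c] = 300.0
        lab[0, r, c] = 1
    vol, mask = _case(hu, lab)
    # one lesion, mean 300 HU, volume 3.75 mm^3, calibration 0.79
    assert mass_score(vol, mask)["Total"] == pytest.approx(0.79 * 300 * 0.00375)
    doubled = ScoringConfig(mass_calibration=1.58)
    assert mass_score(vol, mask, doubled)["Total"] == pytest.approx(
        2 * mass_score(vol, mask)["Total"])
    assert agatston_score(extract_lesions(vol, mask, doubled)) == \
        agatston_score(extract_lesions(vol, mask))


def test_count_calcified_vessels_from_per_vessel_scores():
    table2_auto = {"LM": 32.9, "LAD": 318.7, "LCX": 51.9, "RCA": 127.4,
                   "Total": 530.9}
    assert count_calcified_vessels(table2_auto) == (("LM", "LAD", "LCX", "RCA"), 4)
    zeros = {"LM": 0.0, "LAD": 0.0, "LCX": 0.0, "RCA": 0.0, "Total": 0.0}
    assert count_calcified_vessels(zeros) == ((), 0)
    only_lad = dict(zeros, LAD=5.0)
    assert count_calcified_vessels(only_lad) == (("LAD",), 1)


def test_score_case_matches_certificate_on_phantoms(cohort10):
    for case in cohort10:
        result = score_case(case.volume, case.mask)
        cert = case.certificate
        assert result.agatston == cert.agatston
        for key in result.volume:
            assert result.volume[key] == pytest.approx(cert.volume[key],
                                                       rel=1e-9)
            assert result.mass[key] == pytest.approx(cert.mass[key], rel=1e-9)
        assert result.a_category == cert.a_category
        assert result.n_category == cert.n_category


def test_total_is_sum_of_vessel_scores(cohort10):
    for case in cohort10:
        result = score_case(case.volume, case.mask)
        for table in (result.agatston, result.volume, result.mass):
            vessel_sum = sum(table[v] for v in ("LM", "LAD", "LCX", "RCA"))
            assert table["Total"] == pytest.approx(vessel_sum, rel=1e-12)


def test_adding_a_disjoint_lesion_never_decreases_scores():
    hu = np.zeros((2, 16, 16))
    lab = np.zeros((2, 16, 16))
    hu[0, 2:4, 2:6] = 210.0
    lab[0, 2:4, 2:6] = 2
    before = score_case(*_case(hu, lab))
    hu[1, 10:12, 10:14] = 350.0
    lab[1, 10:12, 10:14] = 4
    after = score_case(*_case(hu, lab))
    for key in before.agatston:
        assert after.agatston[key] >= before.agatston[key]
        assert after.volume[key] >= before.volume[key]
        assert after.mass[key] >= before.mass[key]


def test_raising_peak_across_weight_boundary_raises_as_not_vs():
    hu = np.zeros((1, 16, 16))
    lab = np.zeros((1, 16, 16))
    hu[0, 2:4, 2:6] = 199.0
    lab[0, 2:4, 2:6] = 1
    low = score_case(*_case(hu, lab))
    hu[0, 2, 2] = 200.0  # peak crosses the 200 HU weight boundary
    high = score_case(*_case(hu, lab))
    assert high.agatston["LM"] > low.agatston["LM"]
    assert high.volume["LM"] == low.volume["LM"]


def test_confuser_only_case_is_a0_n0():
    hu = np.zeros((1, 16, 16))
    lab = np.zeros((1, 16, 16))
    hu[0, 4:8, 4:8] = 500.0
    lab[0, 4:8, 4:8] = 5
    result = score_case(*_case(hu, lab))
    assert result.agatston["Total"] == 0.0
    assert result.a_category == "A0"
    assert result.n_category == "N0"


def test_non_3mm_slices_warn_by_default_and_raise_on_request(flat_volume):
    vol, mask = flat_volume
    thin = CtVolume(voxels=vol.voxels, spacing=(1.0, 0.5, 0.5))
    thin_mask = VesselLabelMask(labels=mask.labels, spacing=(1.0, 0.5, 0.5))
    with pytest.warns(ThicknessWarning):
        score_case(thin, thin_mask)
    from cacskit.core_io import GeometryError

    with pytest.raises(GeometryError, match="3 mm"):
        score_case(thin, thin_mask, ScoringConfig(thickness_policy="require-3mm"))
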