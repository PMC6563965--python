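"""Mean maps, correlation labels, eclipse detection, the flip correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone

from venoprf.synthetic import INTEGRATED, LAYERS
from venoprf.voxel_classes import (CorrelationMap, InvertedVoxelCorrector,
                                   MeanMap, classify_nbr_vs_inverted,
                                   correlate_reference, detect_eclipse,
                                   flip_timecourses,
                                   inverted_fraction_by_region,
                                   normalized_mean_map)


def test_mean_map_definition_and_permutation_invariance(rng):
    mm = normalized_mean_map(np.array([[50.0] * 4, [100.0] * 4]))
    assert np.allclose(mm.value, [0.5, 1.0])
    assert mm.normalising_max == 100.0
    Y = rng.random((5, 30)) + 0.5
    perm = rng.permutation(30)
    assert np.allclose(normalized_mean_map(Y).value,
                       normalized_mean_map(Y[:, perm]).value)


def test_mean_map_rejects_nonphysical():
    with pytest.raises(ValueError):
        normalized_mean_map(np.array([[-2.0, -2.0], [-1.0, -1.0]]))
    with pytest.raises(ValueError):
        normalized_mean_map(np.array([[np.nan, 1.0]]))


def test_eclipse_voxels_dimmer_than_rest(bundle_small):
    mm = normalized_mean_map(bundle_small.series["fullfield"][INTEGRATED])
    ecl = bundle_small.patch.eclipse_mask
    assert mm.value[ecl].max() < np.median(mm.value[~ecl])


def test_correlation_sign_labels(reference):
    ref = reference.values
    Y = np.stack([100 + ref, 100 - ref, np.full_like(ref, 42.0)])
    cm = correlate_reference(Y, reference)
    assert cm.r[0] == pytest.approx(1.0)
    assert cm.r[1] == pytest.approx(-1.0)
    assert cm.label[0] == "positive" and cm.label[1] == "inverted"
    assert cm.r[2] == 0.0 and cm.label[2] == "positive" and cm.flagged[2]


def test_noiseless_labels_match_ground_truth(bundle_noiseless, reference):
    b = bundle_noiseless
    cm = correlate_reference(b.series["fullfield"][INTEGRATED], reference)
    cls = b.patch.classes[INTEGRATED]
    should_be_negative = np.isin(cls, ["inverted", "NBR"])
    assert np.array_equal(cm.r < 0, should_be_negative)


@given(arrays(np.float64, (4, 20), elements=st.floats(-50, 50)))
def test_flip_is_involution_and_preserves_mean(Y):
    cmap = CorrelationMap(r=np.array([-0.9, -0.1, 0.0, 0.7]))
    flipped = flip_timecourses(Y, cmap)
    assert np.allclose(flip_timecourses(flipped, cmap), Y, atol=1e-9)
    assert np.allclose(flipped.mean(axis=1), Y.mean(axis=1), atol=1e-9)


def test_flip_exactly_negates_correlation(reference, rng):
    ref = reference.values
    Y = 100 + 0.5 * ref + rng.normal(0, 1.0, (6, ref.size))
    cm = correlate_reference(Y, reference)
    flipped = flip_timecourses(Y, cm)
    cm2 = correlate_reference(flipped, reference)
    mask = cm.r < 0
    assert np.allclose(cm2.r[mask], -cm.r[mask], atol=1e-12)
    assert np.allclose(cm2.r[~mask], cm.r[~mask])


def _voxel_with_exact_r(reference, r, rng):
    """Construct a series with exactly the requested Pearson r."""
    ref = reference.values
    rc = ref / np.linalg.norm(ref)
    e = rng.normal(size=ref.size)
    e -= (e @ rc) * rc
    e -= e.mean()
    e /= np.linalg.norm(e)
    return 100.0 + r * rc + np.sqrt(1 - r ** 2) * e


def test_flip_threshold_is_strict_on_magnitude(reference, rng):
    weak = _voxel_with_exact_r(reference, -0.05, rng)
    strong = _voxel_with_exact_r(reference, -0.30, rng)
    Y = np.stack([weak, strong])
    cm = correlate_reference(Y, reference)
    assert np.allclose(cm.r, [-0.05, -0.30], atol=1e-9)
    out = flip_timecourses(Y, cm, threshold=0.1)
    assert np.array_equal(out[0], Y[0])          # -0.05 is not < -0.1
    assert not np.array_equal(out[1], Y[1])


def test_corrector_transformer_contract(reference, rng):
    ref = reference.values
    Y = 100 + np.outer([1.0, -1.0, 0.2], ref) + rng.normal(0, 0.1, (3, ref.size))
    corr = InvertedVoxelCorrector(reference=reference, threshold=0.0)
    clone(corr)  # sklearn get_params/set_params round-trip
    out = corr.fit(Y).transform(Y)
    assert corr.flipped_.tolist() == [False, True, False]
    assert np.allclose(out[0], Y[0])
    assert np.allclose(out[1], 2 * Y[1].mean() - Y[1])


def test_uniform_mean_map_has_no_eclipse():
    mm = MeanMap(value=np.ones(400), normalising_max=1.0)
    roi = detect_eclipse(mm, (20, 20))
    assert roi.empty


def test_isolated_dark_voxels_filtered_by_size(rng):
    v = np.ones(400)
    v[[5, 111, 222, 333]] = 0.2   # isolated singletons
    roi = detect_eclipse(MeanMap(value=v, normalising_max=1.0), (20, 20))
    assert roi.empty


def test_detected_eclipse_overlaps_truth(bundle_small):
    b = bundle_small
    mm = normalized_mean_map(b.series["fullfield"]["d2.5mm"])
    roi = detect_eclipse(mm, b.patch.shape, layer="d2.5mm")
    det = roi.mask(b.patch.n_voxels)
    truth = b.patch.eclipse_mask
    jaccard = (det & truth).sum() / (det | truth).sum()
    assert jaccard >= 0.8


def test_deep_layer_detection_not_better_than_superficial(bundle_small):
    """Integration across depth weakens the eclipse; detection on the
    superficial layer is at least as good, and the integrated intensity
    contrast is strictly smaller."""
    b = bundle_small
    truth = b.patch.eclipse_mask
    jac = {}
    contrast = {}
    for layer in ("d2.5mm", INTEGRATED):
        mm = normalized_mean_map(b.series["fullfield"][layer])
        det = detect_eclipse(mm, b.patch.shape, layer=layer).mask(truth.size)
        jac[layer] = (det & truth).sum() / max(1, (det | truth).sum())
        contrast[layer] = mm.value[~truth].mean() - mm.value[truth].mean()
    assert jac["d2.5mm"] >= jac[INTEGRATED]
    assert contrast[INTEGRATED] < contrast["d2.5mm"]


def test_nbr_vs_inverted_split_by_eccentricity():
    cm = CorrelationMap(r=np.array([-0.8, -0.8, 0.5, -0.4]))
    ecc = np.array([6.0, 3.0, 6.0, np.nan])
    with pytest.warns(UserWarning):
        out = classify_nbr_vs_inverted(cm, ecc, stim_max=5.5)
    assert out.tolist() == ["NBR", "inverted", "positive", "unclassifiable"]


def test_inverted_fraction_endpoints_and_empty_region():
    cm = CorrelationMap(r=np.array([0.5, 0.6, -0.5, -0.6]))
    frac = inverted_fraction_by_region(cm, {"pos": [0, 1], "inv": [2, 3]})
    assert frac["pos"] == 0.0 and frac["inv"] == 100.0
    with pytest.raises(ValueError):
        inverted_fraction_by_region(cm, {"empty": []})


def test_inverted_fraction_decays_with_depth(bundle_small, reference):
    b = bundle_small
    ecl = np.flatnonzero(b.patch.eclipse_mask)
    fracs = []
    for layer in LAYERS:
        cm = correlate_reference(b.series["fullfield"][layer], reference)
        fracs.append(inverted_fraction_by_region(cm, {"e": ecl})["e"])
    assert fracs[0] > fracs[1] > fracs[2]


def test_mean_intensity_correlates_positively_with_r(bundle_small, reference):
    b = bundle_small
    mapped = b.patch.area != "periphery"
    cm = correlate_reference(b.series["fullfield"][INTEGRATED], reference)
    mm = normalized_mean_map(b.series["fullfield"][INTEGRATED])
    r = np.corrcoef(mm.value[mapped], cm.r[mapped])[0, 1]
    assert r > 0
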