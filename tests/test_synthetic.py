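"""Generator ground truth, determinism, and artefact phenomenology."""

import numpy as np
import pytest

from venoprf.synthetic import (INTEGRATED, LAYERS, PatchSpec,
                               area_column_bounds, generate_fixtures,
                               make_bundle, make_retinotopic_patch,
                               SyntheticBundle)
from venoprf.voxel_classes import normalized_mean_map


def _small_spec(**kw):
    kw.setdefault("rows", 20)
    kw.setdefault("cols", 20)
    return PatchSpec(**kw)


def test_identical_seeds_reproduce_bit_identical_series():
    b1 = make_bundle(_small_spec(seed=3), grid_samples=31,
                     protocols=("bowtie", "fullfield"))
    b2 = make_bundle(_small_spec(seed=3), grid_samples=31,
                     protocols=("bowtie", "fullfield"))
    for p in b1.series:
        for layer in b1.series[p]:
            assert np.array_equal(b1.series[p][layer], b2.series[p][layer])


def test_different_seeds_share_geometry_but_not_noise():
    p1 = make_retinotopic_patch(_small_spec(seed=1))
    p2 = make_retinotopic_patch(_small_spec(seed=2))
    assert np.array_equal(p1.x0, p2.x0)
    assert np.array_equal(p1.area, p2.area)
    assert np.array_equal(p1.eclipse_mask, p2.eclipse_mask)
    b1 = make_bundle(_small_spec(seed=1), 31, protocols=("fullfield",))
    b2 = make_bundle(_small_spec(seed=2), 31, protocols=("fullfield",))
    assert not np.array_equal(b1.series["fullfield"][INTEGRATED],
                              b2.series["fullfield"][INTEGRATED])


def test_ground_truth_class_invariants():
    patch = make_retinotopic_patch(_small_spec(seed=5))
    truth = patch.ground_truth()
    inv = truth[truth["class"] == "inverted"]
    nbr = truth[truth["class"] == "NBR"]
    assert (inv["eccentricity"] <= 5.5).all()
    assert (nbr["eccentricity"] > 5.5).all()
    assert (inv["in_eclipse"]).all()


def test_class_frequencies_match_bernoulli_probabilities():
    spec = PatchSpec(rows=40, cols=40, seed=9)
    patch = make_retinotopic_patch(spec)
    n = patch.eclipse_mask.sum()
    for layer, p in zip(LAYERS, spec.inversion_prob):
        k = (patch.classes[layer][patch.eclipse_mask] == "inverted").sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 4 * sd + 1


def test_integrated_class_is_layer_majority():
    patch = make_retinotopic_patch(_small_spec(seed=4))
    ecl = np.flatnonzero(patch.eclipse_mask)
    n_inv = np.sum([patch.classes[l][ecl] == "inverted" for l in LAYERS],
                   axis=0)
    integrated = patch.classes[INTEGRATED][ecl] == "inverted"
    assert np.array_equal(integrated, n_inv >= 2)


def test_neighbouring_voxels_map_neighbouring_angles():
    spec = _small_spec()
    patch = make_retinotopic_patch(spec)
    step = (spec.angle_range[1] - spec.angle_range[0]) / spec.rows
    grid = patch.angle.reshape(spec.rows, spec.cols)
    assert np.abs(np.diff(grid, axis=0)).max() <= step + 1e-9


def test_missing_lower_mode_silences_lower_sector_hv4():
    patch = make_retinotopic_patch(_small_spec(missing_lower=True,
                                               eclipse_box="none"))
    hv4 = patch.area == "hV4"
    lower = patch.angle > 135.0
    assert (patch.classes[INTEGRATED][hv4 & lower] == "silent").all()
    assert (patch.classes[INTEGRATED][hv4 & ~lower] == "positive").all()


def test_eclipse_contrast_strictly_decays_with_depth(bundle_small):
    b = bundle_small
    truth = b.patch.eclipse_mask
    contrasts = []
    for layer in LAYERS:
        v = normalized_mean_map(b.series["fullfield"][layer]).value
        contrasts.append(v[~truth].mean() - v[truth].mean())
    assert contrasts[0] > contrasts[1] > contrasts[2] > 0


def test_spec_validation_rejects_inconsistencies():
    with pytest.raises(ValueError):
        PatchSpec(inversion_prob=(0.2, 0.5, 0.8)).validate()
    with pytest.raises(ValueError):
        PatchSpec(nbr_band=(5.0, 7.0)).validate()
    with pytest.raises(ValueError):
        PatchSpec(eclipse_box=(0, 50, 0, 5), rows=20, cols=20).validate()


def test_area_strips_tile_all_columns():
    for cols in (12, 20, 24, 30, 37):
        b = area_column_bounds(cols)
        assert b[0] == 0 and b[-1] == cols
        assert all(b[i] < b[i + 1] for i in range(5))


def test_bundle_save_load_roundtrip(tmp_path):
    b = make_bundle(_small_spec(seed=6), 31, protocols=("ring", "fullfield"))
    b.save(tmp_path / "bundle")
    back = SyntheticBundle.load(tmp_path / "bundle")
    assert back.spec == b.spec
    for p in b.series:
        for layer in b.series[p]:
            assert np.allclose(back.series[p][layer], b.series[p][layer])


def test_fixture_bundles_are_complete(tmp_path):
    bundles = generate_fixtures(tmp_path, seed=1)
    assert set(bundles) == {"default", "missing_lower", "subject10"}
    for name in bundles:
        d = tmp_path / name
        assert (d / "ground_truth.csv").exists()
        assert (d / "spec.yaml").exists()
        assert (d / "series.npz").exists()
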