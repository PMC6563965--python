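"""Forward pRF model, two-stage fitting, Fourier phase maps."""

import numpy as np
import pytest
from sklearn.base import clone

from venoprf.prf import (PredictionEngine, PRFMapper, PRFParams, _FitContext,
                         fft_phase_map, fit_prf_grid, fit_prf_refine,
                         predict_timecourse)


@pytest.fixture(scope="module")
def engines(movies41, hrf):
    return {name: PredictionEngine(m, hrf) for name, m in movies41.items()}


def test_fullfield_drives_all_prfs_with_same_shape(movies41, engines):
    e = engines["fullfield"]
    p1 = predict_timecourse(PRFParams(1.0, 2.0, 0.7), movies41["fullfield"],
                            engine=e)
    p2 = predict_timecourse(PRFParams(-3.0, -1.0, 1.5), movies41["fullfield"],
                            engine=e)
    c1, c2 = p1 - p1.mean(), p2 - p2.mean()
    assert np.corrcoef(c1, c2)[0, 1] == pytest.approx(1.0, abs=1e-6)


def test_zero_beta_gives_constant_baseline(movies41, engines):
    p = predict_timecourse(PRFParams(1.0, 1.0, 0.5, beta=0.0, baseline=7.0),
                           movies41["fullfield"], engine=engines["fullfield"])
    assert np.allclose(p, 7.0)


def test_nonpositive_sigma_rejected(movies41):
    with pytest.raises(ValueError):
        predict_timecourse(PRFParams(0.0, 0.0, 0.0), movies41["fullfield"])


def test_bowtie_quarter_rotation_shifts_overlap_quarter_cycle(engines):
    """90 deg rotation of the pRF centre time-shifts the neural overlap by a
    quarter cycle of the rotating wedge (brute force on rendered frames)."""
    e = engines["bowtie"]
    movie = e.movie
    flat = movie.frames.reshape(movie.n_frames, -1)
    x, y = 2.5, 1.0
    over1 = flat @ e.gaussian(x, y, 0.6)
    over2 = flat @ e.gaussian(-y, x, 0.6)   # rotate centre +90 deg CCW
    per_cycle = over1[:12]
    rolled = {s: np.corrcoef(np.roll(per_cycle, s), over2[:12])[0, 1]
              for s in range(12)}
    best = max(rolled, key=rolled.get)
    assert best in (3, 9)  # quarter cycle of 12 frames, either sense
    assert rolled[best] > 0.98


def test_grid_fit_matches_brute_force_oracle(engines, rng):
    """Vectorised coarse search returns the same winner as an independent
    per-candidate least-squares enumeration."""
    engs = [engines["bowtie"], engines["ring"]]
    ctx = _FitContext(engs)
    cands = [PRFParams(-2.2, 1.1, 0.5), PRFParams(3.3, -0.7, 1.0),
             PRFParams(0.0, 4.4, 2.0)]
    truth = cands[1]
    series = 50.0 + 3.0 * ctx.drive(truth.x0, truth.y0, truth.sigma)
    series = series + rng.normal(0, 0.05, series.size)
    best, params, rss, degen = fit_prf_grid(series, engs, cands)
    # independent enumeration
    y = ctx.demean_data(series)[0]
    oracle = []
    for c in cands:
        p = ctx.drive(c.x0, c.y0, c.sigma)
        A = np.column_stack([p, np.ones_like(p)])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        oracle.append(float(resid @ resid))
    assert best[0] == int(np.argmin(oracle))
    assert params[0].x0 == truth.x0 and not degen[0]
    assert rss[0] == pytest.approx(min(oracle), rel=1e-3)


def test_constant_series_flagged_degenerate(engines):
    engs = [engines["bowtie"]]
    _, _, _, degen = fit_prf_grid(np.full(180, 5.0), engs)
    assert degen[0]


def test_refine_recovers_off_grid_prf_and_never_worsens(engines):
    engs = [engines["bowtie"], engines["ring"], engines["bar"]]
    ctx = _FitContext(engs)
    truth = PRFParams(2.0, -1.0, 0.8)
    series = 100.0 + 2.0 * ctx.drive(truth.x0, truth.y0, truth.sigma)
    best, starts, grid_rss, _ = fit_prf_grid(series, engs)
    fit = fit_prf_refine(series, engs, starts[0])
    assert fit.rss <= grid_rss[0] + 1e-9
    assert abs(fit.params.x0 - truth.x0) < 0.1
    assert abs(fit.params.y0 - truth.y0) < 0.1
    assert abs(fit.params.sigma - truth.sigma) < 0.1
    assert fit.variance_explained > 0.99


def test_mapper_sklearn_contract(movies41, engines):
    mapper = PRFMapper(movies=[movies41["bowtie"]], coarse_n_xy=5,
                       coarse_sigmas=(0.5, 1.0), refine=False)
    assert clone(mapper).get_params()["coarse_n_xy"] == 5
    ctx = _FitContext([engines["bowtie"]])
    X = np.stack([10.0 + ctx.drive(1.1, 2.2, 1.0),
                  np.full(180, 3.0)])
    mapper.fit(X)
    assert mapper.x0_.shape == (2,)
    assert mapper.degenerate_[1] and not mapper.degenerate_[0]
    assert not mapper.usable_[1]
    assert mapper.fits_.shape[0] == 2
    assert mapper.predict().shape == (2, 180)


def test_signed_amplitude_recovers_inverted_voxel(engines):
    # the bar run breaks the antipodal degeneracy of bowtie + ring
    engs = [engines["bowtie"], engines["ring"], engines["bar"]]
    ctx = _FitContext(engs)
    truth = PRFParams(-2.0, 2.0, 0.9)
    series = 100.0 - 2.0 * ctx.drive(truth.x0, truth.y0, truth.sigma)
    best, starts, _, _ = fit_prf_grid(series, engs, amplitude="signed")
    fit = fit_prf_refine(series, engs, starts[0], amplitude="signed")
    assert fit.params.beta < 0
    assert abs(fit.params.x0 - truth.x0) < 0.1
    assert fit.variance_explained > 0.99


def test_fft_phase_of_pure_sinusoid():
    n, f, phi = 120, 12, 1.0
    t = np.arange(n)
    y = np.cos(2 * np.pi * f * t / n - phi)
    pm = fft_phase_map(y, f)
    assert pm.coherence[0] == pytest.approx(1.0)
    assert pm.phase[0] == pytest.approx(phi, abs=1e-9)


def test_fft_noise_coherence_near_floor(rng):
    Y = rng.normal(size=(50, 120))
    pm = fft_phase_map(Y, 12)
    assert (pm.coherence < 0.5).all()
    assert np.median(pm.coherence) < 0.25


def test_fft_rejects_super_nyquist_bin():
    with pytest.raises(ValueError):
        fft_phase_map(np.zeros((1, 120)), 60)


def test_phase_orders_voxels_by_polar_angle(bundle_noiseless):
    """Travelling-wave phase of noiseless bowtie responses preserves the
    circular ordering of ground-truth polar angles."""
    b = bundle_noiseless
    sel = (b.patch.area == "V1") & (b.patch.classes["grey_white"] == "positive")
    Y = b.series["bowtie"]["grey_white"][sel]
    # the double wedge passes each voxel twice per rotation: the response
    # fundamental sits at twice the rotation frequency and encodes polar
    # angle modulo 180 degrees
    pm = fft_phase_map(Y, n_cycles=30)
    a = np.radians(2.0 * b.patch.angle[sel])
    p = pm.phase
    # Fisher-Lee circular correlation, sign-free
    num = np.sum(np.sin(a[:, None] - a[None, :]) * np.sin(p[:, None] - p[None, :]))
    den = np.sqrt(np.sum(np.sin(a[:, None] - a[None, :]) ** 2)
                  * np.sum(np.sin(p[:, None] - p[None, :]) ** 2))
    assert abs(num / den) >= 0.9
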