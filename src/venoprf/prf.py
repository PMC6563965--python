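"""Population receptive field (pRF) modelling.

Each voxel's response is modelled as the overlap of an isotropic 2-D
Gaussian receptive field (centre x0, y0; size sigma, all in visual degrees)
with the binary stimulus aperture, convolved with the canonical HRF and
scaled/offset by an amplitude beta and a baseline:

    y(t) = baseline + beta * HRF * (sum_p N(p; x0, y0, sigma) A(p, t))

where A is the aperture movie and the Gaussian is normalised to unit mass
over the field, so the neural drive is the fraction of the pRF covered by
the stimulus.  Fitting is a two-stage coarse-to-fine search: an exhaustive
grid over candidate (x0, y0, sigma) with beta and baseline solved in closed
form per candidate, followed by derivative-free local minimisation of the
residual sum of squares (RSS) over (x0, y0, sigma) starting from the grid
winner.

By default beta is constrained nonnegative, matching standard retinotopy
fitting in which the BOLD response to the preferred stimulus is assumed
positive.  Voxels whose responses are sign-inverted by venous artefact are
then fitted badly or at wrong field positions — which is exactly the map
disturbance this package quantifies and corrects.  ``amplitude="signed"``
lifts the constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .geometry import eccentricity, polar_angle
from .hemodynamics import HRFModel, convolve_regressor
from .stimulus import ApertureMovie


@dataclass(frozen=True)
class PRFParams:
    x0: float
    y0: float
    sigma: float
    beta: float = 1.0
    baseline: float = 0.0

    def validate(self, extent: float | None = None) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if extent is not None and max(abs(self.x0), abs(self.y0)) > 2 * extent:
            raise ValueError("pRF centre beyond twice the grid extent")


@dataclass
class PRFFit:
    params: PRFParams
    rss: float
    variance_explained: float
    corrected: bool = False
    converged: bool = True
    degenerate: bool = False


class PredictionEngine:
    """Precomputed HRF-convolved aperture matrix for fast pRF predictions.

    Convolution commutes with the spatial inner product, so the movie is
    convolved once per (movie, HRF) pair; a prediction is then a single
    matrix-vector product with the Gaussian field vector.
    """

    def __init__(self, movie: ApertureMovie, hrf: HRFModel | None = None,
                 dtype=np.float32):
        self.movie = movie
        self.hrf = hrf or HRFModel()
        flat = movie.frames.reshape(movie.n_frames, -1).astype(float)
        conv = convolve_regressor(flat.T, movie.tr, self.hrf).T
        # scale so a sustained full-field response plateaus at ~1
        ss = convolve_regressor(np.ones(movie.n_frames), movie.tr, self.hrf)
        self._scale = 1.0 / ss.max()
        self.conv = np.ascontiguousarray(conv * self._scale, dtype=dtype)
        X, Y = np.meshgrid(movie.xs, movie.ys)
        self._gx = X.ravel().astype(dtype)
        self._gy = Y.ravel().astype(dtype)
        self.n_volumes = movie.n_frames

    def gaussian(self, x0, y0, sigma) -> np.ndarray:
        """Unit-mass Gaussian field vector (fraction of pRF per grid sample)."""
        g = np.exp(-((self._gx - x0) ** 2 + (self._gy - y0) ** 2)
                   / (2.0 * sigma ** 2))
        s = g.sum()
        # mass of the full (untruncated) Gaussian in grid-sample units, so
        # pRFs partly outside the display keep overlap < 1
        full = 2.0 * np.pi * sigma ** 2 / self.movie.degrees_per_sample ** 2
        return g / max(full, s if s > 0 else 1.0)

    def drive(self, x0, y0, sigma) -> np.ndarray:
        return self.conv @ self.gaussian(x0, y0, sigma)


def predict_timecourse(params: PRFParams, movie: ApertureMovie,
                       model: HRFModel | None = None,
                       engine: PredictionEngine | None = None) -> np.ndarray:
    """Forward-model BOLD time course of one pRF for one aperture movie."""
    params.validate(extent=movie.grid_extent if movie is not None else None)
    engine = engine or PredictionEngine(movie, model)
    return params.baseline + params.beta * engine.drive(
        params.x0, params.y0, params.sigma)


def default_coarse_grid(extent: float = 5.5, n_xy: int = 11,
                        sigmas=(0.25, 0.5, 1.0, 2.0, 4.0)) -> list[PRFParams]:
    """Coarse search lattice: n_xy x n_xy centres over +-extent, 5 sizes."""
    xs = np.linspace(-extent, extent, n_xy)
    return [PRFParams(x, y, s) for s in sigmas for y in xs for x in xs]


class _FitContext:
    """Stacked, per-run-demeaned prediction matrix shared by both stages.

    Multi-run series are fitted jointly after removing each run's temporal
    mean from both data and predictions (per-scan mean removal), so a
    single amplitude/baseline pair applies across runs.  When all movies
    share one spatial grid the per-run convolved matrices are stacked into
    a single matrix, making each prediction one matrix-vector product.
    """

    def __init__(self, engines):
        if not engines:
            raise ValueError("at least one prediction engine is required")
        self.engines = engines
        self.run_lengths = [e.n_volumes for e in engines]
        self.n_volumes = sum(self.run_lengths)
        self.extent = engines[0].movie.grid_extent
        same_grid = all(
            e._gx.shape == engines[0]._gx.shape
            and np.array_equal(e._gx, engines[0]._gx)
            and np.array_equal(e._gy, engines[0]._gy)
            for e in engines)
        self._gx = engines[0]._gx
        self._gy = engines[0]._gy
        if same_grid:
            blocks = []
            for e in engines:
                c = e.conv.astype(np.float64)
                blocks.append(c - c.mean(axis=0, keepdims=True))
            self._C = np.ascontiguousarray(
                np.vstack(blocks), dtype=np.float32)
        else:
            self._C = None

    def demean_data(self, Y):
        Y = np.atleast_2d(np.asarray(Y, dtype=np.float64)).copy()
        i = 0
        for n in self.run_lengths:
            Y[:, i:i + n] -= Y[:, i:i + n].mean(axis=1, keepdims=True)
            i += n
        return Y

    def drive(self, x0, y0, sigma):
        """Per-run-demeaned stacked prediction for one pRF."""
        if self._C is not None:
            g = np.exp(-((self._gx - x0) ** 2 + (self._gy - y0) ** 2)
                       / (2.0 * sigma ** 2)).astype(np.float32)
            full = (2.0 * np.pi * sigma ** 2
                    / self.engines[0].movie.degrees_per_sample ** 2)
            return (self._C @ g) / max(full, float(g.sum()) or 1.0)
        parts = []
        for e in self.engines:
            d = e.drive(x0, y0, sigma)
            parts.append(d - d.mean())
        return np.concatenate(parts)


def _solve_amplitude(p, y, nonnegative):
    """Closed-form least-squares (beta, baseline) for prediction p."""
    pc = p - p.mean()
    q = float(pc @ pc)
    if q <= 0:
        beta = 0.0
    else:
        beta = float(pc @ (y - y.mean())) / q
        if nonnegative and beta < 0:
            beta = 0.0
    baseline = float(y.mean() - beta * p.mean())
    resid = y - beta * p - baseline
    return beta, baseline, float(resid @ resid)


def fit_prf_grid(series: np.ndarray, engines: list[PredictionEngine],
                 grid: list[PRFParams] | None = None,
                 amplitude: str = "nonnegative",
                 context: "_FitContext | None" = None):
    """Stage 1: exhaustive coarse search, vectorised over voxels.

    ``series`` is (n_voxels, n_volumes) with volumes concatenated across the
    engines' movies; data and predictions are demeaned per run before the
    closed-form (beta, baseline) solve.  Returns (best index per voxel,
    PRFParams list, RSS per voxel, degenerate mask).  Degenerate
    (zero-variance) voxels are flagged and assigned the first candidate
    with beta 0.
    """
    ctx = context or _FitContext(engines)
    if grid is None:
        grid = default_coarse_grid(ctx.extent)
    if not grid:
        raise ValueError("empty candidate grid")
    Y = np.atleast_2d(np.asarray(series, dtype=np.float64))
    if Y.shape[1] != ctx.n_volumes:
        raise ValueError(
            f"series has {Y.shape[1]} volumes, movies supply {ctx.n_volumes}")
    nonneg = amplitude == "nonnegative"

    Gc = np.stack([ctx.drive(p.x0, p.y0, p.sigma) for p in grid]
                  ).astype(np.float64)          # (n_cand, T), demeaned
    q = np.einsum("ct,ct->c", Gc, Gc)           # (n_cand,)
    Yc = ctx.demean_data(Y)
    tss = np.einsum("vt,vt->v", Yc, Yc)         # (n_vox,)
    A = Gc @ Yc.T                               # (n_cand, n_vox)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = A / q[:, None]
    beta[~np.isfinite(beta)] = 0.0
    if nonneg:
        np.clip(beta, 0.0, None, out=beta)
    rss = tss[None, :] - 2.0 * beta * A + beta ** 2 * q[:, None]
    best = np.argmin(rss, axis=0)
    degenerate = tss <= 1e-12 * max(1.0, float(np.abs(Y).max()) ** 2)
    vox = np.arange(Y.shape[0])
    best_params = []
    for v in vox:
        c = int(best[v])
        b = 0.0 if degenerate[v] else float(beta[c, v])
        p = grid[c]
        best_params.append(PRFParams(p.x0, p.y0, p.sigma, b,
                                     float(np.asarray(series)[v].mean())))
    return best, best_params, rss[best, vox], degenerate


def fit_prf_refine(series: np.ndarray, engines: list[PredictionEngine],
                   start: PRFParams, amplitude: str = "nonnegative",
                   max_iter: int = 500, tol: float = 1e-6,
                   corrected: bool = False,
                   context: "_FitContext | None" = None) -> PRFFit:
    """Stage 2: continuous local RSS minimisation over (x0, y0, sigma).

    Beta and baseline are profiled out in closed form at every evaluation.
    Nelder-Mead with bound penalties; the result never has higher RSS than
    the start (the start is returned if the optimiser fails to improve).
    """
    ctx = context or _FitContext(engines)
    y = ctx.demean_data(np.asarray(series, dtype=np.float64))[0]
    extent = ctx.extent
    nonneg = amplitude == "nonnegative"
    tss = float(y @ y)
    if tss <= 0:
        return PRFFit(params=start, rss=0.0, variance_explained=0.0,
                      corrected=corrected, degenerate=True)

    drive = ctx.drive

    def objective(theta):
        x0, y0, s = theta
        if (abs(x0) > 2 * extent or abs(y0) > 2 * extent
                or s < 0.05 or s > 2 * extent):
            return np.inf
        _, _, rss = _solve_amplitude(drive(x0, y0, s), y, nonneg)
        return rss

    start_rss = objective([start.x0, start.y0, start.sigma])
    res = minimize(objective, [start.x0, start.y0, start.sigma],
                   method="Nelder-Mead",
                   options={"maxfev": max_iter, "fatol": tol * max(tss, 1e-12),
                            "xatol": 1e-4})
    converged = bool(res.success)
    if np.isfinite(res.fun) and res.fun <= start_rss:
        x0, y0, s = res.x
    else:
        x0, y0, s = start.x0, start.y0, start.sigma
        converged = False
    beta, base, rss = _solve_amplitude(drive(x0, y0, s), y, nonneg)
    base += float(np.asarray(series, dtype=np.float64).mean())
    ve = float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    return PRFFit(params=PRFParams(float(x0), float(y0), float(s), beta, base),
                  rss=rss, variance_explained=ve, corrected=corrected,
                  converged=converged)


class PRFMapper(BaseEstimator):
    """Voxel-wise pRF estimator over one or several aperture movies.

    scikit-learn style: configure in ``__init__``, call :meth:`fit` with
    ``X`` of shape (n_voxels, n_volumes) where volumes are the concatenation
    of the supplied movies' retained volumes (multi-run joint fitting), and
    read the fitted per-voxel attributes ``x0_``, ``y0_``, ``sigma_``,
    ``beta_``, ``baseline_``, ``rss_``, ``variance_explained_``,
    ``degenerate_``, ``converged_``, or the assembled ``fits_`` DataFrame.

    Parameters
    ----------
    movies : list of ApertureMovie
        Stimulus apertures, one per run, in the order the runs are
        concatenated in X.
    hrf : HRFModel, optional
    amplitude : {"nonnegative", "signed"}
    coarse_n_xy, coarse_sigmas : coarse-grid resolution.
    refine : bool
        Run the continuous second stage (on by default).
    ve_floor : float
        Fits below this variance explained are conventionally excluded from
        coverage and smoothness analyses downstream (the mask is exposed as
        ``usable_``).
    corrected : bool
        Provenance flag recorded on the fits (set when fitting flipped
        time courses).
    """

    def __init__(self, movies=None, hrf=None, amplitude="nonnegative",
                 coarse_n_xy=11, coarse_sigmas=(0.25, 0.5, 1.0, 2.0, 4.0),
                 refine=True, max_iter=500, tol=1e-6, ve_floor=0.1,
                 corrected=False):
        self.movies = movies
        self.hrf = hrf
        self.amplitude = amplitude
        self.coarse_n_xy = coarse_n_xy
        self.coarse_sigmas = coarse_sigmas
        self.refine = refine
        self.max_iter = max_iter
        self.tol = tol
        self.ve_floor = ve_floor
        self.corrected = corrected

    def _engines(self):
        if not self.movies:
            raise ValueError("PRFMapper requires at least one aperture movie")
        if self.amplitude not in ("nonnegative", "signed"):
            raise ValueError("amplitude must be 'nonnegative' or 'signed'")
        return [PredictionEngine(m, self.hrf) for m in self.movies]

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        engines = self._engines()
        ctx = _FitContext(engines)
        grid = default_coarse_grid(ctx.extent, self.coarse_n_xy,
                                   self.coarse_sigmas)
        _, starts, grid_rss, degenerate = fit_prf_grid(
            X, engines, grid, amplitude=self.amplitude, context=ctx)
        fits = []
        for v in range(X.shape[0]):
            if degenerate[v]:
                fits.append(PRFFit(params=starts[v], rss=0.0,
                                   variance_explained=0.0,
                                   corrected=self.corrected, degenerate=True))
                continue
            if self.refine:
                fit = fit_prf_refine(X[v], engines, starts[v],
                                     amplitude=self.amplitude,
                                     max_iter=self.max_iter, tol=self.tol,
                                     corrected=self.corrected, context=ctx)
            else:
                yc = ctx.demean_data(X[v])[0]
                tss = float(yc @ yc)
                ve = float(np.clip(1.0 - grid_rss[v] / tss, 0.0, 1.0))
                fit = PRFFit(params=starts[v], rss=float(grid_rss[v]),
                             variance_explained=ve, corrected=self.corrected)
            fits.append(fit)
        self._store(fits)
        self.n_features_in_ = X.shape[1]
        return self

    def _store(self, fits):
        self.fit_results_ = fits
        self.x0_ = np.array([f.params.x0 for f in fits])
        self.y0_ = np.array([f.params.y0 for f in fits])
        self.sigma_ = np.array([f.params.sigma for f in fits])
        self.beta_ = np.array([f.params.beta for f in fits])
        self.baseline_ = np.array([f.params.baseline for f in fits])
        self.rss_ = np.array([f.rss for f in fits])
        self.variance_explained_ = np.array([f.variance_explained for f in fits])
        self.degenerate_ = np.array([f.degenerate for f in fits])
        self.converged_ = np.array([f.converged for f in fits])
        self.usable_ = (~self.degenerate_) & (
            self.variance_explained_ >= self.ve_floor)

    @property
    def fits_(self):
        import pandas as pd

        return pd.DataFrame({
            "voxel": np.arange(self.x0_.size),
            "x0": self.x0_, "y0": self.y0_, "sigma": self.sigma_,
            "polar_angle": polar_angle(self.x0_, self.y0_),
            "eccentricity": eccentricity(self.x0_, self.y0_),
            "beta": self.beta_, "baseline": self.baseline_,
            "rss": self.rss_, "variance_explained": self.variance_explained_,
            "degenerate": self.degenerate_, "converged": self.converged_,
            "usable": self.usable_,
            "corrected": self.corrected,
        })

    def predict(self, X=None):
        """Model-predicted time courses for the fitted voxels."""
        engines = self._engines()
        out = np.empty((self.x0_.size,
                        sum(e.n_volumes for e in engines)))
        for v in range(self.x0_.size):
            d = np.concatenate([
                e.drive(self.x0_[v], self.y0_[v], max(self.sigma_[v], 1e-6))
                for e in engines])
            out[v] = self.baseline_[v] + self.beta_[v] * d
        return out


@dataclass
class PhaseMap:
    """Travelling-wave Fourier phase and coherence per voxel."""

    phase: np.ndarray        # radians in [0, 2*pi)
    coherence: np.ndarray    # [0, 1]
    stimulus_frequency: int  # cycles per scan


def fft_phase_map(series: np.ndarray, n_cycles: int) -> PhaseMap:
    """Discrete Fourier phase/coherence at the stimulus frequency bin.

    Coherence is the amplitude at the stimulus bin divided by the
    root-sum-square amplitude over all non-DC bins.  Phase follows the
    cosine-delay convention: a voxel with time course cos(w t - phi) has
    phase phi.
    """
    Y = np.atleast_2d(np.asarray(series, dtype=np.float64))
    n = Y.shape[1]
    if not (0 < n_cycles < n // 2):
        raise ValueError(
            f"stimulus frequency bin {n_cycles} must lie below the Nyquist "
            f"bin {n // 2}")
    F = np.fft.rfft(Y, axis=1)
    amp = np.abs(F)
    denom = np.sqrt((amp[:, 1:] ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = amp[:, n_cycles] / denom
    coh[~np.isfinite(coh)] = 0.0
    phase = np.mod(-np.angle(F[:, n_cycles]), 2.0 * np.pi)
    return PhaseMap(phase=phase, coherence=coh, stimulus_frequency=n_cycles)
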