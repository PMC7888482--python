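"""Univariate preprocessing of region-averaged BOLD time series.

The chain mirrors standard resting-state fMRI practice on region x time
matrices: voxel-to-region averaging, nuisance regression (e.g. against a
global signal), linear detrending, a hard-threshold FFT high-pass filter,
and z-scoring to unit variance.  Each step is exposed as a standalone
function; :func:`preprocess_bold` applies the whole chain to a
:class:`BoldMatrix`.

A note on composition: ``preprocess_bold`` implements the linear part of the
chain (nuisance regression + detrend + high-pass) as a *single* orthogonal
projection, by joint OLS on [intercept, linear trend, sub-cutoff Fourier
pairs, nuisance regressors].  Residualizing on the exact-bin sine/cosine
pairs is identical to zeroing those FFT bins, and a joint projection -- unlike
a sequence of partial projections -- is exactly idempotent: running the chain
twice changes nothing.  The standalone functions apply the same operations
one at a time for inspection and for use on single series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "BoldMatrix",
    "PreprocessConfig",
    "aggregate_voxels",
    "regress_nuisance",
    "detrend_linear",
    "highpass_hard",
    "zscore",
    "preprocess_bold",
]


@dataclass
class BoldMatrix:
    """A region x time matrix of BOLD-like signals with its sampling period.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_timepoints)
        One row per region.
    tr : float
        Sampling period (repetition time) in seconds.
    region_ids : list of str
        Region labels, one per row.
    """

    values: np.ndarray
    tr: float
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BoldMatrix.values must be 2-D (regions x time)")
        if self.values.shape[1] < 16:
            raise ValueError("BoldMatrix needs at least 16 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BoldMatrix.values must be finite")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not self.region_ids:
            self.region_ids = [f"region_{i:02d}" for i in range(self.values.shape[0])]
        if len(self.region_ids) != self.values.shape[0]:
            raise ValueError("region_ids length must match number of rows")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr


@dataclass
class PreprocessConfig:
    """Settings for the univariate preprocessing chain.

    ``highpass_hz`` is a hard spectral threshold: all Fourier bins with
    ``0 < f < highpass_hz`` (and the DC bin) are removed.  ``nuisance`` is an
    optional (n_timepoints, k) array of regressors shared across regions,
    e.g. a global mean signal.
    """

    highpass_hz: float = 8e-3
    detrend: bool = True
    zscore: bool = True
    nuisance: np.ndarray | None = None

    def validate(self, tr: float, n_timepoints: int) -> None:
        nyq = 0.5 / tr
        if not 0 <= self.highpass_hz < nyq:
            raise ValueError(
                f"highpass_hz must lie in [0, Nyquist={nyq:.4g}), got {self.highpass_hz}"
            )
        if self.nuisance is not None:
            nuis = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
            if nuis.shape[0] == n_timepoints and nuis.shape[1] != n_timepoints:
                nuis = nuis.T  # accept (T, k) or (k, T)
            if nuis.shape[1] != n_timepoints:
                raise ValueError("nuisance regressor length must match the series")


def zscore(ts: np.ndarray) -> np.ndarray:
    """Normalize a series to mean 0 and unit sample standard deviation (ddof=1)."""
    x = np.asarray(ts, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot z-score a constant series")
    return (x - x.mean()) / sd


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from a series (length >= 3)."""
    x = np.asarray(ts, dtype=float)
    if x.size < 3:
        raise ValueError("detrend_linear needs at least 3 samples")
    return _signal.detrend(x, type="linear")


def highpass_hard(ts: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    """Hard-threshold FFT high-pass filter.

    Fourier coefficients at frequencies ``0 < f < cutoff_hz`` are set to
    zero, as is the DC term; coefficients at ``f >= cutoff_hz`` are left
    untouched.  The filter is applied symmetrically to positive and negative
    frequencies (via the real FFT), so the output is real.
    """
    x = np.asarray(ts, dtype=float)
    nyq = 0.5 / tr
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyq:.4g} Hz")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=tr)
    spec[freqs < cutoff_hz] = 0.0
    spec[0] = 0.0  # DC always removed
    return np.fft.irfft(spec, n=x.size)


def regress_nuisance(ts: np.ndarray, regressors: list[np.ndarray]) -> np.ndarray:
    """OLS residuals of a series on [intercept] + regressors.

    Residuals are orthogonal to every regressor and to the intercept.  An
    empty regressor list simply mean-centres the series.  A rank-deficient
    design raises a ``ValueError`` naming the collinear regressor.
    """
    x = np.asarray(ts, dtype=float)
    cols = [np.ones_like(x)]
    for i, r in enumerate(regressors):
        r = np.asarray(r, dtype=float)
        if r.shape != x.shape:
            raise ValueError(f"regressor {i} has length {r.size}, expected {x.size}")
        cols.append(r)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first regressor column lying in the span of the others
        for j in range(1, design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(
                    f"nuisance regressor {j - 1} is collinear with the remaining design"
                )
        raise ValueError("nuisance design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def aggregate_voxels(bundle) -> BoldMatrix:
    """Average voxel time series within each region.

    ``bundle`` is any object with attributes ``voxel_series`` (a list of
    (n_voxels_i, n_timepoints) arrays, one per region), ``tr`` and
    ``region_ids`` -- in particular a :class:`strucdyn.synthetic.VoxelBundle`.
    """
    series = bundle.voxel_series
    if not series:
        raise ValueError("empty voxel bundle")
    lengths = {np.atleast_2d(v).shape[1] for v in series}
    if len(lengths) != 1:
        raise ValueError(f"ragged voxel series lengths: {sorted(lengths)}")
    rows = [np.atleast_2d(np.asarray(v, dtype=float)).mean(axis=0) for v in series]
    return BoldMatrix(np.vstack(rows), tr=bundle.tr, region_ids=list(bundle.region_ids))


def _projection_design(
    n: int, tr: float, config: PreprocessConfig
) -> np.ndarray | None:
    """Design matrix whose joint OLS residual implements the linear chain."""
    cols = [np.ones(n)]
    if config.detrend:
        t = np.arange(n, dtype=float)
        cols.append(t - t.mean())
    if config.highpass_hz > 0:
        freqs = np.fft.rfftfreq(n, d=tr)
        # bins strictly between DC and the cutoff; DC itself is the intercept
        ks = np.nonzero((freqs > 0) & (freqs < config.highpass_hz))[0]
        t = np.arange(n, dtype=float)
        for k in ks:
            cols.append(np.cos(2 * np.pi * k * t / n))
            cols.append(np.sin(2 * np.pi * k * t / n))
    if config.nuisance is not None:
        nuis = np.atleast_2d(np.asarray(config.nuisance, dtype=float))
        if nuis.shape[0] == n and nuis.shape[1] != n:
            nuis = nuis.T
        for row in nuis:
            cols.append(row)
    return np.column_stack(cols)


def preprocess_bold(bold: BoldMatrix, config: PreprocessConfig | None = None) -> BoldMatrix:
    """Apply the full preprocessing chain to every region row.

    Conceptual order: nuisance regression -> linear detrend -> hard FFT
    high-pass -> z-score.  The linear steps are applied as one joint
    orthogonal projection (see module docstring), which makes the chain
    exactly idempotent and leaves exactly zero power in the removed bins.
    """
    config = config or PreprocessConfig()
    config.validate(bold.tr, bold.n_timepoints)
    X = bold.values
    design = _projection_design(bold.n_timepoints, bold.tr, config)
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    resid = (X.T - design @ beta).T
    if config.zscore:
        sds = resid.std(axis=1, ddof=1)
        bad = np.nonzero(sds == 0)[0]
        if bad.size:
            raise ValueError(
                f"zero variance after filtering in region(s) {bad.tolist()}"
            )
        resid = (resid - resid.mean(axis=1, keepdims=True)) / sds[:, None]
    return BoldMatrix(resid, tr=bold.tr, region_ids=list(bold.region_ids))
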