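"""A small zoo of time-series features for characterizing BOLD dynamics.

These are the high-performing statistics from large-scale feature comparison
(hctsa-style) studies of resting-state dynamics: symbolic motif frequencies
on the differenced series, sample entropy and its sliding-window
stationarity ratio, the first minimum of the automutual information of the
differenced series, and a degree-outlier statistic of the natural visibility
graph.  Each feature is registered in :data:`FEATURE_REGISTRY` together with
its parameters and an hctsa-style tag, and :func:`compute_features` builds a
region x feature table from a :class:`~strucdyn.preprocess.BoldMatrix`.

The registry also exposes the spectral (RLFP, fALFF, band powers, log-log
slope) and autocorrelation (decay timescale, ACF area) statistics so that a
single call produces the full feature table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import mutual_info_score

from .preprocess import BoldMatrix, zscore
from .spectral import FrequencyBand, band_power, falff, five_band_powers, loglog_slope, periodogram, rlfp
from .timescales import acf, acf_area_to_zero, decay_timescale, first_zero_lag

__all__ = [
    "motif2_freq",
    "motif3_diffquant_freq",
    "sampen",
    "sliding_sampen_stationarity",
    "auto_mi_first_min_diff",
    "visibility_degrees",
    "visibility_outlier90",
    "FeatureSpec",
    "FEATURE_REGISTRY",
    "DEFAULT_FEATURES",
    "compute_features",
]


# ---------------------------------------------------------------------------
# symbolic motifs


def motif2_freq(ts: np.ndarray, word: str) -> float:
    """Frequency of a binary up/down motif in the differenced series.

    Increments are coded 'u' if positive and 'd' otherwise (zero differences
    count as 'd'); the frequency is the number of overlapping ``|word|``-grams
    equal to ``word`` divided by the total number of grams.
    """
    if not word or set(word) - {"u", "d"}:
        raise ValueError(f"motif word must be over {{'u','d'}}, got {word!r}")
    d = np.diff(np.asarray(ts, dtype=float))
    symbols = np.where(d > 0, "u", "d")
    n_grams = symbols.size - len(word) + 1
    if n_grams < 1:
        raise ValueError("series too short for this motif length")
    target = np.array(list(word))
    hits = np.ones(n_grams, dtype=bool)
    for k, ch in enumerate(target):
        hits &= symbols[k : k + n_grams] == ch
    return float(hits.sum() / n_grams)


def _tercile_symbols(d: np.ndarray) -> np.ndarray:
    """Map differences to 'a'/'b'/'c' terciles by average rank."""
    n = d.size
    ranks = rankdata(d, method="average")
    out = np.full(n, "b")
    out[ranks <= n / 3] = "a"
    out[ranks > 2 * n / 3] = "c"
    return out


def motif3_diffquant_freq(ts: np.ndarray, word: str) -> float:
    """Frequency of a three-letter motif over tercile-coded differences.

    The series is differenced and each increment assigned to the lowest
    ('a'), middle ('b') or highest ('c') third of the empirical distribution
    of increments, using average ranks so that ties are handled
    deterministically (a constant-increment series maps entirely to 'b').
    """
    if not word or set(word) - {"a", "b", "c"}:
        raise ValueError(f"motif word must be over {{'a','b','c'}}, got {word!r}")
    d = np.diff(np.asarray(ts, dtype=float))
    if d.size < len(word) + 2:
        raise ValueError("series too short for this motif length")
    symbols = _tercile_symbols(d)
    n_grams = symbols.size - len(word) + 1
    target = np.array(list(word))
    hits = np.ones(n_grams, dtype=bool)
    for k, ch in enumerate(target):
        hits &= symbols[k : k + n_grams] == ch
    return float(hits.sum() / n_grams)


# ---------------------------------------------------------------------------
# sample entropy


def sampen(ts: np.ndarray, m: int = 2, r: float = 0.1) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    ``r`` is relative to the sample standard deviation of the segment, so on
    z-scored input the tolerance is simply ``r``.  Template pairs (i < j,
    self-matches excluded) of length m and m+1 are counted over the first
    N - m template positions; SampEn = -ln(A/B).  Returns ``inf`` when no
    (m+1)-matches exist and ``nan`` when no m-matches exist.
    """
    x = np.asarray(ts, dtype=float)
    n = x.size
    if n < 2 * (m + 1):
        raise ValueError(f"sampen needs at least {2 * (m + 1)} samples")
    tol = r * x.std(ddof=1)
    if tol == 0:
        raise ValueError("cannot compute sampen of a constant series")
    close = np.abs(x[:, None] - x[None, :]) <= tol
    nt = n - m

    def _pairs(length: int) -> int:
        match = close[:nt, :nt].copy()
        for k in range(1, length):
            match &= close[k : k + nt, k : k + nt]
        iu = np.triu_indices(nt, 1)
        return int(match[iu].sum())

    b = _pairs(m)
    if b == 0:
        return math.nan
    a = _pairs(m + 1)
    if a == 0:
        return math.inf
    return -math.log(a / b)


def sliding_sampen_stationarity(
    ts: np.ndarray, n_windows: int = 10, m: int = 2, r: float = 0.1
) -> float:
    """Stationarity of local sample entropy across equal windows.

    The series is cut into ``n_windows`` equal non-overlapping windows (a
    remainder at the end is dropped); SampEn(m, r) is computed on each
    window after re-z-scoring, and the ratio sd(window values) over
    abs(SampEn(full series)) is returned.  Stationary signals give small
    ratios.  Windows where SampEn is undefined propagate as inf/nan.
    """
    x = np.asarray(ts, dtype=float)
    w = x.size // n_windows
    if w < 2 * (m + 1):
        raise ValueError("windows too short for sampen at this m")
    vals = []
    for i in range(n_windows):
        seg = x[i * w : (i + 1) * w]
        if seg.std(ddof=1) == 0:
            raise ValueError(f"window {i} is constant; sliding sampen undefined")
        vals.append(sampen(zscore(seg), m=m, r=r))
    if not np.all(np.isfinite(vals)):
        return math.nan  # some window had no template matches; ratio undefined
    full = sampen(zscore(x), m=m, r=r)
    return float(np.std(vals, ddof=1) / abs(full))


# ---------------------------------------------------------------------------
# automutual information


def _equiprobable_labels(d: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = rankdata(d, method="average")
    labels = np.floor((ranks - 0.5) / d.size * n_bins).astype(int)
    return np.clip(labels, 0, n_bins - 1)


def auto_mi_first_min_diff(
    ts: np.ndarray, max_lag: int = 20, estimator: str = "hist"
) -> int:
    """First minimum of the automutual information of the differenced series.

    MI between the increments and their k-lagged copy is estimated for
    k = 1..max_lag and the smallest k that is a strict local minimum is
    returned (I(0) is treated as +inf, so k = 1 qualifies when I(1) < I(2)).
    If no interior minimum exists, ``max_lag`` is returned.

    ``estimator="hist"`` uses an equiprobable-binned histogram estimator
    with ceil(sqrt(N/5)) bins; ``estimator="ksg"`` uses the Kraskov
    k-nearest-neighbour estimator (k = 4).  The first-minimum *lag* is
    robust to this choice.
    """
    d = np.diff(np.asarray(ts, dtype=float))
    n = d.size
    if n <= max_lag + 10:
        raise ValueError("series too short for this max_lag")
    if estimator == "hist":
        n_bins = int(np.ceil(np.sqrt(n / 5)))
        labels = _equiprobable_labels(d, n_bins)
        mi = [mutual_info_score(labels[:-k], labels[k:]) for k in range(1, max_lag + 1)]
    elif estimator == "ksg":
        from sklearn.feature_selection import mutual_info_regression

        mi = [
            float(
                mutual_info_regression(
                    d[:-k, None], d[k:], n_neighbors=4, random_state=0
                )[0]
            )
            for k in range(1, max_lag + 1)
        ]
    else:
        raise ValueError(f"unknown MI estimator {estimator!r}")
    profile = np.concatenate([[np.inf], mi])  # profile[k] = I(k), I(0)=inf
    for k in range(1, max_lag):
        if profile[k] < profile[k - 1] and profile[k] < profile[k + 1]:
            return k
    return max_lag


# ---------------------------------------------------------------------------
# visibility graph


def visibility_degrees(ts: np.ndarray) -> np.ndarray:
    """Degree sequence of the natural visibility graph of a series.

    Points a and b see each other iff every intermediate point lies strictly
    below the chord joining them, equivalently iff the slope from a to b
    strictly exceeds the slope from a to every intermediate point.  The
    slope formulation gives an O(N^2) vectorized scan (a running maximum of
    slopes per source node) rather than the O(N^3) pairwise check.
    """
    x = np.asarray(ts, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("visibility graph needs at least 2 points")
    deg = np.zeros(n, dtype=int)
    for a in range(n - 1):
        slopes = (x[a + 1 :] - x[a]) / np.arange(1, n - a)
        vis = np.empty(slopes.size, dtype=bool)
        vis[0] = True  # consecutive points always see each other
        if slopes.size > 1:
            vis[1:] = slopes[1:] > np.maximum.accumulate(slopes[:-1])
        deg[a] += int(vis.sum())
        deg[a + 1 :][vis] += 1
    return deg


def visibility_outlier90(ts: np.ndarray) -> float:
    """Degree-outlier ratio of the visibility graph ("ol90").

    Defined here as mean(degrees at or above the 90th percentile of the
    degree distribution) divided by the mean degree; always >= 1.  The
    natural visibility rule is invariant to affine transforms of the
    series, but the series is z-scored first ("norm") so that a constant
    series raises rather than producing a path graph silently.
    """
    x = zscore(np.asarray(ts, dtype=float))
    deg = visibility_degrees(x)
    thr = np.percentile(deg, 90)
    return float(deg[deg >= thr].mean() / deg.mean())


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class FeatureSpec:
    """A named feature: callable(ts, tr) -> float, parameters, hctsa-style tag."""

    name: str
    func: Callable[[np.ndarray, float], float]
    tag: str
    params: dict = field(default_factory=dict)


def _tau_decay(ts: np.ndarray, tr: float, max_lag: int = 100) -> float:
    est = decay_timescale(acf(ts, max_lag=max_lag, tr=tr))
    return est.value if est.converged else np.nan


def _acf_area(ts: np.ndarray, tr: float, max_lag: int = 100) -> float:
    return acf_area_to_zero(acf(ts, max_lag=max_lag, tr=tr)).value


def _first_zero(ts: np.ndarray, tr: float, max_lag: int = 100) -> float:
    z = first_zero_lag(acf(ts, max_lag=max_lag, tr=tr))
    return float(z) if z is not None else np.nan


def _band(j: int):
    def f(ts, tr):
        return float(five_band_powers(periodogram(ts, tr), np.asarray(ts).size)[j - 1])

    return f


FEATURE_REGISTRY: dict[str, FeatureSpec] = {
    spec.name: spec
    for spec in [
        FeatureSpec("rlfp", lambda ts, tr: rlfp(ts, tr), "SP_RLFP_lowest20pc"),
        FeatureSpec("falff", lambda ts, tr: falff(ts, tr), "SP_fALFF_001_008"),
        FeatureSpec("band1", _band(1), "SP_band1_relpower"),
        FeatureSpec("band2", _band(2), "SP_band2_relpower"),
        FeatureSpec("band3", _band(3), "SP_band3_relpower"),
        FeatureSpec("band4", _band(4), "SP_band4_relpower"),
        FeatureSpec("band5", _band(5), "SP_band5_relpower"),
        FeatureSpec(
            "loglog_slope",
            lambda ts, tr: loglog_slope(periodogram(ts, tr)),
            "SP_Summaries_fft_linfitloglog_mf_a2",
        ),
        FeatureSpec("tau_decay", _tau_decay, "CO_AutoCorrShape_decayTimescale", {"max_lag": 100}),
        FeatureSpec("acf_area", _acf_area, "CO_AutoCorrShape_sumacf", {"max_lag": 100}),
        FeatureSpec("first_zero_lag", _first_zero, "CO_FirstZero_ac", {"max_lag": 100}),
        FeatureSpec(
            "motif2_uduu",
            lambda ts, tr: motif2_freq(ts, "uduu"),
            "SB_MotifTwo_diff_uduu",
            {"word": "uduu"},
        ),
        FeatureSpec(
            "motif3_aabb",
            lambda ts, tr: motif3_diffquant_freq(ts, "aabb"),
            "SB_MotifThree_diffquant_aabb",
            {"word": "aabb"},
        ),
        FeatureSpec("sampen", lambda ts, tr: sampen(ts), "EN_SampEn_2_01", {"m": 2, "r": 0.1}),
        FeatureSpec(
            "sliding_sampen",
            lambda ts, tr: sliding_sampen_stationarity(ts),
            "SY_SlidingWindow_sampen_ent10_2",
            {"n_windows": 10, "m": 2, "r": 0.1},
        ),
        FeatureSpec(
            "ami_first_min_diff",
            lambda ts, tr: float(auto_mi_first_min_diff(ts)),
            "IN_AutoMutualInfoStats_diff_20_fmmi",
            {"max_lag": 20, "estimator": "hist"},
        ),
        FeatureSpec(
            "visibility_ol90",
            lambda ts, tr: visibility_outlier90(ts),
            "NW_VisibilityGraph_norm_ol90",
        ),
    ]
}

#: features computed by default in the end-to-end pipeline
DEFAULT_FEATURES: list[str] = [
    "rlfp",
    "falff",
    "band2",
    "band3",
    "band4",
    "band5",
    "loglog_slope",
    "tau_decay",
    "acf_area",
    "motif2_uduu",
    "motif3_aabb",
    "sampen",
    "sliding_sampen",
    "ami_first_min_diff",
    "visibility_ol90",
]


def compute_features(
    bold: BoldMatrix, names: list[str] | None = None
) -> pd.DataFrame:
    """Region x feature table of dynamical statistics.

    Unknown feature names raise a KeyError listing the registry contents.
    """
    names = list(names) if names is not None else list(DEFAULT_FEATURES)
    unknown = [n for n in names if n not in FEATURE_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown features {unknown}; available: {sorted(FEATURE_REGISTRY)}"
        )
    table = {
        name: [
            FEATURE_REGISTRY[name].func(row, bold.tr) for row in bold.values
        ]
        for name in names
    }
    return pd.DataFrame(table, index=pd.Index(bold.region_ids, name="region_id"))
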