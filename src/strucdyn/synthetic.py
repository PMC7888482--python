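"""Seeded synthetic studies emulating an HCP-like structure-function dataset.

A study comprises, per subject, a weighted undirected connectome and a
region x time BOLD-like matrix, plus a shared region table with volumes and
a known ground truth.  The generative model:

* **Connectomes** -- a common random edge support at a target density;
  log-normal base weights with multiplicative per-subject jitter.  Node
  strengths (weighted degrees) therefore vary across regions.
* **Timescales** -- each region's intrinsic timescale tau is a monotone
  (rank-based) function of its mean node strength, plus Gaussian noise,
  clipped to [tau_min, tau_max].  The AR(1) coefficient is the exact
  Ornstein-Uhlenbeck discretization phi = exp(-tr / tau).
* **BOLD** -- a latent region AR(1) series with unit-variance innovations;
  each voxel adds iid Gaussian noise and a shared global nuisance signal,
  and the region series is the voxel mean.  Because the mean of V iid noise
  terms is Gaussian with sd voxel_noise_sd / sqrt(V), the default path draws
  region noise at that sd directly instead of materializing voxels (a full
  default study would need tens of GB of voxel series); pass
  ``materialize_voxels=True`` on small configs to generate actual
  :class:`VoxelBundle` objects with the identical distribution.
* **Volumes** -- log-uniform over [volume_min, volume_max] voxels, rank-
  coupled to strength through a Gaussian copula (``volume_strength_rho``),
  emulating the empirical confound that large regions both attach more
  streamlines and average away more voxel noise.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams, so fixed seeds give bit-identical
studies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import rankdata

from .connectome import ConnectomeMatrix
from .preprocess import BoldMatrix

__all__ = [
    "SyntheticStudyConfig",
    "GroundTruth",
    "VoxelBundle",
    "SyntheticStudy",
    "generate_connectomes",
    "assign_timescales",
    "simulate_bold",
    "generate_study",
]

_BURN_IN = 300


@dataclass
class SyntheticStudyConfig:
    """Dimensions and noise levels of a synthetic study.

    Defaults emulate the HCP-like setting: 34 left-hemisphere regions,
    100 subjects, 1200 frames at TR = 0.72 s, 25% connectome density,
    intrinsic timescales of 0.5-6 s, and region volumes spanning 49-4570
    voxels (about two orders of magnitude).
    """

    n_regions: int = 34
    n_subjects: int = 100
    n_timepoints: int = 1200
    tr: float = 0.72
    edge_density: float = 0.25
    weight_lognormal_mu: float = 8.5
    weight_lognormal_sigma: float = 1.2
    subject_weight_jitter_sd: float = 0.3
    tau_min: float = 0.5
    tau_max: float = 6.0
    tau_noise_sd: float = 0.5
    volume_min: int = 49
    volume_max: int = 4570
    volume_strength_rho: float = 0.6
    global_signal_amplitude: float = 1.0
    global_signal_tau: float = 4.0
    voxel_noise_sd: float = 7.0
    couple_tau_to_strength: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_subjects < 1 or self.n_timepoints < 16:
            raise ValueError("study dimensions too small")
        if self.n_timepoints % 2:
            raise ValueError("n_timepoints must be even")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        if not self.tau_min > 0 or self.tau_max < self.tau_min:
            raise ValueError("need 0 < tau_min <= tau_max")
        if self.volume_min < 1 or self.volume_max < self.volume_min:
            raise ValueError("need 1 <= volume_min <= volume_max")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if self.tau_noise_sd < 0 or self.voxel_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")
        if not -1 <= self.volume_strength_rho <= 1:
            raise ValueError("volume_strength_rho must lie in [-1, 1]")

    def region_ids(self) -> list[str]:
        return [f"region_{i:02d}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """Generative parameters the analysis is designed to detect."""

    tau: np.ndarray        # seconds, per region
    phi: np.ndarray        # AR(1) coefficient per region, phi = exp(-tr/tau)
    strengths: np.ndarray  # (n_subjects, n_regions) per-subject node strength
    volumes: np.ndarray    # voxels, per region


@dataclass
class VoxelBundle:
    """Per-region voxel x time matrices plus the shared nuisance series."""

    voxel_series: list[np.ndarray]
    global_signal: np.ndarray
    tr: float
    region_ids: list[str]

    def __post_init__(self) -> None:
        lengths = {np.atleast_2d(v).shape[1] for v in self.voxel_series}
        if len(lengths) != 1:
            raise ValueError("all voxel series must share n_timepoints")
        if self.global_signal.size not in lengths:
            raise ValueError("global signal length must match voxel series")

    @property
    def volumes(self) -> np.ndarray:
        return np.asarray([np.atleast_2d(v).shape[0] for v in self.voxel_series])


@dataclass
class SyntheticStudy:
    """A complete generated study, ready for the analysis pipeline."""

    config: SyntheticStudyConfig
    truth: GroundTruth
    connectomes: np.ndarray      # (n_subjects, n_regions, n_regions)
    bold: np.ndarray             # raw region series, (n_subjects, n_regions, n_timepoints)
    global_signals: np.ndarray   # (n_subjects, n_timepoints)
    region_ids: list[str]

    def subject_bold(self, s: int) -> BoldMatrix:
        return BoldMatrix(self.bold[s], tr=self.config.tr, region_ids=self.region_ids)

    def subject_connectome(self, s: int) -> ConnectomeMatrix:
        return ConnectomeMatrix(self.connectomes[s], region_ids=self.region_ids)


def _substream(config: SyntheticStudyConfig, label: str) -> np.random.Generator:
    """Named child stream of the study seed (stage-keyed hierarchical seeding)."""
    key = sum(ord(c) * 31**i for i, c in enumerate(label)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def generate_connectomes(config: SyntheticStudyConfig) -> np.ndarray:
    """Per-subject connectomes on a shared random edge support.

    Returns an (n_subjects, n_regions, n_regions) array of symmetric
    nonnegative matrices with zero diagonal.  Exactly
    round(edge_density * n(n-1)/2) upper-triangle edges are drawn once and
    shared by all subjects; weights are log-normal with per-subject
    multiplicative jitter exp(N(0, jitter_sd)).
    """
    rng = _substream(config, "connectome")
    n = config.n_regions
    iu = np.triu_indices(n, 1)
    n_pairs = iu[0].size
    n_edges = int(round(config.edge_density * n_pairs))
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    base = rng.lognormal(config.weight_lognormal_mu, config.weight_lognormal_sigma, n_edges)
    out = np.zeros((config.n_subjects, n, n))
    for s in range(config.n_subjects):
        jitter = (
            np.exp(rng.normal(0.0, config.subject_weight_jitter_sd, n_edges))
            if config.subject_weight_jitter_sd > 0
            else np.ones(n_edges)
        )
        w = np.zeros((n, n))
        w[iu[0][chosen], iu[1][chosen]] = base * jitter
        out[s] = w + w.T
    return out


def assign_timescales(
    strengths: np.ndarray, config: SyntheticStudyConfig
) -> GroundTruth:
    """Ground-truth timescales as a monotone rank map of mean strength.

    tau_i = tau_min + (tau_max - tau_min) (rank(s_i) - 1)/(n - 1) + noise,
    clipped to [tau_min, tau_max]; phi_i = exp(-tr / tau_i).  Ranks (not raw
    weights) are used so heavy-tailed strengths cannot destabilize tau.
    The returned ``strengths`` field is filled in by :func:`generate_study`.
    """
    s = np.asarray(strengths, dtype=float)
    if s.size < 2:
        raise ValueError("assign_timescales needs at least 2 regions")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("strengths must be finite and nonnegative")
    rng = _substream(config, "timescales")
    ranks = rankdata(s, method="average")
    tau = config.tau_min + (config.tau_max - config.tau_min) * (ranks - 1) / (s.size - 1)
    if config.tau_noise_sd > 0:
        tau = tau + rng.normal(0.0, config.tau_noise_sd, s.size)
    tau = np.clip(tau, config.tau_min, config.tau_max)
    phi = np.exp(-config.tr / tau)
    return GroundTruth(tau=tau, phi=phi, strengths=np.empty((0, s.size)), volumes=np.empty(0))


def _ar1(rng: np.random.Generator, phi: float, shape: tuple[int, int]) -> np.ndarray:
    """AR(1) series with unit-variance innovations, burned in to stationarity."""
    n_series, n_t = shape
    e = rng.standard_normal((n_series, n_t + _BURN_IN))
    x = lfilter([1.0], [1.0, -phi], e, axis=1)
    return x[:, _BURN_IN:]


def _global_signals(config: SyntheticStudyConfig, rng: np.random.Generator) -> np.ndarray:
    phi_g = np.exp(-config.tr / config.global_signal_tau)
    g = _ar1(rng, phi_g, (config.n_subjects, config.n_timepoints))
    return g * np.sqrt(1 - phi_g**2)  # unit stationary sd


def simulate_bold(
    truth: GroundTruth,
    config: SyntheticStudyConfig,
    *,
    materialize_voxels: bool = False,
):
    """Simulate region BOLD series (and optionally voxel bundles).

    Per region i: latent AR(1) x_t = phi_i x_{t-1} + e_t with unit-variance
    innovations; region noise ~ N(0, voxel_noise_sd^2 / V_i) (the exact
    distribution of the mean of V_i iid voxel noise series); plus
    ``global_signal_amplitude`` times a shared per-subject nuisance series.

    Returns ``(bold, global_signals)`` where bold has shape
    (n_subjects, n_regions, n_timepoints), or
    ``(bold, global_signals, bundles)`` with per-subject
    :class:`VoxelBundle` objects when ``materialize_voxels`` is set (small
    configs only: memory grows with total voxel count).
    """
    if not (np.all(np.isfinite(truth.phi)) and np.all(np.isfinite(truth.volumes))):
        raise ValueError("non-finite ground-truth parameters")
    if np.any((truth.phi <= 0) | (truth.phi >= 1)):
        raise ValueError("phi must lie in (0, 1)")
    rng = _substream(config, "bold")
    s_count, n, t = config.n_subjects, config.n_regions, config.n_timepoints
    g = _global_signals(config, _substream(config, "global"))
    volumes = truth.volumes.astype(int)

    latent = np.empty((s_count, n, t))
    for i in range(n):
        latent[:, i, :] = _ar1(rng, float(truth.phi[i]), (s_count, t))

    if not materialize_voxels:
        bold = latent.copy()
        if config.voxel_noise_sd > 0:
            sds = config.voxel_noise_sd / np.sqrt(volumes)
            bold += rng.standard_normal((s_count, n, t)) * sds[None, :, None]
        bold += config.global_signal_amplitude * g[:, None, :]
        return bold, g

    bundles = []
    bold = np.empty((s_count, n, t))
    region_ids = config.region_ids()
    for s in range(s_count):
        series = []
        for i in range(n):
            v = volumes[i]
            vox = np.tile(latent[s, i], (v, 1))
            if config.voxel_noise_sd > 0:
                vox = vox + rng.normal(0.0, config.voxel_noise_sd, (v, t))
            vox = vox + config.global_signal_amplitude * g[s]
            series.append(vox)
            bold[s, i] = vox.mean(axis=0)
        bundles.append(
            VoxelBundle(series, global_signal=g[s], tr=config.tr, region_ids=region_ids)
        )
    return bold, g, bundles


def _volumes(config: SyntheticStudyConfig, mean_strength: np.ndarray) -> np.ndarray:
    """Log-uniform volumes, rank-coupled to strength via a Gaussian copula."""
    rng = _substream(config, "volumes")
    n = config.n_regions
    raw = np.exp(
        rng.uniform(np.log(config.volume_min), np.log(config.volume_max), n)
    )
    raw = np.sort(np.round(raw).astype(int))
    rho = config.volume_strength_rho
    z_s = (rankdata(mean_strength) - 0.5) / n
    latent = rho * z_s + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n) * (1 / np.sqrt(12))
    order = np.argsort(np.argsort(latent))
    vols = raw[order]
    return np.maximum(vols, config.volume_min)


def generate_study(config: SyntheticStudyConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study from a config (deterministic per seed)."""
    config = config or SyntheticStudyConfig()
    connectomes = generate_connectomes(config)
    strengths = connectomes.sum(axis=2)  # (n_subjects, n_regions)
    mean_strength = strengths.mean(axis=0)
    if config.couple_tau_to_strength:
        truth = assign_timescales(mean_strength, config)
    else:
        # decoupled null: same graded taus, assigned independently of strength
        perm = _substream(config, "decouple").permutation(config.n_regions)
        truth = assign_timescales(mean_strength[perm], config)
    truth.strengths = strengths
    truth.volumes = _volumes(config, mean_strength).astype(float)
    bold, g = simulate_bold(truth, config)
    return SyntheticStudy(
        config=config,
        truth=truth,
        connectomes=connectomes,
        bold=bold,
        global_signals=g,
        region_ids=config.region_ids(),
    )
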