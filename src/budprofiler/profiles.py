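"""In-silico synchronization: cell-stage assignment and LOESS time profiles.

A budding cell's bud grows monotonically through the cycle, so a monotone
transform of bud area serves as a continuous cell-stage ("time")
covariate for both members of a mother-bud pair — area^(3/2) by default,
the reading under which bud volume grows at a constant rate.  For each
protein, the mean and variance of each feature are estimated at 10
equidistant stage keypoints by confidence-weighted local regression with a
Gaussian kernel (bandwidth 1700 stage units by default), and concatenated
into a 120-value "time profile" (10 keypoints x 6 features x {bud,
mother}).  Leave-one-out jackknifing quantifies sampling variability and a
stage-permutation test assesses whether a profile's stage dependence
exceeds chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _permutations

import numpy as np

from .features import FEATURE_NAMES

__all__ = [
    "StageSeries",
    "TimeProfile",
    "cell_stage",
    "stage_keypoints",
    "loess_profile",
    "jackknife_profile_variance",
    "stage_permutation_test",
    "expected_null_tail_count",
    "N_KEYPOINTS",
    "DEFAULT_BANDWIDTH",
    "PROFILE_LENGTH",
    "profile_column_names",
]

N_KEYPOINTS = 10
DEFAULT_BANDWIDTH = 1700.0
N_FEATURES = len(FEATURE_NAMES)
PROFILE_LENGTH = 2 * N_FEATURES * N_KEYPOINTS  # 120
_SIDES = ("bud", "mother")


def profile_column_names(n_keypoints: int = N_KEYPOINTS) -> list[str]:
    """Canonical layout of the 120-entry profile: side, feature, keypoint."""
    return [
        f"{side}:{feat}:k{k}"
        for side in _SIDES
        for feat in FEATURE_NAMES
        for k in range(n_keypoints)
    ]


def cell_stage(bud_area, exponent: float = 1.5):
    """Cell-stage covariate: bud_area ** exponent (monotone in bud area)."""
    a = np.asarray(bud_area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("bud area must be positive")
    out = a**exponent
    return float(out) if np.ndim(bud_area) == 0 else out


@dataclass
class StageSeries:
    """Per-pair stage covariate, feature values and confidence weights.

    ``values`` is (n_pairs, 12): the six bud-cell features followed by the
    six mother-cell features; ``weights`` are the products of the two cell
    probabilities.
    """

    stage: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.stage = np.asarray(self.stage, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.stage)
        if self.values.shape[0] != n or len(self.weights) != n:
            raise ValueError("stage, values and weights lengths disagree")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.stage)


@dataclass
class TimeProfile:
    """LOESS means and variances at the stage keypoints, flattened.

    Layout follows :func:`profile_column_names`; ``reliable`` marks
    keypoints with enough kernel mass.
    """

    protein: str
    keypoints: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    n_pairs: int
    reliable: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.reliable is None:
            self.reliable = np.ones(len(self.means), dtype=bool)


def stage_keypoints(
    stage: np.ndarray, n_keypoints: int = N_KEYPOINTS,
    lo_pct: float = 1.0, hi_pct: float = 99.0,
) -> np.ndarray:
    """Equidistant keypoints spanning the 1st-99th stage percentiles."""
    lo, hi = np.percentile(np.asarray(stage, float), [lo_pct, hi_pct])
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_keypoints)


def _kernel_weights(
    stage: np.ndarray, keypoints: np.ndarray, bandwidth: float,
    weights: np.ndarray,
) -> np.ndarray:
    """(n_keypoints, n_pairs) combined confidence x Gaussian kernel weights."""
    z = (stage[None, :] - keypoints[:, None]) / bandwidth
    return np.exp(-0.5 * z**2) * weights[None, :]


def _weighted_moments(w: np.ndarray, values: np.ndarray, min_mass: float):
    """Per-keypoint weighted means/variances for all columns at once."""
    mass = w.sum(axis=1)
    reliable = mass > min_mass
    safe = np.where(reliable, mass, 1.0)
    means = (w @ values) / safe[:, None]
    sq = (w @ values**2) / safe[:, None]
    variances = np.maximum(sq - means**2, 0.0)
    means[~reliable] = np.nan
    variances[~reliable] = np.nan
    return means, variances, reliable


def loess_profile(
    series: StageSeries,
    protein: str = "",
    keypoints: np.ndarray | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_mass: float = 1e-8,
) -> TimeProfile:
    """Confidence-weighted Gaussian-kernel mean/variance at each keypoint.

    At keypoint t the weight of pair i is w_i K((s_i - t)/h); the mean is
    the weighted average and the variance the weighted plug-in variance
    about it.  Keypoints with total kernel mass below ``min_mass`` are
    flagged unreliable (NaN entries).
    """
    if np.sum(series.weights > 0) < 1:
        raise ValueError("need >= 1 pair with positive weight")
    if keypoints is None:
        keypoints = stage_keypoints(series.stage)
    w = _kernel_weights(series.stage, keypoints, bandwidth, series.weights)
    means, variances, reliable = _weighted_moments(w, series.values, min_mass)
    # flatten in the canonical side/feature/keypoint order
    return TimeProfile(
        protein=protein,
        keypoints=keypoints,
        means=means.T.ravel(),
        variances=variances.T.ravel(),
        n_pairs=series.n_pairs,
        reliable=np.repeat(reliable[None, :], series.values.shape[1], axis=0).ravel(),
    )


def jackknife_profile_variance(
    series: StageSeries,
    keypoints: np.ndarray | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> np.ndarray:
    """Fraction of profile variance attributable to sampling, per entry.

    Leave-one-pair-out keypoint means give the jackknife variance of the
    LOESS mean, reported as a fraction of the total (kernel-weighted)
    cell-to-cell variance at the same keypoint.  Shape matches the
    flattened profile.
    """
    n = series.n_pairs
    if n < 3:
        raise ValueError("jackknife needs >= 3 pairs")
    if keypoints is None:
        keypoints = stage_keypoints(series.stage)
    w = _kernel_weights(series.stage, keypoints, bandwidth, series.weights)
    mass = w.sum(axis=1)  # (k,)
    wsum = w @ series.values  # (k, f)
    # leave-one-out means: remove pair i's contribution from every keypoint
    loo_mass = mass[:, None] - w  # (k, n)
    loo_sum = wsum[:, None, :] - w[:, :, None] * series.values[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        loo_means = loo_sum / loo_mass[:, :, None]  # (k, n, f)
    theta_bar = np.nanmean(loo_means, axis=1)  # (k, f)
    jack_var = (n - 1) / n * np.nansum(
        (loo_means - theta_bar[:, None, :]) ** 2, axis=1
    )
    _, total_var, _ = _weighted_moments(w, series.values, 1e-8)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = jack_var / np.where(total_var > 0, total_var, np.nan)
    return frac.T.ravel()


def stage_permutation_test(
    series: StageSeries,
    keypoints: np.ndarray | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
    two_sided: bool = True,
) -> np.ndarray:
    """Empirical per-entry p-values for stage dependence of a profile.

    The stage covariates are permuted across pairs (features and weights
    stay attached to their pair), the keypoint means recomputed, and the
    deviation of the observed mean assessed against the permutation
    distribution.  Two-sided by default (2.5% per tail); p-values use the
    add-one rule (b+1)/(n_perm+1).  ``exact=True`` enumerates all stage
    orderings (small n only).
    """
    if keypoints is None:
        keypoints = stage_keypoints(series.stage)
    if not exact and n_perm < 100:
        raise ValueError("need n_perm >= 100 (or exact=True)")
    w_obs = _kernel_weights(series.stage, keypoints, bandwidth, series.weights)
    obs_means, _, _ = _weighted_moments(w_obs, series.values, 1e-8)
    if exact:
        perms = np.array(list(_permutations(range(series.n_pairs))))
    else:
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        perms = np.array(
            [rng.permutation(series.n_pairs) for _ in range(n_perm)]
        )
    n_perm_eff = len(perms)
    hi = np.zeros_like(obs_means, dtype=int)
    lo = np.zeros_like(obs_means, dtype=int)
    for p in perms:
        w = _kernel_weights(series.stage[p], keypoints, bandwidth, series.weights)
        m, _, _ = _weighted_moments(w, series.values, 1e-8)
        hi += m >= obs_means
        lo += m <= obs_means
    p_hi = (hi + 1) / (n_perm_eff + 1)
    p_lo = (lo + 1) / (n_perm_eff + 1)
    if two_sided:
        pvals = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    else:
        pvals = p_hi
    return pvals.T.ravel()


def expected_null_tail_count(n_points: int, tail: float = 0.05) -> float:
    """Expected number of keypoints in the ``tail`` under the null."""
    if n_points < 0 or not 0 <= tail <= 1:
        raise ValueError("invalid arguments")
    return float(n_points * tail)
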