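"""Two-stage bootstrap (TSB) with shrinkage correction for clustered data.

A cluster-randomised trial violates the i.i.d. assumption of the ordinary
bootstrap: women in the same maternity clinic are correlated.  The TSB
respects the two-level structure by resampling clusters first and individuals
within clusters second.  Two corrections make the resampled variance match the
variance components of the data-generating process:

* cluster means are *shrunk* toward the grand mean by a factor ``c`` before
  being resampled, so the variance of resampled cluster means matches the
  between-cluster variance component rather than the (inflated) raw variance
  of observed cluster means;
* within-cluster residuals are *standardised* by ``sqrt(n_j / (n_j - 1))`` so
  that resampling them with replacement reproduces the unbiased within-cluster
  variance.

Unbalanced clusters are handled by letting each drawn cluster contribute its
own original size (rather than the size of the slot it lands in), and the
cost-effect pairing is preserved by drawing cluster and residual indices
jointly for the two variables.

Confidence intervals use the bias-corrected and accelerated (BCa) percentile
method with a leave-one-cluster-out jackknife for the acceleration constant
(the cluster is the independence unit in a cluster-randomised trial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .trial_io import ARMS, INTERVENTION, USUAL_CARE, TrialDataError


@dataclass
class BootstrapConfig:
    """Replicate count, seed and confidence level for one TSB run."""

    R: int = 5000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if self.R < 1:
            raise TrialDataError(f"R must be >= 1, got {self.R}")
        if not (0.0 < self.level < 1.0):
            raise TrialDataError(f"confidence level must be in (0, 1), got {self.level}")


@dataclass
class ShrinkageStats:
    """Cluster summaries feeding the first resampling stage."""

    cluster_ids: list
    n_j: np.ndarray               # cluster sizes
    cluster_means: np.ndarray     # raw means ybar_j
    grand_mean: float             # pooled mean over individuals
    ss_within: float              # sum_j sum_i (y_ij - ybar_j)^2
    ss_between: float             # sum_j n_j (ybar_j - ybar)^2
    harmonic_size: float          # b, harmonic mean of n_j
    c: float                      # shrinkage factor in [0, 1]
    shrunken_means: np.ndarray    # ybar + c (ybar_j - ybar)


def _cluster_index(clusters) -> Tuple[list, np.ndarray]:
    clusters = np.asarray(clusters)
    ids = list(dict.fromkeys(clusters.tolist()))  # order of first appearance
    codes = np.array([ids.index(c) for c in clusters.tolist()])
    return ids, codes


def shrunken_means(values: Sequence[float], clusters: Sequence,
                   c_override: Optional[float] = None) -> ShrinkageStats:
    """Shrunken cluster means and the variance decomposition behind them.

    Raw cluster means over-disperse relative to the between-cluster variance
    component (each carries within-cluster noise sigma_W^2 / n_j), so
    resampling them directly would inflate the bootstrap variance of an arm
    mean; resampling them with replacement through an empirical distribution
    with denominator M would also lose a factor (M-1)/M.  The shrinkage
    factor used here calibrates both at once: the variance of one draw from
    the shrunken means, ``c^2 (1/M) sum_j (ybar_j - ybar)^2``, is set equal
    to the one-way ANOVA estimate of the between-cluster variance component
    ``sigma_B^2 = (MSB - MSW) / n0``, and c is clamped to [0, 1] so shrunken
    means always lie between each cluster mean and the grand mean.

    Degenerate cases: ``SS_B = 0`` gives c = 0 (with a warning — every
    shrunken mean is the grand mean); ``SS_W = 0`` with ``SS_B > 0`` gives
    c = 1 (raw cluster means are resampled as-is).  ``c_override`` forces a
    fixed factor, mainly for reductions in tests.
    """
    y = np.asarray(values, dtype=float)
    ids, codes = _cluster_index(clusters)
    if len(ids) < 2:
        raise TrialDataError("shrunken_means needs at least 2 clusters")
    n_j = np.bincount(codes).astype(float)
    if np.any(n_j == 0):
        raise TrialDataError("every cluster must be non-empty")
    sums = np.bincount(codes, weights=y)
    means = sums / n_j
    grand = float(y.mean())
    ss_w = float(np.sum((y - means[codes]) ** 2))
    ss_b = float(np.sum(n_j * (means - grand) ** 2))
    b = float(len(n_j) / np.sum(1.0 / n_j))
    M, N = len(n_j), y.size
    if c_override is not None:
        c = float(c_override)
    elif ss_b == 0.0:
        warnings.warn("between-cluster sum of squares is zero; shrinkage factor set to 0",
                      stacklevel=2)
        c = 0.0
    elif ss_w == 0.0:
        c = 1.0
    else:
        msb = ss_b / (M - 1)
        msw = ss_w / max(N - M, 1)
        n0 = (N - np.sum(n_j ** 2) / N) / (M - 1)  # ANOVA average cluster size
        sigma_b2 = max((msb - msw) / n0, 0.0)
        spread = np.sum((means - grand) ** 2) / M  # variance of one uniform draw
        c = float(np.sqrt(np.clip(sigma_b2 / spread, 0.0, 1.0))) if spread > 0 else 0.0
    shrunk = grand + c * (means - grand)
    return ShrinkageStats(cluster_ids=ids, n_j=n_j, cluster_means=means,
                          grand_mean=grand, ss_within=ss_w, ss_between=ss_b,
                          harmonic_size=b, c=c, shrunken_means=shrunk)


def standardised_residuals(values: Sequence[float], clusters: Sequence) -> np.ndarray:
    """Within-cluster residuals scaled by sqrt(n_j / (n_j - 1)).

    The scaling makes the mean of squared residuals within a cluster equal its
    unbiased within-cluster variance, correcting the downward bias of
    with-replacement resampling.  A singleton cluster has residual 0.
    """
    y = np.asarray(values, dtype=float)
    _, codes = _cluster_index(clusters)
    n_j = np.bincount(codes).astype(float)
    sums = np.bincount(codes, weights=y)
    means = sums / n_j
    scale = np.where(n_j > 1, np.sqrt(n_j / np.maximum(n_j - 1.0, 1.0)), 0.0)
    return (y - means[codes]) * scale[codes]


def _replicate_seeds(seed: int, R: int) -> list:
    # one root seed; per-replicate substreams so changing R never perturbs
    # earlier replicates
    return np.random.SeedSequence(seed).spawn(R)


class _ArmSampler:
    """Pre-computed per-arm ingredients for the second-stage resampling."""

    def __init__(self, costs, effects, clusters, c_override=None):
        self.cost_stats = shrunken_means(costs, clusters, c_override=c_override)
        self.effect_stats = shrunken_means(effects, clusters, c_override=c_override)
        rc = standardised_residuals(costs, clusters)
        re = standardised_residuals(effects, clusters)
        _, codes = _cluster_index(clusters)
        self.M = len(self.cost_stats.cluster_ids)
        self.n_j = self.cost_stats.n_j.astype(int)
        self.cost_resid = [rc[codes == j] for j in range(self.M)]
        self.effect_resid = [re[codes == j] for j in range(self.M)]

    def draw_means(self, rng) -> Tuple[float, float]:
        """One synthetic-sample pair of arm means (cost, effect)."""
        slots = rng.integers(0, self.M, self.M)
        tot_c = tot_e = 0.0
        n_tot = 0
        for j in slots:
            m = self.n_j[j]
            # paired draw: the same residual indices serve cost and effect
            sel = rng.integers(0, m, m)
            tot_c += m * self.cost_stats.shrunken_means[j] + self.cost_resid[j][sel].sum()
            tot_e += m * self.effect_stats.shrunken_means[j] + self.effect_resid[j][sel].sum()
            n_tot += m
        return tot_c / n_tot, tot_e / n_tot


def tsb_resample(costs: Sequence[float], effects: Sequence[float],
                 clusters: Sequence, arms: Sequence,
                 config: BootstrapConfig,
                 c_override: Optional[float] = None) -> np.ndarray:
    """R replicate pairs (delta cost, delta effect), intervention minus usual care.

    ``costs`` and ``effects`` are aligned per participant (the pairing is what
    preserves the cost-effect correlation); ``clusters`` and ``arms`` give each
    participant's cluster and trial arm.  Effects should already be
    benefit-signed by the caller.  Returns an (R, 2) array with columns
    (delta_cost, delta_effect); the stream is bit-reproducible from the seed
    and the first replicates do not change when R is increased.
    """
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    arms = np.asarray(arms)
    clusters = np.asarray(clusters)
    if not (len(costs) == len(effects) == len(clusters) == len(arms)):
        raise TrialDataError("costs, effects, clusters and arms must align per participant")
    samplers = {}
    for arm in ARMS:
        mask = arms == arm
        if not mask.any():
            raise TrialDataError(f"arm {arm!r} has no participants")
        samplers[arm] = _ArmSampler(costs[mask], effects[mask], clusters[mask],
                                    c_override=c_override)
    out = np.empty((config.R, 2))
    for r, child in enumerate(_replicate_seeds(config.seed, config.R)):
        rng = np.random.default_rng(child)
        ci, ei = samplers[INTERVENTION].draw_means(rng)
        cu, eu = samplers[USUAL_CARE].draw_means(rng)
        out[r, 0] = ci - cu
        out[r, 1] = ei - eu
    return out


def bootstrap_arm_means(values: Sequence[float], clusters: Sequence,
                        R: int, seed: int,
                        c_override: Optional[float] = None) -> np.ndarray:
    """TSB replicate means for a single arm (calibration/diagnostic helper)."""
    values = np.asarray(values, dtype=float)
    sampler = _ArmSampler(values, values, clusters, c_override=c_override)
    out = np.empty(R)
    for r, child in enumerate(_replicate_seeds(seed, R)):
        rng = np.random.default_rng(child)
        out[r], _ = sampler.draw_means(rng)
    return out


def jackknife_cluster_deltas(costs: Sequence[float], clusters: Sequence,
                             arms: Sequence,
                             benefit_signed: bool = True) -> np.ndarray:
    """Leave-one-cluster-out estimates of the arm-mean difference.

    Drops one cluster at a time (across both arms) and recomputes
    mean(intervention) - mean(usual care); feeds the BCa acceleration.
    """
    y = np.asarray(costs, dtype=float)
    clusters = np.asarray(clusters)
    arms = np.asarray(arms)
    ids = list(dict.fromkeys(clusters.tolist()))
    if len(ids) < 3:
        raise TrialDataError("jackknife needs at least 3 clusters")
    out = []
    for cid in ids:
        keep = clusters != cid
        iv = y[keep & (arms == INTERVENTION)]
        uv = y[keep & (arms == USUAL_CARE)]
        if iv.size == 0 or uv.size == 0:
            raise TrialDataError(f"dropping cluster {cid!r} empties an arm")
        out.append(iv.mean() - uv.mean())
    return np.asarray(out)


def bca_interval(replicates: Sequence[float], observed: float,
                 jackknife_values: Sequence[float],
                 level: float = 0.95) -> Tuple[float, float]:
    """Bias-corrected and accelerated percentile interval.

    The bias constant is ``z0 = Phi^-1(#{replicate < observed} / R)`` and the
    acceleration ``a`` is the jackknife skewness
    ``sum(d_i^3) / (6 (sum(d_i^2))^(3/2))`` with ``d_i`` the deviations of the
    leave-one-out estimates from their mean.  The adjusted percentile points
    ``Phi(z0 + (z0 + z_alpha) / (1 - a (z0 + z_alpha)))`` are mapped through
    the empirical replicate distribution.  If every replicate is identical the
    interval degenerates to (observed, observed) with a warning.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2 or np.all(reps == reps[0]):
        warnings.warn("degenerate bootstrap distribution; interval collapses to the "
                      "observed value", stacklevel=2)
        return float(observed), float(observed)
    R = reps.size
    # midrank tie handling: replicates exactly at the observed value count half
    prop = (np.count_nonzero(reps < observed)
            + 0.5 * np.count_nonzero(reps == observed)) / R
    prop = min(max(prop, 1.0 / (R + 1)), R / (R + 1))  # keep z0 finite
    z0 = stats.norm.ppf(prop)
    jack = np.asarray(jackknife_values, dtype=float)
    d = jack.mean() - jack
    denom = np.sum(d ** 2) ** 1.5
    a = float(np.sum(d ** 3) / (6.0 * denom)) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for z_alpha in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(reps, np.clip(stats.norm.cdf(adj), 0.0, 1.0))))
    lower, upper = min(lo_hi), max(lo_hi)
    return lower, upper
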