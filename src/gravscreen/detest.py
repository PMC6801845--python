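"""Two-group exact negative-binomial differential-expression test.

This is the statistic behind every contrast in the pipeline: counts are
quantile-adjusted to a common library size, the replicate sums of the two
groups are compared conditionally on their total, and the two-sided p-value
sums the probabilities of all splits no more likely than the observed one.

With per-sample counts NB(mu, phi) and equal library sizes, the group sums
are NB with sizes n_a/phi and n_b/phi and a shared success probability, so
the split of the conditional total follows a beta-binomial
BetaBinomial(s, n_a/phi, n_b/phi); for phi -> 0 this degenerates to the
binomial split of a Poisson total. The common dispersion phi is estimated
by maximizing the conditional log-likelihood of the within-group counts
given the group totals (qCML), with a method-of-moments fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "Contrast",
    "DispersionEstimate",
    "q2qnbinom",
    "equalize_library_sizes",
    "estimate_common_dispersion",
    "exact_nb_test",
    "run_contrast",
]

#: Relative tolerance when comparing outcome probabilities to the observed
#: one (guards against ties lost to floating point).
_TIE_RTOL = 1e-10

#: Support enumeration window: outcomes outside the central
#: 1 - 2 * _TAIL_EPS probability mass are truncated for very large totals.
_TAIL_EPS = 1e-13


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison (group_b relative to group_a)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValueError(f"contrast {self.name!r}: both groups must be nonempty")
        if a & b:
            raise ValueError(f"contrast {self.name!r}: groups overlap: {sorted(a & b)}")


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str = "cml"  # "cml" or "moments"

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError("dispersion must be nonnegative")


def q2qnbinom(
    x: np.ndarray,
    input_mean: np.ndarray,
    output_mean: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    """Quantile-to-quantile mapping between NB distributions.

    Maps observations with mean ``input_mean`` to equivalent quantiles of an
    NB distribution with ``output_mean`` (same dispersion), averaging a
    normal and a gamma continuous approximation; used to place all samples
    on a common library size before conditioning.
    """
    x = np.asarray(x, dtype=float)
    in_m = np.array(np.broadcast_to(np.asarray(input_mean, float), x.shape))
    out_m = np.array(np.broadcast_to(np.asarray(output_mean, float), x.shape))
    tiny = in_m < 1e-14
    in_m[tiny] += 0.25
    out_m[out_m < 1e-14] += 0.25

    ri = 1.0 + dispersion * in_m
    vi = in_m * ri
    ro = 1.0 + dispersion * out_m
    vo = out_m * ro

    q = np.empty_like(x)
    upper = x >= in_m
    for mask, cdf_from, q_to in (
        (upper, "sf", "isf"),
        (~upper, "cdf", "ppf"),
    ):
        if not mask.any():
            continue
        xm, im, om = x[mask], in_m[mask], out_m[mask]
        vim, vom = vi[mask], vo[mask]
        rim, rom = ri[mask], ro[mask]
        p_norm = getattr(stats.norm, cdf_from)(xm, loc=im, scale=np.sqrt(vim))
        q_norm = getattr(stats.norm, q_to)(p_norm, loc=om, scale=np.sqrt(vom))
        p_gam = getattr(stats.gamma, cdf_from)(xm, a=im / rim, scale=rim)
        q_gam = getattr(stats.gamma, q_to)(p_gam, a=om / rom, scale=rom)
        q[mask] = 0.5 * (q_norm + q_gam)
    return np.maximum(q, 0.0)


def equalize_library_sizes(
    counts: pd.DataFrame,
    dispersion: float,
    lib_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Pseudo-counts on a common library size (geometric mean of lib sizes).

    ``lib_sizes`` defaults to raw column sums; pass factor-adjusted
    (effective) sizes to fold scaling normalization into the adjustment.
    Returns (pseudo_counts, common_size).
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(lib).any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive and cover all samples")
    common = float(np.exp(np.mean(np.log(lib))))
    prop = counts.sum(axis=1).to_numpy(dtype=float) / lib.sum()
    input_mean = np.outer(prop, lib)
    output_mean = prop[:, None] * common
    pseudo = q2qnbinom(counts.to_numpy(dtype=float), input_mean, output_mean, dispersion)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


def _group_matrices(
    counts: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> list[np.ndarray]:
    groups = pd.Series(groups)
    out: list[np.ndarray] = []
    for label in groups.unique():
        samples = groups.index[groups == label]
        samples = [s for s in samples if s in counts.columns]
        if samples:
            out.append(counts[samples].to_numpy(dtype=float))
    return out


def _cond_log_lik(mats: Sequence[np.ndarray], phi: float) -> float:
    """Summed conditional log-likelihood of within-group counts given totals."""
    r = 1.0 / phi
    total = 0.0
    for y in mats:
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) + np.sum(gammaln(n * r) - gammaln(z + n * r)) - y.size * gammaln(r)
        )
    return total


def _moments_dispersion(mats: Sequence[np.ndarray]) -> float:
    """Method-of-moments phi from pooled within-group mean/variance."""
    num = 0.0
    den = 0.0
    for y in mats:
        n = y.shape[1]
        if n < 2:
            continue
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        ok = m > 0
        w = n - 1
        num += w * np.sum((v[ok] - m[ok]) / m[ok] ** 2)
        den += w * ok.sum()
    return max(0.0, num / den) if den else 0.0


def _golden_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximization of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    lib_sizes: pd.Series | None = None,
    phi_max: float = 10.0,
    tol: float = 1e-6,
    min_row_sum: float = 5.0,
) -> DispersionEstimate:
    """Common NB dispersion by quantile-adjusted conditional maximum likelihood.

    ``groups`` maps sample_id -> group label. Counts are first placed on a
    common library size (quantile adjustment at a pilot dispersion), the
    conditional log-likelihood summed over genes and groups is maximized
    over phi in [0, phi_max] by golden-section search, and the adjustment is
    refined once at the estimate. Genes with total count <= ``min_row_sum``
    are excluded from estimation (their conditional likelihood carries
    almost no information and is dominated by discreteness).
    """
    groups = pd.Series(groups)
    samples = [s for s in counts.columns if s in groups.index]
    if not samples:
        raise ValueError("no overlap between counts columns and group map")
    sub = counts[samples]
    sizes = groups[samples].value_counts()
    if (sizes < 2).all():
        raise ValueError(
            "every group has a single replicate; the dispersion is not "
            "identifiable -- supply phi explicitly"
        )
    keep = sub.sum(axis=1) > min_row_sum
    if not keep.any():
        raise ValueError("no genes pass the minimum row-sum filter")
    sub = sub.loc[keep]

    pilot = _moments_dispersion(_group_matrices(sub, groups))
    phi = min(max(pilot, 0.01), phi_max)
    for _ in range(2):
        pseudo, _ = equalize_library_sizes(sub, phi, lib_sizes=lib_sizes)
        mats = _group_matrices(pseudo, groups)
        obj = lambda p: _cond_log_lik(mats, p)  # noqa: E731
        phi = _golden_max(obj, tol, phi_max, tol)
    if not np.isfinite(phi) or phi >= phi_max - 10 * tol:
        return DispersionEstimate(phi=_moments_dispersion(mats), method="moments")
    if phi <= 2 * tol:
        # maximum at (or numerically indistinguishable from) the Poisson boundary
        phi = 0.0
    return DispersionEstimate(phi=float(phi), method="cml")


@lru_cache(maxsize=256)
def _split_log_pmf(s: int, n_a: int, n_b: int, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Log pmf of the conditional split sum_a = k given total s.

    Returns (k values, log pmf), truncated to the central 1 - 2e-13 mass for
    very large totals. BetaBinomial(s, n_a/phi, n_b/phi); binomial when
    phi == 0. Computed directly via log-gamma for speed; results are cached.
    """
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")
    if s > 20000:
        if phi == 0:
            dist = stats.binom(s, n_a / (n_a + n_b))
        else:
            dist = stats.betabinom(s, n_a / phi, n_b / phi)
        lo = max(int(dist.ppf(_TAIL_EPS)) - 1, 0)
        hi = min(int(dist.ppf(1.0 - _TAIL_EPS)) + 1, s)
    else:
        lo, hi = 0, s
    k = np.arange(lo, hi + 1)
    logp = _log_pmf_at(s, n_a, n_b, phi, k)
    k.setflags(write=False)
    logp.setflags(write=False)
    return k, logp


def _log_pmf_at(s: int, n_a: int, n_b: int, phi: float, k) -> np.ndarray:
    """Log pmf of the conditional split at k (binomial / beta-binomial)."""
    k = np.asarray(k, dtype=float)
    log_choose = gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1)
    if phi == 0:
        p = n_a / (n_a + n_b)
        return log_choose + k * np.log(p) + (s - k) * np.log1p(-p)
    ra, rb = n_a / phi, n_b / phi
    return (
        log_choose
        + gammaln(k + ra) + gammaln(s - k + rb) + gammaln(ra + rb)
        - gammaln(ra) - gammaln(rb) - gammaln(s + ra + rb)
    )


def exact_nb_test(
    sum_a: float,
    sum_b: float,
    n_a: int,
    n_b: int,
    mean_total: float | None = None,
    phi: float = 0.0,
) -> float:
    """Two-sided exact test of equal means from group sums of counts.

    ``sum_a``/``sum_b`` are replicate sums of library-size-equalized counts
    (rounded to integers); ``n_a``/``n_b`` the replicate numbers; ``phi``
    the common NB dispersion. The p-value sums, over all splits of the
    conditional total, the probabilities that do not exceed the observed
    split's probability, renormalized by the (possibly truncated) total
    mass. A zero total is untestable and returns 1.0 by convention.
    ``mean_total`` is accepted for interface compatibility; the conditional
    split distribution does not depend on it.
    """
    del mean_total
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one sample")
    if sum_a < 0 or sum_b < 0:
        raise ValueError("group sums must be nonnegative")
    obs = int(round(sum_a))
    s = obs + int(round(sum_b))
    if s == 0:
        return 1.0
    k, logp = _split_log_pmf(s, n_a, n_b, phi)
    if obs < k[0] or obs > k[-1]:
        log_obs = float(_log_pmf_at(s, n_a, n_b, phi, obs))
    else:
        log_obs = logp[obs - k[0]]
    le_obs = logp <= log_obs + np.log1p(_TIE_RTOL)
    if not le_obs.any():
        return 0.0
    return float(min(1.0, np.exp(logsumexp(logp[le_obs]) - logsumexp(logp))))


def run_contrast(
    counts: pd.DataFrame,
    normalized: pd.DataFrame,
    contrast: Contrast,
    phi: float,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    lib_sizes: pd.Series | None = None,
    bh: bool = False,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Exact NB test of every gene for one two-group contrast.

    Fold change is computed on normalized group means with a pseudocount
    added to both means; ``significant`` requires p < alpha AND a fold
    change beyond ``fc_threshold`` in either direction. Pass ``bh=True`` to
    append Benjamini-Hochberg adjusted p-values (the screen itself follows
    the unadjusted convention).
    """
    group_a = [s for s in contrast.group_a if s in counts.columns]
    group_b = [s for s in contrast.group_b if s in counts.columns]
    if not group_a or not group_b:
        raise ValueError(f"contrast {contrast.name!r}: samples missing from the matrix")
    sub = counts[group_a + group_b]
    pseudo, _ = equalize_library_sizes(sub, phi, lib_sizes=lib_sizes)
    sums_a = pseudo[group_a].sum(axis=1)
    sums_b = pseudo[group_b].sum(axis=1)

    p_values = np.array(
        [
            exact_nb_test(sa, sb, len(group_a), len(group_b), phi=phi)
            for sa, sb in zip(sums_a.to_numpy(), sums_b.to_numpy())
        ]
    )
    mean_a = normalized[group_a].mean(axis=1)
    mean_b = normalized[group_b].mean(axis=1)
    fold_change = (mean_b + pseudocount) / (mean_a + pseudocount)
    result = pd.DataFrame(
        {
            "gene_id": counts.index,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "fold_change": fold_change.to_numpy(),
            "log2_fc": np.log2(fold_change.to_numpy()),
            "p_value": p_values,
        }
    )
    if bh:
        from statsmodels.stats.multitest import multipletests

        result["fdr"] = multipletests(p_values, method="fdr_bh")[1]
    result["significant"] = (result["p_value"] < alpha) & (
        (result["fold_change"] > fc_threshold) | (result["fold_change"] < 1.0 / fc_threshold)
    )
    return result
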