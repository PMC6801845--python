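"""Scaling-factor normalization of the count matrix.

Per-sample scaling factors are trimmed weighted means of gene-wise log
ratios against a reference sample (TMM-style), and normalized expression is
counts per million after factor adjustment:

    value(g, s) = count(g, s) / (library_size(s) * factor(s)) * 1e6

The factor computation is isolated here so alternative scaling schemes
(median-of-ratios, upper quartile) can be swapped without touching the rest
of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    values = counts.to_numpy(dtype=float)
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(f"sample {counts.columns[zero[0]]!r} has all-zero counts")
    return values


def choose_reference(counts: pd.DataFrame) -> str:
    """Reference sample: column whose upper quartile of relative abundance
    (count / library size) is closest to the mean upper quartile."""
    values = _check_counts(counts)
    rel = values / values.sum(axis=0, keepdims=True)
    q75 = np.quantile(rel, 0.75, axis=0)
    idx = int(np.argmin(np.abs(q75 - q75.mean())))
    return str(counts.columns[idx])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """Trimmed weighted mean of log2 ratios of one sample vs the reference.

    Genes with a zero count in either column are excluded. Weights are the
    inverse approximate (binomial) variances of the log ratio. Returns the
    log2 scaling factor.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    A factor > 1 means the sample's counts over-represent its true relative
    abundances (its effective library size is larger than the raw one).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to compute scaling factors")
    values = _check_counts(counts)
    if reference is None:
        reference = choose_reference(counts)
    ref = values[:, counts.columns.get_loc(reference)]
    log_factors = np.array(
        [_tmm_pair(values[:, j], ref, trim_m, trim_a) for j in range(values.shape[1])]
    )
    factors = np.power(2.0, log_factors)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on factor-adjusted library sizes.

    Genes that are zero everywhere stay in the output (value 0) so the gene
    universe is identical across pipeline stages.
    """
    if factors is None:
        factors = tmm_factors(counts)
    if len(factors) != counts.shape[1]:
        raise ValueError("one factor per sample required")
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        missing = factors.index[factors.isna()][0]
        raise ValueError(f"no factor for sample {missing!r}")
    if (factors <= 0).any():
        raise ValueError("scaling factors must be strictly positive")
    lib = counts.sum(axis=0).astype(float)
    return counts / (lib * factors) * 1e6


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Factor-adjusted library sizes (raw column sum times factor)."""
    return counts.sum(axis=0).astype(float) * factors.reindex(counts.columns)
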