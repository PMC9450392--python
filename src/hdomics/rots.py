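"""Reproducibility-optimized two-group differential abundance testing.

The statistic family is

    d_g = |mean1_g - mean2_g| / (alpha1 + alpha2 * s_g)

where ``s_g`` is the standard error of the mean difference
(sqrt(var1/n1 + var2/n2), the Welch denominator). ``(alpha1, alpha2) =
(1, 0)`` reduces to the plain absolute mean difference; ``(0, 1)`` to the
absolute Welch t statistic. Instead of fixing the normalization a priori,
the procedure chooses the member of the family — and the top-list size k
— that maximizes the *reproducibility* of the feature ranking:

1. Draw B pairs of bootstrap datasets (resampling samples with
   replacement within each group); for each pair rank features by d and
   record the fractional overlap of the two top-k lists, R_k.
2. Repeat with group labels randomly permuted to obtain null overlaps
   R0_k, whose mean and spread calibrate chance agreement.
3. The reproducibility Z-score Z_k(alpha) = (R_k - R0_k) / sd(R0_k) is
   maximized over the (alpha, k) grid.

Significance of the chosen statistic is assessed by permuting group
labels: pooled permutation p-values and a permutation-based FDR (expected
null exceedances over observed rank, made monotone in |d|).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA1_LADDER = (0.0, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0)


def default_k_grid(n_features: int) -> tuple[int, ...]:
    """Logarithmic ladder of top-list sizes, capped at the feature count."""
    ladder = [10, 25, 50, 100, 250, 500, 1000, 2500, 5000, 10000, 25000]
    ks = [k for k in ladder if k < n_features]
    if not ks or ks[-1] != n_features:
        ks.append(n_features)
    return tuple(ks)


@dataclass
class RotsParams:
    """Grid and bookkeeping for the optimization.

    The alpha grid always contains the plain mean-difference member
    ``(1, 0)`` and the t-like member ``(0, 1)``.
    """

    alpha_grid: tuple = tuple((a, 1.0) for a in DEFAULT_ALPHA1_LADDER) + ((1.0, 0.0),)
    k_grid: tuple | None = None  # default: ladder up to the feature count
    B: int = 1000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not self.alpha_grid:
            raise ValueError("alpha grid must be non-empty")

    def resolved_k_grid(self, n_features: int) -> tuple[int, ...]:
        ks = self.k_grid if self.k_grid is not None else default_k_grid(n_features)
        if any(k > n_features for k in ks):
            raise ValueError("k grid exceeds the number of features")
        return tuple(ks)


@dataclass
class RotsResult:
    """Per-feature results plus the provenance of the optimization."""

    d: pd.Series
    p: pd.Series
    fdr: pd.Series
    alpha1: float
    alpha2: float
    k: int
    reproducibility_z: float
    R_observed: float
    R_null: float
    B: int
    n_perm: int
    seed: int


def _group_stats(x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-complete per-feature mean, variance and observation count
    over the sample columns ``idx``."""
    import warnings

    sub = x[:, idx]
    cnt = np.sum(~np.isnan(sub), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # features with < 2 obs
        mean = np.nanmean(sub, axis=1)
        var = np.nanvar(sub, axis=1, ddof=1)
    mean[cnt < 1] = np.nan
    var[cnt < 2] = np.nan
    return mean, var, cnt


def _num_den(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    m1, v1, n1 = _group_stats(x, idx1)
    m2, v2, n2 = _group_stats(x, idx2)
    num = np.abs(m1 - m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt(v1 / n1 + v2 / n2)
    bad = (n1 < 2) | (n2 < 2)
    num[bad] = np.nan
    den[bad] = np.nan
    return num, den


def rots_statistic(group1: np.ndarray | pd.DataFrame, group2: np.ndarray | pd.DataFrame,
                   alpha1: float, alpha2: float) -> np.ndarray:
    """d = |mean1 - mean2| / (alpha1 + alpha2 * s) per feature (rows).

    ``s`` is the Welch standard error of the mean difference. Features
    with fewer than two observations in either group get NaN.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    x = np.hstack([g1, g2])
    idx1 = np.arange(g1.shape[1])
    idx2 = np.arange(g1.shape[1], x.shape[1])
    num, den = _num_den(x, idx1, idx2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (alpha1 + alpha2 * den)
    return d


def _rank_positions(d: np.ndarray) -> np.ndarray:
    """rank[g] = position of feature g in the descending-|d| ordering
    (0 = top). NaN statistics rank last."""
    key = np.where(np.isnan(d), -np.inf, d)
    order = np.argsort(-key, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return ranks


def top_k_overlap(d_a: np.ndarray, d_b: np.ndarray, k: int) -> float:
    """Fractional overlap of the two top-k lists ranked by descending d."""
    if k > len(d_a):
        raise ValueError("k exceeds the number of features")
    ra = _rank_positions(np.asarray(d_a, dtype=float))
    rb = _rank_positions(np.asarray(d_b, dtype=float))
    return float(np.sum((ra < k) & (rb < k)) / k)


def _pair_overlaps(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                   alphas: tuple, ks: tuple, rng: np.random.Generator,
                   B: int, permute: bool) -> np.ndarray:
    """Overlap fractions, shape (B, len(alphas), len(ks)).

    For each of B rounds two bootstrap datasets are drawn (stratified
    within groups, with replacement); with ``permute`` the group labels
    are randomly reassigned first, giving the null scheme.
    """
    n1, n2 = len(idx1), len(idx2)
    pool = np.concatenate([idx1, idx2])
    out = np.empty((B, len(alphas), len(ks)))
    ks_arr = np.asarray(ks)
    for b in range(B):
        if permute:
            perm = rng.permutation(pool)
            g1, g2 = perm[:n1], perm[n1:]
        else:
            g1, g2 = idx1, idx2
        max_ranks = None
        for half in range(2):
            bs1 = rng.choice(g1, size=n1, replace=True)
            bs2 = rng.choice(g2, size=n2, replace=True)
            num, den = _num_den(x, bs1, bs2)
            ranks_per_alpha = []
            for (a1, a2) in alphas:
                with np.errstate(invalid="ignore", divide="ignore"):
                    d = num / (a1 + a2 * den)
                ranks_per_alpha.append(_rank_positions(d))
            ranks_per_alpha = np.asarray(ranks_per_alpha)
            if half == 0:
                max_ranks = ranks_per_alpha
            else:
                max_ranks = np.maximum(max_ranks, ranks_per_alpha)
        # overlap at k = #{features whose max rank over the pair < k} / k
        for ai in range(len(alphas)):
            sorted_m = np.sort(max_ranks[ai])
            out[b, ai, :] = np.searchsorted(sorted_m, ks_arr, side="left") / ks_arr
    return out


def bootstrap_reproducibility(matrix: pd.DataFrame, labels,
                              params: RotsParams | None = None) -> pd.DataFrame:
    """Observed bootstrap top-list overlap curve R_k per (alpha, k).

    Returns a DataFrame indexed by (alpha1, alpha2) with one column per k,
    each entry the mean overlap over the B bootstrap pairs.
    """
    params = params or RotsParams()
    x, idx1, idx2, _ = _split(matrix, labels)
    ks = params.resolved_k_grid(x.shape[0])
    rng = np.random.default_rng(params.seed)
    ov = _pair_overlaps(x, idx1, idx2, params.alpha_grid, ks, rng,
                        params.B, permute=False)
    idx = pd.MultiIndex.from_tuples(params.alpha_grid, names=["alpha1", "alpha2"])
    return pd.DataFrame(ov.mean(axis=0), index=idx, columns=list(ks))


def _split(matrix: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    lab = np.asarray(pd.Series(labels).loc[list(matrix.columns)]
                     if isinstance(labels, (pd.Series, dict)) else labels)
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValueError(f"exactly two group labels required, got {list(uniq)}")
    idx1 = np.flatnonzero(lab == uniq[0])
    idx2 = np.flatnonzero(lab == uniq[1])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each group needs at least two samples")
    return matrix.to_numpy(dtype=float), idx1, idx2, tuple(uniq)


def optimize_parameters(matrix: pd.DataFrame, labels,
                        params: RotsParams | None = None
                        ) -> tuple[float, float, int, float, dict]:
    """Choose (alpha1, alpha2, k) maximizing the reproducibility Z-score.

    Z_k(alpha) = (R_k - R0_k) / sd(R0_k), with R from bootstrap pairs on
    the observed labels and R0 / sd from the same scheme under label
    permutation. Ties prefer smaller k, then smaller alpha2, then smaller
    alpha1; grid points with zero null spread are skipped with a warning.

    Returns ``(alpha1, alpha2, k, Z, details)`` where ``details`` carries
    the full R, R0 and Z grids plus the chosen point's overlap values.
    """
    params = params or RotsParams()
    x, idx1, idx2, _ = _split(matrix, labels)
    ks = params.resolved_k_grid(x.shape[0])
    alphas = params.alpha_grid
    rng = np.random.default_rng(params.seed)
    ov_obs = _pair_overlaps(x, idx1, idx2, alphas, ks, rng, params.B, permute=False)
    ov_null = _pair_overlaps(x, idx1, idx2, alphas, ks, rng, params.B, permute=True)
    r = ov_obs.mean(axis=0)
    r0 = ov_null.mean(axis=0)
    sd0 = ov_null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (r - r0) / sd0
    degenerate = sd0 == 0
    if degenerate.any():
        logger.warning("optimize_parameters: %d grid points with zero null "
                       "spread skipped", int(degenerate.sum()))
        z[degenerate] = -np.inf
    best, best_key = None, None
    for ai, (a1, a2) in enumerate(alphas):
        for ki, k in enumerate(ks):
            if not np.isfinite(z[ai, ki]):
                continue
            key = (-z[ai, ki], k, a2, a1)  # max Z; ties: small k, small alpha2
            if best_key is None or key < best_key:
                best_key = key
                best = (a1, a2, k, float(z[ai, ki]),
                        float(r[ai, ki]), float(r0[ai, ki]))
    if best is None:
        raise ValueError("no usable grid point (all null spreads degenerate)")
    a1, a2, k, zval, robs, rnull = best
    details = {"R": r, "R0": r0, "Z": z, "alphas": alphas, "ks": ks,
               "R_observed": robs, "R_null": rnull}
    return a1, a2, k, zval, details


def permutation_fdr(matrix: pd.DataFrame, labels, alpha1: float, alpha2: float,
                    n_perm: int = 1000, seed: int = 0,
                    strata=None) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Permutation p-values and FDR for the chosen statistic.

    Group labels are permuted ``n_perm`` times (within strata when
    given); p_g is the add-one-smoothed fraction of pooled null |d| at or
    above |d_g|, and FDR_g is the average number of null statistics at or
    above |d_g| per permutation divided by the observed rank of d_g,
    enforced monotone (larger |d| never gets a larger FDR) and capped at 1.

    Returns ``(d, p, fdr)`` as Series over the feature index.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is below 100; FDR estimates are coarse", n_perm)
    x, idx1, idx2, _ = _split(matrix, labels)
    rng = np.random.default_rng(seed)
    num, den = _num_den(x, idx1, idx2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (alpha1 + alpha2 * den)
    n1 = idx1.size
    pool = np.concatenate([idx1, idx2])
    strata_arr = None
    if strata is not None:
        strata_arr = np.asarray(pd.Series(strata).loc[list(matrix.columns)]
                                if isinstance(strata, (pd.Series, dict)) else strata)
    seen = set()
    null_stats = []
    for _ in range(n_perm):
        if strata_arr is None:
            perm = rng.permutation(pool)
        else:
            perm = pool.copy()
            for s in np.unique(strata_arr[pool]):
                mask = strata_arr[pool] == s
                perm[mask] = rng.permutation(perm[mask])
        key = tuple(sorted(perm[:n1]))
        seen.add(key)
        pnum, pden = _num_den(x, perm[:n1], perm[n1:])
        with np.errstate(invalid="ignore", divide="ignore"):
            null_stats.append(pnum / (alpha1 + alpha2 * pden))
    if len(seen) < n_perm:
        logger.info("permutation_fdr: %d distinct permutations among %d draws",
                    len(seen), n_perm)
    null = np.concatenate(null_stats)
    null = null[np.isfinite(null)]
    null_sorted = np.sort(null)

    valid = np.isfinite(d)
    p = np.full(d.shape, np.nan)
    fdr = np.full(d.shape, np.nan)
    dv = d[valid]
    # pooled exceedance counts (>= |d_g|), add-one smoothing for p
    exceed = len(null_sorted) - np.searchsorted(null_sorted, dv, side="left")
    p[valid] = (exceed + 1.0) / (len(null_sorted) + 1.0)
    order = np.argsort(-dv, kind="stable")
    ranks = np.empty(dv.size)
    ranks[order] = np.arange(1, dv.size + 1)
    raw = (exceed / n_perm) / ranks
    # monotone enforcement: walk up from the least significant feature
    raw_sorted = raw[order]
    q = np.minimum.accumulate(raw_sorted[::-1])[::-1]
    fdr_v = np.empty_like(raw)
    fdr_v[order] = np.minimum(q, 1.0)
    fdr[valid] = fdr_v
    index = matrix.index
    return (pd.Series(d, index=index, name="d"),
            pd.Series(p, index=index, name="p"),
            pd.Series(fdr, index=index, name="fdr"))


def rots_test(matrix: pd.DataFrame, labels, params: RotsParams | None = None
              ) -> RotsResult:
    """Full procedure: optimize (alpha, k) by reproducibility, then score
    significance by permutation. Deterministic given ``params.seed``."""
    params = params or RotsParams()
    a1, a2, k, z, details = optimize_parameters(matrix, labels, params)
    d, p, fdr = permutation_fdr(matrix, labels, a1, a2,
                                n_perm=params.n_perm, seed=params.seed + 1)
    return RotsResult(d=d, p=p, fdr=fdr, alpha1=a1, alpha2=a2, k=k,
                      reproducibility_z=z,
                      R_observed=details["R_observed"],
                      R_null=details["R_null"],
                      B=params.B, n_perm=params.n_perm, seed=params.seed)


def pairwise_rots(matrix: pd.DataFrame, groups, params: RotsParams | None = None
                  ) -> dict[tuple[str, str], RotsResult]:
    """Run the test for every ordered pair of distinct group labels
    (e.g. pre-HD vs control, early-HD vs control, early-HD vs pre-HD)."""
    import itertools

    lab = pd.Series(groups).loc[list(matrix.columns)] \
        if isinstance(groups, (pd.Series, dict)) else pd.Series(groups, index=matrix.columns)
    results = {}
    for g1, g2 in itertools.combinations(pd.unique(lab), 2):
        cols = lab[(lab == g1) | (lab == g2)].index
        results[(str(g1), str(g2))] = rots_test(matrix[cols], lab.loc[cols], params)
    return results
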