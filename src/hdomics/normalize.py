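"""Missing-value imputation, quantile normalization, covariate removal.

Iterative-PCA imputation alternates a truncated-SVD low-rank fit of the
column-centered completed matrix with replacement of the missing cells by
their fitted values, an EM-style completion that converges to a low-rank
reconstruction consistent with the observed entries. Quantile
normalization forces every sample's value distribution onto the mean of
the per-sample sorted distributions, centering samples across TMT plex
sets. Covariate removal fits, per feature, a least-squares linear model
containing both protected factors (e.g. disease stage, whose effects must
survive) and nuisance terms (plex set, site, gender, age, BMI) and
subtracts only the fitted nuisance contribution — the removeBatchEffect
convention, which leaves protected effects and residuals intact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def impute_iterative_pca(matrix: pd.DataFrame, rank: int | None = None,
                         tol: float = 1e-6, max_iter: int = 1000,
                         seed: int = 0) -> pd.DataFrame:
    """Impute missing cells of a feature x sample matrix by iterative PCA.

    Missing cells are initialized with column means; then the completed
    matrix is column-centered, fitted with a rank-``rank`` truncated SVD,
    and the missing cells are replaced by the fitted values, iterating
    until the largest relative change over imputed cells falls below
    ``tol`` or ``max_iter`` is reached (non-convergence warns and returns
    the last iterate). Observed cells are never altered.

    When ``rank`` is None it is chosen by cross-validated masking: 5% of
    the observed cells are held out and the rank in 1..10 minimizing their
    reconstruction RMSE is used.
    """
    x = matrix.to_numpy(dtype=float)
    miss = np.isnan(x)
    if not miss.any():
        return matrix.copy()
    bad_rows = np.flatnonzero(miss.all(axis=1))
    bad_cols = np.flatnonzero(miss.all(axis=0))
    if bad_rows.size or bad_cols.size:
        raise ValueError(
            f"all-missing rows {list(matrix.index[bad_rows])[:5]} / "
            f"columns {list(matrix.columns[bad_cols])[:5]}")
    if rank is None:
        rank = _select_rank(x, seed=seed)
        logger.info("iterative PCA: cross-validated rank %d", rank)
    if rank >= min(x.shape):
        raise ValueError("rank must be below min(rows, columns)")
    filled = _iterate(x, miss, rank, tol, max_iter)
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def _iterate(x: np.ndarray, miss: np.ndarray, rank: int, tol: float,
             max_iter: int) -> np.ndarray:
    filled = x.copy()
    col_means = np.nanmean(x, axis=0)
    filled[miss] = np.broadcast_to(col_means, x.shape)[miss]
    prev = filled[miss].copy()
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        centered = filled - mu
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        fit = (u[:, :rank] * s[:rank]) @ vt[:rank] + mu
        filled[miss] = fit[miss]
        cur = filled[miss]
        scale = np.maximum(np.abs(prev), 1e-12)
        if np.max(np.abs(cur - prev) / scale) < tol:
            break
        prev = cur.copy()
    else:
        warnings.warn("iterative PCA imputation did not converge; returning "
                      f"the max_iter={max_iter} iterate", RuntimeWarning)
    return filled


def _select_rank(x: np.ndarray, seed: int, holdout: float = 0.05,
                 max_rank: int = 10) -> int:
    rng = np.random.default_rng(seed)
    obs = np.argwhere(~np.isnan(x))
    n_hold = max(1, int(round(holdout * len(obs))))
    pick = obs[rng.choice(len(obs), size=n_hold, replace=False)]
    masked = x.copy()
    masked[pick[:, 0], pick[:, 1]] = np.nan
    # masking may empty a row/column; those candidates are skipped
    if np.isnan(masked).all(axis=1).any() or np.isnan(masked).all(axis=0).any():
        masked = x.copy()
        keep = []
        for r, c in pick:
            masked[r, c] = np.nan
            if np.isnan(masked[r]).all() or np.isnan(masked[:, c]).all():
                masked[r, c] = x[r, c]
            else:
                keep.append((r, c))
        pick = np.array(keep)
    truth = x[pick[:, 0], pick[:, 1]]
    best_rank, best_rmse = 1, np.inf
    miss = np.isnan(masked)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # coarse CV fits
        for r in range(1, min(max_rank, min(x.shape) - 1) + 1):
            fit = _iterate(masked, miss, r, tol=1e-5, max_iter=200)
            rmse = float(np.sqrt(np.mean((fit[pick[:, 0], pick[:, 1]] - truth) ** 2)))
            if rmse < best_rmse:
                best_rank, best_rmse = r, rmse
    return best_rank


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean of the per-column sorted distributions.

    Ties within a column receive the mean of the reference quantiles they
    span. Requires a complete matrix; run imputation first.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires a complete matrix; "
                         "impute missing values first")
    ref = np.sort(x, axis=0).mean(axis=1)  # mean of sorted columns
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        sort_idx = np.argsort(x[:, j], kind="stable")
        col = np.empty(n)
        col[sort_idx] = ref
        if np.unique(x[:, j]).size < n:  # ties share the mean reference quantile
            col = (pd.Series(col).groupby(x[:, j]).transform("mean")
                   .to_numpy())
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class CovariateDesign:
    """Which metadata columns to preserve and which to remove.

    ``protected`` factors (e.g. HD stage) enter the model so their effects
    are estimated jointly but never subtracted; ``nuisance`` entries — an
    ordered list of factors or continuous covariates (plex set, site,
    gender, age, BMI) — are subtracted. ``categorical`` lists nuisance /
    protected names to dummy-encode (treatment contrasts); others enter as
    numeric columns.
    """

    protected: list = field(default_factory=list)
    nuisance: list = field(default_factory=list)
    categorical: list = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.protected) & set(self.nuisance)
        if overlap:
            raise ValueError(f"factors both protected and nuisance: {sorted(overlap)}")


def _encode(metadata: pd.DataFrame, names: list, categorical: set) -> tuple[np.ndarray, list]:
    blocks, labels = [], []
    for name in names:
        col = metadata[name]
        if name in categorical or col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            for lvl in dummies.columns:
                blocks.append(dummies[lvl].to_numpy(dtype=float))
                labels.append(f"{name}[{lvl}]")
        else:
            blocks.append(col.to_numpy(dtype=float))
            labels.append(name)
    if not blocks:
        return np.empty((len(metadata), 0)), []
    return np.column_stack(blocks), labels


def remove_covariate_effects(matrix: pd.DataFrame, metadata: pd.DataFrame,
                             design: CovariateDesign,
                             sequential: bool = False) -> pd.DataFrame:
    """Subtract fitted nuisance-covariate contributions from every feature.

    The default fits one joint least-squares model per feature (intercept +
    protected + nuisance) and subtracts only the nuisance part, which is
    order-invariant. ``sequential=True`` instead removes the nuisance terms
    one at a time in the listed order, refitting against the protected
    design at each step.

    Raises when the design is rank-deficient or a nuisance term is aliased
    with the protected block (its column lies in the protected span).
    """
    meta = metadata.loc[list(matrix.columns)]
    cat = set(design.categorical)
    x_prot, prot_labels = _encode(meta, design.protected, cat)
    if sequential:
        out = matrix
        for name in design.nuisance:
            out = remove_covariate_effects(
                out, metadata,
                CovariateDesign(protected=design.protected, nuisance=[name],
                                categorical=design.categorical))
        return out
    x_nuis, nuis_labels = _encode(meta, design.nuisance, cat)
    n = len(meta)
    intercept = np.ones((n, 1))
    base = np.hstack([intercept, x_prot])
    full = np.hstack([base, x_nuis])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        # locate an aliased nuisance column for the error message
        q, _ = np.linalg.qr(base)
        for j, lab in enumerate(nuis_labels):
            col = x_nuis[:, j]
            resid = col - q @ (q.T @ col)
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
                raise ValueError(
                    f"nuisance term {lab!r} is confounded with the protected "
                    f"design ({['intercept'] + prot_labels})")
        raise ValueError("design matrix is rank-deficient")
    y = matrix.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    n_base = base.shape[1]
    fitted_nuis = x_nuis @ beta[n_base:]
    out = y - fitted_nuis
    return pd.DataFrame(out.T, index=matrix.index, columns=matrix.columns)
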