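"""Sample quality control and outlier detection.

Two complementary detectors are provided. Control-chart QC flags samples
whose distributional summaries (median log abundance, inter-quartile
range) sit more than a set number of standard deviations from the cohort
mean. The expression-outlier detector applies a dual criterion: a sample
is an outlier only if it falls outside a probability ellipse in PCA space
*and* its standardized connectivity — derived from the Euclidean distance
matrix over all samples — is below a cutoff (default -2.5). The
conjunction makes false flags on homogeneous data rare.

Also here: the prevalence filter for count matrices (keep a feature when
enough samples in some compared group express it) and equal-width
factorization of continuous covariates into intervals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    medians: pd.Series
    iqrs: pd.Series
    flags: dict = field(default_factory=dict)  # sample -> {"median_outlier", "iqr_outlier"}
    sd_multiplier: float = 3.0

    @property
    def strong_outliers(self) -> list:
        """Samples flagged on either metric."""
        return [s for s, f in self.flags.items() if f]


@dataclass
class OutlierCall:
    sample_id: str
    pca_outside_ellipse: bool
    connectivity_z: float
    is_outlier: bool


def control_chart_qc(matrix: pd.DataFrame, sd_multiplier: float = 3.0) -> QCReport:
    """Median / IQR control-chart QC over samples (columns).

    A sample is flagged on a metric when its value is more than
    ``sd_multiplier`` standard deviations from the across-sample mean of
    that metric; a "strong outlier" is flagged on either metric. When a
    metric has zero spread no sample is flagged on it.
    """
    if matrix.shape[1] < 3:
        raise ValueError("control-chart QC requires at least 3 samples")
    medians = matrix.median(axis=0, skipna=True)
    q3 = matrix.quantile(0.75, axis=0)
    q1 = matrix.quantile(0.25, axis=0)
    iqrs = q3 - q1
    flags = {s: set() for s in matrix.columns}
    for name, metric in (("median_outlier", medians), ("iqr_outlier", iqrs)):
        sd = float(metric.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            logger.info("control chart: zero spread on %s, no flags", name)
            continue
        center = float(metric.mean())
        for s, v in metric.items():
            if abs(v - center) > sd_multiplier * sd:
                flags[s].add(name)
    return QCReport(medians=medians, iqrs=iqrs, flags=flags,
                    sd_multiplier=sd_multiplier)


def detect_expression_outliers(matrix: pd.DataFrame, ellipse_prob: float = 0.68,
                               z_cutoff: float = -2.5) -> list[OutlierCall]:
    """Dual-criterion expression sample-outlier detection.

    Samples (columns) are projected onto the first two principal
    components of the feature-centered matrix; a bivariate-normal
    probability ellipse at ``ellipse_prob`` (chi-square quantile, 2 df) is
    fitted to the scores. Per-sample connectivity is the mean Euclidean
    distance to all other samples, standardized with a sign flip so that
    distant samples get negative Z. A sample is called an outlier iff it
    is outside the ellipse AND its connectivity Z is below ``z_cutoff``.
    """
    n = matrix.shape[1]
    if n < 4:
        raise ValueError("outlier detection requires at least 4 samples")
    if matrix.shape[0] < 2:
        raise ValueError("outlier detection requires at least 2 features")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    scores = PCA(n_components=2).fit_transform(x)
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    cov_inv = np.linalg.pinv(cov)
    delta = scores - center
    mahal2 = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
    outside = mahal2 > chi2.ppf(ellipse_prob, df=2)

    dist = squareform(pdist(x, metric="euclidean"))
    k = dist.sum(axis=1) / (n - 1)  # mean distance to the other samples
    sd = k.std(ddof=1)
    z = np.zeros(n) if sd == 0 else -(k - k.mean()) / sd

    calls = []
    for i, s in enumerate(matrix.columns):
        flag = bool(outside[i]) and (z[i] < z_cutoff)
        calls.append(OutlierCall(sample_id=s, pca_outside_ellipse=bool(outside[i]),
                                 connectivity_z=float(z[i]), is_outlier=flag))
    return calls


def prevalence_filter(counts: pd.DataFrame, groups: dict,
                      min_samples: int = 9,
                      comparisons: list[tuple[str, str]] | None = None
                      ) -> pd.DataFrame:
    """Keep features with counts in at least ``min_samples`` samples of some
    group taking part in at least one comparison.

    ``groups`` maps sample id -> group label and must cover every column.
    ``comparisons`` is a list of group pairs (default: all pairs of groups
    present); a comparison naming an unknown group raises.
    """
    missing = [s for s in counts.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    present_groups = sorted(set(groups[s] for s in counts.columns))
    if comparisons is None:
        comparisons = list(itertools.combinations(present_groups, 2))
    compared = set(itertools.chain.from_iterable(comparisons))
    unknown = compared - set(present_groups)
    if unknown:
        raise ValueError(f"comparisons name unknown groups: {sorted(unknown)}")
    keep = np.zeros(counts.shape[0], dtype=bool)
    for g in compared:
        cols = [s for s in counts.columns if groups[s] == g]
        nonzero = (counts[cols] > 0).sum(axis=1)
        keep |= (nonzero >= min_samples).to_numpy()
    return counts.loc[keep]


def factorize_covariate(values, n_bins: int = 5) -> np.ndarray:
    """Cut a continuous covariate into ``n_bins`` equal-width intervals.

    The covariate range is widened by 0.1% at both edges so the extremes
    fall inside the outer bins (the convention of R's ``cut``); labels are
    the integers 1..n_bins. A constant vector admits no partition and
    raises.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0:
        raise ValueError("no finite values to factorize")
    lo, hi = finite.min(), finite.max()
    if hi <= lo:
        raise ValueError("constant covariate cannot be factorized")
    pad = (hi - lo) / 1000.0
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    labels = np.digitize(v, edges[1:-1], right=True) + 1
    labels = labels.astype(float)
    labels[~np.isfinite(v)] = np.nan
    return labels
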