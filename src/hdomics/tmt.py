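"""TMT 10-plex PSM-level processing chain.

Implements the quantitative preprocessing applied to isobarically labeled
proteomics data: a reporter-signal filter, isotope-impurity correction by
solving the channel cross-contamination linear system, sum-scaling
normalization that equalizes per-channel totals within a run, log2 ratios
against a designated reference channel, and the collapse of PSM-level rows
to unique peptides and aggregated proteins.

The in-memory container is :class:`PSMTable`: a pandas DataFrame of PSM
annotations plus ten reporter-intensity columns, together with plex/run
identifiers and the reference-channel label. Missing reporter signals are
``NaN``; present signals are non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reporter-ion channel labels of a TMT 10-plex, in mass order.
CHANNELS = ("126", "127N", "127C", "128N", "128C",
            "129N", "129C", "130N", "130C", "131")
N_CHANNELS = len(CHANNELS)
INTENSITY_COLUMNS = tuple(f"channel_{c}" for c in CHANNELS)
DEFAULT_REFERENCE_CHANNEL = "131"

ANNOTATION_COLUMNS = ("psm_id", "peptide", "protein_id", "shared_status")


@dataclass
class PSMTable:
    """One TMT 10-plex run's worth of peptide-spectrum matches.

    Parameters
    ----------
    data
        DataFrame with columns ``psm_id``, ``peptide``, ``protein_id``
        (may be NaN for unassigned spectra), ``shared_status`` (True when
        the peptide maps to more than one gene) and the ten
        ``channel_<label>`` reporter-intensity columns. Missing values are
        NaN; present intensities must be >= 0.
    plex_id, run_id
        Identifiers of the 10-plex set and the MS run.
    reference_channel
        Label of the pooled-reference channel (default ``"131"``).
    """

    data: pd.DataFrame
    plex_id: str = "plex1"
    run_id: str = "run1"
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS + INTENSITY_COLUMNS
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"PSMTable missing columns: {missing}")
        if self.reference_channel not in CHANNELS:
            raise ValueError(
                f"reference_channel {self.reference_channel!r} is not one of {CHANNELS}")
        inten = self.intensities
        if np.nanmin(inten, initial=0.0) < 0:
            raise ValueError("reporter intensities must be >= 0 where present")

    @property
    def intensities(self) -> np.ndarray:
        """(n_psms, 10) float array of reporter intensities (NaN = missing)."""
        return self.data.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)

    @property
    def reference_index(self) -> int:
        return CHANNELS.index(self.reference_channel)

    def with_intensities(self, values: np.ndarray) -> "PSMTable":
        """Copy of the table with the intensity block replaced."""
        data = self.data.copy()
        data.loc[:, list(INTENSITY_COLUMNS)] = values
        return replace(self, data=data)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ImpurityMatrix:
    """Channel cross-contamination coefficients for one TMT lot.

    ``matrix[i, j]`` is the fraction of channel *j*'s true signal observed
    in channel *i*, so ``observed = matrix @ true``. Columns sum to
    approximately one and each diagonal entry is the maximum of its column
    (diagonal dominance), as in manufacturer-supplied correction factors.
    """

    matrix: np.ndarray
    batch_id: str = "lot1"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError(f"impurity matrix must be {N_CHANNELS}x{N_CHANNELS}")
        if (m < 0).any():
            raise ValueError("impurity coefficients must be non-negative")
        if not np.all(np.diag(m) >= m.max(axis=0) - 1e-12):
            raise ValueError("impurity matrix must be diagonally dominant "
                             "(each diagonal entry the maximum of its column)")
        self.matrix = m


def identity_impurities(batch_id: str = "identity") -> ImpurityMatrix:
    return ImpurityMatrix(np.eye(N_CHANNELS), batch_id=batch_id)


def make_impurity_matrix(spill: float = 0.05, batch_id: str = "lot1") -> ImpurityMatrix:
    """Simple tridiagonal impurity model: fraction ``spill`` of each channel's
    signal leaks into each mass-adjacent channel."""
    m = np.eye(N_CHANNELS) * (1.0 - 2.0 * spill)
    m[0, 0] = m[-1, -1] = 1.0 - spill
    for j in range(N_CHANNELS):
        if j > 0:
            m[j - 1, j] = spill
        if j < N_CHANNELS - 1:
            m[j + 1, j] = spill
    return ImpurityMatrix(m, batch_id=batch_id)


def filter_psms(table: PSMTable) -> PSMTable:
    """Retain PSMs with a signal in at least one of the 10 reporter channels.

    A "signal" is a present (non-NaN), strictly positive intensity.
    """
    inten = table.intensities
    keep = np.nansum(inten > 0, axis=1) >= 1
    return replace(table, data=table.data.loc[keep].reset_index(drop=True))


def correct_isotope_impurities(table: PSMTable, impurities: ImpurityMatrix,
                               cond_bound: float = 1e8) -> PSMTable:
    """Invert the lot-specific isotope-impurity mixing per PSM.

    For each PSM the linear system ``mixing @ corrected = observed`` is
    solved over the *present* channels only (the corresponding submatrix);
    missing channels stay missing. Small negative solutions, which arise
    when observed intensities are inconsistent with non-negative true
    signals, are clamped to zero.
    """
    m = impurities.matrix
    if np.linalg.cond(m) > cond_bound:
        raise ValueError(
            f"impurity matrix for batch {impurities.batch_id!r} is "
            f"ill-conditioned (cond > {cond_bound:g})")
    inten = table.intensities
    out = np.full_like(inten, np.nan)
    present = ~np.isnan(inten)
    # Solve per missingness pattern so each submatrix factorization is reused.
    patterns = {}
    for i, row in enumerate(present):
        patterns.setdefault(row.tobytes(), []).append(i)
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = m[np.ix_(idx, idx)]
        obs = inten[np.ix_(rows, idx)]
        sol = np.linalg.solve(sub, obs.T).T
        out[np.ix_(rows, idx)] = np.clip(sol, 0.0, None)
    return table.with_intensities(out)


def sum_scale_normalize(table: PSMTable, literal: bool = False) -> PSMTable:
    """Sum-scaling normalization at the PSM level, per run.

    Per-channel intensity sums ``S_c`` are computed over present values and
    the median ``M`` of the ten sums is taken. Each channel is multiplied by
    ``M / S_c``, so every channel's post-normalization sum equals ``M``.

    ``literal=True`` instead multiplies by ``S_c / M`` (the amplifying
    reading of "divide the channel sum by the median"); it is provided for
    fidelity but defeats the purpose of sum-scaling.

    Channels whose sum is zero have no defined factor; they are left
    unscaled with a warning.
    """
    inten = table.intensities
    sums = np.nansum(inten, axis=0)
    if not (sums > 0).any():
        raise ValueError("sum-scaling requires at least one channel with a positive sum")
    med = float(np.median(sums))
    factors = np.ones(N_CHANNELS)
    ok = sums > 0
    if not ok.all():
        bad = [CHANNELS[i] for i in np.flatnonzero(~ok)]
        logger.warning("run %s: channels with zero sum left unscaled: %s",
                       table.run_id, bad)
    factors[ok] = (sums[ok] / med) if literal else (med / sums[ok])
    return table.with_intensities(inten * factors)


def reference_log_ratios(table: PSMTable) -> pd.DataFrame:
    """log2 ratios of each sample channel against the reference channel.

    Returns a PSM x 9 DataFrame (index ``psm_id``, columns
    ``"<plex_id>_<channel>"``). PSMs whose reference intensity is missing
    or zero yield an all-missing row (counted in the log) rather than
    infinite ratios.
    """
    inten = table.intensities
    ref_idx = table.reference_index
    ref = inten[:, ref_idx]
    sample_idx = [i for i in range(N_CHANNELS) if i != ref_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(inten[:, sample_idx] / ref[:, None])
    bad_ref = ~(ref > 0) | np.isnan(ref)
    ratios[bad_ref, :] = np.nan
    ratios[~np.isfinite(ratios)] = np.nan
    n_bad = int(bad_ref.sum())
    if n_bad:
        logger.info("run %s: %d PSMs emitted all-missing (reference channel "
                    "missing or zero)", table.run_id, n_bad)
    cols = [f"{table.plex_id}_{CHANNELS[i]}" for i in sample_idx]
    return pd.DataFrame(ratios, index=pd.Index(table.data["psm_id"], name="psm_id"),
                        columns=cols)


def _max_mean_representative(matrix: pd.DataFrame, keys: pd.Series) -> pd.DataFrame:
    """One row per unique key: the row with the largest mean over present
    values; ties broken by stable input order."""
    means = matrix.mean(axis=1, skipna=True).to_numpy()
    order = np.arange(len(matrix))
    df = pd.DataFrame({"key": np.asarray(keys), "mean": means, "order": order})
    # stable sort: by key, then descending mean; original order breaks ties
    df = df.sort_values(["key", "mean"], ascending=[True, False], kind="stable")
    chosen = df.drop_duplicates("key", keep="first")["order"].to_numpy()
    chosen.sort()
    out = matrix.iloc[chosen].copy()
    out.index = pd.Index(np.asarray(keys)[chosen], name=keys.name)
    return out


def collapse_to_peptides(matrix: pd.DataFrame,
                         annotations: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a PSM-level ratio matrix to unique peptides.

    Rows flagged as shared (non-unique peptide-to-gene mapping) are removed
    first, then rows with an unassigned protein ID; the surviving PSMs are
    collapsed to one representative per peptide, chosen as the PSM with the
    maximum row mean (ties go to the first in input order).

    Parameters
    ----------
    matrix
        PSM x sample DataFrame indexed by ``psm_id``.
    annotations
        DataFrame with columns ``psm_id``, ``peptide``, ``protein_id``,
        ``shared_status`` covering every row of ``matrix``.

    Returns
    -------
    (peptide_matrix, peptide_to_protein)
    """
    ann = annotations.set_index("psm_id").loc[matrix.index]
    keep = ~ann["shared_status"].astype(bool).to_numpy()
    ann = ann.loc[keep]
    sub = matrix.loc[keep]
    has_protein = ann["protein_id"].notna() & (ann["protein_id"].astype(str) != "")
    ann = ann.loc[has_protein.to_numpy()]
    sub = sub.loc[has_protein.to_numpy()]
    if sub.empty:
        empty = sub.copy()
        empty.index = pd.Index([], name="peptide")
        return empty, pd.Series(dtype=object, name="protein_id")
    pep_matrix = _max_mean_representative(sub, ann["peptide"].rename("peptide"))
    pep2prot = (ann.drop_duplicates("peptide").set_index("peptide")["protein_id"]
                .loc[pep_matrix.index])
    return pep_matrix, pep2prot


def aggregate_to_proteins(peptides: pd.DataFrame,
                          peptide_to_protein: pd.Series) -> pd.DataFrame:
    """Aggregate a peptide matrix to proteins via the max-mean representative
    rule (the same family as the peptide collapse)."""
    mapped = peptide_to_protein.reindex(peptides.index)
    if mapped.isna().any():
        missing = list(peptides.index[mapped.isna()])[:5]
        raise ValueError(f"peptides with no protein mapping: {missing}")
    out = _max_mean_representative(peptides, mapped.rename("protein_id"))
    return out


def process_plex(table: PSMTable, impurities: ImpurityMatrix | None = None,
                 literal_sum_scaling: bool = False) -> pd.DataFrame:
    """Run filter -> isotope correction -> sum-scaling -> reference log ratios
    on one plex, in the stated order."""
    t = filter_psms(table)
    t = correct_isotope_impurities(t, impurities or identity_impurities())
    t = sum_scale_normalize(t, literal=literal_sum_scaling)
    return reference_log_ratios(t)


def process_to_peptides(tables: list[PSMTable],
                        impurities: ImpurityMatrix | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Full PSM chain across plexes, joined at the peptide level.

    Each plex is processed independently (filter, correction, sum-scaling,
    reference ratios, peptide collapse); peptide matrices are then
    outer-joined on peptide so each plex contributes its 9 sample columns.
    """
    pep_mats, maps = [], []
    for t in tables:
        ratios = process_plex(t, impurities)
        ann = t.data.loc[:, list(ANNOTATION_COLUMNS)]
        ann = ann[ann["psm_id"].isin(ratios.index)]
        pep, p2p = collapse_to_peptides(ratios, ann)
        pep_mats.append(pep)
        maps.append(p2p)
    combined = pd.concat(pep_mats, axis=1, join="outer")
    pep2prot = pd.concat(maps).groupby(level=0).first().loc[combined.index]
    return combined, pep2prot


def read_psm_table(path) -> PSMTable:
    """Read a PSM table from TSV (missing intensities = empty fields)."""
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "peptide": str,
                                            "protein_id": str})
    plex = str(df["plex_id"].iloc[0]) if "plex_id" in df and len(df) else "plex1"
    run = str(df["run_id"].iloc[0]) if "run_id" in df and len(df) else "run1"
    ref = str(df["reference_channel"].iloc[0]) if "reference_channel" in df and len(df) \
        else DEFAULT_REFERENCE_CHANNEL
    df["shared_status"] = df.get("shared_status", False)
    df["shared_status"] = df["shared_status"].fillna(False).astype(bool)
    return PSMTable(df, plex_id=plex, run_id=run, reference_channel=ref)


def write_psm_table(table: PSMTable, path) -> None:
    df = table.data.copy()
    df["plex_id"] = table.plex_id
    df["run_id"] = table.run_id
    df["reference_channel"] = table.reference_channel
    df.to_csv(path, sep="\t", index=False)
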