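"""Synthetic-data generators for every stage of the pipeline.

Raw study data of this kind (TMT reporter tables, expression matrices,
phased HTT-region genotypes, cohort metadata) are access-controlled in
practice, so these generators emulate their statistical structure: 10-channel
TMT plexes with channel loadings, batch/plex shifts, isotopic impurity
mixing, missing-at-random reporter signals and planted group effects;
expression matrices with planted outlier samples; phased haplotype panels
drawn from specified haplotype frequencies; and a cohort with CAG 40-55
carriers aged 30-50.

Every generator is a pure function of its arguments including ``seed``, and
returns a :class:`SimTruth` describing exactly what was planted so that
downstream detectors and tests can be scored against ground truth.

Planted differential-abundance effects are balanced: planted features come
in up/down pairs whose base abundances are chosen so the total signal per
channel is unchanged. This mirrors the assumption behind global
normalization (equal total loading per channel), so sum-scaling removes
channel loadings without distorting the planted log-ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import compute_dbs
from .tmt import (CHANNELS, INTENSITY_COLUMNS, N_CHANNELS, ImpurityMatrix,
                  PSMTable, identity_impurities)

#: The 21 HTT-region haplotype-defining variants: 20 SNPs plus one
#: insertion-deletion polymorphism (rs149109767). Placeholder SNP ids are
#: used for the synthetic panels; real panels supply their own locus list.
DEFAULT_HTT_LOCI = tuple(f"snp{i:02d}" for i in range(1, 21)) + ("rs149109767",)

#: Channel-to-group design within one plex: the nine sample channels
#: alternate control/case, channel 131 is the pooled reference.
SAMPLE_CHANNELS = tuple(c for c in CHANNELS if c != "131")
CHANNEL_GROUPS = tuple("control" if i % 2 == 0 else "case"
                       for i in range(len(SAMPLE_CHANNELS)))


@dataclass
class SimTruth:
    """Ground truth of a synthetic dataset.

    Fields are only populated by the generator that uses them; e.g. a
    phased-panel truth carries ``haplotype_frequencies`` and leaves the
    proteomics fields empty.
    """

    planted_effect_features: set = field(default_factory=set)
    effect_size: float = 0.0
    effect_directions: dict = field(default_factory=dict)  # feature -> +1/-1
    batch_shifts: dict = field(default_factory=dict)       # plex_id -> log2 shift
    outlier_samples: set = field(default_factory=set)
    haplotype_frequencies: dict = field(default_factory=dict)  # allele tuple -> freq
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.haplotype_frequencies:
            total = sum(self.haplotype_frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"haplotype frequencies sum to {total}, not 1")


def gen_cohort_metadata(n_control: int, n_pre: int, n_early: int,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort metadata table.

    Carriers (pre-HD and early-HD) draw a long CAG allele uniformly in
    40..55 and all participants draw ages uniformly in [30, 50], matching
    the study's inclusion window. TFC and diagnostic-confidence (DCL)
    scores are drawn consistently with the staging rules: pre-HD has
    DCL <= 2, early-HD has DCL > 2 with TFC in 7..13.
    """
    for name, n in (("n_control", n_control), ("n_pre", n_pre), ("n_early", n_early)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    groups = (["control"] * n_control + ["pre-HD"] * n_pre + ["early-HD"] * n_early)
    for i, group in enumerate(groups):
        age = float(rng.uniform(30.0, 50.0))
        cag_short = int(rng.integers(15, 26))
        if group == "control":
            cag_long, dbs = np.nan, np.nan
            tfc, dcl = 13, 0
        else:
            cag_long = int(rng.integers(40, 56))
            dbs = compute_dbs(cag_long, age)
            if group == "pre-HD":
                tfc = int(rng.integers(11, 14))
                dcl = int(rng.integers(0, 3))
            else:
                tfc = int(rng.integers(7, 14))
                dcl = int(rng.integers(3, 5))
        rows.append({
            "subject_id": f"S{i + 1:03d}",
            "group": group,
            "site": int(1 + (i % 2)),
            "gender": "f" if rng.random() < 0.5 else "m",
            "age": round(age, 1),
            "bmi": round(float(np.clip(rng.normal(24.5, 2.5), 18.0, 30.0)), 1),
            "cag_short": cag_short,
            "cag_long": cag_long,
            "tfc": tfc,
            "dcl": dcl,
            "dbs": round(dbs, 1) if not np.isnan(dbs) else np.nan,
        })
    columns = ["subject_id", "group", "site", "gender", "age", "bmi",
               "cag_short", "cag_long", "tfc", "dcl", "dbs"]
    return pd.DataFrame(rows, columns=columns)


def psm_sample_groups(tables: list[PSMTable]) -> pd.DataFrame:
    """Sample sheet for a generated PSM dataset: one row per sample channel
    with its plex, channel label and planted group."""
    rows = []
    for t in tables:
        for ch, grp in zip(SAMPLE_CHANNELS, CHANNEL_GROUPS):
            rows.append({"sample_id": f"{t.plex_id}_{ch}", "plex_id": t.plex_id,
                         "channel": ch, "group": grp})
    return pd.DataFrame(rows)


def gen_psm_dataset(n_plexes: int, n_psms: int, truth: SimTruth | None = None,
                    missing_rate: float = 0.1, noise_sd: float = 0.3,
                    seed: int = 0, *,
                    impurities: ImpurityMatrix | None = None,
                    psms_per_peptide: int = 2,
                    peptides_per_protein: int = 2,
                    planted_fraction: float = 0.1,
                    effect_size: float = 1.0,
                    base_mean: float = 20.0, base_sd: float = 2.0,
                    batch_shift_sd: float = 0.25,
                    channel_loading_sd: float = 0.1
                    ) -> tuple[list[PSMTable], SimTruth]:
    """Simulate reporter-intensity tables for ``n_plexes`` TMT 10-plexes.

    Each plex carries the same ``n_psms`` PSMs (grouped into peptides and
    proteins), nine sample channels in an alternating control/case design
    and the pooled reference in channel 131. log2 intensities are
    ``base + group effect + plex shift + channel loading + noise``; linear
    intensities are then mixed by the impurity matrix and thinned missing
    at random at ``missing_rate``.

    Planted effects of ``effect_size`` log2 units are applied to a fraction
    of peptides in balanced up/down pairs (see module docstring), recorded
    in the returned :class:`SimTruth` with their signs.
    """
    if n_plexes < 1:
        raise ValueError("n_plexes must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    impurities = impurities or identity_impurities()

    n_peptides = max(1, n_psms // psms_per_peptide)
    peptide_of_psm = np.arange(n_psms) % n_peptides
    peptides = [f"PEP{i:05d}" for i in range(n_peptides)]
    proteins = [f"PROT{i // peptides_per_protein:05d}" for i in range(n_peptides)]

    if truth is None:
        n_pairs = int(round(planted_fraction * n_peptides / 2))
        chosen = rng.choice(n_peptides, size=2 * n_pairs, replace=False)
        directions = {}
        for j in range(n_pairs):
            directions[peptides[chosen[2 * j]]] = +1
            directions[peptides[chosen[2 * j + 1]]] = -1
        shifts = {f"plex{p + 1}": float(rng.normal(0.0, batch_shift_sd))
                  for p in range(n_plexes)}
        truth = SimTruth(planted_effect_features=set(directions),
                         effect_size=float(effect_size),
                         effect_directions=directions,
                         batch_shifts=shifts, seed=seed)
    e = truth.effect_size
    pep_index = {p: i for i, p in enumerate(peptides)}

    # Base abundance per peptide. Down-regulated planted peptides are paired
    # with up-regulated ones and given base b_up + e (log2), i.e. b_up * 2^e
    # linear, so each pair's total signal per channel is conserved and the
    # equal-loading assumption behind sum-scaling holds exactly.
    base_pep = rng.normal(base_mean, base_sd, size=n_peptides)
    ups = [p for p, s in truth.effect_directions.items() if s > 0]
    downs = [p for p, s in truth.effect_directions.items() if s < 0]
    for u, d in zip(ups, downs):
        base_pep[pep_index[d]] = base_pep[pep_index[u]] + e
    base = base_pep[peptide_of_psm]

    effect_col = np.zeros(n_psms)
    for pep, sign in truth.effect_directions.items():
        effect_col[peptide_of_psm == pep_index[pep]] = sign * e

    is_case = np.array([g == "case" for g in CHANNEL_GROUPS])

    tables: list[PSMTable] = []
    for p in range(n_plexes):
        plex_id = f"plex{p + 1}"
        shift = truth.batch_shifts.get(plex_id, 0.0)
        loadings = rng.normal(0.0, channel_loading_sd, size=N_CHANNELS)
        log2_int = np.tile(base[:, None], (1, N_CHANNELS)) + shift + loadings[None, :]
        for ci, ch in enumerate(SAMPLE_CHANNELS):
            if is_case[ci]:
                col = CHANNELS.index(ch)
                log2_int[:, col] += effect_col
        if noise_sd > 0:
            log2_int += rng.normal(0.0, noise_sd, size=log2_int.shape)
        inten = np.exp2(log2_int)
        inten = inten @ impurities.matrix.T  # observed = M @ true, per PSM row
        if missing_rate > 0:
            mask = rng.random(inten.shape) < missing_rate
            inten[mask] = np.nan
        df = pd.DataFrame({
            "psm_id": [f"{plex_id}_PSM{i:06d}" for i in range(n_psms)],
            "peptide": [peptides[k] for k in peptide_of_psm],
            "protein_id": [proteins[k] for k in peptide_of_psm],
            "shared_status": False,
        })
        for col, name in enumerate(INTENSITY_COLUMNS):
            df[name] = inten[:, col]
        tables.append(PSMTable(df, plex_id=plex_id, run_id=f"run{p + 1}"))
    return tables, truth


def gen_expression_matrix(n_features: int, n_samples: int, outliers: int = 0,
                          shift_sd: float = 10.0, seed: int = 0
                          ) -> tuple[pd.DataFrame, SimTruth]:
    """Feature x sample matrix with optional planted outlier samples.

    Regular samples share a common per-feature Gaussian distribution;
    each outlier sample is shifted by ``shift_sd`` feature-SDs (random
    sign) on a random half of the features.
    """
    if n_features <= 0:
        raise ValueError("n_features must be > 0")
    if outliers > n_samples:
        raise ValueError("outliers cannot exceed n_samples")
    rng = np.random.default_rng(seed)
    feat_mean = rng.normal(10.0, 2.0, size=n_features)
    feat_sd = rng.uniform(0.5, 1.5, size=n_features)
    x = feat_mean[:, None] + feat_sd[:, None] * rng.normal(size=(n_features, n_samples))
    samples = [f"sample{j + 1:03d}" for j in range(n_samples)]
    outlier_idx = rng.choice(n_samples, size=outliers, replace=False) if outliers else []
    outlier_ids = set()
    for j in outlier_idx:
        affected = rng.choice(n_features, size=n_features // 2, replace=False)
        signs = rng.choice([-1.0, 1.0], size=affected.size)
        x[affected, j] += signs * shift_sd * feat_sd[affected]
        outlier_ids.add(samples[j])
    mat = pd.DataFrame(x, index=[f"feat{i + 1:05d}" for i in range(n_features)],
                       columns=samples)
    return mat, SimTruth(outlier_samples=outlier_ids, seed=seed)


def gen_phased_panel(n_chromosomes: int, truth: SimTruth, n_loci: int = 21,
                     seed: int = 0, loci: tuple[str, ...] | None = None):
    """Draw phased chromosomes i.i.d. from ``truth.haplotype_frequencies``.

    Consecutive chromosome pairs form one diploid sample (phase 1 / 2).
    Returns a :class:`~hdomics.haplotype.HaplotypePanel`.
    """
    from .haplotype import HaplotypePanel

    freqs = truth.haplotype_frequencies
    if not freqs:
        raise ValueError("truth.haplotype_frequencies is empty")
    vectors = list(freqs)
    for v in vectors:
        if len(v) != n_loci:
            raise ValueError(f"haplotype vector of length {len(v)}, expected {n_loci}")
    probs = np.array([freqs[v] for v in vectors], dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(vectors), size=n_chromosomes, p=probs)
    alleles = np.array([vectors[d] for d in draws], dtype=np.int8)
    sample_ids = [f"IND{(i // 2) + 1:05d}" for i in range(n_chromosomes)]
    phase = np.array([1 + (i % 2) for i in range(n_chromosomes)], dtype=np.int8)
    if loci is None:
        loci = (DEFAULT_HTT_LOCI if n_loci == len(DEFAULT_HTT_LOCI)
                else tuple(f"locus{i + 1:02d}" for i in range(n_loci)))
    return HaplotypePanel(loci=tuple(loci), chromosomes=alleles,
                          sample_ids=sample_ids, phase_index=phase)
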