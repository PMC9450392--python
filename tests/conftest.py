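import numpy as np
import pandas as pd
import pytest

from hdomics.tmt import INTENSITY_COLUMNS, PSMTable


def make_psm_table(intensities, peptides=None, proteins=None, shared=None,
                   reference_channel="131", plex_id="plex1") -> PSMTable:
    """Build a PSMTable from an (n, 10) array (NaN = missing)."""
    inten = np.asarray(intensities, dtype=float)
    n = inten.shape[0]
    df = pd.DataFrame({
        "psm_id": [f"PSM{i}" for i in range(n)],
        "peptide": peptides if peptides is not None else [f"PEP{i}" for i in range(n)],
        "protein_id": proteins if proteins is not None else [f"PROT{i}" for i in range(n)],
        "shared_status": shared if shared is not None else [False] * n,
    })
    for j, col in enumerate(INTENSITY_COLUMNS):
        df[col] = inten[:, j]
    return PSMTable(df, plex_id=plex_id, reference_channel=reference_channel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
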