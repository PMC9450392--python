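"""PSM-level TMT chain: filter, impurity correction, sum-scaling, ratios,
peptide/protein collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_psm_table
from hdomics import tmt


class TestFilter:
    def test_signal_rule(self):
        inten = np.full((3, 10), np.nan)
        inten[1, 4] = 100.0          # one present channel -> retained
        inten[2, :] = 0.0            # present but zero everywhere -> removed
        out = tmt.filter_psms(make_psm_table(inten))
        assert list(out.data["psm_id"]) == ["PSM1"]

    def test_empty_in_empty_out(self):
        out = tmt.filter_psms(make_psm_table(np.empty((0, 10))))
        assert len(out) == 0


class TestImpurityCorrection:
    @staticmethod
    def two_channel_matrix():
        """0.95/0.05 cross-talk between channels 126 and 127N, identity
        elsewhere."""
        m = np.eye(10)
        m[0, 0] = m[1, 1] = 0.95
        m[0, 1] = m[1, 0] = 0.05
        return tmt.ImpurityMatrix(m, batch_id="lotX")

    def test_identity_is_noop(self):
        inten = np.abs(np.random.default_rng(0).normal(100, 10, (5, 10)))
        table = make_psm_table(inten)
        out = tmt.correct_isotope_impurities(table, tmt.identity_impurities())
        np.testing.assert_allclose(out.intensities, inten)

    def test_hand_solved_two_channel_system(self):
        # [[0.95, 0.05], [0.05, 0.95]] @ [100, 0] = [95, 5]
        inten = np.full((1, 10), 50.0)
        inten[0, 0], inten[0, 1] = 95.0, 5.0
        out = tmt.correct_isotope_impurities(make_psm_table(inten),
                                             self.two_channel_matrix())
        assert out.intensities[0, 0] == pytest.approx(100.0)
        assert out.intensities[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_negative_solution_clamped(self):
        # observed [1, 0] -> solution [1.0555..., -0.0555...]; clamps to 0
        inten = np.full((1, 10), 50.0)
        inten[0, 0], inten[0, 1] = 1.0, 0.0
        out = tmt.correct_isotope_impurities(make_psm_table(inten),
                                             self.two_channel_matrix())
        assert out.intensities[0, 0] == pytest.approx(1.0 / 0.9 * 0.95)
        assert out.intensities[0, 1] == 0.0

    def test_missing_channels_solved_on_submatrix(self):
        inten = np.full((1, 10), np.nan)
        inten[0, 0], inten[0, 1] = 95.0, 5.0
        out = tmt.correct_isotope_impurities(make_psm_table(inten),
                                             self.two_channel_matrix())
        assert out.intensities[0, 0] == pytest.approx(100.0)
        assert np.isnan(out.intensities[0, 2:]).all()

    def test_mix_of_corrected_recovers_observed(self, rng):
        m = np.eye(10) * 0.9
        m += rng.uniform(0, 0.01, (10, 10)) * (1 - np.eye(10))
        imp = tmt.ImpurityMatrix(m)
        true = rng.uniform(10, 1000, (50, 10))
        observed = true @ m.T
        out = tmt.correct_isotope_impurities(make_psm_table(observed), imp)
        np.testing.assert_allclose(out.intensities @ m.T, observed, rtol=1e-8)

    def test_ill_conditioned_matrix_names_batch(self):
        m = np.eye(10)
        m[0, 0] = 1e-12
        with pytest.raises(ValueError, match="badlot"):
            tmt.correct_isotope_impurities(
                make_psm_table(np.ones((1, 10))),
                tmt.ImpurityMatrix(m, batch_id="badlot"), cond_bound=1e6)


class TestSumScaling:
    def test_post_sums_equal_median(self, rng):
        inten = rng.uniform(10, 1000, (40, 10))
        inten[rng.random((40, 10)) < 0.2] = np.nan
        table = make_psm_table(inten)
        pre_median = np.median(np.nansum(inten, axis=0))
        out = tmt.sum_scale_normalize(table)
        np.testing.assert_allclose(np.nansum(out.intensities, axis=0),
                                   pre_median, rtol=1e-9)

    def test_equal_sums_unchanged(self):
        inten = np.ones((5, 10)) * 7.0
        out = tmt.sum_scale_normalize(make_psm_table(inten))
        np.testing.assert_allclose(out.intensities, inten)

    def test_single_psm_equalized_to_median(self):
        vals = np.arange(1.0, 11.0)[None, :]  # sums are the values themselves
        out = tmt.sum_scale_normalize(make_psm_table(vals))
        np.testing.assert_allclose(out.intensities, np.median(vals))

    def test_literal_reading_amplifies(self):
        inten = np.ones((4, 10))
        inten[:, 0] = 10.0  # channel 126 has 10x the sum
        out = tmt.sum_scale_normalize(make_psm_table(inten), literal=True)
        assert out.intensities[0, 0] > inten[0, 0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tmt.sum_scale_normalize(make_psm_table(np.zeros((3, 10))))


class TestReferenceRatios:
    def test_basic_ratios(self):
        inten = np.full((2, 10), 100.0)
        inten[1, 0] = 400.0  # 4x the reference
        ratios = tmt.reference_log_ratios(make_psm_table(inten))
        assert ratios.shape == (2, 9)
        assert ratios.iloc[0, 0] == pytest.approx(0.0)
        assert ratios.loc["PSM1", "plex1_126"] == pytest.approx(2.0)

    def test_missing_reference_gives_all_missing_row(self):
        inten = np.full((1, 10), 100.0)
        inten[0, 9] = np.nan  # channel 131 is the reference
        ratios = tmt.reference_log_ratios(make_psm_table(inten))
        assert ratios.isna().all(axis=None)

    def test_zero_reference_is_missing_not_infinite(self):
        inten = np.full((1, 10), 100.0)
        inten[0, 9] = 0.0
        ratios = tmt.reference_log_ratios(make_psm_table(inten))
        assert ratios.isna().all(axis=None)


class TestCollapse:
    @staticmethod
    def toy():
        mat = pd.DataFrame([[3.0, 3.0], [5.0, 5.0], [1.0, 1.0]],
                           index=pd.Index(["PSM0", "PSM1", "PSM2"], name="psm_id"),
                           columns=["s1", "s2"])
        ann = pd.DataFrame({
            "psm_id": ["PSM0", "PSM1", "PSM2"],
            "peptide": ["pepA", "pepA", "pepB"],
            "protein_id": ["P1", "P1", "P2"],
            "shared_status": [False, False, False],
        })
        return mat, ann

    def test_max_mean_representative_survives(self):
        mat, ann = self.toy()
        pep, p2p = tmt.collapse_to_peptides(mat, ann)
        assert list(pep.index) == ["pepA", "pepB"]
        assert pep.loc["pepA", "s1"] == 5.0  # mean-5 row beats mean-3 row
        assert p2p["pepA"] == "P1"

    def test_shared_and_unassigned_removed(self):
        mat, ann = self.toy()
        ann.loc[ann.peptide == "pepA", "shared_status"] = True
        ann.loc[ann.peptide == "pepB", "protein_id"] = np.nan
        pep, _ = tmt.collapse_to_peptides(mat, ann)
        assert pep.empty

    def test_one_psm_per_peptide_is_identity(self):
        mat, ann = self.toy()
        mat, ann = mat.iloc[1:], ann.iloc[1:]
        pep, _ = tmt.collapse_to_peptides(mat, ann)
        assert pep.shape == (2, 2)
        np.testing.assert_allclose(pep.to_numpy(), mat.to_numpy())

    def test_tie_goes_to_first_in_input_order(self):
        mat = pd.DataFrame([[2.0, 2.0], [2.0, 2.0]],
                           index=pd.Index(["PSM0", "PSM1"], name="psm_id"),
                           columns=["s1", "s2"])
        mat.iloc[1] = [3.0, 1.0]  # same mean, different values
        ann = pd.DataFrame({"psm_id": ["PSM0", "PSM1"], "peptide": ["p", "p"],
                            "protein_id": ["P", "P"],
                            "shared_status": [False, False]})
        pep, _ = tmt.collapse_to_peptides(mat, ann)
        assert pep.loc["p", "s1"] == 2.0


class TestProteinAggregation:
    def test_max_mean_rule_and_row_count(self):
        pep = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [9.0, 9.0]],
                           index=pd.Index(["a", "b", "c"], name="peptide"),
                           columns=["s1", "s2"])
        p2p = pd.Series({"a": "P1", "b": "P1", "c": "P2"})
        prot = tmt.aggregate_to_proteins(pep, p2p)
        assert prot.shape == (2, 2)
        assert prot.loc["P1", "s1"] == 2.0
        assert prot.loc["P2", "s1"] == 9.0

    def test_unmapped_peptide_rejected(self):
        pep = pd.DataFrame([[1.0]], index=pd.Index(["a"], name="peptide"),
                           columns=["s1"])
        with pytest.raises(ValueError):
            tmt.aggregate_to_proteins(pep, pd.Series(dtype=object))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_sum_scaling_conservation_property(seed):
    """Channel sums after sum-scaling always equal the pre-normalization
    median channel sum."""
    rng = np.random.default_rng(seed)
    inten = rng.uniform(1, 500, (rng.integers(2, 30), 10))
    inten[rng.random(inten.shape) < 0.3] = np.nan
    # guarantee the signal filter contract: every channel keeps some signal
    inten[0] = rng.uniform(1, 500, 10)
    table = make_psm_table(inten)
    med = np.median(np.nansum(inten, axis=0))
    out = tmt.sum_scale_normalize(table)
    np.testing.assert_allclose(np.nansum(out.intensities, axis=0), med, rtol=1e-9)


def test_psm_tsv_round_trip(tmp_path):
    from hdomics import synthetic
    tables, _ = synthetic.gen_psm_dataset(1, 30, missing_rate=0.2, seed=5)
    path = tmp_path / "psm.tsv"
    tmt.write_psm_table(tables[0], path)
    back = tmt.read_psm_table(path)
    np.testing.assert_allclose(back.intensities, tables[0].intensities, rtol=1e-12)
    assert back.plex_id == tables[0].plex_id
    assert back.reference_channel == tables[0].reference_channel
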