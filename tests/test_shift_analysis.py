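"""Composite CSPs, titration trajectories, CSI and zinc scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bboxnmr import shift_analysis as sa
from bboxnmr.io_formats import Peak, PeakList, ShiftRecord, ShiftTable
from bboxnmr.synthetic_data import BindingModel, bound_fraction, gen_titration


def _peak_list(entries):
    """entries: (residue, dH, dN[, site])"""
    peaks = []
    for entry in entries:
        res, dh, dn = entry[:3]
        site = entry[3] if len(entry) > 3 else "bb"
        peaks.append(Peak(res, "ALA", "N", "H", dn, dh, 1e6,
                          site_label=site))
    return PeakList(entries=peaks)


class TestCompositeCSP:
    def test_identical_lists_zero(self):
        apo = _peak_list([(1, 8.0, 120.0), (2, 8.5, 115.0)])
        result = sa.compute_csp(apo, apo)
        assert all(r.csp == 0.0 for r in result.records)

    def test_hand_value(self):
        # dH = 0.06 ppm, dN = 0.52 ppm -> sqrt(0.0036 + 0.08^2) = 0.10 ppm
        apo = _peak_list([(1, 8.00, 120.00)])
        bound = _peak_list([(1, 8.06, 120.52)])
        result = sa.compute_csp(apo, bound)
        assert result.records[0].csp == pytest.approx(0.10, abs=1e-12)

    def test_proton_only_term(self):
        apo = _peak_list([(1, 8.0, 120.0)])
        bound = _peak_list([(1, 8.1, 120.0)])
        assert sa.compute_csp(apo, bound).records[0].csp == pytest.approx(0.1)

    def test_unmatched_reported(self):
        apo = _peak_list([(1, 8.0, 120.0), (2, 8.5, 115.0)])
        bound = _peak_list([(1, 8.0, 120.0), (3, 7.9, 118.0)])
        result = sa.compute_csp(apo, bound)
        assert len(result.records) == 1
        assert {(r, w) for r, _, w in result.unmatched} \
            == {(2, "apo-only"), (3, "bound-only")}

    def test_no_match_warns(self):
        result = sa.compute_csp(_peak_list([(1, 8.0, 120.0)]),
                                _peak_list([(2, 8.0, 120.0)]))
        assert not result.records and result.warnings

    def test_sidechain_tracked_separately(self):
        apo = _peak_list([(112, 8.0, 120.0), (112, 10.1, 129.3, "sc")])
        bound = _peak_list([(112, 8.0, 120.0), (112, 10.2, 129.9, "sc")])
        result = sa.compute_csp(apo, bound)
        by_site = {(r.residue_index, r.site_label): r.csp for r in result.records}
        assert by_site[(112, "bb")] == 0.0
        assert by_site[(112, "sc")] > 0.1

    @given(st.floats(-0.5, 0.5), st.floats(-3.0, 3.0))
    def test_sign_and_order_symmetry(self, dh, dn):
        apo = _peak_list([(1, 8.0, 120.0)])
        bound = _peak_list([(1, 8.0 + dh, 120.0 + dn)])
        forward = sa.compute_csp(apo, bound).records[0].csp
        backward = sa.compute_csp(bound, apo).records[0].csp
        mirrored = sa.compute_csp(apo, _peak_list([(1, 8.0 - dh, 120.0 - dn)])).records[0].csp
        assert forward == pytest.approx(backward, rel=1e-12)
        assert forward == pytest.approx(mirrored, rel=1e-12)

    def test_unit_scale_reduces_to_euclidean(self):
        apo = _peak_list([(1, 8.0, 120.0)])
        bound = _peak_list([(1, 8.3, 120.4)])
        csp = sa.compute_csp(apo, bound, nitrogen_scale=1.0).records[0].csp
        assert csp == pytest.approx(np.hypot(0.3, 0.4), rel=1e-12)


class TestSelectSignificant:
    def _records(self, values):
        return [sa.CSPRecord(i, "bb", v, 0.0, v) for i, v in enumerate(values, 1)]

    def test_all_zero(self):
        assert sa.select_significant(self._records([0.0, 0.0]), 0.10) == set()

    def test_inclusive_boundary(self):
        selected = sa.select_significant(self._records([0.09, 0.10, 0.11]), 0.10)
        assert {r for r, _ in selected} == {2, 3}

    def test_zero_cutoff_selects_everything(self):
        selected = sa.select_significant(self._records([0.0, 0.01]), 0.0)
        assert {r for r, _ in selected} == {1, 2}

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            sa.select_significant([], -0.1)


class TestTitration:
    def test_static_spectra_no_flags(self):
        model = BindingModel(kd=1.0, max_shifts={})
        series = gen_titration(model, static_sites=[(1, "bb"), (2, "bb")], seed=0)
        result = sa.titration_trajectory(series)
        assert all(np.allclose(v, 0.0) for v in result.csp.values())
        assert not result.non_monotone

    def test_endpoint_approaches_planted_maximum(self):
        model = BindingModel(kd=1.0, protein_concentration=200.0,
                             max_shifts={(5, "bb"): (0.08, 0.40)})
        series = gen_titration(model, seed=3)
        result = sa.titration_trajectory(series)
        planted = np.hypot(0.08, 0.40 / sa.NITROGEN_SCALE)
        assert result.csp[(5, "bb")][-1] == pytest.approx(planted, rel=0.02)

    def test_fast_exchange_monotone(self):
        model = BindingModel(kd=5.0, max_shifts={(i, "bb"): (0.05 * i, 0.2 * i)
                                                 for i in range(1, 6)})
        result = sa.titration_trajectory(gen_titration(model, seed=2))
        assert not result.non_monotone
        for values in result.csp.values():
            assert np.all(np.diff(values) >= 0)

    def test_missing_apo_point_rejected(self):
        with pytest.raises(ValueError):
            sa.TitrationSeries(equivalents=[0.25, 0.5],
                               shifts={(1, "bb"): np.zeros((2, 2))})

    def test_decrease_beyond_noise_floor_flagged(self):
        series = sa.TitrationSeries(
            equivalents=[0.0, 1.0, 2.0],
            shifts={(1, "bb"): np.array([[8.0, 120.0], [8.2, 120.0], [8.05, 120.0]])})
        assert (1, "bb") in sa.titration_trajectory(series).non_monotone
        assert not sa.titration_trajectory(series, noise_floor=0.2).non_monotone


def _table(rows):
    return ShiftTable(records=[ShiftRecord(r, name, atom, value)
                               for r, name, atom, value in rows])


class TestCSI:
    SEQ = "A" * 30

    def _obs(self, offsets):
        """Random-coil table plus {residue: {atom: offset}} perturbations."""
        coil = sa.random_coil_table(self.SEQ)
        records = []
        for rec in coil.records:
            delta = offsets.get(rec.residue_index, {}).get(rec.atom, 0.0)
            records.append(ShiftRecord(rec.residue_index, rec.residue_name,
                                       rec.atom, rec.shift + delta))
        return ShiftTable(records=records)

    def test_coil_everywhere_when_matching(self):
        coil = sa.random_coil_table(self.SEQ)
        assignment = sa.csi_classify(self._obs({}), coil)
        assert set(assignment.states.values()) == {"C"}

    def test_helix_run_from_ca_offsets(self):
        offsets = {r: {"CA": 3.0} for r in range(10, 18)}
        assignment = sa.csi_classify(self._obs(offsets), sa.random_coil_table(self.SEQ))
        assert all(assignment.states[r] == "H" for r in range(10, 18))
        assert assignment.states[9] == "C" and assignment.states[18] == "C"

    def test_strand_run_from_ca_cb_offsets(self):
        offsets = {r: {"CA": -2.0, "CB": 2.0} for r in range(5, 10)}
        assignment = sa.csi_classify(self._obs(offsets), sa.random_coil_table(self.SEQ))
        assert all(assignment.states[r] == "E" for r in range(5, 10))

    def test_short_run_stays_coil(self):
        offsets = {r: {"CA": 3.0} for r in range(10, 13)}  # only 3 residues
        assignment = sa.csi_classify(self._obs(offsets), sa.random_coil_table(self.SEQ))
        assert all(assignment.states[r] == "C" for r in range(10, 13))

    def test_referencing_offset_cancels(self):
        offsets = {r: {"CA": 3.0} for r in range(10, 18)}
        obs = self._obs(offsets)
        coil = sa.random_coil_table(self.SEQ)
        shifted_obs = ShiftTable(records=[
            ShiftRecord(r.residue_index, r.residue_name, r.atom, r.shift + 0.3)
            for r in obs.records])
        shifted_coil = ShiftTable(records=[
            ShiftRecord(r.residue_index, r.residue_name, r.atom, r.shift + 0.3)
            for r in coil.records])
        assert sa.csi_classify(obs, coil).states \
            == sa.csi_classify(shifted_obs, shifted_coil).states

    def test_residue_missing_from_reference_skipped(self):
        obs = _table([(1, "ALA", "CA", 52.5), (99, "ALA", "CA", 52.5)])
        coil = _table([(1, "ALA", "CA", 52.5)])
        assignment = sa.csi_classify(obs, coil)
        assert 99 not in assignment.states
        assert assignment.warnings


class TestZincScore:
    def test_free_centroid_below_half(self):
        table = _table([(92, "CYS", "CA", 59.0), (92, "CYS", "CB", 28.0)])
        scores, _ = sa.zinc_probability(table, [92])
        assert scores[0].score < 0.5

    def test_bound_centroid_above_half(self):
        table = _table([(92, "CYS", "CA", 58.5), (92, "CYS", "CB", 31.5)])
        scores, _ = sa.zinc_probability(table, [92])
        assert scores[0].score > 0.5

    def test_monotone_along_centroid_segment(self):
        free = np.array(sa.ZINC_FREE_CENTROID)
        bound = np.array(sa.ZINC_BOUND_CENTROID)
        values = []
        for t in np.linspace(0.0, 1.0, 20):
            ca, cb = free + t * (bound - free)
            table = _table([(1, "CYS", "CA", ca), (1, "CYS", "CB", cb)])
            values.append(sa.zinc_probability(table, [1])[0][0].score)
        assert np.all(np.diff(values) > 0)
        assert values[0] < 0.5 < values[-1]

    def test_missing_cb_omitted_with_warning(self):
        table = _table([(92, "CYS", "CA", 58.5)])
        scores, warnings = sa.zinc_probability(table, [92])
        assert not scores and warnings
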