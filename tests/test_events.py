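import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memassoc import (
    AnalysisParams,
    analyze_trajectory,
    classify_trajectory,
    contact_series,
    detect_insertion,
    ensemble_curves,
)
from memassoc.distances import brute_min_distance
from memassoc.events import EventRecord, find_first_run
from conftest import make_trajectory


def oracle_first_run(mask, run_length):
    """Exhaustive run scan: first start index i with mask[i:i+L] all true."""
    for i in range(len(mask) - run_length + 1):
        if all(mask[i : i + run_length]):
            return i
    return None


def _record(contact_mask, insertion_frame=None, first_contact=None, tid="t"):
    mask = np.asarray(contact_mask, dtype=bool)
    if first_contact is None:
        first_contact = int(np.argmax(mask)) if mask.any() else None
    return EventRecord(
        trajectory_id=tid,
        times=2.0 * (np.arange(len(mask)) + 1),
        contact_mask=mask,
        anchor_contact_mask=np.zeros(len(mask), dtype=bool),
        first_contact_frame=first_contact,
        insertion_frame=insertion_frame,
        classification=classify_trajectory(mask, insertion_frame),
    )


class TestRunDetection:
    def test_first_run_of_three(self):
        assert find_first_run([0, 1, 1, 1, 0, 1], 3) == 1

    def test_run_end_reporting(self):
        assert find_first_run([0, 1, 1, 1, 0], 3, report="run_end") == 3

    def test_subthreshold_run_is_none(self):
        assert find_first_run([1, 1, 0, 1, 1, 0], 3) is None

    def test_exhaustive_masks_match_oracle(self):
        """All 4096 binary masks of length 12, several run lengths."""
        for L in (1, 2, 3, 5):
            for code in range(4096):
                mask = [(code >> k) & 1 == 1 for k in range(12)]
                assert find_first_run(mask, L) == oracle_first_run(mask, L), (L, mask)


def _two_bead_trajectory(separations_nm):
    """One protein bead above one PO4 lipid bead at given z separations."""
    coords = [[[5.0, 5.0, 1.0 + s], [5.0, 5.0, 1.0]] for s in separations_nm]
    return make_trajectory(
        coords,
        box=(10.0, 10.0, 10.0),
        bead_names=["BB", "PO4"],
        residue_indices=[70, 2],
        residue_names=["CYS", "POPE"],
        groups=["protein", "lipid"],
    )


class TestContactSeries:
    def test_strict_inequality_at_threshold(self, params):
        traj = _two_bead_trajectory([0.59, 0.60, 0.61])
        np.testing.assert_array_equal(
            contact_series(traj, params), [True, False, False]
        )

    def test_matches_per_frame_brute_force(self, params):
        rng = np.random.default_rng(5)
        n_prot, n_lip = 7, 9
        box = (4.0, 4.0, 4.0)
        coords = rng.uniform(-2, 6, size=(20, n_prot + n_lip, 3))
        traj = make_trajectory(
            list(coords),
            box=box,
            bead_names=["BB"] * n_prot + ["PO4"] * n_lip,
            residue_indices=list(range(1, n_prot + 1)) + [100] * n_lip,
            residue_names=["ALA"] * n_prot + ["POPE"] * n_lip,
            groups=["protein"] * n_prot + ["lipid"] * n_lip,
        )
        got = contact_series(traj, params)
        expect = [
            brute_min_distance(c[:n_prot], c[n_prot:], np.asarray(box))
            < params.contact_threshold
            for c in coords
        ]
        np.testing.assert_array_equal(got, expect)


class TestInsertionDetection:
    def test_insertion_from_anchor_run(self, params):
        # anchor residue 70 in contact at snapshots 1,2,3 only
        traj = _two_bead_trajectory([1.0, 0.5, 0.5, 0.5, 1.0, 1.0])
        assert detect_insertion(traj, params) == 1

    def test_run_of_two_is_not_insertion(self, params):
        traj = _two_bead_trajectory([1.0, 0.5, 0.5, 1.0, 0.5, 0.5])
        assert detect_insertion(traj, params) is None

    def test_analyze_trajectory_is_consistent_with_pieces(self, params):
        traj = _two_bead_trajectory([1.0, 0.5, 0.5, 0.5, 1.0])
        rec = analyze_trajectory(traj, params)
        np.testing.assert_array_equal(rec.contact_mask, contact_series(traj, params))
        assert rec.insertion_frame == detect_insertion(traj, params) == 1
        assert rec.classification == "inserted"
        assert rec.first_contact_frame == 1


class TestClassification:
    @pytest.mark.parametrize(
        "mask,ins,expected",
        [
            ([0, 1, 1], 1, "inserted"),
            ([0, 1, 0], None, "contact_only"),
            ([0, 0, 0], None, "no_contact"),
        ],
    )
    def test_priority(self, mask, ins, expected):
        assert classify_trajectory(np.asarray(mask, bool), ins) == expected


class TestEnsembleCurves:
    def test_cumulative_hand_enumeration(self, params):
        recs = [
            _record([1, 1, 1, 1]),          # first contact at snapshot 0
            _record([0, 0, 1, 0]),          # first contact at snapshot 2
            _record([0, 0, 0, 0]),          # never
        ]
        curves = ensemble_curves(recs, params)
        np.testing.assert_allclose(
            curves.cumulative_contact, [1 / 3, 1 / 3, 2 / 3, 2 / 3]
        )

    def test_subtotal_window_arithmetic(self, params):
        # only contact at snapshot 0 -> contributes to subtotal snapshots 0..4
        mask = np.zeros(8, dtype=bool)
        mask[0] = True
        curves = ensemble_curves([_record(mask)], params)
        np.testing.assert_allclose(
            curves.subtotal_contact, [1, 1, 1, 1, 1, 0, 0, 0]
        )

    def test_saturated_ensemble(self, params):
        recs = [_record(np.ones(6, dtype=bool)) for _ in range(4)]
        curves = ensemble_curves(recs, params)
        assert np.all(curves.cumulative_contact == 1.0)
        assert np.all(curves.subtotal_contact == 1.0)

    def test_inserted_curve_denominators(self, params):
        recs = [
            _record([1, 1, 1, 1], insertion_frame=1),
            _record([0, 1, 0, 0]),
        ]
        sub = ensemble_curves(recs, params, inserted_denominator="inserted")
        np.testing.assert_allclose(sub.cumulative_inserted, [0, 1, 1, 1])
        full = ensemble_curves(recs, params, inserted_denominator="all")
        np.testing.assert_allclose(full.cumulative_inserted, [0, 0.5, 0.5, 0.5])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        masks=st.lists(
            st.lists(st.booleans(), min_size=12, max_size=12),
            min_size=1,
            max_size=6,
        ),
        window_ns=st.sampled_from([2.0, 6.0, 10.0, 24.0, 40.0]),
    )
    def test_curve_invariants(self, masks, window_ns):
        params = AnalysisParams(subtotal_window=window_ns)
        recs = [_record(m, tid=f"t{i}") for i, m in enumerate(masks)]
        curves = ensemble_curves(recs, params)
        cum = curves.cumulative_contact
        sub = curves.subtotal_contact
        assert np.all(np.diff(cum) >= 0)
        assert np.all((0 <= cum) & (cum <= 1))
        assert np.all((0 <= sub) & (sub <= 1))
        assert np.all(sub <= cum + 1e-12)
        if window_ns >= 12 * params.frame_interval:
            np.testing.assert_allclose(sub, cum)
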