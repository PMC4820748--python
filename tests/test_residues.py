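import numpy as np
import pytest

from memassoc import (
    AnalysisParams,
    high_contact_residues,
    residue_contact_probability,
    write_bfactor_pdb,
)
from memassoc.distances import brute_min_distance
from memassoc.events import EventRecord, analyze_trajectory, classify_trajectory
from memassoc.residues import EmptyWindowError, ResidueContactProfile, _phase_window
from conftest import make_trajectory


def _toy_profile(ids, probs, names=None):
    ids = np.asarray(ids)
    probs = np.asarray(probs, float)
    return ResidueContactProfile(
        residue_ids=ids,
        residue_names=np.asarray(names or ["ALA"] * len(ids), dtype=object),
        probabilities=probs,
        counts=(probs * 10).astype(int),
        denominator=10,
        phase="after_insertion",
        ensemble_size=1,
    )


def _toy_ensemble(params):
    """Two protein residues over one PO4 head; residue 1 within threshold in
    2 of 4 snapshots, residue 2 never."""
    frames = []
    for z1 in (0.5, 0.5, 1.5, 1.5):
        frames.append(
            [
                [5.0, 5.0, 1.0 + z1],  # residue 1 bead
                [5.0, 5.0, 4.0],       # residue 2 bead, always far
                [5.0, 5.0, 1.0],       # PO4
                [5.0, 5.0, 0.5],       # tail bead GL1
            ]
        )
    traj = make_trajectory(
        frames,
        box=(10.0, 10.0, 10.0),
        bead_names=["BB", "BB", "PO4", "GL1"],
        residue_indices=[1, 2, 10, 10],
        residue_names=["ALA", "ALA", "POPE", "POPE"],
        groups=["protein", "protein", "lipid", "lipid"],
    )
    rec = analyze_trajectory(traj, AnalysisParams(anchor_residue_index=1))
    return [traj], [rec]


class TestProfile:
    def test_hand_counted_probability(self, params):
        trajs, recs = _toy_ensemble(params)
        assert recs[0].first_contact_frame == 0
        prof = residue_contact_probability(trajs, recs, params, "after_first_contact")
        assert prof.denominator == 4
        assert prof.probability_of(1) == pytest.approx(0.5)
        assert prof.probability_of(2) == 0.0

    def test_profile_matches_brute_force_recomputation(self, anchored_ensemble_small):
        trajs, recs, _, params = anchored_ensemble_small
        prof = residue_contact_probability(trajs, recs, params, "after_insertion")
        # independent oracle: per-snapshot all-pairs distances per residue
        top = trajs[0].topology
        heads = top.head_group_indices(params.head_group_bead_names)
        rid_list = list(prof.residue_ids)
        counts = np.zeros(len(rid_list), dtype=int)
        denom = 0
        for traj, rec in zip(trajs, recs):
            if rec.insertion_frame is None:
                continue
            for i in range(rec.insertion_frame, rec.n_snapshots):
                fr = traj.frames[i]
                denom += 1
                for j, rid in enumerate(rid_list):
                    beads = top.residue_beads(rid)
                    d = brute_min_distance(fr.coords[beads], fr.coords[heads], fr.box)
                    if d < params.contact_threshold:
                        counts[j] += 1
        assert denom == prof.denominator
        np.testing.assert_allclose(prof.probabilities, counts / denom)

    def test_pinned_anchor_has_probability_one(self, anchored_ensemble_small):
        trajs, recs, _, params = anchored_ensemble_small
        assert any(r.insertion_frame is not None for r in recs)
        prof = residue_contact_probability(trajs, recs, params, "after_insertion")
        assert prof.probability_of(params.anchor_residue_index) == 1.0

    def test_phase_windows_partition_the_contacted_span(self):
        rec = EventRecord(
            trajectory_id="t",
            times=2.0 * (np.arange(10) + 1),
            contact_mask=np.ones(10, dtype=bool),
            anchor_contact_mask=np.zeros(10, dtype=bool),
            first_contact_frame=2,
            insertion_frame=6,
            classification="inserted",
        )
        before = _phase_window(rec, "before_insertion")
        after = _phase_window(rec, "after_insertion")
        assert set(before) & set(after) == set()
        assert sorted(set(before) | set(after)) == list(range(2, 10))

    def test_empty_window_is_an_error_not_a_zero_profile(self, params):
        trajs, recs = _toy_ensemble(params)  # nothing inserts
        with pytest.raises(EmptyWindowError):
            residue_contact_probability(trajs, recs, params, "after_insertion")

    def test_per_trajectory_weighting_option(self, params):
        trajs, recs = _toy_ensemble(params)
        pooled = residue_contact_probability(trajs, recs, params, "after_first_contact")
        pertraj = residue_contact_probability(
            trajs, recs, params, "after_first_contact", weighting="per_trajectory"
        )
        np.testing.assert_allclose(pooled.probabilities, pertraj.probabilities)


class TestHighContact:
    def test_cutoff_zero_returns_all_sorted_descending(self):
        prof = _toy_profile([1, 2, 3], [0.2, 0.9, 0.5])
        assert high_contact_residues(prof, 0.0) == [2, 3, 1]

    def test_cutoff_above_one_returns_empty(self):
        prof = _toy_profile([1, 2], [1.0, 0.3])
        assert high_contact_residues(prof, 1.0 + 1e-9) == []

    def test_cutoff_filters(self):
        prof = _toy_profile([5, 6, 7], [0.45, 0.55, 0.95])
        assert high_contact_residues(prof, 0.5) == [7, 6]


def _write_toy_pdb(path, resids):
    lines = []
    serial = 1
    for r in resids:
        for name in ("N", "CA", "C"):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}ALA A{r:4d}    "
                f"{1.0 * r:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"           {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestBfactorMapping:
    def test_round_trip_of_probabilities(self, tmp_path):
        import gemmi

        pdb_in = tmp_path / "in.pdb"
        _write_toy_pdb(pdb_in, resids=[69, 70, 71])
        prof = _toy_profile([70, 71], [1.0, 0.25])
        out = tmp_path / "out.pdb"
        write_bfactor_pdb(pdb_in, prof, out)
        st = gemmi.read_structure(str(out))
        got = {res.seqid.num: sorted(a.b_iso for a in res) for res in st[0]["A"]}
        assert got[70] == pytest.approx([100.0] * 3)
        assert got[71] == pytest.approx([25.0] * 3)
        assert got[69] == pytest.approx([0.0] * 3)

    def test_no_residue_overlap_is_an_error(self, tmp_path):
        pdb_in = tmp_path / "in.pdb"
        _write_toy_pdb(pdb_in, resids=[1, 2])
        prof = _toy_profile([70], [1.0])
        with pytest.raises(Exception, match="overlap"):
            write_bfactor_pdb(pdb_in, prof, tmp_path / "out.pdb")
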