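"""Contact and insertion-event statistics for protein/membrane ensembles.

A snapshot is a *contact* when the minimum protein-membrane bead distance is
strictly below the contact threshold (0.6 nm by default).  An *insertion
event* is the first run of ``insertion_run_length`` successive snapshots in
which the anchor residue (the palmitoylated cysteine) is in membrane
contact; a trajectory with an insertion event is classified *inserted*.
Ensemble curves report, per snapshot, the cumulative fraction of
trajectories that have made contact, the fraction with a contact in the
trailing ``subtotal_window`` (the "subtotal"), and the cumulative inserted
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .distances import SelectionError, nearest_distances, periodic_tree
from .model import AnalysisParams, ConfigurationError, Topology, Trajectory

CLASSIFICATIONS = ("inserted", "contact_only", "no_contact")


@dataclass
class EventRecord:
    """Per-trajectory contact/insertion bookkeeping (one entry per snapshot)."""

    trajectory_id: str
    times: np.ndarray
    contact_mask: np.ndarray
    anchor_contact_mask: np.ndarray
    first_contact_frame: Optional[int]
    insertion_frame: Optional[int]
    classification: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.contact_mask = np.asarray(self.contact_mask, dtype=bool)
        self.anchor_contact_mask = np.asarray(self.anchor_contact_mask, dtype=bool)
        if self.contact_mask.shape != self.times.shape:
            raise ValueError("contact_mask length must equal snapshot count")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"bad classification {self.classification!r}")
        if self.insertion_frame is not None:
            if self.classification != "inserted":
                raise ValueError("insertion_frame set but not classified inserted")
            if self.first_contact_frame is None or (
                self.first_contact_frame > self.insertion_frame
            ):
                raise ValueError("first contact must precede insertion")

    @property
    def n_snapshots(self) -> int:
        return len(self.times)


def _lipid_selection(topology: Topology, params: AnalysisParams) -> np.ndarray:
    if params.contact_lipid_beads == "head":
        sel = topology.head_group_indices(params.head_group_bead_names)
    else:
        sel = topology.lipid_indices
    if sel.size == 0:
        raise SelectionError("lipid selection is empty; run assign_groups first")
    return sel


def find_first_run(mask, run_length: int, report: str = "run_start") -> Optional[int]:
    """Index of the first run of >= ``run_length`` consecutive True values.

    Returns the first snapshot of the run ("run_start") or the snapshot
    completing it ("run_end"); None when no run qualifies.
    """
    mask = np.asarray(mask, dtype=bool)
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= run_length:
            return i if report == "run_end" else i - run_length + 1
    return None


def contact_series(trajectory: Trajectory, params: AnalysisParams) -> np.ndarray:
    """Boolean per-snapshot contact mask (protein vs membrane beads)."""
    top = trajectory.topology
    prot = top.protein_indices
    lip = _lipid_selection(top, params)
    if prot.size == 0:
        raise SelectionError("protein selection is empty; run assign_groups first")
    out = np.empty(trajectory.n_frames, dtype=bool)
    for i, fr in enumerate(trajectory.frames):
        d = nearest_distances(fr.coords[prot], fr.box, coords_ref=fr.coords[lip])
        out[i] = float(d.min()) < params.contact_threshold
    return out


def anchor_contact_series(trajectory: Trajectory, params: AnalysisParams) -> np.ndarray:
    """Per-snapshot contact mask of the anchor residue vs membrane beads."""
    top = trajectory.topology
    anchor = top.residue_beads(params.anchor_residue_index, "protein")
    if anchor.size == 0:
        raise ConfigurationError(
            f"anchor residue {params.anchor_residue_index} absent from topology"
        )
    lip = _lipid_selection(top, params)
    out = np.empty(trajectory.n_frames, dtype=bool)
    for i, fr in enumerate(trajectory.frames):
        d = nearest_distances(fr.coords[anchor], fr.box, coords_ref=fr.coords[lip])
        out[i] = float(d.min()) < params.contact_threshold
    return out


def detect_insertion(trajectory: Trajectory, params: AnalysisParams) -> Optional[int]:
    """Snapshot index of the insertion event, or None."""
    mask = anchor_contact_series(trajectory, params)
    return find_first_run(mask, params.insertion_run_length, params.insertion_report)


def classify_trajectory(
    contact_mask, insertion_frame: Optional[int]
) -> str:
    """inserted > contact_only > no_contact."""
    if insertion_frame is not None:
        return "inserted"
    if np.any(np.asarray(contact_mask, dtype=bool)):
        return "contact_only"
    return "no_contact"


def analyze_trajectory(
    trajectory: Trajectory, params: AnalysisParams, trajectory_id: str = "traj"
) -> EventRecord:
    """Single-pass contact + insertion analysis of one trajectory.

    Equivalent to running :func:`contact_series` and
    :func:`detect_insertion` separately, but shares one periodic KD-tree
    query per frame.
    """
    top = trajectory.topology
    prot = top.protein_indices
    if prot.size == 0:
        raise SelectionError("protein selection is empty; run assign_groups first")
    anchor = top.residue_beads(params.anchor_residue_index, "protein")
    if anchor.size == 0:
        raise ConfigurationError(
            f"anchor residue {params.anchor_residue_index} absent from topology"
        )
    lip = _lipid_selection(top, params)
    # positions of the anchor beads within the protein selection
    anchor_rows = np.flatnonzero(np.isin(prot, anchor))
    n = trajectory.n_frames
    contact = np.empty(n, dtype=bool)
    anchor_contact = np.empty(n, dtype=bool)
    for i, fr in enumerate(trajectory.frames):
        tree = periodic_tree(fr.coords[lip], fr.box)
        d = nearest_distances(fr.coords[prot], fr.box, tree=tree)
        contact[i] = float(d.min()) < params.contact_threshold
        anchor_contact[i] = float(d[anchor_rows].min()) < params.contact_threshold
    insertion = find_first_run(
        anchor_contact, params.insertion_run_length, params.insertion_report
    )
    first_contact = int(np.argmax(contact)) if contact.any() else None
    return EventRecord(
        trajectory_id=trajectory_id,
        times=trajectory.times,
        contact_mask=contact,
        anchor_contact_mask=anchor_contact,
        first_contact_frame=first_contact,
        insertion_frame=insertion,
        classification=classify_trajectory(contact, insertion),
    )


@dataclass
class EnsembleCurves:
    """Ensemble time courses (fractions in [0, 1] per snapshot)."""

    times: np.ndarray
    cumulative_contact: np.ndarray
    subtotal_contact: np.ndarray
    cumulative_inserted: np.ndarray
    n_trajectories: int
    inserted_denominator: str = "inserted"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "cumulative_contact": self.cumulative_contact,
                "subtotal_contact": self.subtotal_contact,
                "cumulative_inserted": self.cumulative_inserted,
            }
        )


def _trailing_window_any(mask: np.ndarray, window: int) -> np.ndarray:
    """Per snapshot i: any True among snapshots (i-window, i]."""
    x = mask.astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(0, np.arange(1, n + 1) - window)
    return (cs[1:] - cs[lo]) > 0


def ensemble_curves(
    records: list[EventRecord],
    params: AnalysisParams,
    inserted_denominator: str = "inserted",
) -> EnsembleCurves:
    """Cumulative / subtotal contact and cumulative inserted fractions.

    ``inserted_denominator`` selects the normalisation of the inserted
    curve: the inserted subset ("inserted") or the full ensemble ("all").
    """
    if not records:
        raise ConfigurationError("no records")
    n_snap = records[0].n_snapshots
    times = records[0].times
    for r in records:
        if r.n_snapshots != n_snap:
            raise ConfigurationError(
                f"record {r.trajectory_id} has {r.n_snapshots} snapshots, "
                f"expected {n_snap}"
            )
    if inserted_denominator not in ("inserted", "all"):
        raise ConfigurationError("inserted_denominator must be 'inserted' or 'all'")
    window = params.subtotal_window_frames
    n = len(records)
    cum = np.zeros(n_snap)
    sub = np.zeros(n_snap)
    ins = np.zeros(n_snap)
    n_inserted = sum(1 for r in records if r.insertion_frame is not None)
    for r in records:
        cum += np.cumsum(r.contact_mask) > 0
        sub += _trailing_window_any(r.contact_mask, window)
        if r.insertion_frame is not None:
            ins += np.arange(n_snap) >= r.insertion_frame
    denom_ins = n_inserted if inserted_denominator == "inserted" else n
    return EnsembleCurves(
        times=times,
        cumulative_contact=cum / n,
        subtotal_contact=sub / n,
        cumulative_inserted=ins / denom_ins if denom_ins else np.zeros(n_snap),
        n_trajectories=n,
        inserted_denominator=inserted_denominator,
    )


def records_to_frame(records: list[EventRecord]) -> pd.DataFrame:
    """One row per (trajectory, snapshot) with contact flags."""
    rows = []
    for r in records:
        for i in range(r.n_snapshots):
            rows.append(
                {
                    "trajectory_id": r.trajectory_id,
                    "snapshot": i,
                    "time_ns": r.times[i],
                    "contact": bool(r.contact_mask[i]),
                    "anchor_contact": bool(r.anchor_contact_mask[i]),
                }
            )
    return pd.DataFrame(rows)


def classification_counts(records: list[EventRecord]) -> dict[str, int]:
    out = {c: 0 for c in CLASSIFICATIONS}
    for r in records:
        out[r.classification] += 1
    return out
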