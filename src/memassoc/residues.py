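"""Per-residue lipid-contact probabilities and B-factor structure mapping.

A residue is "in contact" at a snapshot when the minimum distance between
any of its beads and any lipid *head-group* bead (NH3, PO4, C1A, C1B) is
strictly below the contact threshold.  Probabilities are the ratio of
in-contact snapshots to all snapshots of a phase window, pooled across the
trajectories of an ensemble:

* ``after_insertion``   — snapshots >= the insertion event (inserted
  trajectories only); the stable binding interface.
* ``before_insertion``  — snapshots in [first contact, insertion) of
  inserted trajectories; transient pre-anchoring contacts.
* ``after_first_contact`` — snapshots >= the first contact of any
  contacting trajectory (the window used for variants that never insert).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .distances import nearest_distances, periodic_tree
from .events import EventRecord
from .model import AnalysisParams, ConfigurationError, Topology, Trajectory

PHASES = ("after_insertion", "before_insertion", "after_first_contact")


class EmptyWindowError(ConfigurationError):
    """The pooled phase window contains no snapshots."""


@dataclass
class ResidueContactProfile:
    """Pooled per-residue head-group contact probabilities."""

    residue_ids: np.ndarray
    residue_names: np.ndarray
    probabilities: np.ndarray
    counts: np.ndarray
    denominator: int
    phase: str
    ensemble_size: int

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise EmptyWindowError("profile denominator must be >= 1")
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must be in [0, 1]")

    def probability_of(self, residue_index: int) -> float:
        i = np.flatnonzero(self.residue_ids == residue_index)
        if i.size == 0:
            raise KeyError(residue_index)
        return float(self.probabilities[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_index": self.residue_ids,
                "residue_name": self.residue_names,
                "probability": self.probabilities,
                "contact_snapshots": self.counts,
                "denominator": self.denominator,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _phase_window(record: EventRecord, phase: str) -> np.ndarray:
    """Snapshot indices of one trajectory belonging to the phase window."""
    n = record.n_snapshots
    if phase == "after_insertion":
        if record.insertion_frame is None:
            return np.empty(0, dtype=int)
        return np.arange(record.insertion_frame, n)
    if phase == "before_insertion":
        if record.insertion_frame is None or record.first_contact_frame is None:
            return np.empty(0, dtype=int)
        return np.arange(record.first_contact_frame, record.insertion_frame)
    if phase == "after_first_contact":
        if record.first_contact_frame is None:
            return np.empty(0, dtype=int)
        return np.arange(record.first_contact_frame, n)
    raise ConfigurationError(f"unknown phase {phase!r}; one of {PHASES}")


def residue_contact_matrix(
    trajectory: Trajectory,
    params: AnalysisParams,
    snapshots=None,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(residue_ids, bool matrix snapshots x residues) of head-group contact."""
    top = trajectory.topology
    prot = top.protein_indices
    heads = top.head_group_indices(params.head_group_bead_names)
    if heads.size == 0:
        raise ConfigurationError("no head-group beads in topology")
    if prot.size == 0:
        raise ConfigurationError("no protein beads in topology")
    thr = params.contact_threshold if threshold is None else threshold
    res_of_bead = top.residue_indices[prot]
    residue_ids, inverse = np.unique(res_of_bead, return_inverse=True)
    if snapshots is None:
        snapshots = np.arange(trajectory.n_frames)
    out = np.zeros((len(snapshots), len(residue_ids)), dtype=bool)
    for row, i in enumerate(snapshots):
        fr = trajectory.frames[int(i)]
        tree = periodic_tree(fr.coords[heads], fr.box)
        d = nearest_distances(fr.coords[prot], fr.box, tree=tree)
        hit = d < thr
        if hit.any():
            np.logical_or.at(out[row], inverse[hit], True)
    return residue_ids, out


class ProfileAccumulator:
    """Streaming builder of a pooled residue-contact profile.

    Feed trajectories one at a time with :meth:`add` (they can then be
    discarded, keeping memory flat for large ensembles) and call
    :meth:`finalize` for the :class:`ResidueContactProfile`.
    """

    def __init__(
        self,
        params: AnalysisParams,
        phase: str,
        threshold: float | None = None,
    ) -> None:
        if phase not in PHASES:
            raise ConfigurationError(f"unknown phase {phase!r}; one of {PHASES}")
        self.params = params
        self.phase = phase
        self.threshold = threshold
        self.residue_ids: np.ndarray | None = None
        self.residue_names: np.ndarray | None = None
        self.counts: np.ndarray | None = None
        self.total = 0
        self.per_traj_probs: list[np.ndarray] = []

    def add(self, trajectory: Trajectory, record: EventRecord) -> None:
        win = _phase_window(record, self.phase)
        if win.size == 0:
            return
        rids, mat = residue_contact_matrix(
            trajectory, self.params, snapshots=win, threshold=self.threshold
        )
        if self.residue_ids is None:
            self.residue_ids = rids
            self.counts = np.zeros(len(rids), dtype=np.int64)
            top = trajectory.topology
            name_of = {}
            for b in top.protein_indices:
                name_of.setdefault(
                    int(top.residue_indices[b]), str(top.residue_names[b])
                )
            self.residue_names = np.asarray(
                [name_of[int(r)] for r in rids], dtype=object
            )
        elif not np.array_equal(rids, self.residue_ids):
            raise ConfigurationError(
                "trajectories have inconsistent protein residues"
            )
        self.counts += mat.sum(axis=0)
        self.total += mat.shape[0]
        self.per_traj_probs.append(mat.mean(axis=0))

    def finalize(self, weighting: str = "pooled") -> ResidueContactProfile:
        if weighting not in ("pooled", "per_trajectory"):
            raise ConfigurationError("weighting must be 'pooled' or 'per_trajectory'")
        if self.residue_ids is None or self.total == 0:
            raise EmptyWindowError(
                f"phase {self.phase!r} selects no snapshots in this ensemble"
            )
        if weighting == "pooled":
            probs = self.counts / self.total
        else:
            probs = np.mean(self.per_traj_probs, axis=0)
        return ResidueContactProfile(
            residue_ids=self.residue_ids,
            residue_names=self.residue_names,
            probabilities=probs,
            counts=self.counts,
            denominator=self.total,
            phase=self.phase,
            ensemble_size=len(self.per_traj_probs),
        )


def residue_contact_probability(
    trajectories: list[Trajectory],
    records: list[EventRecord],
    params: AnalysisParams,
    phase: str,
    weighting: str = "pooled",
    threshold: float | None = None,
) -> ResidueContactProfile:
    """Pooled (snapshot-weighted) or per-trajectory-averaged residue profile.

    Raises :class:`EmptyWindowError` when the pooled window is empty (for
    example ``after_insertion`` on an ensemble with no inserted
    trajectory) rather than returning a zero profile.
    """
    if len(trajectories) != len(records):
        raise ConfigurationError("trajectories and records differ in length")
    acc = ProfileAccumulator(params, phase, threshold=threshold)
    for traj, rec in zip(trajectories, records):
        acc.add(traj, rec)
    return acc.finalize(weighting)


def high_contact_residues(profile: ResidueContactProfile, cutoff: float) -> list[int]:
    """Residues with probability >= cutoff, sorted by descending probability
    (ties by ascending residue index)."""
    order = np.lexsort((profile.residue_ids, -profile.probabilities))
    return [
        int(profile.residue_ids[i])
        for i in order
        if profile.probabilities[i] >= cutoff
    ]


def write_bfactor_pdb(
    structure_path,
    profile: ResidueContactProfile,
    out_path,
    residue_offset: int = 0,
) -> None:
    """Copy a PDB with B-factors set to 100 x contact probability.

    ``residue_offset`` is added to the PDB residue numbers before matching
    the profile; residues absent from the profile get B = 0.00.
    """
    st = gemmi.read_structure(str(structure_path))
    st.setup_entities()
    prob = {int(r): float(p) for r, p in zip(profile.residue_ids, profile.probabilities)}
    matched = 0
    for model in st:
        for chain in model:
            for res in chain:
                key = res.seqid.num + residue_offset
                b = prob.get(key)
                if b is not None:
                    matched += 1
                for atom in res:
                    atom.b_iso = 0.0 if b is None else round(100.0 * b, 2)
    if matched == 0:
        raise ConfigurationError(
            "no residue overlap between the structure and the profile "
            f"(offset {residue_offset})"
        )
    st.write_pdb(str(out_path))
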