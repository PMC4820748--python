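"""Core data model for coarse-grained membrane-association analysis.

The objects here are deliberately light: a :class:`Topology` is a columnar
table of beads (name, residue, group, molecule), a :class:`Frame` is one
timestamped snapshot of coordinates in an orthorhombic periodic box, and a
:class:`Trajectory` ties the two together.  All lengths are nanometres and
all times nanoseconds throughout the package; thresholds quoted in angstrom
in the literature (e.g. the 6 A contact cut-off) are stored as nm.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

GROUPS = ("protein", "lipid", "solvent", "ion")

#: Martini-style head-group bead names of a phospholipid (glycerol linkers,
#: phosphate and amine beads); per-residue contact probabilities are scored
#: against these beads only.
DEFAULT_HEAD_GROUP_BEADS = frozenset({"C1A", "C1B", "NH3", "PO4"})


class FormatError(ValueError):
    """A file did not conform to the expected on-disk format."""


class ConfigurationError(ValueError):
    """A parameter set or selection is invalid for the requested analysis."""


@dataclass(frozen=True)
class Bead:
    """One coarse-grained interaction site."""

    bead_id: int
    bead_name: str
    residue_index: int
    residue_name: str
    group: str
    molecule_id: int


class Topology(Sequence):
    """Columnar table of beads.

    Bead ids are implicit: bead ``i`` of the table has ``bead_id == i``.
    Stored column-wise (numpy arrays) so that selections used in the
    distance kernels are plain index arrays.
    """

    def __init__(
        self,
        bead_names: Iterable[str],
        residue_indices: Iterable[int],
        residue_names: Iterable[str],
        groups: Iterable[str],
        molecule_ids: Iterable[int],
    ) -> None:
        self.bead_names = np.asarray(list(bead_names), dtype=object)
        self.residue_indices = np.asarray(list(residue_indices), dtype=np.int64)
        self.residue_names = np.asarray(list(residue_names), dtype=object)
        self.groups = np.asarray(list(groups), dtype=object)
        self.molecule_ids = np.asarray(list(molecule_ids), dtype=np.int64)
        n = len(self.bead_names)
        for col in (self.residue_indices, self.residue_names, self.groups, self.molecule_ids):
            if len(col) != n:
                raise ValueError("topology columns have unequal lengths")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.bead_names)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return Bead(
            bead_id=int(i) if i >= 0 else len(self) + int(i),
            bead_name=str(self.bead_names[i]),
            residue_index=int(self.residue_indices[i]),
            residue_name=str(self.residue_names[i]),
            group=str(self.groups[i]),
            molecule_id=int(self.molecule_ids[i]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            np.array_equal(self.bead_names, other.bead_names)
            and np.array_equal(self.residue_indices, other.residue_indices)
            and np.array_equal(self.residue_names, other.residue_names)
            and np.array_equal(self.groups, other.groups)
            and np.array_equal(self.molecule_ids, other.molecule_ids)
        )

    # -- selections --------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self)

    def group_indices(self, group: str) -> np.ndarray:
        """Bead indices belonging to one group label."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.flatnonzero(self.groups == group)

    @property
    def protein_indices(self) -> np.ndarray:
        return self.group_indices("protein")

    @property
    def lipid_indices(self) -> np.ndarray:
        return self.group_indices("lipid")

    def head_group_indices(self, bead_names: Iterable[str] = DEFAULT_HEAD_GROUP_BEADS) -> np.ndarray:
        """Lipid beads whose name is in the head-group vocabulary."""
        names = set(bead_names)
        mask = (self.groups == "lipid") & np.asarray(
            [b in names for b in self.bead_names], dtype=bool
        )
        return np.flatnonzero(mask)

    def residue_beads(self, residue_index: int, group: str = "protein") -> np.ndarray:
        """Bead indices of one residue (restricted to a group)."""
        mask = (self.residue_indices == residue_index) & (self.groups == group)
        return np.flatnonzero(mask)

    def group_counts(self) -> dict[str, int]:
        return {g: int(np.sum(self.groups == g)) for g in GROUPS}

    def protein_residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices of the protein group."""
        return np.unique(self.residue_indices[self.groups == "protein"])

    @classmethod
    def from_beads(cls, beads: Iterable[Bead]) -> "Topology":
        beads = list(beads)
        return cls(
            [b.bead_name for b in beads],
            [b.residue_index for b in beads],
            [b.residue_name for b in beads],
            [b.group for b in beads],
            [b.molecule_id for b in beads],
        )


@dataclass
class Frame:
    """One snapshot: time (ns), orthorhombic box edges (nm), coords (nm).

    Coordinates may lie outside ``[0, box)``; wrapping is the distance
    kernel's responsibility.
    """

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(self.box > 0):
            raise ValueError("all box edges must be positive")


@dataclass
class Trajectory:
    """An ordered sequence of frames over one topology."""

    topology: Topology
    frames: list[Frame]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.topology.n_beads
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.coords.shape[0]} beads, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([fr.time for fr in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class AnalysisParams:
    """All constants of the contact / insertion analysis.

    contact_threshold
        Strict upper bound on the minimum protein-membrane bead distance for
        a snapshot to count as a "contact" (nm; 0.6 nm = 6 A).
    insertion_run_length
        Number of successive snapshots of anchor-membrane contact that
        defines an insertion event.
    subtotal_window
        Width (ns) of the trailing window of the "subtotal" ensemble curve.
    frame_interval
        Analysis snapshot spacing (ns).
    head_group_bead_names
        Lipid bead names counted as head-group for residue contact
        probabilities.
    anchor_residue_index
        Residue carrying the lipid anchor (the palmitoylated cysteine).
    insertion_report
        Whether the insertion time is the first ("run_start") or last
        ("run_end") snapshot of the qualifying run.
    contact_lipid_beads
        Which lipid beads enter the global/anchor contact criterion:
        "all" (default) or "head".
    """

    contact_threshold: float = 0.6
    insertion_run_length: int = 3
    subtotal_window: float = 10.0
    frame_interval: float = 2.0
    head_group_bead_names: frozenset = DEFAULT_HEAD_GROUP_BEADS
    anchor_residue_index: int = 70
    insertion_report: str = "run_start"
    contact_lipid_beads: str = "all"

    def __post_init__(self) -> None:
        if self.contact_threshold <= 0:
            raise ConfigurationError("contact_threshold must be positive")
        if self.insertion_run_length < 1:
            raise ConfigurationError("insertion_run_length must be >= 1")
        if not (self.subtotal_window >= self.frame_interval > 0):
            raise ConfigurationError("need subtotal_window >= frame_interval > 0")
        if not self.head_group_bead_names:
            raise ConfigurationError("head_group_bead_names must be non-empty")
        if self.insertion_report not in ("run_start", "run_end"):
            raise ConfigurationError("insertion_report must be run_start or run_end")
        if self.contact_lipid_beads not in ("all", "head"):
            raise ConfigurationError("contact_lipid_beads must be all or head")
        object.__setattr__(
            self, "head_group_bead_names", frozenset(self.head_group_bead_names)
        )

    @property
    def subtotal_window_frames(self) -> int:
        """Window width in snapshots (10 ns / 2 ns = 5 at defaults)."""
        w = self.subtotal_window / self.frame_interval
        return max(1, int(round(w)))


def assign_groups(
    topology: Topology,
    lipid_residue_names: Iterable[str],
    solvent_residue_names: Iterable[str] = (),
    ion_residue_names: Iterable[str] = (),
) -> Topology:
    """Partition beads into protein / lipid / solvent / ion by residue name.

    Every bead whose residue name is in none of the given sets becomes
    protein.  Raises :class:`ConfigurationError` if the lipid set is empty
    or if either the protein or the lipid group ends up empty.
    """
    lipid = set(lipid_residue_names)
    solvent = set(solvent_residue_names)
    ion = set(ion_residue_names)
    if not lipid:
        raise ConfigurationError("lipid_residue_names must not be empty")
    groups = []
    for rn in topology.residue_names:
        if rn in lipid:
            groups.append("lipid")
        elif rn in ion:
            groups.append("ion")
        elif rn in solvent:
            groups.append("solvent")
        else:
            groups.append("protein")
    out = Topology(
        topology.bead_names,
        topology.residue_indices,
        topology.residue_names,
        groups,
        topology.molecule_ids,
    )
    counts = out.group_counts()
    if counts["protein"] == 0 or counts["lipid"] == 0:
        raise ConfigurationError(
            f"group assignment left an empty protein or lipid group: {counts}"
        )
    return out


def subsample_frames(trajectory: Trajectory, interval: float) -> Trajectory:
    """Pick the frames nearest to ``interval, 2*interval, ...``.

    The grid starts at ``t = interval`` (the t=0 initial structure is not an
    analysis snapshot, so a 1000 ns trajectory at 2 ns yields exactly 500
    snapshots).  Ties between equally near frames go to the earlier frame,
    and no source frame is selected twice.  Raises if the requested interval
    is finer than the native frame spacing (no upsampling).
    """
    if interval <= 0:
        raise ConfigurationError("interval must be positive")
    if trajectory.n_frames == 0:
        raise ConfigurationError("trajectory has no frames")
    times = trajectory.times
    if len(times) > 1:
        native = float(np.min(np.diff(times)))
        if interval < native * (1 - 1e-9):
            raise ConfigurationError(
                f"interval {interval} ns is finer than the native spacing "
                f"{native} ns; cannot upsample"
            )
    t_final = float(times[-1])
    n_targets = int(math.floor(t_final / interval + 1e-9))
    picked: list[int] = []
    seen: set[int] = set()
    for k in range(1, n_targets + 1):
        target = k * interval
        j = int(np.searchsorted(times, target))
        # candidates j-1 and j; ties toward the earlier frame
        best = None
        for c in (j - 1, j):
            if 0 <= c < len(times):
                d = abs(times[c] - target)
                if best is None or d < best[0] - 1e-12:
                    best = (d, c)
        idx = best[1]
        if idx not in seen:
            seen.add(idx)
            picked.append(idx)
    frames = [trajectory.frames[i] for i in picked]
    prov = dict(trajectory.provenance)
    prov["subsample_interval_ns"] = interval
    return Trajectory(topology=trajectory.topology, frames=frames, provenance=prov)
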