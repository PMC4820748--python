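"""Seeded Brownian-dynamics generator of protein-near-membrane ensembles.

This is a phenomenological rigid-body surrogate for coarse-grained MD of a
peripheral membrane protein near a planar bilayer: it reproduces the
*observable event structure* of such simulations — diffusive approach,
transient membrane contacts, and (for the lipid-anchored variant) an
irreversible anchor-insertion event — with exact ground truth, not the
underlying force-field physics.

Model summary
-------------
* The membrane is a static single leaflet of lipids on a jittered square
  lattice; each lipid carries four head-group beads (NH3, PO4, C1A, C1B)
  at the surface plane and eight tail beads below it.
* The protein is a rigid random bead cloud (two beads per residue) that
  performs overdamped rigid-body Brownian motion: isotropic Gaussian
  centre-of-mass steps (variance ``2 D_t dt`` per axis), small random
  rotations about the centre of mass (variance ``2 D_r dt``), and a
  short-range downhill drift toward the membrane surface.  The surface
  acts as a soft wall; the box top reflects.
* While the anchor residue (the palmitoylated cysteine) is within
  ``anchor_capture_distance`` of a head bead, insertion fires with
  probability ``anchor_capture_hazard`` per snapshot.  Once fired (in
  irreversible mode) the anchor side-chain bead is tethered to the surface
  plane for all later frames, which keeps it in permanent head-bead
  contact.
* A *failed* capture attempt at the end of ``insertion_run_length - 1``
  successive anchor-contact snapshots detaches the anchor on the next
  snapshot.  Anchor-site contacts are therefore transient unless capture
  fires — the "made and lost contact before insertion" phenomenology — and
  the analysis-side insertion detector recovers the logged insertion frame
  exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .distances import nearest_distances, periodic_tree
from .model import ConfigurationError, Frame, Topology, Trajectory

LIPID_HEAD_BEADS = ("NH3", "PO4", "C1A", "C1B")
LIPID_TAIL_BEADS = ("GL1", "GL2", "C2A", "C3A", "C4A", "C2B", "C3B", "C4B")
LIPID_RESNAME = "POPE"
TAIL_SPACING = 0.3  # nm between successive tail beads
HEAD_Z_JITTER = 0.15  # nm, head beads stay within +-0.2 nm of the plane
KICK_CLEARANCE = 0.9  # nm above the plane after a detachment kick
TOP_MARGIN = 0.8  # nm kept clear below the box top (avoids z-wrap contacts)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic trajectory.

    Defaults mirror the reference study conditions: an ~11 x 11 x 17 nm box
    with 410 lipids, the protein started at a 7 nm centre-of-mass z-offset
    from the membrane, 500 snapshots at 2 ns, and a 163-residue monomer
    whose residue 70 carries the anchor.
    """

    box: tuple = (11.0, 11.0, 17.0)
    n_lipids: int = 410
    lipid_lattice_spacing: Optional[float] = None
    protein_model: str = "monomer"  # or "dimer"
    n_residues: int = 163
    beads_per_residue: int = 2
    radius_of_gyration: float = 2.0
    anchor_residue_index: int = 70
    anchored: bool = True
    initial_z_offset: float = 7.0
    translational_diffusion: float = 0.05  # nm^2/ns
    rotational_diffusion: float = 0.2  # rad^2/ns
    membrane_well_depth: float = 1.2  # nm/ns drift speed at the surface
    membrane_well_range: float = 1.5  # nm decay length of the attraction
    anchor_capture_distance: float = 0.6  # nm
    anchor_capture_hazard: float = 0.2  # per snapshot while in range
    contact_threshold: float = 0.6  # nm, ground-truth bookkeeping
    insertion_run_length: int = 3
    irreversible: bool = True
    timestep: float = 2.0  # ns per snapshot
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.anchor_capture_hazard <= 1.0):
            raise ConfigurationError("anchor_capture_hazard must be in [0, 1]")
        for name in (
            "radius_of_gyration",
            "initial_z_offset",
            "membrane_well_range",
            "anchor_capture_distance",
            "contact_threshold",
            "timestep",
        ):
            if getattr(self, name) < 0 or (
                name in ("radius_of_gyration", "membrane_well_range", "timestep")
                and getattr(self, name) <= 0
            ):
                raise ConfigurationError(f"{name} must be positive")
        if self.translational_diffusion < 0 or self.rotational_diffusion < 0:
            raise ConfigurationError("diffusion coefficients must be >= 0")
        if self.membrane_well_depth < 0:
            raise ConfigurationError("membrane_well_depth must be >= 0")
        if self.n_lipids < 1 or self.n_frames < 1 or self.n_residues < 2:
            raise ConfigurationError("n_lipids, n_frames >= 1 and n_residues >= 2")
        if self.beads_per_residue < 1:
            raise ConfigurationError("beads_per_residue must be >= 1")
        if not (1 <= self.anchor_residue_index <= self.n_residues):
            raise ConfigurationError("anchor_residue_index outside protein")
        if self.protein_model not in ("monomer", "dimer"):
            raise ConfigurationError("protein_model must be monomer or dimer")
        if self.anchored and self.anchor_capture_distance < self.contact_threshold:
            raise ConfigurationError(
                "anchor_capture_distance must be >= contact_threshold so that "
                "every anchor-contact snapshot is a capture attempt"
            )
        if self.insertion_run_length < 1:
            raise ConfigurationError("insertion_run_length must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["box"] = list(self.box)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "box" in d:
            d["box"] = tuple(d["box"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruthLog:
    """True event times emitted by the generator, for validating analysis."""

    trajectory_id: str
    true_first_contact_frame: Optional[int]
    true_insertion_frame: Optional[int]
    anchored_state: np.ndarray
    irreversible: bool = True

    def __post_init__(self) -> None:
        self.anchored_state = np.asarray(self.anchored_state, dtype=bool)
        if self.irreversible and self.true_insertion_frame is not None:
            after = self.anchored_state[self.true_insertion_frame :]
            if not np.all(after):
                raise ValueError("anchored_state must stay true after insertion")

    def to_dict(self) -> dict:
        return {
            "trajectory_id": self.trajectory_id,
            "true_first_contact_frame": self.true_first_contact_frame,
            "true_insertion_frame": self.true_insertion_frame,
            "anchored_state": self.anchored_state.astype(int).tolist(),
            "irreversible": self.irreversible,
        }


def _lattice_dims(config: SimConfig) -> tuple[int, int, float, float]:
    bx, by = config.box[0], config.box[1]
    if config.lipid_lattice_spacing is not None:
        s = config.lipid_lattice_spacing
        nx, ny = int(bx // s), int(by // s)
        if nx * ny < config.n_lipids:
            raise ConfigurationError(
                f"lattice overflow: {nx}x{ny} sites at spacing {s} nm cannot "
                f"hold {config.n_lipids} lipids; reduce the spacing below "
                f"{math.sqrt(bx * by / config.n_lipids):.3f} nm"
            )
        return nx, ny, bx / nx, by / ny
    nx = int(math.ceil(math.sqrt(config.n_lipids)))
    ny = int(math.ceil(config.n_lipids / nx))
    return nx, ny, bx / nx, by / ny


def membrane_surface_z(config: SimConfig) -> float:
    """z of the head-bead surface plane.

    The leaflet is placed so its centre of mass sits ``initial_z_offset``
    below the protein's initial centre of mass, with the protein starting
    at mid-box height.
    """
    # per-lipid mean bead z relative to the plane: 4 heads at 0, 8 tails below
    tail_mean = -TAIL_SPACING * sum(range(1, len(LIPID_TAIL_BEADS) + 1)) / (
        len(LIPID_HEAD_BEADS) + len(LIPID_TAIL_BEADS)
    )
    mem_com_target = config.box[2] / 2.0 - config.initial_z_offset
    return mem_com_target - tail_mean


def build_membrane(config: SimConfig) -> tuple[Topology, np.ndarray]:
    """Place lipids on a jittered square lattice; returns (topology, coords).

    Head beads lie within +-0.2 nm of the surface plane; tail beads hang
    below.  Lipid residue indices are 1-based within the membrane (callers
    composing a full system renumber them after the protein).
    """
    rng = np.random.default_rng([config.seed, 11])
    nx, ny, sx, sy = _lattice_dims(config)
    plane = membrane_surface_z(config)
    s = min(sx, sy)
    names, resids, resnames, mols = [], [], [], []
    coords = []
    placed = 0
    for iy in range(ny):
        for ix in range(nx):
            if placed >= config.n_lipids:
                break
            cx = (ix + 0.5) * sx + rng.uniform(-0.05 * s, 0.05 * s)
            cy = (iy + 0.5) * sy + rng.uniform(-0.05 * s, 0.05 * s)
            # four head beads in a small cross around the lipid centre
            off = 0.1 * s
            head_xy = [(0.0, 0.0), (off, 0.0), (0.0, off), (-off, 0.0)]
            for bn, (dx, dy) in zip(LIPID_HEAD_BEADS, head_xy):
                names.append(bn)
                coords.append(
                    (cx + dx, cy + dy, plane + rng.uniform(-HEAD_Z_JITTER, HEAD_Z_JITTER))
                )
            for k, bn in enumerate(LIPID_TAIL_BEADS, start=1):
                names.append(bn)
                coords.append((cx, cy, plane - TAIL_SPACING * k))
            n_beads = len(LIPID_HEAD_BEADS) + len(LIPID_TAIL_BEADS)
            resids.extend([placed + 1] * n_beads)
            resnames.extend([LIPID_RESNAME] * n_beads)
            mols.extend([placed] * n_beads)
            placed += 1
    top = Topology(names, resids, resnames, ["lipid"] * len(names), mols)
    return top, np.asarray(coords, dtype=float)


def build_protein(config: SimConfig) -> tuple[Topology, np.ndarray]:
    """Rigid random bead cloud standing in for the folded repeat domain.

    A fixed-step random walk defines the backbone; side-chain beads are
    short random offsets from it; the whole cloud is rescaled about its
    centre of mass to hit the radius-of-gyration target exactly.  Dimer
    mode appends a second copy rotated 180 degrees with the two anchor
    residues adjacent.  Fully deterministic in ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 22])
    n = config.n_residues
    bb = np.zeros((n, 3))
    step = 0.35
    for i in range(1, n):
        v = rng.normal(size=3)
        bb[i] = bb[i - 1] + step * v / np.linalg.norm(v)
    names, resids, resnames, coords = [], [], [], []
    for i in range(n):
        resid = i + 1
        resname = "CYS" if resid == config.anchor_residue_index else "ALA"
        names.append("BB")
        resids.append(resid)
        resnames.append(resname)
        coords.append(bb[i])
        for k in range(1, config.beads_per_residue):
            v = rng.normal(size=3)
            names.append(f"SC{k}")
            resids.append(resid)
            resnames.append(resname)
            coords.append(bb[i] + 0.25 * v / np.linalg.norm(v))
    coords = np.asarray(coords, dtype=float)
    coords -= coords.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum(coords**2, axis=1))))
    scale = config.radius_of_gyration / rg
    if scale < 0.02:
        raise ConfigurationError(
            f"radius_of_gyration target {config.radius_of_gyration} nm is "
            "unreachably small for this chain"
        )
    coords *= scale
    if config.protein_model == "dimer":
        # second subunit: 180-degree rotation about the x-axis through the
        # anchor side-chain bead, then a short shift so the anchors touch
        anchor_rows = [
            j for j in range(len(resids)) if resids[j] == config.anchor_residue_index
        ]
        pivot = coords[anchor_rows[-1]]
        rot = np.diag([1.0, -1.0, -1.0])
        coords2 = (coords - pivot) @ rot.T + pivot + np.array([0.4, 0.0, 0.0])
        names = names + list(names)
        resnames = resnames + list(resnames)
        resids = resids + [r + n for r in resids]
        mols = [0] * len(coords) + [1] * len(coords2)
        coords = np.vstack([coords, coords2])
        coords -= coords.mean(axis=0)
    else:
        mols = [0] * len(coords)
    top = Topology(names, resids, resnames, ["protein"] * len(names), mols)
    return top, coords


def compose_system(config: SimConfig) -> tuple[Topology, np.ndarray, np.ndarray, dict]:
    """Protein + membrane in one topology; returns (topology, protein
    coords, lipid coords, geometry info)."""
    prot_top, prot_xyz = build_protein(config)
    mem_top, mem_xyz = build_membrane(config)
    n_prot_res = int(prot_top.residue_indices.max())
    n_prot_mol = int(prot_top.molecule_ids.max()) + 1
    top = Topology(
        np.concatenate([prot_top.bead_names, mem_top.bead_names]),
        np.concatenate(
            [prot_top.residue_indices, mem_top.residue_indices + n_prot_res]
        ),
        np.concatenate([prot_top.residue_names, mem_top.residue_names]),
        np.concatenate([prot_top.groups, mem_top.groups]),
        np.concatenate([prot_top.molecule_ids, mem_top.molecule_ids + n_prot_mol]),
    )
    info = {"plane_z": membrane_surface_z(config), "n_protein_beads": len(prot_xyz)}
    return top, prot_xyz, mem_xyz, info


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a normalised random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def geometric_insertion_probability(hazard: float, n_attempts: int) -> float:
    """Closed-form probability that a geometric waiting time with
    per-attempt success probability ``hazard`` succeeds within
    ``n_attempts`` attempts."""
    return 1.0 - (1.0 - hazard) ** n_attempts


def simulate_trajectory(
    config: SimConfig, trajectory_id: str = "traj"
) -> tuple[Trajectory, GroundTruthLog]:
    """Run one rigid-body Brownian trajectory; fully seeded.

    The emitted trajectory has an initial frame at t=0 plus ``n_frames``
    snapshots at multiples of ``timestep``; ground-truth frame indices
    refer to the analysis snapshots (t=0 excluded), i.e. index i is the
    frame at t = (i+1) * timestep.
    """
    top, prot_xyz, mem_xyz, info = compose_system(config)
    rng = np.random.default_rng([config.seed, 33])
    box = np.asarray(config.box, dtype=float)
    plane = info["plane_z"]
    dt = config.timestep

    # initial placement: random orientation, COM at mid-box in x-y and
    # initial_z_offset above the membrane COM (i.e. mid-box height in z)
    prot = prot_xyz @ _random_rotation(rng).T
    com = np.array([box[0] / 2.0, box[1] / 2.0, box[2] / 2.0])
    prot = prot - prot.mean(axis=0) + com

    lipid_rows = top.lipid_indices
    prot_rows = top.protein_indices
    anchor_ids = (
        [config.anchor_residue_index, config.anchor_residue_index + config.n_residues]
        if config.protein_model == "dimer"
        else [config.anchor_residue_index]
    )
    anchor_rows_local = np.flatnonzero(
        np.isin(top.residue_indices[prot_rows], anchor_ids)
        & (top.groups[prot_rows] == "protein")
    )
    # the bead that gets pinned: last bead (side chain) of the first anchor residue
    pin_candidates = np.flatnonzero(
        top.residue_indices[prot_rows] == config.anchor_residue_index
    )
    pin_row = int(pin_candidates[-1])

    lipid_tree = periodic_tree(mem_xyz, box)
    head_rows_global = top.head_group_indices()
    head_local = head_rows_global - len(prot_rows)  # membrane coords offset
    head_tree = periodic_tree(mem_xyz[head_local], box)

    sigma_t = math.sqrt(2.0 * config.translational_diffusion * dt)
    sigma_r = math.sqrt(2.0 * config.rotational_diffusion * dt)

    frames = [
        Frame(time=0.0, box=box.copy(), coords=np.vstack([prot, mem_xyz]))
    ]
    inserted = False
    kick_pending = False
    contact_run = 0
    true_first_contact: Optional[int] = None
    true_insertion: Optional[int] = None
    inserted_from = 0
    state_per_frame = np.zeros(config.n_frames, dtype=bool)

    for i in range(config.n_frames):
        # rigid-body update
        disp = rng.normal(0.0, sigma_t, size=3) if sigma_t > 0 else np.zeros(3)
        angle = rng.normal(0.0, sigma_r) if sigma_r > 0 else 0.0
        axis = rng.normal(size=3)
        com = prot.mean(axis=0)
        rel = prot - com
        if angle != 0.0:
            rel = rel @ _axis_angle_rotation(axis, angle).T
        h = max(com[2] - plane, 0.0)
        drift = -config.membrane_well_depth * dt * math.exp(-h / config.membrane_well_range)
        com = com + disp + np.array([0.0, 0.0, drift])
        prot = rel + com
        # soft wall at the surface plane and reflection margin at the box top
        low = prot[:, 2].min()
        if not inserted and low < plane:
            prot[:, 2] += plane - low
        high = prot[:, 2].max()
        if high > box[2] - TOP_MARGIN:
            prot[:, 2] -= high - (box[2] - TOP_MARGIN)
        if kick_pending and not inserted:
            a_low = prot[anchor_rows_local, 2].min()
            if a_low < plane + KICK_CLEARANCE:
                prot[:, 2] += plane + KICK_CLEARANCE - a_low
            kick_pending = False
        if inserted:
            prot[:, 2] += plane - prot[pin_row, 2]

        d_all = nearest_distances(prot, box, tree=lipid_tree)
        d_anchor_head = float(
            np.min(nearest_distances(prot[anchor_rows_local], box, tree=head_tree))
        )
        fired = False
        if (
            config.anchored
            and not inserted
            and d_anchor_head < config.anchor_capture_distance
        ):
            if rng.random() < config.anchor_capture_hazard:
                fired = True
                inserted = True
                prot[:, 2] += plane - prot[pin_row, 2]
                d_all = nearest_distances(prot, box, tree=lipid_tree)
        d_anchor = float(d_all[anchor_rows_local].min())
        d_prot = float(d_all.min())

        anchor_contact = d_anchor < config.contact_threshold
        contact_run = contact_run + 1 if anchor_contact else 0
        if fired:
            if true_insertion is None:
                true_insertion = i - (contact_run - 1)
            inserted_from = i - (contact_run - 1)
        elif not inserted and anchor_contact and contact_run >= config.insertion_run_length - 1:
            # transient anchor-site contact must not masquerade as insertion
            kick_pending = True
        if true_first_contact is None and d_prot < config.contact_threshold:
            true_first_contact = i
        state_per_frame[i] = inserted
        if inserted and fired:
            state_per_frame[inserted_from : i + 1] = True
        if inserted and not config.irreversible and not fired:
            # reversible tether: release with the capture hazard per snapshot
            if rng.random() < config.anchor_capture_hazard:
                inserted = False
                kick_pending = True
                contact_run = 0

        frames.append(
            Frame(
                time=(i + 1) * dt,
                box=box.copy(),
                coords=np.vstack([prot, mem_xyz]),
            )
        )

    if (
        true_insertion is not None
        and true_insertion + config.insertion_run_length > config.n_frames
    ):
        # the capture fired too close to the end of the run for the
        # required number of successive snapshots to be observed; by the
        # event definition no insertion event occurred in this trajectory
        true_insertion = None
    anchored_state = state_per_frame
    if config.irreversible and true_insertion is not None:
        anchored_state[true_insertion:] = True
    traj = Trajectory(
        topology=top,
        frames=frames,
        provenance={
            "generator": "memassoc.synth",
            "seed": config.seed,
            "config": config.to_dict(),
            "trajectory_id": trajectory_id,
        },
    )
    log = GroundTruthLog(
        trajectory_id=trajectory_id,
        true_first_contact_frame=true_first_contact,
        true_insertion_frame=true_insertion,
        anchored_state=anchored_state,
        irreversible=config.irreversible,
    )
    return traj, log


def ensemble_configs(
    config: SimConfig, n_trajectories: int, base_seed: int
) -> list[tuple[SimConfig, str]]:
    """Per-trajectory (config, id) pairs with seeds ``base_seed + i``."""
    if n_trajectories < 1:
        raise ConfigurationError("n_trajectories must be >= 1")
    return [
        (
            dataclasses.replace(config, seed=int((base_seed + i) % 2**31)),
            f"traj{i:04d}",
        )
        for i in range(n_trajectories)
    ]


def run_ensemble(
    config: SimConfig, n_trajectories: int, base_seed: int
) -> tuple[list[Trajectory], list[GroundTruthLog]]:
    """Independent trajectories with seeds ``base_seed + i`` (mod 2^31).

    Holds the whole ensemble in memory; for large systems iterate over
    :func:`ensemble_configs` and process trajectories one at a time.
    """
    trajs, logs = [], []
    for cfg, tid in ensemble_configs(config, n_trajectories, base_seed):
        t, g = simulate_trajectory(cfg, trajectory_id=tid)
        trajs.append(t)
        logs.append(g)
    return trajs, logs


def write_ground_truth(logs: list[GroundTruthLog], path) -> None:
    Path(path).write_text(
        json.dumps([g.to_dict() for g in logs], indent=2) + "\n"
    )
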