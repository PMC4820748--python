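"""Readers and writers for multi-model GRO, a whitespace XYZ dialect, and
JSON sidecars.

GRO models are fixed-column (resid 5, resname 5, atom name 5, atom id 5,
then 8.3f coordinates in nm); concatenated models form a trajectory.  Frame
times are read from a ``t=`` token in the title line (ps, converted to ns);
models without one are assigned ``frame_order * default_spacing_ns``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import numpy as np

from .model import Bead, FormatError, Frame, Topology, Trajectory

_T_TOKEN = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_gro_model(lines: list[str], start: int, model_index: int):
    """Parse one GRO model starting at line ``start``; return
    (title, names, resids, resnames, coords, box, next_start)."""
    title = lines[start].rstrip("\n")
    try:
        natoms = int(lines[start + 1].strip())
    except (ValueError, IndexError) as exc:
        raise FormatError(
            f"model {model_index}: malformed atom count line"
        ) from exc
    end = start + 2 + natoms
    if end >= len(lines) + 1 or len(lines) < end + 1:
        raise FormatError(f"model {model_index}: truncated (expected {natoms} atoms)")
    names, resids, resnames = [], [], []
    coords = np.empty((natoms, 3), dtype=float)
    for i in range(natoms):
        ln = lines[start + 2 + i]
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            coords[i, 0] = float(ln[20:28])
            coords[i, 1] = float(ln[28:36])
            coords[i, 2] = float(ln[36:44])
        except ValueError as exc:
            raise FormatError(
                f"model {model_index}: malformed atom record at line {start + 3 + i}"
            ) from exc
    box_fields = lines[end].split()
    try:
        box_vals = [float(x) for x in box_fields]
    except ValueError as exc:
        raise FormatError(f"model {model_index}: malformed box line") from exc
    if len(box_vals) < 3:
        raise FormatError(f"model {model_index}: box line needs >= 3 components")
    if len(box_vals) > 3 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise FormatError(
            f"model {model_index}: triclinic box (off-diagonal components) "
            "is not supported"
        )
    box = np.asarray(box_vals[:3], dtype=float)
    return title, names, resids, resnames, coords, box, end + 1


def _molecule_ids(resids: list[int], resnames: list[str]) -> list[int]:
    """Heuristic molecule numbering: a new molecule starts whenever the
    residue changes; callers with multi-residue molecules (proteins) should
    renumber after group assignment if they care."""
    mol = []
    current = -1
    prev = None
    for key in zip(resids, resnames):
        if key != prev:
            current += 1
            prev = key
        mol.append(current)
    return mol


def read_gro_trajectory(path, default_spacing_ns: float = 2.0) -> Trajectory:
    """Read a (possibly multi-model) GRO file into a :class:`Trajectory`.

    The topology (bead/residue names and indices) comes from the first
    model; all beads are provisionally labelled ``protein`` — run
    :func:`memassoc.model.assign_groups` to partition them.
    """
    lines = Path(path).read_text().splitlines()
    pos = 0
    model_index = 0
    topology: Optional[Topology] = None
    frames: list[Frame] = []
    any_time_token = False
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break
        title, names, resids, resnames, coords, box, pos = _parse_gro_model(
            lines, pos, model_index
        )
        if topology is None:
            topology = Topology(
                names,
                resids,
                resnames,
                ["protein"] * len(names),
                _molecule_ids(resids, resnames),
            )
        elif len(names) != topology.n_beads:
            raise FormatError(
                f"model {model_index}: bead count {len(names)} differs from "
                f"first model ({topology.n_beads})"
            )
        m = _T_TOKEN.search(title)
        if m:
            any_time_token = True
            time_ns = float(m.group(1)) / 1000.0  # GRO titles carry ps
        else:
            time_ns = model_index * default_spacing_ns
        frames.append(Frame(time=time_ns, box=box, coords=coords))
        model_index += 1
    if topology is None:
        raise FormatError("empty GRO file")
    return Trajectory(
        topology=topology,
        frames=frames,
        provenance={"source": str(path), "time_tokens": any_time_token},
    )


def write_gro_trajectory(trajectory: Trajectory, path, title: str = "memassoc") -> None:
    """Write a trajectory as concatenated GRO models (times as ``t=`` in ps)."""
    top = trajectory.topology
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            fh.write(f"{title} t= {fr.time * 1000.0:.3f}\n")
            fh.write(f"{top.n_beads:5d}\n")
            for i in range(top.n_beads):
                resid = int(top.residue_indices[i]) % 100000
                atomid = (i + 1) % 100000
                fh.write(
                    f"{resid:5d}{str(top.residue_names[i]):<5.5s}"
                    f"{str(top.bead_names[i]):>5.5s}{atomid:5d}"
                    f"{fr.coords[i, 0]:8.3f}{fr.coords[i, 1]:8.3f}{fr.coords[i, 2]:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def read_xyz_trajectory(path) -> Trajectory:
    """Read the whitespace XYZ dialect.

    Per frame: a header line ``time_ns n_beads box_x box_y box_z`` followed
    by ``n_beads`` rows of ``bead_name residue_index residue_name x y z``.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    pos = 0
    frame_index = 0
    topology: Optional[Topology] = None
    frames: list[Frame] = []
    while pos < len(lines):
        head = lines[pos].split()
        if len(head) != 5:
            raise FormatError(f"frame {frame_index}: bad header line")
        try:
            time_ns = float(head[0])
            n = int(head[1])
            box = np.asarray([float(x) for x in head[2:5]])
        except ValueError as exc:
            raise FormatError(f"frame {frame_index}: bad header line") from exc
        if pos + 1 + n > len(lines):
            raise FormatError(f"frame {frame_index}: truncated")
        names, resids, resnames = [], [], []
        coords = np.empty((n, 3), dtype=float)
        for i in range(n):
            f = lines[pos + 1 + i].split()
            if len(f) != 6:
                raise FormatError(f"frame {frame_index}: bad bead row {i}")
            names.append(f[0])
            resids.append(int(f[1]))
            resnames.append(f[2])
            coords[i] = [float(f[3]), float(f[4]), float(f[5])]
        if topology is None:
            topology = Topology(
                names, resids, resnames, ["protein"] * n, _molecule_ids(resids, resnames)
            )
        elif n != topology.n_beads:
            raise FormatError(
                f"frame {frame_index}: bead count {n} differs from first frame"
            )
        frames.append(Frame(time=time_ns, box=box, coords=coords))
        pos += 1 + n
        frame_index += 1
    if topology is None:
        raise FormatError("empty XYZ file")
    return Trajectory(topology=topology, frames=frames, provenance={"source": str(path)})


def write_xyz_trajectory(trajectory: Trajectory, path) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            fh.write(
                f"{fr.time:.6f} {top.n_beads} "
                f"{fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}\n"
            )
            for i in range(top.n_beads):
                fh.write(
                    f"{top.bead_names[i]} {top.residue_indices[i]} "
                    f"{top.residue_names[i]} "
                    f"{fr.coords[i, 0]:.6f} {fr.coords[i, 1]:.6f} {fr.coords[i, 2]:.6f}\n"
                )


def topology_summary(topology: Topology) -> dict:
    """JSON-serialisable summary of a topology (counts per group/residue)."""
    return {
        "n_beads": topology.n_beads,
        "group_counts": topology.group_counts(),
        "n_protein_residues": int(len(topology.protein_residue_ids())),
        "n_molecules": int(len(np.unique(topology.molecule_ids))),
    }


def write_topology_summary(topology: Topology, path) -> None:
    Path(path).write_text(json.dumps(topology_summary(topology), indent=2) + "\n")
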