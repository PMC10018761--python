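"""Trajectory containers and I/O.

Units at the API boundary are fixed: lengths in nm, times in ns, stress in
GPa, energies in kJ mol^-1.  Readers convert on the way in (e.g. MDAnalysis
works in Angstrom/ps), writers on the way out.

Only orthorhombic periodic boxes are supported; the simulation cells this
toolkit targets are rectangular and triclinic minimum-image handling would
add complexity without payoff here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "Trajectory",
    "ThermoSeries",
    "StressStrainTable",
    "TrajectoryError",
    "read_trajectory",
    "write_internal_csv",
    "read_internal_csv",
    "write_xyz",
    "read_xyz",
    "write_gro_xtc",
    "read_gro_xtc",
    "unwrap",
    "wrap",
    "WATER_RESIDUES",
]

#: residue names tagged as water when reading topology-bearing formats
WATER_RESIDUES = frozenset({"SOL", "HOH", "WAT"})

_UNIFORM_RTOL = 1e-6


class TrajectoryError(ValueError):
    """Malformed trajectory data or unsupported geometry."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (3,):
            raise TrajectoryError(f"box lengths must be a 3-vector, got shape {lengths.shape}")
        if not np.all(lengths > 0):
            raise TrajectoryError(f"box lengths must be positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @classmethod
    def cubic(cls, length: float) -> "Box":
        return cls(np.full(3, float(length)))

    @classmethod
    def from_lengths_angles(cls, lengths, angles) -> "Box":
        """Build from (lx, ly, lz, alpha, beta, gamma); rejects non-orthorhombic cells."""
        angles = np.asarray(angles, dtype=float)
        if not np.allclose(angles, 90.0, atol=1e-3):
            raise TrajectoryError(
                f"only orthorhombic boxes are supported (angles {angles} != 90)"
            )
        return cls(np.asarray(lengths, dtype=float))

    @property
    def min_length(self) -> float:
        return float(self.lengths.min())


@dataclass
class Trajectory:
    """Per-molecule, time-ordered positions under periodic boundaries.

    Attributes
    ----------
    times : (n_frames,) float array, ns; strictly increasing, uniform spacing.
    positions : (n_molecules, n_frames, 3) float array, nm.
    box : (n_frames, 3) float array of box edge lengths, nm.
    mol_ids : (n_molecules,) int array.
    species : optional (n_molecules,) array of tags ("water", "polymer", ...).
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    mol_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    species: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError(
                f"positions must have shape (n_molecules, n_frames, 3), got {self.positions.shape}"
            )
        n_mol, n_frames, _ = self.positions.shape
        if self.times.shape != (n_frames,):
            raise TrajectoryError(
                f"times length {self.times.shape} does not match frame count {n_frames}"
            )
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (n_frames, 3)).copy()
        if box.shape != (n_frames, 3):
            raise TrajectoryError(f"box must have shape (n_frames, 3), got {box.shape}")
        if not np.all(box > 0):
            raise TrajectoryError("box lengths must be positive")
        self.box = box
        if self.mol_ids is None:
            self.mol_ids = np.arange(n_mol)
        else:
            self.mol_ids = np.asarray(self.mol_ids)
            if self.mol_ids.shape != (n_mol,):
                raise TrajectoryError("mol_ids length does not match molecule count")
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=object)
            if self.species.shape != (n_mol,):
                raise TrajectoryError("species length does not match molecule count")
        if n_frames > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise TrajectoryError("times must be strictly increasing")
            mean_dt = dt.mean()
            if np.any(np.abs(dt - mean_dt) > _UNIFORM_RTOL * mean_dt):
                raise TrajectoryError(
                    "frame spacing must be uniform to relative tolerance 1e-6"
                )
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("positions contain non-finite values")

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame_box(self, k: int) -> Box:
        return Box(self.box[k])

    def select_species(self, tag: str) -> "Trajectory":
        """Sub-trajectory of molecules carrying a given species tag."""
        if self.species is None:
            raise TrajectoryError("trajectory carries no species tags")
        mask = self.species == tag
        return Trajectory(
            times=self.times,
            positions=self.positions[mask],
            box=self.box,
            mol_ids=self.mol_ids[mask],
            species=self.species[mask],
        )


@dataclass
class ThermoSeries:
    """Per-frame thermodynamic observables: U (kJ/mol), P (bar), V (nm^3), T (K)."""

    U: np.ndarray
    P: np.ndarray
    V: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        n = len(self.U)
        if not (len(self.P) == len(self.V) == len(self.T) == n):
            raise ValueError("U, P, V, T series must have equal length")
        if not np.all(self.V > 0):
            raise ValueError("volumes must be positive")
        if not np.all(self.T > 0):
            raise ValueError("temperatures must be positive")

    def __len__(self) -> int:
        return len(self.U)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"U_kJ_mol": self.U, "P_bar": self.P, "V_nm3": self.V, "T_K": self.T}
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str) -> "ThermoSeries":
        df = pd.read_csv(path)
        return cls(
            U=df["U_kJ_mol"].to_numpy(),
            P=df["P_bar"].to_numpy(),
            V=df["V_nm3"].to_numpy(),
            T=df["T_K"].to_numpy(),
        )


@dataclass
class StressStrainTable:
    """Uniaxial tensile test record: strain (dimensionless) vs stress (GPa)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be matching 1-D arrays")
        if np.any(self.strain < 0):
            raise ValueError("strain must be non-negative")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")

    def __len__(self) -> int:
        return len(self.strain)

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"strain": self.strain, "stress_GPa": self.stress}).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path: str) -> "StressStrainTable":
        df = pd.read_csv(path)
        return cls(strain=df["strain"].to_numpy(), stress=df["stress_GPa"].to_numpy())


# ---------------------------------------------------------------------------
# periodic wrapping / unwrapping
# ---------------------------------------------------------------------------

def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps so displacements are continuous.

    Assumes every frame-to-frame move is smaller than half the box along each
    axis (minimum-image validity).  A corrected displacement reaching half the
    box is ambiguous and raises, naming the offending molecule and frame.
    """
    pos = traj.positions
    if traj.n_frames < 2:
        return Trajectory(traj.times, pos.copy(), traj.box.copy(), traj.mol_ids, traj.species)
    disp = np.diff(pos, axis=1)                       # (M, N-1, 3)
    L = traj.box[1:][np.newaxis, :, :]                # box of the later frame
    shift = np.round(disp / L)
    corr = disp - shift * L
    bad = np.abs(corr) >= 0.5 * L * (1 - 1e-12)
    if np.any(bad):
        m, k, ax = np.argwhere(bad)[0]
        raise TrajectoryError(
            f"displacement of molecule {traj.mol_ids[m]} between frames {k} and {k + 1} "
            f"reaches half the box along axis {ax}; minimum-image unwrapping is ambiguous"
        )
    out = np.empty_like(pos)
    out[:, 0] = pos[:, 0]
    np.cumsum(corr, axis=1, out=corr)
    out[:, 1:] = pos[:, :1] + corr
    return Trajectory(traj.times, out, traj.box.copy(), traj.mol_ids, traj.species)


def wrap(traj: Trajectory) -> Trajectory:
    """Fold all coordinates back into the primary box [0, L) per frame."""
    L = traj.box[np.newaxis, :, :]
    pos = traj.positions - np.floor(traj.positions / L) * L
    return Trajectory(traj.times, pos, traj.box.copy(), traj.mol_ids, traj.species)


# ---------------------------------------------------------------------------
# internal columnar format
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "mol_id", "frame", "time_ns",
    "x_nm", "y_nm", "z_nm",
    "bx_nm", "by_nm", "bz_nm",
    "species",
]


def write_internal_csv(traj: Trajectory, path: str) -> None:
    """Write the diffable text trajectory format (one row per molecule-frame)."""
    n_mol, n_frames, _ = traj.positions.shape
    mol = np.repeat(np.asarray(traj.mol_ids), n_frames)
    frame = np.tile(np.arange(n_frames), n_mol)
    time = np.tile(traj.times, n_mol)
    xyz = traj.positions.reshape(n_mol * n_frames, 3)
    box = np.tile(traj.box, (n_mol, 1))
    species = (
        np.repeat(np.asarray(traj.species, dtype=object), n_frames)
        if traj.species is not None
        else np.repeat("", n_mol * n_frames)
    )
    df = pd.DataFrame(
        {
            "mol_id": mol,
            "frame": frame,
            "time_ns": time,
            "x_nm": xyz[:, 0],
            "y_nm": xyz[:, 1],
            "z_nm": xyz[:, 2],
            "bx_nm": box[:, 0],
            "by_nm": box[:, 1],
            "bz_nm": box[:, 2],
            "species": species,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_internal_csv(path: str) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise TrajectoryError(f"internal CSV missing columns: {missing}")
    df = df.sort_values(["mol_id", "frame"], kind="mergesort")
    mol_ids = df["mol_id"].unique()
    frames = np.sort(df["frame"].unique())
    n_mol, n_frames = len(mol_ids), len(frames)
    if len(df) != n_mol * n_frames:
        raise TrajectoryError("every molecule must be present in every frame")
    xyz = df[["x_nm", "y_nm", "z_nm"]].to_numpy().reshape(n_mol, n_frames, 3)
    first = df.iloc[:n_frames]
    times = first["time_ns"].to_numpy()
    box = first[["bx_nm", "by_nm", "bz_nm"]].to_numpy()
    species = None
    if "species" in df.columns and not df["species"].isna().all():
        species = df["species"].to_numpy()[::n_frames].astype(object)
    return Trajectory(times=times, positions=xyz, box=box, mol_ids=mol_ids, species=species)


# ---------------------------------------------------------------------------
# XYZ dialect with a box comment line
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str) -> None:
    """XYZ stream; the comment line carries ``time=<ns> box=<bx> <by> <bz>`` (nm)."""
    n_mol = traj.n_molecules
    species = traj.species if traj.species is not None else ["X"] * n_mol
    with open(path, "w", encoding="utf-8") as fh:
        for k in range(traj.n_frames):
            bx, by, bz = traj.box[k]
            fh.write(f"{n_mol}\n")
            fh.write(f"time={traj.times[k]:.17g} box={bx:.17g} {by:.17g} {bz:.17g}\n")
            for m in range(n_mol):
                x, y, z = traj.positions[m, k]
                fh.write(f"{species[m]} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path: str) -> Trajectory:
    times, boxes, frames_pos = [], [], []
    species = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        fields = dict()
        tokens = comment.replace("=", " = ").split()
        if "box" not in comment:
            raise TrajectoryError("box required: XYZ comment line must carry 'box=bx by bz'")
        # parse "time=<t>" and "box=<bx> <by> <bz>"
        t = None
        box = None
        j = 0
        while j < len(tokens):
            if tokens[j] == "time" and tokens[j + 1] == "=":
                t = float(tokens[j + 2])
                j += 3
            elif tokens[j] == "box" and tokens[j + 1] == "=":
                box = [float(tokens[j + 2]), float(tokens[j + 3]), float(tokens[j + 4])]
                j += 5
            else:
                j += 1
        if box is None:
            raise TrajectoryError("box required: XYZ comment line must carry 'box=bx by bz'")
        times.append(len(times) * 1.0 if t is None else t)
        boxes.append(box)
        sp, pos = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            sp.append(parts[0])
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if species is None:
            species = sp
        frames_pos.append(pos)
        i += 2 + n
    positions = np.asarray(frames_pos, dtype=float).transpose(1, 0, 2)
    return Trajectory(
        times=np.asarray(times),
        positions=positions,
        box=np.asarray(boxes),
        species=np.asarray(species, dtype=object),
    )


# ---------------------------------------------------------------------------
# GRO + XTC via MDAnalysis
# ---------------------------------------------------------------------------

def write_gro_xtc(traj: Trajectory, gro_path: str, xtc_path: str) -> None:
    """Write a one-site-per-molecule GRO topology and XTC coordinate stream."""
    import MDAnalysis as mda

    n = traj.n_molecules
    species = traj.species if traj.species is not None else np.repeat("water", n)
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n),
        residue_segindex=np.zeros(n, dtype=int), trajectory=True,
    )
    names = ["OW" if s == "water" else "C1" for s in species]
    resnames = ["SOL" if s == "water" else "POL" for s in species]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    ts = u.trajectory.ts
    ts.positions = traj.positions[:, 0] * 10.0  # nm -> Angstrom
    ts.dimensions = [*(traj.box[0] * 10.0), 90.0, 90.0, 90.0]
    u.atoms.write(gro_path)
    with mda.Writer(xtc_path, n) as writer:
        for k in range(traj.n_frames):
            ts.positions = traj.positions[:, k] * 10.0
            ts.dimensions = [*(traj.box[k] * 10.0), 90.0, 90.0, 90.0]
            ts.frame = k
            ts.time = traj.times[k] * 1000.0        # ns -> ps
            writer.write(u.atoms)


def read_gro_xtc(
    topology: str, trajectory: str, water_residues=WATER_RESIDUES
) -> Trajectory:
    """Read a GRO+XTC pair; one site per atom, species tagged from residue names."""
    import MDAnalysis as mda

    u = mda.Universe(topology, trajectory)
    species = np.asarray(
        ["water" if r in water_residues else "polymer" for r in u.atoms.resnames],
        dtype=object,
    )
    times, boxes, pos = [], [], []
    for ts in u.trajectory:
        if ts.dimensions is None:
            raise TrajectoryError("box required: XTC frame carries no dimensions")
        if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
            raise TrajectoryError(
                f"only orthorhombic boxes are supported (angles {ts.dimensions[3:]})"
            )
        times.append(ts.time / 1000.0)
        boxes.append(ts.dimensions[:3] / 10.0)
        pos.append(ts.positions / 10.0)
    positions = np.asarray(pos, dtype=float).transpose(1, 0, 2)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        positions=positions,
        box=np.asarray(boxes, dtype=float),
        mol_ids=u.atoms.ids,
        species=species,
    )


def read_trajectory(
    path: str,
    format_hint: str | None = None,
    *,
    topology: str | None = None,
    water_residues=WATER_RESIDUES,
) -> Trajectory:
    """Read a trajectory, dispatching on ``format_hint`` or the file extension.

    Supported: internal columnar CSV, XYZ-with-box, and GRO+XTC pairs (pass the
    XTC as ``path`` and the GRO as ``topology``).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".csv": "internal", ".xyz": "xyz", ".xtc": "xtc", ".gro": "gro"}.get(ext)
    if fmt in ("internal", "csv"):
        return read_internal_csv(path)
    if fmt == "xyz":
        return read_xyz(path)
    if fmt in ("xtc", "gro-xtc"):
        if topology is None:
            raise TrajectoryError("reading XTC requires a GRO topology path")
        return read_gro_xtc(topology, path, water_residues=water_residues)
    raise TrajectoryError(f"unrecognized trajectory format for {path!r} (hint={format_hint!r})")
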