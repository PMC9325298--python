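"""Coordinate-trajectory container and standard-format I/O.

The in-memory :class:`Trajectory` holds time-ordered frames of atom
coordinates (nm) in an orthorhombic periodic box together with an
atom -> (lipid, species, atom label, moiety) mapping.  Reading and writing of
standard MD formats (GRO/PDB topologies, XTC/TRR/DCD frames) is delegated to
MDAnalysis; the species/moiety mapping is supplied as a YAML table (see
:mod:`micellekin.species`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import LipidSpecies, DEFAULT_SPECIES
from .utils import wrap_coords


def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) from ``a`` to ``b`` (nm).

    Works on broadcastable arrays of shape (..., 3); the box is orthorhombic.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between points under periodic boundaries."""
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class Trajectory:
    """Time-ordered coordinate frames plus the atom -> lipid/species mapping.

    Attributes
    ----------
    times : (F,) frame times in ns.
    coords : (F, A, 3) atom coordinates in nm.
    boxes : (F, 3) orthorhombic box edge lengths in nm.
    atoms : DataFrame indexed by atom id with columns ``lipid_id``,
        ``species``, ``atom_label`` and ``moiety`` (None for tail atoms).
    """

    times: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray
    atoms: pd.DataFrame
    species: dict[str, LipidSpecies] = field(default_factory=lambda: dict(DEFAULT_SPECIES))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.coords) or len(self.boxes) != len(self.coords):
            raise ValueError("times, coords and boxes must agree on frame count")
        if np.any(self.boxes <= 0):
            raise ValueError("box lengths must be positive")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table does not match coordinate atom count")
        counts = self.atoms.groupby("lipid_id").size()
        if (counts < 1).any():
            raise ValueError("every lipid needs at least one atom")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def lipid_ids(self) -> np.ndarray:
        """Sorted unique lipid ids."""
        return np.unique(self.atoms["lipid_id"].to_numpy())

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)

    def species_of_lipid(self) -> pd.Series:
        """Series mapping lipid id -> species name."""
        return self.atoms.groupby("lipid_id")["species"].first()

    def dt(self) -> float:
        """Median frame spacing in ns (0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def atom_indices_of_lipid(self, lipid_id: int) -> np.ndarray:
        return np.flatnonzero(self.atoms["lipid_id"].to_numpy() == lipid_id)

    def head_atom_index(self, lipid_id: int) -> int:
        """Index of the lipid's prominent head atom."""
        sp = self.species[self.atoms.loc[self.atom_indices_of_lipid(lipid_id)[0], "species"]]
        idx = self.atom_indices_of_lipid(lipid_id)
        labels = self.atoms.loc[idx, "atom_label"].to_numpy()
        hit = idx[labels == sp.prominent_head_atom]
        if len(hit) != 1:
            raise ValueError(f"lipid {lipid_id}: prominent head atom not unique")
        return int(hit[0])

    def tail_atom_index(self, lipid_id: int) -> int:
        """Index of the lipid's terminal tail atom."""
        sp = self.species[self.atoms.loc[self.atom_indices_of_lipid(lipid_id)[0], "species"]]
        idx = self.atom_indices_of_lipid(lipid_id)
        labels = self.atoms.loc[idx, "atom_label"].to_numpy()
        hit = idx[labels == sp.terminal_tail_atom]
        if len(hit) != 1:
            raise ValueError(f"lipid {lipid_id}: terminal tail atom not unique")
        return int(hit[0])


def write_trajectory(traj: Trajectory, topology_path, trajectory_path=None) -> None:
    """Write a trajectory as a GRO coordinate file plus an XTC frame file.

    ``topology_path`` receives the first frame (GRO); if ``trajectory_path``
    is given, all frames are written there (format chosen by extension, e.g.
    ``.xtc``).  Coordinates are converted from nm to Angstrom for MDAnalysis.
    """
    import MDAnalysis as mda

    n_lipids = traj.n_lipids
    u = mda.Universe.empty(
        n_atoms=traj.n_atoms,
        n_residues=n_lipids,
        atom_resindex=pd.factorize(traj.atoms["lipid_id"], sort=True)[0],
        trajectory=True,
    )
    u.add_TopologyAttr("names", traj.atoms["atom_label"].tolist())
    resnames = traj.atoms.groupby("lipid_id")["species"].first().sort_index().tolist()
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(range(1, n_lipids + 1)))

    def _load(i):
        u.atoms.positions = traj.coords[i] * 10.0  # nm -> A
        u.dimensions = [*(traj.boxes[i] * 10.0), 90.0, 90.0, 90.0]
        u.trajectory.ts.time = traj.times[i] * 1000.0  # ns -> ps

    _load(0)
    u.atoms.write(str(topology_path))
    if trajectory_path is not None:
        with mda.Writer(str(trajectory_path), n_atoms=traj.n_atoms) as w:
            for i in range(traj.n_frames):
                _load(i)
                w.write(u.atoms)


def read_trajectory(topology_path, trajectory_path=None, species=None) -> Trajectory:
    """Read a coordinate + trajectory file pair into a :class:`Trajectory`.

    Residue names must match species names in ``species`` (defaults to the
    five built-in lipid types); lipid ids are assigned in residue order.
    """
    import MDAnalysis as mda

    species = dict(species) if species is not None else dict(DEFAULT_SPECIES)
    args = [str(topology_path)] + ([str(trajectory_path)] if trajectory_path else [])
    u = mda.Universe(*args)
    resnames = [r.resname for r in u.residues]
    unknown = sorted(set(resnames) - set(species))
    if unknown:
        raise ValueError(f"residues with no species-table entry: {unknown}")
    rows = []
    for lipid_id, res in enumerate(u.residues):
        for atom in res.atoms:
            label = atom.name
            sp = species[res.resname]
            rows.append(
                {
                    "lipid_id": lipid_id,
                    "species": res.resname,
                    "atom_label": label,
                    "moiety": sp.moiety_of_atom.get(label),
                }
            )
    atoms = pd.DataFrame(rows)
    times, coords, boxes = [], [], []
    for ts in u.trajectory:
        times.append(ts.time / 1000.0)  # ps -> ns
        coords.append(u.atoms.positions / 10.0)  # A -> nm
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
    coords = np.asarray(coords)
    boxes = np.asarray(boxes)
    coords = np.stack([wrap_coords(c, b) for c, b in zip(coords, boxes)])
    return Trajectory(np.asarray(times), coords, boxes, atoms, species)
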