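"""Distance-cutoff cluster detection under periodic boundaries and tracking.

Two lipids belong to the same cluster when their minimum inter-atomic
minimum-image distance is at or below a cutoff (default 0.24 nm, twice the
hydrogen van der Waals radius, i.e. the closest approach of two lipid
molecules in contact).  Clusters are the connected components of that contact
graph (single linkage).  Neighbour search uses a periodic KD-tree, which is
contractually identical to the all-pairs computation.

Cluster identities are tracked across frames by maximal member overlap:
a fusion product inherits the id of the larger parent; on fission the id
stays with the fragment sharing most members.  Ties break deterministically
towards the fragment/parent containing the lowest lipid id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .trajectory import Trajectory
from .utils import counts_to_molar, moving_average, wrap_coords


@dataclass
class ClusterSnapshot:
    """Per-frame lipid partition.

    ``clusters`` is a list of disjoint frozensets of lipid ids covering every
    lipid (singletons included), ordered by their lowest member id.
    """

    time: float
    clusters: list[frozenset]
    compositions: list[dict]  # per cluster: species -> fraction
    box: np.ndarray

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def cluster_of(self) -> dict:
        """Mapping lipid id -> index of its cluster in ``clusters``."""
        return {lip: i for i, c in enumerate(self.clusters) for lip in c}

    def validate(self, n_lipids: int | None = None) -> None:
        seen: set = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("cluster sets are not disjoint")
            seen |= c
        if n_lipids is not None and len(seen) != n_lipids:
            raise ValueError("partition does not cover all lipids")
        for comp in self.compositions:
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError("composition fractions must sum to 1")


def cluster_partition(
    traj: Trajectory, frame: int, cutoff: float = 0.24
) -> ClusterSnapshot:
    """Partition the lipids of one frame into distance-cutoff clusters.

    All atoms participate in the contact criterion.  Deterministic and
    independent of lipid ordering (the partition is a set of sets).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    box = traj.boxes[frame]
    coords = wrap_coords(traj.coords[frame], box)
    lipid_of_atom = traj.atoms["lipid_id"].to_numpy()
    lipids = traj.lipid_ids
    lidx = {lip: i for i, lip in enumerate(lipids)}

    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        li = np.vectorize(lidx.get)(lipid_of_atom[pairs[:, 0]])
        lj = np.vectorize(lidx.get)(lipid_of_atom[pairs[:, 1]])
        keep = li != lj
        li, lj = li[keep], lj[keep]
    else:
        li = lj = np.array([], dtype=int)
    n = len(lipids)
    adj = coo_matrix((np.ones(len(li)), (li, lj)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)

    species_of = traj.species_of_lipid()
    clusters = []
    for lab in range(labels.max() + 1):
        members = frozenset(int(lipids[i]) for i in np.flatnonzero(labels == lab))
        clusters.append(members)
    clusters.sort(key=min)
    comps = []
    for c in clusters:
        sp = pd.Series([species_of[m] for m in c]).value_counts()
        comps.append((sp / sp.sum()).to_dict())
    return ClusterSnapshot(float(traj.times[frame]), clusters, comps, box.copy())


@dataclass
class ClusterTimeline:
    """Time-ordered snapshots with persistent cluster identities.

    ``ids[f]`` maps a cluster's index within ``snapshots[f].clusters`` to its
    persistent id (only clusters of size >= 2 carry ids; monomers are free).
    ``membership`` is an (F, n_lipids) array of persistent ids, -1 when the
    lipid is monomeric.  ``lineage`` records (frame, parent_id, child_id,
    event) tuples for merges, splits and births.
    """

    snapshots: list[ClusterSnapshot]
    ids: list[dict]
    membership: np.ndarray
    lipid_index: dict  # lipid id -> column of membership
    lineage: list = field(default_factory=list)
    species_of_lipid: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def dt(self) -> float:
        t = self.times
        return float(np.median(np.diff(t))) if len(t) > 1 else 0.0

    def members_of(self, frame: int, persistent_id: int) -> frozenset:
        for ci, pid in self.ids[frame].items():
            if pid == persistent_id:
                return self.snapshots[frame].clusters[ci]
        raise KeyError(f"cluster {persistent_id} absent in frame {frame}")

    def free_counts(self) -> pd.DataFrame:
        """Per-frame free-monomer counts per species (singleton lipids)."""
        species = sorted(set(self.species_of_lipid.values()))
        rows = np.zeros((len(self.snapshots), len(species)), dtype=int)
        for f, snap in enumerate(self.snapshots):
            for c in snap.clusters:
                if len(c) == 1:
                    (lip,) = c
                    rows[f, species.index(self.species_of_lipid[lip])] += 1
        return pd.DataFrame(rows, columns=species, index=self.times)

    def free_concentration(self) -> pd.DataFrame:
        """Per-frame free-monomer molarity per species."""
        counts = self.free_counts()
        vols = np.array([np.prod(s.box) for s in self.snapshots])
        conc = np.vstack(
            [counts_to_molar(counts.to_numpy()[f], vols[f]) for f in range(len(vols))]
        )
        return pd.DataFrame(conc, columns=counts.columns, index=counts.index)


def track_clusters(snapshots: list[ClusterSnapshot]) -> ClusterTimeline:
    """Assign persistent ids to clusters across a snapshot sequence."""
    if not snapshots:
        raise ValueError("empty snapshot list")
    all_lipids = sorted(set().union(*[set().union(*s.clusters) for s in snapshots]))
    lipid_index = {lip: i for i, lip in enumerate(all_lipids)}
    membership = np.full((len(snapshots), len(all_lipids)), -1, dtype=int)
    ids: list[dict] = []
    lineage: list = []
    next_id = 0
    prev: dict = {}  # persistent id -> frozenset members

    for f, snap in enumerate(snapshots):
        cur = [c for c in snap.clusters]
        cur_ids: dict = {}
        # each previous cluster claims the current fragment with max overlap
        claims: dict = {}  # cur index -> list of (pid, parent_members)
        for pid, members in prev.items():
            overlaps = [(len(members & c), ci) for ci, c in enumerate(cur) if len(c) >= 2]
            overlaps = [(o, ci) for o, ci in overlaps if o > 0]
            if not overlaps:
                continue  # cluster evaporated
            best = max(o for o, _ in overlaps)
            tied = [ci for o, ci in overlaps if o == best]
            # tie-break: fragment containing the lowest shared lipid id
            target = min(tied, key=lambda ci: min(members & cur[ci]))
            claims.setdefault(target, []).append((pid, members))
            for o, ci in overlaps:
                if ci != target:
                    lineage.append((f, pid, None, "split"))
        for ci, c in enumerate(cur):
            if len(c) < 2:
                continue
            claimants = claims.get(ci, [])
            if claimants:
                # fusion: id of the larger parent; tie -> parent with lowest lipid id
                claimants.sort(key=lambda t: (-len(t[1]), min(t[1])))
                winner_pid = claimants[0][0]
                cur_ids[ci] = winner_pid
                for pid, _ in claimants[1:]:
                    lineage.append((f, pid, winner_pid, "merge"))
            else:
                cur_ids[ci] = next_id
                lineage.append((f, None, next_id, "birth"))
                next_id += 1
        # fission fragments without a claim already got fresh ids above
        ids.append(cur_ids)
        for ci, pid in cur_ids.items():
            for lip in cur[ci]:
                membership[f, lipid_index[lip]] = pid
        prev = {pid: cur[ci] for ci, pid in cur_ids.items()}

    species_of = {}
    return ClusterTimeline(snapshots, ids, membership, lipid_index, lineage, species_of)


def build_timeline(traj: Trajectory, cutoff: float = 0.24) -> ClusterTimeline:
    """Cluster every frame of a trajectory and track identities over time."""
    snaps = [cluster_partition(traj, f, cutoff) for f in range(traj.n_frames)]
    tl = track_clusters(snaps)
    tl.species_of_lipid = traj.species_of_lipid().to_dict()
    return tl


def cluster_size_series(timeline: ClusterTimeline, window: float = 1.0) -> pd.Series:
    """Mean non-monomeric cluster size over time, window-smoothed.

    Monomers (size-1 sets) are excluded, so values are >= 2 whenever any
    cluster exists.  Frames without clusters carry NaN; an entirely
    cluster-free timeline yields an empty series.
    """
    if not timeline.snapshots:
        raise ValueError("empty timeline")
    times = timeline.times
    vals = []
    for snap in timeline.snapshots:
        sizes = [s for s in snap.sizes if s >= 2]
        vals.append(np.mean(sizes) if sizes else np.nan)
    vals = np.asarray(vals)
    if np.all(np.isnan(vals)):
        return pd.Series(dtype=float)
    dt = timeline.dt()
    steps = max(1, int(round(window / dt))) if dt > 0 else 1
    return pd.Series(moving_average(vals, steps), index=times)


def timeline_to_frame(timeline: ClusterTimeline) -> pd.DataFrame:
    """Flatten a timeline to a table (time_ns, cluster_id, size, comp_<sp>...)."""
    species = sorted(set(timeline.species_of_lipid.values()))
    rows = []
    for f, snap in enumerate(timeline.snapshots):
        for ci, pid in timeline.ids[f].items():
            comp = snap.compositions[ci]
            row = {"time_ns": snap.time, "cluster_id": pid, "size": len(snap.clusters[ci])}
            for sp in species:
                row[f"comp_{sp}"] = comp.get(sp, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
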