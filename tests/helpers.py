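"""Shared test utilities: brute-force oracles and hand-built containers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from micellekin.clustering import ClusterSnapshot, ClusterTimeline
from micellekin.events import AdditionReaction, ResidenceReaction
from micellekin.synthetic import EventLog
from micellekin.trajectory import Trajectory, min_image_distance


def make_point_trajectory(lipid_positions, box_edge, species=None, times=None):
    """Trajectory of single-atom lipids at given positions.

    ``lipid_positions`` is (F, L, 3) or (L, 3); species defaults to "X" for
    every lipid.  Intended for pure-geometry clustering tests.
    """
    pos = np.asarray(lipid_positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    n_frames, n_lipids = pos.shape[:2]
    species = species or ["X"] * n_lipids
    atoms = pd.DataFrame(
        {
            "lipid_id": np.arange(n_lipids),
            "species": species,
            "atom_label": ["A"] * n_lipids,
            "moiety": [None] * n_lipids,
        }
    )
    times = np.arange(n_frames) * 0.002 if times is None else np.asarray(times)
    boxes = np.tile([box_edge] * 3, (n_frames, 1))
    return Trajectory(times, pos, boxes, atoms, {})


def brute_force_partition(traj, frame, cutoff):
    """All-pairs union-find over lipid minimum-image minimum distances."""
    lipids = traj.lipid_ids
    box = traj.boxes[frame]
    coords = traj.coords[frame]
    atom_lipid = traj.atoms["lipid_id"].to_numpy()
    parent = {int(l): int(l) for l in lipids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i, a in enumerate(lipids):
        ai = np.flatnonzero(atom_lipid == a)
        for b in lipids[i + 1 :]:
            bi = np.flatnonzero(atom_lipid == b)
            dmin = min(
                float(min_image_distance(coords[x], coords[y], box))
                for x in ai
                for y in bi
            )
            if dmin <= cutoff:
                union(int(a), int(b))
    groups: dict[int, set] = {}
    for l in lipids:
        groups.setdefault(find(int(l)), set()).add(int(l))
    return {frozenset(g) for g in groups.values()}


def timeline_from_membership(times, membership, species_of, box_edge=7.4):
    """Build a ClusterTimeline by fiat from a per-frame membership table.

    ``membership`` maps lipid id -> list of per-frame cluster ids (-1 free).
    """
    times = np.asarray(times, dtype=float)
    lipids = sorted(membership)
    n_frames = len(times)
    box = np.array([box_edge] * 3)
    snapshots, ids = [], []
    mem_arr = np.full((n_frames, len(lipids)), -1, dtype=int)
    for f in range(n_frames):
        by_cluster: dict[int, set] = {}
        free = []
        for li, lip in enumerate(lipids):
            cid = membership[lip][f]
            mem_arr[f, li] = cid
            if cid >= 0:
                by_cluster.setdefault(cid, set()).add(lip)
            else:
                free.append(lip)
        clusters, id_map = [], {}
        for cid in sorted(by_cluster):
            id_map[len(clusters)] = cid
            clusters.append(frozenset(by_cluster[cid]))
        for lip in free:
            clusters.append(frozenset([lip]))
        comps = []
        for c in clusters:
            counts: dict[str, int] = {}
            for m in c:
                counts[species_of[m]] = counts.get(species_of[m], 0) + 1
            tot = sum(counts.values())
            comps.append({sp: n / tot for sp, n in counts.items()})
        snapshots.append(ClusterSnapshot(float(times[f]), clusters, comps, box.copy()))
        ids.append(id_map)
    return ClusterTimeline(
        snapshots,
        ids,
        mem_arr,
        {lip: i for i, lip in enumerate(lipids)},
        [],
        dict(species_of),
    )


def hand_built_event_log():
    """Twelve hand-written events: one cluster grows from a dimer to 12
    members, one same-species entry pair becomes an addition reaction, and
    one early member exits late.

    Hand-counted ground truth: exactly 1 completed residence (94 ns,
    time-averaged non-probe size 10.40) surviving the exit filters, and
    exactly 1 addition (2 ns, size 11, zero drift) surviving the entry
    filters.
    """
    species = ("A", "B")
    rows = []

    def ev(t, kind, lipid, sp, size_before, comp_a, comp_b, free_a, free_b, partner=-1):
        rows.append(
            {
                "time_ns": float(t),
                "kind": kind,
                "lipid_id": lipid,
                "species": sp,
                "cluster_id": 0,
                "size_before": size_before,
                "partner_id": partner,
                "released_id": -1,
                "comp_A": comp_a,
                "comp_B": comp_b,
                "free_A": free_a,
                "free_B": free_b,
            }
        )

    # lipids: A = 0..6, B = 7..12; cluster nucleates from A0+B7 and grows
    ev(1.0, "entry", 7, "B", 1, 1.0, 0.0, 6, 5, partner=0)
    ev(2.0, "entry", 1, "A", 2, 0.5, 0.5, 5, 5)
    ev(3.0, "entry", 8, "B", 3, 2 / 3, 1 / 3, 5, 4)
    ev(4.0, "entry", 2, "A", 4, 0.5, 0.5, 4, 4)
    ev(5.0, "entry", 9, "B", 5, 0.6, 0.4, 4, 3)
    ev(6.0, "entry", 3, "A", 6, 0.5, 0.5, 3, 3)
    ev(7.0, "entry", 10, "B", 7, 4 / 7, 3 / 7, 3, 2)
    ev(8.0, "entry", 4, "A", 8, 0.5, 0.5, 2, 2)
    ev(9.0, "entry", 11, "B", 9, 5 / 9, 4 / 9, 2, 1)
    ev(10.0, "entry", 5, "A", 10, 0.5, 0.5, 1, 1)
    ev(12.0, "entry", 6, "A", 11, 6 / 11, 5 / 11, 0, 1)
    ev(95.0, "exit", 0, "A", 11, 6 / 11, 5 / 11, 1, 1)
    return EventLog(pd.DataFrame(rows), species, (7, 6), 7.4**3, 100.0)


def fixture_residences():
    """Twelve hand-built residences; survivors of the exit filter
    (>1 ns, >=10 monomers) are exactly ids {0, 3, 7, 9, 10}."""
    spec = [
        (2.0, 12),  # 0 keep
        (0.8, 12),  # 1 short
        (3.0, 5),  # 2 small cluster
        (1.5, 10),  # 3 keep (size boundary inclusive)
        (1.0, 15),  # 4 residence not above 1 ns
        (0.5, 5),  # 5
        (12.0, 9.9),  # 6 just below size threshold
        (94.0, 10.4),  # 7 keep
        (0.99, 54),  # 8
        (1.01, 54),  # 9 keep (just above the residence threshold)
        (6.0, 30),  # 10 keep
        (0.2, 2),  # 11
    ]
    out = []
    for i, (t, size) in enumerate(spec):
        out.append(
            ResidenceReaction(
                probe_id=i,
                species="A",
                cluster_id=0,
                t_first=0.0,
                t_last=t,
                residence_time=t,
                cluster_size=size,
                composition={"A": 1.0},
            )
        )
    return out


def fixture_additions():
    """Twelve hand-built additions; survivors of the entry filter (>300 ps,
    >=10 monomers, <=5% drift) are exactly ids {0, 4, 8, 11}."""
    spec = [
        (0.5, 15, 0.01),  # 0 keep
        (0.2, 15, 0.01),  # 1 below 300 ps
        (0.3, 15, 0.01),  # 2 not above 300 ps
        (0.5, 9, 0.01),  # 3 small cluster
        (2.0, 10, 0.05),  # 4 keep (both boundaries inclusive)
        (0.5, 15, 0.08),  # 5 drift above 5%
        (0.31, 9.4, 0.0),  # 6 small cluster
        (1.0, 20, 0.051),  # 7 drift
        (0.301, 10, 0.0),  # 8 keep
        (0.299, 10, 0.0),  # 9
        (5.0, 54, 0.2),  # 10 drift
        (0.4, 12, 0.04),  # 11 keep
    ]
    out = []
    for i, (t, size, drift) in enumerate(spec):
        out.append(
            AdditionReaction(
                species="A",
                cluster_id=i,
                t_prev_entry=0.0,
                t_entry=t,
                addition_time=t,
                mean_free_conc=0.01,
                cluster_size=size,
                composition={"A": 1.0},
                composition_drift=drift,
            )
        )
    return out
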