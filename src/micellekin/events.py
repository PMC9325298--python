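"""Extraction of residence (exit) and addition (entry) reactions.

A *residence* spans a probe lipid's first to last contact with one tracked
cluster; its reciprocal duration feeds the exit-rate estimator.  An
*addition* spans two consecutive entries of same-species monomers into one
cluster; its duration (with zero-free-probe segments subtracted) and the
mean free-monomer concentration feed the entry-rate estimator.  Exit
analysis keeps residences longer than 1 ns in clusters of at least 10
monomers; entry analysis keeps additions longer than 300 ps in clusters of
at least 10 monomers whose composition drifts by at most 5% of the total.

Reactions can be extracted from a :class:`~micellekin.clustering.ClusterTimeline`
(trajectory route) or exactly from a simulator :class:`~micellekin.synthetic.EventLog`
(:func:`reactions_from_event_log`), which serves as ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSnapshot, ClusterTimeline
from .synthetic import EventLog
from .utils import counts_to_molar


@dataclass
class ResidenceReaction:
    """One probe residence: first-to-last contact with a tracked cluster.

    ``cluster_size`` and ``composition`` are time averages over the residence
    and exclude the probe itself, so the modulator fractions are
    uncontaminated by the probe species.
    """

    probe_id: int
    species: str
    cluster_id: int
    t_first: float
    t_last: float
    residence_time: float
    cluster_size: float
    composition: dict[str, float]
    frames: np.ndarray | None = None
    dissolved: bool = False

    def modulator_fraction(self, modulator: str) -> float:
        return self.composition.get(modulator, 0.0)


@dataclass
class AdditionReaction:
    """Two consecutive same-species entries into one cluster.

    ``addition_time`` excludes segments with zero free probes;
    ``mean_free_conc`` is the time-averaged free-probe molarity over the
    counted (non-zero) segments.  ``cluster_size``/``composition`` are taken
    at the second entry, just before the probe joins, and therefore include
    the previously entered lipid.  ``composition_drift`` is the largest
    change of any species' fraction of the cluster during the interval.
    """

    species: str
    cluster_id: int
    t_prev_entry: float
    t_entry: float
    addition_time: float
    mean_free_conc: float
    cluster_size: float
    composition: dict[str, float]
    composition_drift: float

    def modulator_fraction(self, modulator: str) -> float:
        return self.composition.get(modulator, 0.0)


# ---------------------------------------------------------------------------
# trajectory (timeline) route
# ---------------------------------------------------------------------------


def _visits(ids: np.ndarray, times: np.ndarray, grace: float):
    """Maximal same-cluster visits of one lipid, bridging short monomeric gaps.

    ``ids`` is the per-frame persistent cluster id (-1 when monomeric).
    Returns a list of (cluster_id, frame_indices) with frame_indices the
    contact frames only.  A gap is bridged when every intervening frame is
    monomeric and the contact-to-contact time difference is below ``grace``;
    touching a different cluster always ends the visit.
    """
    runs = []
    start = None
    for f in range(len(ids) + 1):
        cur = ids[f] if f < len(ids) else -2
        if start is None:
            if cur >= 0:
                start = f
        elif cur != ids[start]:
            runs.append((int(ids[start]), start, f - 1))
            start = f if cur >= 0 else None
    merged = []
    for cid, s, e in runs:
        if merged:
            pcid, ps, pe, frames = merged[-1]
            gap_frames = ids[pe + 1 : s]
            if (
                cid == pcid
                and np.all(gap_frames == -1)
                and (times[s] - times[pe]) < grace
            ):
                merged[-1] = (pcid, ps, e, frames + list(range(s, e + 1)))
                continue
        merged.append((cid, s, e, list(range(s, e + 1))))
    return [(cid, np.array(frames)) for cid, _s, _e, frames in merged]


def _members_by_frame(timeline: ClusterTimeline):
    out = []
    for f in range(len(timeline.snapshots)):
        out.append({pid: timeline.snapshots[f].clusters[ci] for ci, pid in timeline.ids[f].items()})
    return out


def detect_residences(timeline: ClusterTimeline, grace: float = 0.01) -> list[ResidenceReaction]:
    """Find all probe residences in a tracked timeline.

    Requires frame spacing at or below ``grace`` (ns); single-frame visits
    carry zero duration and are dropped.
    """
    times = timeline.times
    if len(times) > 1 and timeline.dt() > grace + 1e-12:
        raise ValueError("frame spacing exceeds the grace interval")
    members = _members_by_frame(timeline)
    species_of = timeline.species_of_lipid
    species = sorted(set(species_of.values()))
    out = []
    for lip, col in timeline.lipid_index.items():
        for cid, frames in _visits(timeline.membership[:, col], times, grace):
            t_first, t_last = times[frames[0]], times[frames[-1]]
            if t_last <= t_first:
                continue
            counts = np.zeros(len(species))
            sizes = []
            for f in frames:
                mem = members[f].get(cid, frozenset())
                others = [m for m in mem if m != lip]
                sizes.append(len(others))
                for m in others:
                    counts[species.index(species_of[m])] += 1
            tot = counts.sum()
            comp = {sp: counts[i] / tot for i, sp in enumerate(species)} if tot else {}
            out.append(
                ResidenceReaction(
                    probe_id=int(lip),
                    species=species_of[lip],
                    cluster_id=int(cid),
                    t_first=float(t_first),
                    t_last=float(t_last),
                    residence_time=float(t_last - t_first),
                    cluster_size=float(np.mean(sizes)),
                    composition=comp,
                    frames=frames,
                )
            )
    out.sort(key=lambda r: (r.t_first, r.probe_id))
    return out


def detect_additions(
    timeline: ClusterTimeline, grace: float = 0.01, open_size: int = 10
) -> list[AdditionReaction]:
    """Find addition reactions (consecutive same-species entries per cluster).

    Pairing for a cluster/species opens once the cluster has reached
    ``open_size`` members, mirroring the entry filter's size condition.
    """
    times = timeline.times
    members = _members_by_frame(timeline)
    species_of = timeline.species_of_lipid
    species = sorted(set(species_of.values()))
    free_counts = timeline.free_counts()
    vols = np.array([np.prod(s.box) for s in timeline.snapshots])
    dt_next = np.diff(times, append=times[-1])  # last frame contributes no duration

    # entry records: (time, frame, lipid, species, cluster); membership in the
    # very first frame is not an observed entry (the true entry predates the
    # record) and never opens or closes an addition interval
    entries: dict[tuple[int, str], list[tuple[float, int, int]]] = {}
    for lip, col in timeline.lipid_index.items():
        for cid, frames in _visits(timeline.membership[:, col], times, grace):
            if frames[0] == 0:
                continue
            entries.setdefault((int(cid), species_of[lip]), []).append(
                (float(times[frames[0]]), int(frames[0]), int(lip))
            )
    # first frame each cluster reaches open_size
    opened_at: dict[int, float] = {}
    for f in range(len(times)):
        for pid, mem in members[f].items():
            if pid not in opened_at and len(mem) >= open_size:
                opened_at[pid] = times[f]

    out = []
    for (cid, sp), ent in entries.items():
        ent.sort()
        t_open = opened_at.get(cid)
        if t_open is None:
            continue
        eligible = [e for e in ent if e[0] >= t_open]
        fc = free_counts[sp].to_numpy()
        for (t_prev, f_prev, _l0), (t_cur, f_cur, lip) in zip(eligible, eligible[1:]):
            if t_cur <= t_prev:
                continue
            # piecewise-constant free counts between frames
            zero_time = 0.0
            conc_int = 0.0
            for f in range(f_prev, f_cur):
                seg = min(times[f + 1], t_cur) - max(times[f], t_prev)
                if seg <= 0:
                    continue
                if fc[f] == 0:
                    zero_time += seg
                else:
                    conc_int += counts_to_molar(fc[f], vols[f]) * seg
            addition_time = (t_cur - t_prev) - zero_time
            if addition_time <= 0:
                continue
            mem = members[f_cur].get(cid, frozenset())
            others = [m for m in mem if m != lip]
            counts = np.zeros(len(species))
            for m in others:
                counts[species.index(species_of[m])] += 1
            tot = counts.sum()
            comp = {s2: counts[i] / tot for i, s2 in enumerate(species)} if tot else {}
            # composition drift over the interval (full-cluster fractions)
            fr = []
            for f in range(f_prev, f_cur):
                mem_f = members[f].get(cid)
                if not mem_f:
                    continue
                cnt = np.zeros(len(species))
                for m in mem_f:
                    cnt[species.index(species_of[m])] += 1
                fr.append(cnt / cnt.sum())
            drift = float(np.max(np.ptp(np.array(fr), axis=0))) if len(fr) > 1 else 0.0
            out.append(
                AdditionReaction(
                    species=sp,
                    cluster_id=cid,
                    t_prev_entry=t_prev,
                    t_entry=t_cur,
                    addition_time=float(addition_time),
                    mean_free_conc=float(conc_int / addition_time),
                    cluster_size=float(tot),
                    composition=comp,
                    composition_drift=drift,
                )
            )
    out.sort(key=lambda r: (r.t_entry, r.cluster_id))
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_exit_reactions(
    reactions: list[ResidenceReaction], min_residence: float = 1.0, min_cluster: float = 10
) -> list[ResidenceReaction]:
    """Keep residences longer than ``min_residence`` ns in clusters of at
    least ``min_cluster`` monomers; order preserved, idempotent."""
    return [
        r
        for r in reactions
        if r.residence_time > min_residence and r.cluster_size >= min_cluster
    ]


def filter_entry_reactions(
    reactions: list[AdditionReaction],
    min_addition: float = 0.3,
    min_cluster: float = 10,
    max_drift: float = 0.05,
) -> list[AdditionReaction]:
    """Keep additions longer than ``min_addition`` ns in clusters of at least
    ``min_cluster`` monomers whose composition drift does not exceed
    ``max_drift``."""
    return [
        r
        for r in reactions
        if r.addition_time > min_addition
        and r.cluster_size >= min_cluster
        and r.composition_drift <= max_drift
    ]


# ---------------------------------------------------------------------------
# exact event-log replay
# ---------------------------------------------------------------------------


class _StepCum:
    """Cumulative integrals of a piecewise-constant step function."""

    def __init__(self, times: np.ndarray, values: np.ndarray):
        self.t = times  # breakpoints; values[k] holds on [t[k], t[k+1])
        self.v = values.astype(float)
        dt = np.diff(times)
        self.cum_zero = np.concatenate([[0.0], np.cumsum(np.where(self.v[:-1] == 0, dt, 0.0))])
        self.cum_val = np.concatenate([[0.0], np.cumsum(self.v[:-1] * dt)])

    def _at(self, cum, t):
        k = int(np.searchsorted(self.t, t, side="right") - 1)
        k = min(max(k, 0), len(self.t) - 1)
        extra = t - self.t[k]
        return cum[k] + extra * (
            (self.v[k] == 0) if cum is self.cum_zero else self.v[k]
        )

    def zero_time(self, a: float, b: float) -> float:
        return self._at(self.cum_zero, b) - self._at(self.cum_zero, a)

    def value_integral(self, a: float, b: float) -> float:
        return self._at(self.cum_val, b) - self._at(self.cum_val, a)


@dataclass
class _ClusterReplay:
    counts: np.ndarray
    members: dict  # lipid -> species index
    t_last: float
    i_counts: np.ndarray
    i_size: float = 0.0
    opened: bool = False
    trackers: dict = field(default_factory=dict)  # species idx -> tracker

    def advance(self, t: float):
        dt = t - self.t_last
        if dt > 0:
            self.i_counts = self.i_counts + self.counts * dt
            self.i_size += self.counts.sum() * dt
            self.t_last = t

    def fractions(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts.astype(float)

    def update_trackers(self):
        f = self.fractions()
        for tr in self.trackers.values():
            tr["fmin"] = np.minimum(tr["fmin"], f)
            tr["fmax"] = np.maximum(tr["fmax"], f)


def reactions_from_event_log(
    log: EventLog, open_size: int = 10, include_dissolution_exits: bool = True
):
    """Convert a simulator event stream into residence and addition reactions.

    Exact: durations come straight from event times and compositions from
    closed-form time integrals of the cluster state, so the result is the
    ground-truth oracle for the trajectory-based detectors.  Residences still
    open at ``t_end`` are discarded.  An exit that dissolves a size-2 cluster
    also closes the released partner's residence (flagged ``dissolved``).
    """
    species = log.species
    s = len(species)
    sidx = {sp: i for i, sp in enumerate(species)}

    ev_times = log.events["time_ns"].to_numpy()
    free_mat = log.events[[f"free_{sp}" for sp in species]].to_numpy()
    bp = np.concatenate([[0.0], ev_times])
    free_cums = [
        _StepCum(bp, np.concatenate([[log.total_counts[i]], free_mat[:, i]]))
        for i in range(s)
    ]
    conc_per_count = counts_to_molar(1.0, log.box_volume_nm3)

    clusters: dict[int, _ClusterReplay] = {}
    open_res: dict[int, tuple] = {}  # lipid -> (t0, cid, i_counts0, i_size0, species idx)
    residences: list[ResidenceReaction] = []
    additions: list[AdditionReaction] = []

    def close_residence(lip: int, cl: _ClusterReplay, t: float, dissolved: bool):
        t0, cid, i0, is0, si = open_res.pop(lip)
        dt = t - t0
        if dt <= 0:
            return
        avg_counts = (cl.i_counts - i0) / dt
        avg_counts[si] -= 1.0  # exclude the probe itself
        avg_counts = np.clip(avg_counts, 0.0, None)
        tot = avg_counts.sum()
        comp = {sp: avg_counts[j] / tot for j, sp in enumerate(species)} if tot > 0 else {}
        residences.append(
            ResidenceReaction(
                probe_id=int(lip),
                species=species[si],
                cluster_id=int(cid),
                t_first=float(t0),
                t_last=float(t),
                residence_time=float(dt),
                cluster_size=float((cl.i_size - is0) / dt - 1.0),
                composition=comp,
                dissolved=dissolved,
            )
        )

    def open_residence(lip: int, cl: _ClusterReplay, cid: int, t: float, si: int):
        open_res[lip] = (t, cid, cl.i_counts.copy(), cl.i_size, si)

    def emit_addition(cl: _ClusterReplay, cid: int, si: int, t: float, row):
        """Create an addition reaction; call with the pre-entry cluster state."""
        eligible = cl.opened
        tr = cl.trackers.get(si)
        if tr is not None and tr["armed"] and eligible:
            t_prev = tr["t"]
            if t > t_prev:
                zero = free_cums[si].zero_time(t_prev, t)
                addition_time = (t - t_prev) - zero
                if addition_time > 0:
                    conc_int = free_cums[si].value_integral(t_prev, t) * conc_per_count
                    comp = {sp: getattr(row, f"comp_{sp}") for sp in species}
                    drift = float(np.max(tr["fmax"] - tr["fmin"]))
                    additions.append(
                        AdditionReaction(
                            species=species[si],
                            cluster_id=int(cid),
                            t_prev_entry=float(t_prev),
                            t_entry=float(t),
                            addition_time=float(addition_time),
                            mean_free_conc=float(conc_int / addition_time),
                            cluster_size=float(row.size_before),
                            composition=comp,
                            composition_drift=drift,
                        )
                    )
        return eligible

    # comp columns are addressed via getattr on itertuples rows; map names
    for row in log.events.itertuples(index=False):
        t = float(row.time_ns)
        cid = int(row.cluster_id)
        si = sidx[row.species]
        lip = int(row.lipid_id)
        if row.kind == "entry":
            if int(row.partner_id) >= 0:
                partner = int(row.partner_id)
                comp = np.array([getattr(row, f"comp_{sp}") for sp in species])
                pj = int(np.argmax(comp))
                counts = np.zeros(s, dtype=float)
                counts[pj] = 1
                cl = _ClusterReplay(counts=counts, members={partner: pj}, t_last=t, i_counts=np.zeros(s))
                clusters[cid] = cl
                open_residence(partner, cl, cid, t, pj)
            cl = clusters[cid]
            cl.advance(t)
            eligible = emit_addition(cl, cid, si, t, row)
            open_residence(lip, cl, cid, t, si)
            cl.counts[si] += 1
            cl.members[lip] = si
            if cl.counts.sum() >= open_size:
                cl.opened = True
            cl.update_trackers()
            # the interval to the next same-species entry starts now, with the
            # cluster including this entrant (post-entry fractions)
            f = cl.fractions()
            cl.trackers[si] = {"t": t, "fmin": f.copy(), "fmax": f.copy(), "armed": eligible}
        else:
            cl = clusters[cid]
            cl.advance(t)
            close_residence(lip, cl, t, dissolved=False)
            cl.counts[si] -= 1
            del cl.members[lip]
            if int(row.released_id) >= 0:
                partner = int(row.released_id)
                pj = cl.members.pop(partner)
                close_residence(partner, cl, t, dissolved=True)
                cl.counts[pj] -= 1
                del clusters[cid]
            else:
                cl.update_trackers()
    residences.sort(key=lambda r: (r.t_last, r.probe_id))
    if not include_dissolution_exits:
        residences = [r for r in residences if not r.dissolved]
    additions.sort(key=lambda r: (r.t_entry, r.cluster_id))
    return residences, additions


def timeline_from_event_log(log: EventLog, dt: float = 0.01) -> ClusterTimeline:
    """Sample an event stream into a regular-spacing cluster timeline.

    Cluster states are piecewise constant between events; snapshots carry the
    simulator's cluster ids as persistent ids, so the trajectory-route
    detectors can be cross-checked against the exact replay.  Durations
    measured on the sampled timeline agree with the log to within ``dt``.
    """
    species = log.species
    sidx = {sp: i for i, sp in enumerate(species)}
    edge = log.box_volume_nm3 ** (1.0 / 3.0)
    box = np.array([edge] * 3)
    n_total = sum(log.total_counts)
    # lipid ids are contiguous per species (simulator convention)
    species_of_lipid = {}
    off = 0
    for i, n in enumerate(log.total_counts):
        for lip in range(off, off + n):
            species_of_lipid[lip] = species[i]
        off += n
    for row in log.events.itertuples(index=False):
        species_of_lipid[int(row.lipid_id)] = row.species

    sample_times = np.arange(0.0, log.t_end + dt / 2, dt)
    snapshots: list[ClusterSnapshot] = []
    ids: list[dict] = []
    membership = np.full((len(sample_times), n_total), -1, dtype=int)

    clusters: dict[int, set] = {}
    ev = log.events
    ev_iter = list(ev.itertuples(index=False))
    k = 0
    for fi, t in enumerate(sample_times):
        while k < len(ev_iter) and float(ev_iter[k].time_ns) <= t:
            row = ev_iter[k]
            cid = int(row.cluster_id)
            lip = int(row.lipid_id)
            if row.kind == "entry":
                if int(row.partner_id) >= 0:
                    clusters[cid] = {int(row.partner_id)}
                clusters[cid].add(lip)
            else:
                clusters[cid].discard(lip)
                if int(row.released_id) >= 0 or len(clusters[cid]) < 2:
                    del clusters[cid]
            k += 1
        clustered = set()
        snap_clusters = []
        snap_ids = {}
        for cid in sorted(clusters):
            mem = frozenset(clusters[cid])
            snap_ids[len(snap_clusters)] = cid
            snap_clusters.append(mem)
            clustered |= mem
            for m in mem:
                membership[fi, m] = cid
        for lip in range(n_total):
            if lip not in clustered:
                snap_clusters.append(frozenset([lip]))
        comps = []
        for c in snap_clusters:
            cnt = np.zeros(len(species))
            for m in c:
                cnt[sidx[species_of_lipid[m]]] += 1
            comps.append({sp: cnt[i] / cnt.sum() for i, sp in enumerate(species) if cnt[i] > 0})
        snapshots.append(ClusterSnapshot(float(t), snap_clusters, comps, box.copy()))
        ids.append(snap_ids)
    lipid_index = {lip: lip for lip in range(n_total)}
    return ClusterTimeline(snapshots, ids, membership, lipid_index, [], species_of_lipid)


# ---------------------------------------------------------------------------
# tabular round trip
# ---------------------------------------------------------------------------


def residences_to_frame(reactions: list[ResidenceReaction], species: list[str]) -> pd.DataFrame:
    rows = []
    for r in reactions:
        row = {
            "probe_id": r.probe_id,
            "species": r.species,
            "cluster_id": r.cluster_id,
            "t_first_ns": r.t_first,
            "t_last_ns": r.t_last,
            "residence_ns": r.residence_time,
            "cluster_size": r.cluster_size,
            "dissolved": r.dissolved,
        }
        for sp in species:
            row[f"comp_{sp}"] = r.composition.get(sp, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def additions_to_frame(reactions: list[AdditionReaction], species: list[str]) -> pd.DataFrame:
    rows = []
    for r in reactions:
        row = {
            "species": r.species,
            "cluster_id": r.cluster_id,
            "t_prev_entry_ns": r.t_prev_entry,
            "t_entry_ns": r.t_entry,
            "addition_ns": r.addition_time,
            "mean_free_conc_M": r.mean_free_conc,
            "cluster_size": r.cluster_size,
            "composition_drift": r.composition_drift,
        }
        for sp in species:
            row[f"comp_{sp}"] = r.composition.get(sp, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def residences_from_frame(df: pd.DataFrame) -> list[ResidenceReaction]:
    species = [c[len("comp_") :] for c in df.columns if c.startswith("comp_")]
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ResidenceReaction(
                probe_id=int(row.probe_id),
                species=row.species,
                cluster_id=int(row.cluster_id),
                t_first=float(row.t_first_ns),
                t_last=float(row.t_last_ns),
                residence_time=float(row.residence_ns),
                cluster_size=float(row.cluster_size),
                composition={sp: float(getattr(row, f"comp_{sp}")) for sp in species},
                dissolved=bool(row.dissolved),
            )
        )
    return out


def additions_from_frame(df: pd.DataFrame) -> list[AdditionReaction]:
    species = [c[len("comp_") :] for c in df.columns if c.startswith("comp_")]
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AdditionReaction(
                species=row.species,
                cluster_id=int(row.cluster_id),
                t_prev_entry=float(row.t_prev_entry_ns),
                t_entry=float(row.t_entry_ns),
                addition_time=float(row.addition_ns),
                mean_free_conc=float(row.mean_free_conc_M),
                cluster_size=float(row.cluster_size),
                composition={sp: float(getattr(row, f"comp_{sp}")) for sp in species},
                composition_drift=float(row.composition_drift),
            )
        )
    return out
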