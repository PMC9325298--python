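"""Headgroup-interaction prevalence (HIP) and probe-orientation analyses.

HIP measures, per residence reaction, the fraction of the residence during
which a probe headgroup moiety sits within an interaction cutoff (0.3 nm) of
a given moiety type in the cluster.  Comparing long (>10 ns) and short
(1-2 ns) residences gives per-pair HIP fold changes; comparing
modulator-rich (>=50%) and modulator-poor (<50%) clusters step-by-step over
the first/last 0.5 ns of residence gives the dynamic HIP shift.  The probe
orientation is the angle between the lipid's head-to-tail vector and the
head-to-cluster-centre vector (0 deg radial, 90 deg tangential); its
rich-minus-poor shift reveals composition-driven changes in the mode of
interaction.  All distances honour the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterTimeline
from .events import ResidenceReaction
from .trajectory import Trajectory, min_image_displacement, min_image_distance
from .utils import moving_average

PairKey = tuple[str, str, str, str]  # probe species, probe moiety, cluster species, cluster moiety


@dataclass
class HIPRecord:
    """Fraction of one residence during which a moiety pair interacts."""

    reaction_id: int
    probe_species: str
    probe_moiety: str
    cluster_species: str
    cluster_moiety: str
    hip: float

    def __post_init__(self):
        if not (0.0 <= self.hip <= 1.0):
            raise ValueError("hip must lie in [0, 1]")

    @property
    def pair(self) -> PairKey:
        return (self.probe_species, self.probe_moiety, self.cluster_species, self.cluster_moiety)


@dataclass
class OrientationSeries:
    """Per-step probe orientation angles (degrees) over part of a residence."""

    reaction_id: int
    probe_species: str
    times: np.ndarray  # ns, relative to the alignment point
    angles: np.ndarray  # degrees in [0, 180]
    group: str | None = None
    n_skipped: int = 0


def _moiety_atoms(traj: Trajectory, lipid_id: int):
    """(moiety label, atom index) pairs of one lipid's headgroup."""
    idx = traj.atom_indices_of_lipid(lipid_id)
    sub = traj.atoms.loc[idx]
    return [(row.moiety, i) for i, row in zip(idx, sub.itertuples(index=False)) if row.moiety]


def _pair_presence(traj, members_by_frame, reaction, cutoff, frames):
    """Per-frame presence booleans for every probe-cluster moiety pair.

    At each time step the minimal distance of each probe headgroup moiety to
    each moiety type present in the cluster is compared with the cutoff.
    Pairs absent from a frame (the moiety type left the cluster) count as
    not interacting.
    """
    probe = reaction.probe_id
    probe_sp = reaction.species
    probe_moieties = _moiety_atoms(traj, probe)
    presence: dict[PairKey, list[bool]] = {}
    for fi, f in enumerate(frames):
        mem = members_by_frame[f].get(reaction.cluster_id, frozenset())
        others = [m for m in mem if m != probe]
        box = traj.boxes[f]
        groups: dict[tuple[str, str], list[int]] = {}
        for m in others:
            sp = traj.atoms.loc[traj.atom_indices_of_lipid(m)[0], "species"]
            for lab, ai in _moiety_atoms(traj, m):
                groups.setdefault((sp, lab), []).append(ai)
        for pm, pai in probe_moieties:
            ppos = traj.coords[f, pai]
            for (csp, cm), ais in groups.items():
                d = min_image_distance(ppos, traj.coords[f][ais], box).min()
                key = (probe_sp, pm, csp, cm)
                if key not in presence:
                    presence[key] = [False] * len(frames)
                presence[key][fi] = bool(d <= cutoff)
    return presence


def _members_by_frame(timeline: ClusterTimeline):
    return [
        {pid: timeline.snapshots[f].clusters[ci] for ci, pid in timeline.ids[f].items()}
        for f in range(len(timeline.snapshots))
    ]


def hip_values(
    traj: Trajectory,
    timeline: ClusterTimeline,
    reaction: ResidenceReaction,
    cutoff: float = 0.3,
    reaction_id: int = 0,
) -> list[HIPRecord]:
    """HIP values of one residence: contact fraction per moiety pair."""
    if reaction.frames is None or len(reaction.frames) == 0:
        raise ValueError("reaction carries no frame-resolved record")
    if reaction.residence_time <= 0:
        raise ValueError("zero-length residence")
    members = _members_by_frame(timeline)
    presence = _pair_presence(traj, members, reaction, cutoff, list(reaction.frames))
    return [
        HIPRecord(reaction_id, *key, float(np.mean(vals)))
        for key, vals in sorted(presence.items())
    ]


def hip_fold_change(
    records_by_reaction: dict[int, list[HIPRecord]],
    residence_times: dict[int, float],
    long_min: float = 10.0,
    short_range: tuple[float, float] = (1.0, 2.0),
    salient_fold: float = 2.5,
    salient_p: float = 1e-5,
) -> pd.DataFrame:
    """Fold change of mean HIP between long and short residences, per pair.

    ``fold = mean(HIP | T > long_min) / mean(HIP | short_range[0] <= T <=
    short_range[1])`` with an unequal-variance two-sample t-test on the
    per-reaction HIP values.  Pairs whose short-group mean is zero have an
    undefined fold and are flagged.  ``salient`` marks pairs beyond the
    display thresholds (fold >= 2.5 and p <= 1e-5).
    """
    long_ids = [i for i, t in residence_times.items() if t > long_min]
    short_ids = [
        i for i, t in residence_times.items() if short_range[0] <= t <= short_range[1]
    ]
    by_pair: dict[PairKey, dict[str, list[float]]] = {}
    for rid, recs in records_by_reaction.items():
        grp = "long" if rid in long_ids else "short" if rid in short_ids else None
        if grp is None:
            continue
        for rec in recs:
            by_pair.setdefault(rec.pair, {"long": [], "short": []})[grp].append(rec.hip)
    rows = []
    for pair, groups in sorted(by_pair.items()):
        lo, sh = np.array(groups["long"]), np.array(groups["short"])
        if len(lo) == 0 or len(sh) == 0:
            continue
        short_mean = sh.mean()
        undefined = short_mean == 0
        fold = np.nan if undefined else lo.mean() / short_mean
        if len(lo) > 1 and len(sh) > 1 and (lo.std() > 0 or sh.std() > 0):
            p = float(stats.ttest_ind(lo, sh, equal_var=False).pvalue)
        else:
            p = 1.0 if np.isclose(lo.mean(), short_mean) else np.nan
        rows.append(
            {
                "probe_species": pair[0],
                "probe_moiety": pair[1],
                "cluster_species": pair[2],
                "cluster_moiety": pair[3],
                "fold_change": fold,
                "p_value": p,
                "n_long": len(lo),
                "n_short": len(sh),
                "undefined_fold": undefined,
                "salient": bool(
                    not undefined and fold >= salient_fold and np.isfinite(p) and p <= salient_p
                ),
            }
        )
    return pd.DataFrame(rows)


def split_by_modulator(reactions, modulator: str, split: float = 0.5):
    """Partition reactions into modulator-rich (fraction >= split, ties rich)
    and modulator-poor groups."""
    rich = [r for r in reactions if r.modulator_fraction(modulator) >= split]
    poor = [r for r in reactions if r.modulator_fraction(modulator) < split]
    return rich, poor


def prevalence_shift(
    series_rich: list[np.ndarray],
    series_poor: list[np.ndarray],
    dt: float,
    smooth: float = 0.01,
) -> pd.DataFrame:
    """Rich-minus-poor prevalence difference per time step, smoothed.

    Each series is a per-step record for one reaction: booleans (interaction
    present) or NaN-padded floats.  Prevalence per group and step is the mean
    over reactions contributing that step; both prevalence curves are
    smoothed with a sliding window of ``smooth`` ns before differencing.
    """
    if not series_rich:
        raise ValueError("modulator-rich group is empty")
    if not series_poor:
        raise ValueError("modulator-poor group is empty")

    def stack(series):
        n = max(len(s) for s in series)
        m = np.full((len(series), n), np.nan)
        for i, s in enumerate(series):
            m[i, : len(s)] = np.asarray(s, dtype=float)
        return m

    rich = np.nanmean(stack(series_rich), axis=0)
    poor = np.nanmean(stack(series_poor), axis=0)
    n = min(len(rich), len(poor))
    steps = max(1, int(round(smooth / dt))) if dt > 0 else 1
    rich_s = moving_average(rich[:n], steps)
    poor_s = moving_average(poor[:n], steps)
    return pd.DataFrame(
        {
            "time_ns": np.arange(n) * dt,
            "prevalence_rich": rich_s,
            "prevalence_poor": poor_s,
            "shift": rich_s - poor_s,
        }
    )


def _window_frames(reaction, times, window, align):
    frames = np.asarray(reaction.frames)
    ft = times[frames]
    if align == "first":
        sel = frames[ft - reaction.t_first <= window + 1e-12]
    elif align == "last":
        sel = frames[reaction.t_last - ft <= window + 1e-12][::-1]
    else:
        raise ValueError("align must be 'first' or 'last'")
    return sel


def dynamic_hip_shift(
    traj: Trajectory,
    timeline: ClusterTimeline,
    reactions: list[ResidenceReaction],
    modulator: str,
    cutoff: float = 0.3,
    split: float = 0.5,
    window: float = 0.5,
    smooth: float = 0.01,
    align: str = "first",
) -> dict[PairKey, pd.DataFrame]:
    """Dynamic HIP shift between modulator-rich and -poor clusters.

    Per cross-species moiety pair (same-species pairs are excluded), the
    interaction presence of each reaction is recorded per time step over the
    first (or last) ``window`` ns of residence, averaged within each
    composition group, smoothed, and differenced (rich - poor).
    """
    rich, poor = split_by_modulator(reactions, modulator, split)
    if not rich:
        raise ValueError("modulator-rich group is empty")
    if not poor:
        raise ValueError("modulator-poor group is empty")
    members = _members_by_frame(timeline)
    times = timeline.times
    dt = timeline.dt()
    series: dict[PairKey, dict[str, list[np.ndarray]]] = {}
    for group_name, group in (("rich", rich), ("poor", poor)):
        for r in group:
            frames = _window_frames(r, times, window, align)
            if len(frames) == 0:
                continue
            presence = _pair_presence(traj, members, r, cutoff, list(frames))
            for key, vals in presence.items():
                if key[0] == key[2]:  # same-species pair: not informative
                    continue
                series.setdefault(key, {"rich": [], "poor": []})[group_name].append(
                    np.asarray(vals, dtype=float)
                )
    out = {}
    for key, grp in sorted(series.items()):
        if grp["rich"] and grp["poor"]:
            out[key] = prevalence_shift(grp["rich"], grp["poor"], dt, smooth)
    return out


def probe_orientation(
    traj: Trajectory,
    timeline: ClusterTimeline,
    reaction: ResidenceReaction,
    window: float | None = None,
    align: str = "first",
    reaction_id: int = 0,
) -> OrientationSeries:
    """Orientation angle of the probe relative to the cluster centre.

    The lipid vector runs from the prominent head atom to the terminal tail
    carbon; the reference vector runs from the head atom to the geometric
    centre of the non-probe members' head atoms (minimum-image displacements
    relative to the probe).  Degenerate zero-length vectors skip the step.
    """
    if reaction.frames is None or len(reaction.frames) == 0:
        raise ValueError("reaction carries no frame-resolved record")
    times = timeline.times
    frames = (
        _window_frames(reaction, times, window, align)
        if window is not None
        else np.asarray(reaction.frames)
    )
    members = _members_by_frame(timeline)
    head_i = traj.head_atom_index(reaction.probe_id)
    tail_i = traj.tail_atom_index(reaction.probe_id)
    angles, rel_times = [], []
    skipped = 0
    for f in frames:
        box = traj.boxes[f]
        head = traj.coords[f, head_i]
        lipid_vec = min_image_displacement(head, traj.coords[f, tail_i], box)
        mem = members[f].get(reaction.cluster_id, frozenset())
        others = [m for m in mem if m != reaction.probe_id]
        if not others:
            skipped += 1
            continue
        disp = np.array(
            [
                min_image_displacement(head, traj.coords[f, traj.head_atom_index(m)], box)
                for m in others
            ]
        )
        ref_vec = disp.mean(axis=0)
        nl, nr = np.linalg.norm(lipid_vec), np.linalg.norm(ref_vec)
        if nl == 0 or nr == 0:
            skipped += 1
            continue
        cosang = np.clip(np.dot(lipid_vec, ref_vec) / (nl * nr), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
        t0 = reaction.t_first if align == "first" else reaction.t_last
        rel_times.append(abs(times[f] - t0))
    return OrientationSeries(
        reaction_id=reaction_id,
        probe_species=reaction.species,
        times=np.asarray(rel_times),
        angles=np.asarray(angles),
        n_skipped=skipped,
    )


def orientation_shift(
    traj: Trajectory,
    timeline: ClusterTimeline,
    reactions: list[ResidenceReaction],
    modulator: str,
    split: float = 0.5,
    window: float = 0.5,
    smooth: float = 0.01,
    align: str = "first",
    single_moiety_only: bool = True,
) -> pd.DataFrame:
    """Mean-orientation shift (degrees) between modulator-rich and -poor groups.

    Positive shifts mean the rich group sits more tangentially.  By default
    only single-moiety probes are analysed (for zwitterionic heads the
    orientation reference is ambiguous).
    """
    if single_moiety_only:
        reactions = [
            r for r in reactions if traj.species[r.species].is_single_moiety
        ]
    rich, poor = split_by_modulator(reactions, modulator, split)
    if not rich:
        raise ValueError("modulator-rich group is empty")
    if not poor:
        raise ValueError("modulator-poor group is empty")
    dt = timeline.dt()

    def angle_series(group):
        out = []
        for i, r in enumerate(group):
            s = probe_orientation(traj, timeline, r, window=window, align=align, reaction_id=i)
            if len(s.angles):
                out.append(s.angles)
        return out

    rich_series, poor_series = angle_series(rich), angle_series(poor)
    if not rich_series or not poor_series:
        raise ValueError("a composition group contributed no orientation steps")
    df = prevalence_shift(rich_series, poor_series, dt, smooth)
    return df.rename(
        columns={
            "prevalence_rich": "angle_rich_deg",
            "prevalence_poor": "angle_poor_deg",
            "shift": "shift_deg",
        }
    )
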