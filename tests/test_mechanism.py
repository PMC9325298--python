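"""HIP, fold changes, dynamic shifts and probe orientation geometry."""

import numpy as np
import pandas as pd
import pytest

from helpers import timeline_from_membership
from micellekin.clustering import build_timeline
from micellekin.events import ResidenceReaction, detect_residences
from micellekin.mechanism import (
    HIPRecord,
    dynamic_hip_shift,
    hip_fold_change,
    hip_values,
    orientation_shift,
    prevalence_shift,
    probe_orientation,
    split_by_modulator,
)
from micellekin.species import DEFAULT_SPECIES
from micellekin.synthetic import FrameConfig, ToyCluster, generate_toy_frames
from micellekin.trajectory import Trajectory
from micellekin.utils import moving_average


def _two_lipid_traj(head_distances):
    """SDS probe (lipid 0) and DDA partner (lipid 1); per-frame distance
    between the S and N head atoms is prescribed, tails kept adjacent so the
    pair is always one cluster."""
    sds, dda = DEFAULT_SPECIES["SDS"], DEFAULT_SPECIES["DDA"]
    rows = []
    for lip, sp in ((0, sds), (1, dda)):
        for label in sp.atom_labels:
            rows.append(
                {
                    "lipid_id": lip,
                    "species": sp.name,
                    "atom_label": label,
                    "moiety": sp.moiety_of_atom.get(label),
                }
            )
    atoms = pd.DataFrame(rows)
    frames = []
    for d in head_distances:
        # lipid 0: S head at origin, tail along +x; lipid 1: N head at (d, 0, 0),
        # tail along +x displaced in y so the C12 atoms stay within 0.2 nm
        c = np.zeros((8, 3))
        c[0] = (1.0, 1.0, 1.0)  # S
        c[1] = (1.12, 1.0, 1.0)
        c[2] = (1.24, 1.0, 1.0)
        c[3] = (1.36, 1.0, 1.0)  # C12 of lipid 0
        c[4] = (1.0 + d, 1.0, 1.0)  # N of lipid 1
        c[5] = (1.24, 1.15, 1.0)
        c[6] = (1.30, 1.15, 1.0)
        c[7] = (1.36, 1.15, 1.0)  # C12 of lipid 1: 0.15 nm from lipid 0's
        frames.append(c)
    coords = np.asarray(frames)
    times = np.arange(len(frames)) * 0.002
    boxes = np.tile([7.4, 7.4, 7.4], (len(frames), 1))
    traj = Trajectory(times, coords, boxes, atoms, dict(DEFAULT_SPECIES))
    membership = {0: [0] * len(frames), 1: [0] * len(frames)}
    tl = timeline_from_membership(times, membership, {0: "SDS", 1: "DDA"})
    reaction = ResidenceReaction(
        0, "SDS", 0, 0.0, times[-1], times[-1], 1.0, {"DDA": 1.0}, frames=np.arange(len(frames))
    )
    return traj, tl, reaction


class TestHipValues:
    def test_always_within_cutoff_gives_one(self):
        traj, tl, r = _two_lipid_traj([0.25] * 10)
        recs = hip_values(traj, tl, r, cutoff=0.3)
        by_pair = {rec.pair: rec.hip for rec in recs}
        assert by_pair[("SDS", "S", "DDA", "N")] == 1.0

    def test_never_within_cutoff_gives_zero(self):
        traj, tl, r = _two_lipid_traj([0.5] * 10)
        recs = hip_values(traj, tl, r, cutoff=0.3)
        assert {rec.hip for rec in recs if rec.pair == ("SDS", "S", "DDA", "N")} == {0.0}

    def test_half_contact_gives_half(self):
        traj, tl, r = _two_lipid_traj([0.25] * 5 + [0.5] * 5)
        recs = hip_values(traj, tl, r, cutoff=0.3)
        by_pair = {rec.pair: rec.hip for rec in recs}
        assert by_pair[("SDS", "S", "DDA", "N")] == 0.5

    def test_cutoff_boundary_inclusive(self):
        traj, tl, r = _two_lipid_traj([0.2999] * 4)
        by_pair = {rec.pair: rec.hip for rec in hip_values(traj, tl, r, cutoff=0.3)}
        assert by_pair[("SDS", "S", "DDA", "N")] == 1.0
        traj, tl, r = _two_lipid_traj([0.3001] * 4)
        by_pair = {rec.pair: rec.hip for rec in hip_values(traj, tl, r, cutoff=0.3)}
        assert by_pair[("SDS", "S", "DDA", "N")] == 0.0

    def test_record_range_validated(self):
        with pytest.raises(ValueError):
            HIPRecord(0, "SDS", "S", "DDA", "N", 1.2)


class TestHipFoldChange:
    def _records(self, long_vals, short_vals):
        records, times = {}, {}
        rid = 0
        for v in long_vals:
            records[rid] = [HIPRecord(rid, "SDS", "S", "DDA", "N", v)]
            times[rid] = 15.0
            rid += 1
        for v in short_vals:
            records[rid] = [HIPRecord(rid, "SDS", "S", "DDA", "N", v)]
            times[rid] = 1.5
            rid += 1
        return records, times

    def test_identical_groups_fold_one(self):
        records, times = self._records([0.4, 0.6], [0.4, 0.6])
        df = hip_fold_change(records, times)
        assert df["fold_change"].iloc[0] == pytest.approx(1.0)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_fourfold_change(self):
        records, times = self._records([0.8, 0.8], [0.2, 0.2])
        df = hip_fold_change(records, times)
        assert df["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_salient_classification(self):
        rng = np.random.default_rng(0)
        records, times = self._records(
            0.9 + rng.normal(0, 0.01, 30), 0.3 + rng.normal(0, 0.01, 30)
        )
        df = hip_fold_change(records, times)
        assert df["fold_change"].iloc[0] == pytest.approx(3.0, rel=0.05)
        assert df["p_value"].iloc[0] < 1e-5
        assert bool(df["salient"].iloc[0])

    def test_zero_short_mean_flagged_undefined(self):
        records, times = self._records([0.5, 0.5], [0.0, 0.0])
        df = hip_fold_change(records, times)
        assert bool(df["undefined_fold"].iloc[0])
        assert np.isnan(df["fold_change"].iloc[0])

    def test_reactions_outside_both_windows_ignored(self):
        records, times = self._records([0.5], [0.5])
        records[9] = [HIPRecord(9, "SDS", "S", "DDA", "N", 1.0)]
        times[9] = 5.0  # neither long (>10) nor short (1-2)
        df = hip_fold_change(records, times)
        assert df["n_long"].iloc[0] == 1 and df["n_short"].iloc[0] == 1


class TestPrevalenceShift:
    def test_identical_groups_zero_shift(self):
        s = [np.ones(20), np.zeros(20)]
        df = prevalence_shift(s, [x.copy() for x in s], dt=0.01)
        assert np.allclose(df["shift"], 0.0)

    def test_full_contrast_unit_shift(self):
        df = prevalence_shift([np.ones(30)] * 5, [np.zeros(30)] * 5, dt=0.01)
        assert np.allclose(df["shift"], 1.0)

    def test_bernoulli_prevalences_recovered(self):
        """Streams with presence probability 0.7 (rich) vs 0.4 (poor) show a
        ~0.3 shift within binomial error."""
        rng = np.random.default_rng(7)
        n, steps = 400, 50
        rich = [(rng.random(steps) < 0.7).astype(float) for _ in range(n)]
        poor = [(rng.random(steps) < 0.4).astype(float) for _ in range(n)]
        df = prevalence_shift(rich, poor, dt=0.01, smooth=0.01)
        se = np.sqrt(0.7 * 0.3 / n + 0.4 * 0.6 / n)
        assert abs(df["shift"].mean() - 0.3) <= 3 * se
        assert np.all(np.abs(df["shift"] - 0.3) <= 5 * se)

    def test_empty_group_error_names_group(self):
        with pytest.raises(ValueError, match="poor"):
            prevalence_shift([np.ones(5)], [], dt=0.01)
        with pytest.raises(ValueError, match="rich"):
            prevalence_shift([], [np.ones(5)], dt=0.01)

    def test_shift_bounded(self):
        rng = np.random.default_rng(3)
        rich = [rng.integers(0, 2, 20).astype(float) for _ in range(10)]
        poor = [rng.integers(0, 2, 20).astype(float) for _ in range(10)]
        df = prevalence_shift(rich, poor, dt=0.01)
        assert df["shift"].between(-1, 1).all()
        assert df["prevalence_rich"].between(0, 1).all()


class TestSmoothing:
    def test_constant_series_unchanged(self):
        y = np.full(50, 3.3)
        assert np.allclose(moving_average(y, 7), y)

    def test_mean_approximately_preserved(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=200)
        sm = moving_average(y, 5)
        assert abs(sm.mean() - y.mean()) < 5 * np.ptp(y) / len(y)

    def test_stays_within_bounds(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(-2, 5, 100)
        sm = moving_average(y, 9)
        assert sm.min() >= y.min() - 1e-12 and sm.max() <= y.max() + 1e-12


class TestGroupSplit:
    def test_tie_at_split_goes_rich(self):
        r = ResidenceReaction(0, "A", 0, 0.0, 1.0, 1.0, 10.0, {"A": 0.5, "B": 0.5})
        rich, poor = split_by_modulator([r], "B", split=0.5)
        assert rich == [r] and poor == []


class TestOrientation:
    def test_placed_angles_recovered_exactly(self):
        for angle in (0.0, 45.0, 90.0, 180.0):
            fc = FrameConfig(
                clusters=[ToyCluster({"DDA": 11}, (3.0, 3.0, 3.0), 0.8, probe=("SDS", angle))],
                n_frames=2,
                jitter_sd=0.0,
                seed=1,
            )
            traj, _ = generate_toy_frames(fc)
            tl = build_timeline(traj)
            r = [x for x in detect_residences(tl, grace=0.01) if x.species == "SDS"][0]
            s = probe_orientation(traj, tl, r)
            assert np.allclose(s.angles, angle, atol=1e-6)

    def test_orientation_shift_between_groups(self):
        """Probes placed at 80 deg in modulator-rich and 60 deg in
        modulator-poor clusters give a +20 deg tangential shift."""
        fc = FrameConfig(
            clusters=[
                ToyCluster({"SDS": 3, "DDA": 9}, (2.0, 2.0, 2.0), 0.8, probe=("SDS", 80.0)),
                ToyCluster({"SDS": 9, "DDA": 3}, (5.5, 5.5, 5.5), 0.8, probe=("SDS", 60.0)),
            ],
            n_frames=10,
            jitter_sd=0.0,
            seed=2,
        )
        traj, _ = generate_toy_frames(fc)
        tl = build_timeline(traj)
        res = detect_residences(tl, grace=0.01)
        probes = [r for r in res if r.probe_id in (12, 25)]  # the placed probes
        df = orientation_shift(traj, tl, probes, modulator="DDA", window=0.5, smooth=0.002)
        assert np.allclose(df["shift_deg"], 20.0, atol=1e-6)

    def test_dynamic_hip_shift_excludes_same_species_pairs(self):
        fc = FrameConfig(
            clusters=[
                ToyCluster({"SDS": 3, "DDA": 9}, (2.0, 2.0, 2.0), 0.8),
                ToyCluster({"SDS": 9, "DDA": 3}, (5.5, 5.5, 5.5), 0.8),
            ],
            n_frames=6,
            jitter_sd=0.0,
            seed=3,
        )
        traj, _ = generate_toy_frames(fc)
        tl = build_timeline(traj)
        res = [r for r in detect_residences(tl, grace=0.01) if r.species == "SDS"]
        shifts = dynamic_hip_shift(traj, tl, res, modulator="DDA", window=0.5)
        assert shifts  # at least one cross pair observed
        for key in shifts:
            assert key[0] != key[2]

    def test_empty_group_raises(self):
        traj, tl, r = _two_lipid_traj([0.25] * 6)
        r.frames = np.arange(6)
        with pytest.raises(ValueError, match="poor"):
            dynamic_hip_shift(traj, tl, [r], modulator="DDA")  # fraction 1.0 -> all rich
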