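"""Synthetic data with known ground truth.

Two generators make every downstream stage testable without MD data:

* :func:`simulate_accretion` -- a Gillespie (stochastic simulation algorithm)
  model of cluster growth by monomer exchange.  Free monomers of species *i*
  enter a cluster *c* with propensity ``C_i_free * k_entry_i *
  (1 + sum_j f_j(c) * beta_entry_ij)`` and each resident monomer leaves with
  propensity ``k_exit_i * (1 + sum_j f_j(c) * beta_exit_ij)``, where the
  composition fractions ``f_j`` always exclude the moving probe.  Dimers
  nucleate from free monomer pairs at a configurable rate.  Whole-cluster
  fusion is deliberately absent: the analysed regime is stepwise monomer
  accretion, and fusion would contaminate residence bookkeeping.

* :func:`generate_toy_frames` -- coordinate frames with a known cluster
  partition, controllable headgroup geometry and probe orientation, for
  exercising the distance-based analyses.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .species import DEFAULT_SPECIES, LipidSpecies
from .trajectory import Trajectory, min_image_distance
from .utils import AVOGADRO, NM3_TO_L, counts_to_molar, wrap_coords

#: Binary mixture ratios used for the two-component systems (54 monomers total).
TABLE1_RATIOS: tuple[tuple[int, int], ...] = ((6, 48), (16, 38), (27, 27), (38, 16), (48, 6))


class NegativePropensityError(ValueError):
    """A beta matrix admits a negative propensity at a reachable composition."""


@dataclass
class SimConfig:
    """Parameters of the stochastic accretion simulator.

    Rates are basal (pure-cluster) values; ``beta_entry``/``beta_exit`` are
    probe-by-modulator matrices of dimensionless fractional modifiers.
    Defaults emulate the depleted-monomer study conditions: 54 monomers in a
    7.4 nm cubic box (~220 mM), entry ~50 /(M ns) and exit 0.02 /ns so that
    the free pool settles near 10% of the total and typical residences sit
    well above the 1 ns analysis filter.
    """

    species: tuple[str, ...] = ("SDS", "DPC")
    counts: tuple[int, ...] = (27, 27)
    box_volume_nm3: float = 7.4**3
    k_entry: tuple[float, ...] | float = 50.0  # 1/(M ns)
    k_exit: tuple[float, ...] | float = 0.02  # 1/ns
    beta_entry: np.ndarray | None = None
    beta_exit: np.ndarray | None = None
    k_nucleation: float = 0.2  # 1/(M ns); slow vs growth: few clusters, early depletion
    t_end: float = 50.0  # ns
    record_interval: float = 0.1  # ns, coarse state records
    seed: int = 0

    def __post_init__(self):
        s = len(self.species)
        if len(self.counts) != s:
            raise ValueError("counts must match species")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if np.isscalar(self.k_entry):
            self.k_entry = tuple([float(self.k_entry)] * s)
        if np.isscalar(self.k_exit):
            self.k_exit = tuple([float(self.k_exit)] * s)
        if any(k < 0 for k in self.k_entry) or any(k < 0 for k in self.k_exit):
            raise ValueError("basal rates must be non-negative")
        if self.box_volume_nm3 <= 0:
            raise ValueError("box volume must be positive")
        if self.k_nucleation < 0:
            raise ValueError("nucleation rate must be non-negative")
        for name in ("beta_entry", "beta_exit"):
            b = getattr(self, name)
            b = np.zeros((s, s)) if b is None else np.asarray(b, dtype=float)
            if b.shape != (s, s):
                raise ValueError(f"{name} must be {s}x{s}")
            setattr(self, name, b)
            # 1 + sum_j f_j beta_ij is affine in f, so its minimum over the
            # composition simplex is attained at a vertex (a pure modulator).
            for i in range(s):
                j = int(np.argmin(b[i]))
                if 1.0 + b[i, j] < 0:
                    raise NegativePropensityError(
                        f"{name}: probe {self.species[i]} has negative propensity "
                        f"in pure-{self.species[j]} clusters (1 + beta = {1 + b[i, j]:.3f})"
                    )

    @property
    def n_total(self) -> int:
        return int(sum(self.counts))

    def to_yaml(self, path) -> None:
        data = {
            "species": list(self.species),
            "counts": [int(c) for c in self.counts],
            "box_volume_nm3": float(self.box_volume_nm3),
            "k_entry": [float(k) for k in self.k_entry],
            "k_exit": [float(k) for k in self.k_exit],
            "beta_entry": np.asarray(self.beta_entry).tolist(),
            "beta_exit": np.asarray(self.beta_exit).tolist(),
            "k_nucleation": float(self.k_nucleation),
            "t_end": float(self.t_end),
            "record_interval": float(self.record_interval),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["species"] = tuple(data["species"])
        data["counts"] = tuple(data["counts"])
        for key in ("beta_entry", "beta_exit"):
            if data.get(key) is not None:
                data[key] = np.asarray(data[key], dtype=float)
        return cls(**data)


@dataclass
class EventLog:
    """Time-ordered entry/exit events plus the free-monomer trajectory.

    One row per Gillespie event.  ``partner_id`` names the co-nucleating
    monomer when a dimer forms (the row is the entering probe); ``released_id``
    names the partner freed when an exit dissolves a size-2 cluster.  The
    ``comp_<species>`` columns hold the involved cluster's composition before
    the event, excluding the moving probe; ``free_<species>`` hold free counts
    after the event.
    """

    events: pd.DataFrame
    species: tuple[str, ...]
    total_counts: tuple[int, ...]
    box_volume_nm3: float
    t_end: float
    seed: int | None = None

    def __len__(self):
        return len(self.events)

    def assert_conservation(self) -> None:
        """Check lipid conservation at every event (free + clustered = totals)."""
        times = self.events["time_ns"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise AssertionError("event times are not strictly increasing")
        clustered = np.zeros(len(self.species), dtype=int)
        sidx = {sp: i for i, sp in enumerate(self.species)}
        spec_of: dict[int, int] = {}
        for _, row in self.events.iterrows():
            si = sidx[row["species"]]
            spec_of[int(row["lipid_id"])] = si
            if row["kind"] == "entry":
                clustered[si] += 1
                if row["partner_id"] >= 0:
                    pj = int(row["partner_id"])
                    # partner species is recorded on its own later events; infer
                    # from the pre-event composition (the partner is the whole
                    # size-1 cluster when size_before == 1)
                    comp = np.array([row[f"comp_{sp}"] for sp in self.species])
                    pj_si = int(np.argmax(comp))
                    spec_of[pj] = pj_si
                    clustered[pj_si] += 1
            else:
                clustered[si] -= 1
                if row["released_id"] >= 0:
                    comp = np.array([row[f"comp_{sp}"] for sp in self.species])
                    clustered[int(np.argmax(comp))] -= 1
            free = np.array([row[f"free_{sp}"] for sp in self.species], dtype=int)
            if not np.array_equal(free + clustered, np.asarray(self.total_counts)):
                raise AssertionError(
                    f"conservation violated at t={row['time_ns']:.6f}: "
                    f"free {free} + clustered {clustered} != totals {self.total_counts}"
                )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# micellekin EventLog"
                f"\tspecies={','.join(self.species)}"
                f"\ttotals={','.join(str(c) for c in self.total_counts)}"
                f"\tbox_volume_nm3={self.box_volume_nm3!r}"
                f"\tt_end={self.t_end!r}"
                f"\tseed={self.seed!r}\n"
            )
            self.events.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# micellekin EventLog"):
                raise ValueError("not a micellekin EventLog TSV")
            meta = dict(tok.split("=", 1) for tok in header.strip().split("\t")[1:])
            events = pd.read_csv(fh, sep="\t")
        species = tuple(meta["species"].split(","))
        totals = tuple(int(x) for x in meta["totals"].split(","))
        seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
        return cls(events, species, totals, float(meta["box_volume_nm3"]), float(meta["t_end"]), seed)


def simulate_accretion(config: SimConfig) -> EventLog:
    """Run the Gillespie accretion model and return the event stream.

    The free-monomer concentration entering the propensities is the free
    count over (Avogadro x box volume), updated after every event.
    """
    rng = np.random.default_rng(config.seed)
    s = len(config.species)
    ke = np.asarray(config.k_entry)
    kx = np.asarray(config.k_exit)
    be = config.beta_entry
    bx = config.beta_exit
    conc_per_count = 1.0 / (AVOGADRO * config.box_volume_nm3 * NM3_TO_L)

    # lipid ids are assigned contiguously per species, deterministic
    free: list[list[int]] = []
    off = 0
    for si, n in enumerate(config.counts):
        free.append(list(range(off, off + n)))
        off += n
    clusters: dict[int, dict] = {}  # cid -> {"counts": np.ndarray, "members": list per species}
    next_cid = 0
    t = 0.0
    rows: list[dict] = []

    def comp_vec(counts, exclude=None):
        c = counts.astype(float).copy()
        if exclude is not None:
            c[exclude] -= 1
        tot = c.sum()
        return c / tot if tot > 0 else c

    def record(kind, lipid, si, cid, size_before, comp, partner=-1, released=-1):
        row = {
            "time_ns": t,
            "kind": kind,
            "lipid_id": lipid,
            "species": config.species[si],
            "cluster_id": cid,
            "size_before": int(size_before),
            "partner_id": int(partner),
            "released_id": int(released),
        }
        for j, sp in enumerate(config.species):
            row[f"comp_{sp}"] = float(comp[j])
        for j, sp in enumerate(config.species):
            row[f"free_{sp}"] = len(free[j])
        rows.append(row)

    while True:
        nfree = np.array([len(f) for f in free], dtype=float)
        cfree = nfree * conc_per_count
        props: list[tuple[float, tuple]] = []
        if config.k_nucleation > 0:
            for i in range(s):
                for j in range(i, s):
                    pairs = nfree[i] * (nfree[i] - 1) / 2 if i == j else nfree[i] * nfree[j]
                    if pairs > 0:
                        props.append((config.k_nucleation * pairs * conc_per_count, ("nuc", i, j)))
        for cid, cl in clusters.items():
            counts = cl["counts"]
            f = comp_vec(counts)
            for i in range(s):
                if nfree[i] > 0:
                    a = cfree[i] * ke[i] * (1.0 + f @ be[i])
                    if a > 0:
                        props.append((a, ("entry", cid, i)))
                if counts[i] > 0:
                    fex = comp_vec(counts, exclude=i)
                    a = counts[i] * kx[i] * (1.0 + fex @ bx[i])
                    if a > 0:
                        props.append((a, ("exit", cid, i)))
        a0 = sum(p for p, _ in props)
        if a0 <= 0:
            break
        t = t + rng.exponential(1.0 / a0)
        if t >= config.t_end:
            t = config.t_end
            break
        r = rng.random() * a0
        acc = 0.0
        for a, ev in props:
            acc += a
            if r < acc:
                break
        if ev[0] == "nuc":
            _, i, j = ev
            a_id = free[i].pop(int(rng.integers(len(free[i]))))
            b_id = free[j].pop(int(rng.integers(len(free[j]))))
            counts = np.zeros(s, dtype=int)
            counts[i] += 1
            members = [[] for _ in range(s)]
            members[i].append(a_id)
            cid = next_cid
            next_cid += 1
            clusters[cid] = {"counts": counts, "members": members}
            # log as the entry of b into the nascent single-member cluster
            comp = comp_vec(counts)
            counts[j] += 1
            members[j].append(b_id)
            record("entry", b_id, j, cid, 1, comp, partner=a_id)
        elif ev[0] == "entry":
            _, cid, i = ev
            cl = clusters[cid]
            lip = free[i].pop(int(rng.integers(len(free[i]))))
            comp = comp_vec(cl["counts"])
            size_before = int(cl["counts"].sum())
            cl["counts"][i] += 1
            cl["members"][i].append(lip)
            record("entry", lip, i, cid, size_before, comp)
        else:
            _, cid, i = ev
            cl = clusters[cid]
            lip = cl["members"][i].pop(int(rng.integers(len(cl["members"][i]))))
            cl["counts"][i] -= 1
            comp = comp_vec(cl["counts"])  # already excludes the probe
            size_before = int(cl["counts"].sum())
            free[i].append(lip)
            if size_before <= 1:
                released = -1
                for j in range(s):
                    if cl["members"][j]:
                        released = cl["members"][j].pop()
                        free[j].append(released)
                del clusters[cid]
                record("exit", lip, i, cid, size_before, comp, released=released)
            else:
                record("exit", lip, i, cid, size_before, comp)

    events = pd.DataFrame(
        rows,
        columns=[
            "time_ns", "kind", "lipid_id", "species", "cluster_id", "size_before",
            "partner_id", "released_id",
        ]
        + [f"comp_{sp}" for sp in config.species]
        + [f"free_{sp}" for sp in config.species],
    )
    return EventLog(events, config.species, tuple(config.counts), config.box_volume_nm3, config.t_end, config.seed)


def binary_ratio_configs(species_a: str, species_b: str, base: SimConfig | None = None) -> list[SimConfig]:
    """The five binary-mixture configurations (10/90 ... 90/10 of 54 monomers)."""
    base = base if base is not None else SimConfig()
    out = []
    for na, nb in TABLE1_RATIOS:
        out.append(replace(base, species=(species_a, species_b), counts=(na, nb)))
    return out


def example_mutual_catalysis_config() -> SimConfig:
    """A synthetic two-species example with strong mutual exit deceleration.

    SDS and DDA mutually slow each other's exit (beta_exit = -0.5 both ways)
    and mildly boost each other's entry -- a caricature of cooperative
    accretion between oppositely charged surfactants, useful for demos and
    round-trip tests.  Synthetic parameters; not fitted to any measurement.
    """
    return SimConfig(
        species=("SDS", "DDA"),
        counts=(27, 27),
        beta_exit=np.array([[0.0, -0.5], [-0.5, 0.0]]),
        beta_entry=np.array([[0.0, 0.3], [0.3, 0.0]]),
    )


# ---------------------------------------------------------------------------
# toy coordinate frames
# ---------------------------------------------------------------------------


class PackingError(ValueError):
    """The requested toy-frame layout cannot satisfy its distance constraints."""


@dataclass
class ToyCluster:
    """One ground-truth cluster: composition, centroid (nm) and packing radius."""

    counts: dict[str, int]
    centroid: tuple[float, float, float]
    radius: float
    probe: tuple[str, float] | None = None  # (species, orientation angle in degrees)


@dataclass
class FrameConfig:
    """Layout of synthetic coordinate frames with a known partition.

    Lipids are pseudo-atom chains (see :mod:`micellekin.species`); cluster
    members sit on a snake-ordered lattice (0.15 nm spacing, inside the
    packing radius) so nearest-neighbour head distances are below the cluster
    cutoff by construction, while clusters and free monomers are mutually
    separated by more than the cutoff plus the lipid extent.
    """

    clusters: list[ToyCluster] = field(default_factory=list)
    free: dict[str, int] = field(default_factory=dict)
    box_edge: float = 7.4
    jitter_sd: float = 0.0
    n_frames: int = 1
    dt: float = 0.002
    seed: int = 0
    cutoff: float = 0.24
    species: dict[str, LipidSpecies] = field(default_factory=lambda: dict(DEFAULT_SPECIES))

    def __post_init__(self):
        if self.jitter_sd > 0.01:
            raise ValueError("jitter_sd above 0.01 nm would void the partition guarantee")
        for tc in self.clusters:
            if tc.radius >= self.box_edge / 4:
                raise PackingError(
                    f"packing radius {tc.radius} must be below box_edge/4 = {self.box_edge / 4}"
                )

    def to_yaml(self, path) -> None:
        data = {
            "clusters": [
                {
                    "counts": dict(tc.counts),
                    "centroid": [float(x) for x in tc.centroid],
                    "radius": float(tc.radius),
                    "probe": None if tc.probe is None else [tc.probe[0], float(tc.probe[1])],
                }
                for tc in self.clusters
            ],
            "free": dict(self.free),
            "box_edge": float(self.box_edge),
            "jitter_sd": float(self.jitter_sd),
            "n_frames": int(self.n_frames),
            "dt": float(self.dt),
            "seed": int(self.seed),
            "cutoff": float(self.cutoff),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FrameConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        clusters = [
            ToyCluster(
                counts=dict(d["counts"]),
                centroid=tuple(d["centroid"]),
                radius=float(d["radius"]),
                probe=None if d.get("probe") is None else (d["probe"][0], float(d["probe"][1])),
            )
            for d in data.pop("clusters", [])
        ]
        return cls(clusters=clusters, **data)


_LATTICE_SPACING = 0.15
_LIPID_EXTENT = 0.45  # conservative max head-to-tail atom span, nm


def _snake_lattice(radius: float) -> np.ndarray:
    """Lattice points within a centred cube of half-diagonal ``radius``, snake order."""
    half = radius / np.sqrt(3.0)
    n = max(1, int(np.floor(2 * half / _LATTICE_SPACING)) + 1)
    ax = (np.arange(n) - (n - 1) / 2) * _LATTICE_SPACING
    pts = []
    for iz in range(n):
        ys = range(n) if iz % 2 == 0 else range(n - 1, -1, -1)
        for k, iy in enumerate(ys):
            xs = range(n) if k % 2 == 0 else range(n - 1, -1, -1)
            for ix in xs:
                pts.append((ax[ix], ax[iy], ax[iz]))
    return np.asarray(pts)


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _perpendicular(u):
    trial = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, trial)
    return _unit(v)


def generate_toy_frames(config: FrameConfig):
    """Build a synthetic trajectory and its ground-truth lipid partition.

    Returns ``(Trajectory, partition)`` where ``partition`` is the list of
    lipid-id frozensets (clusters first, then free-monomer singletons) that
    :func:`micellekin.clustering.cluster_partition` must recover in every
    frame at the configured cutoff.
    """
    rng = np.random.default_rng(config.seed)
    box = np.array([config.box_edge] * 3)
    species = config.species

    lipid_rows = []  # (species, head_pos, direction)
    partition: list[frozenset] = []
    centroids = []
    radii = []

    clearance = config.cutoff + 2 * _LIPID_EXTENT + 0.1
    for a, tc_a in enumerate(config.clusters):
        for b in range(a):
            d = min_image_distance(np.asarray(tc_a.centroid), np.asarray(config.clusters[b].centroid), box)
            need = tc_a.radius + config.clusters[b].radius + clearance
            if d <= need:
                raise PackingError(
                    f"clusters {a} and {b} are {d:.2f} nm apart; need > {need:.2f} nm"
                )

    for tc in config.clusters:
        n_members = sum(tc.counts.values())
        lattice = _snake_lattice(tc.radius)
        n_slots = n_members  # probe placed off-lattice
        if n_slots > len(lattice):
            raise PackingError(
                f"cannot pack {n_slots} lipids inside radius {tc.radius} nm "
                f"({len(lattice)} lattice slots at {_LATTICE_SPACING} nm spacing)"
            )
        anchors = lattice[:n_slots] + np.asarray(tc.centroid)
        member_ids = []
        names = [sp for sp, n in sorted(tc.counts.items()) for _ in range(n)]
        for pos, sp_name in zip(anchors, names):
            member_ids.append(len(lipid_rows))
            lipid_rows.append((sp_name, pos, _unit(np.asarray(tc.centroid) - pos)))
        if tc.probe is not None:
            sp_name, angle = tc.probe
            anchor0 = anchors[0]
            u_out = _unit(anchor0 - np.asarray(tc.centroid))
            head = anchor0 + 0.2 * u_out
            center = anchors.mean(axis=0)  # geometric centre of the non-probe heads
            u0 = _unit(center - head)
            v = _perpendicular(u0)
            ang = np.deg2rad(angle)
            direction = np.cos(ang) * u0 + np.sin(ang) * v
            member_ids.append(len(lipid_rows))
            lipid_rows.append((sp_name, head, direction))
        partition.append(frozenset(member_ids))
        centroids.append(np.asarray(tc.centroid))
        radii.append(tc.radius)

    free_heads: list[np.ndarray] = []
    for sp_name, n in sorted(config.free.items()):
        for _ in range(n):
            for _try in range(2000):
                pos = rng.uniform(0, config.box_edge, 3)
                ok = all(
                    min_image_distance(pos, c, box) > r + clearance
                    for c, r in zip(centroids, radii)
                ) and all(
                    min_image_distance(pos, hp, box) > clearance for hp in free_heads
                )
                if ok:
                    break
            else:
                raise PackingError(
                    f"cannot place free {sp_name} monomer with >{clearance:.2f} nm clearance"
                )
            partition_idx = len(lipid_rows)
            lipid_rows.append((sp_name, pos, _unit(rng.normal(size=3))))
            partition.append(frozenset([partition_idx]))
            free_heads.append(pos)

    atom_rows = []
    base_coords = []
    for lipid_id, (sp_name, head, direction) in enumerate(lipid_rows):
        sp = species[sp_name]
        for label, offset in zip(sp.atom_labels, sp.atom_offsets):
            atom_rows.append(
                {
                    "lipid_id": lipid_id,
                    "species": sp_name,
                    "atom_label": label,
                    "moiety": sp.moiety_of_atom.get(label),
                }
            )
            base_coords.append(head + offset * direction)
    base_coords = np.asarray(base_coords)
    atoms = pd.DataFrame(atom_rows)

    frames = []
    for _f in range(config.n_frames):
        c = base_coords.copy()
        if config.jitter_sd > 0:
            c = c + rng.normal(0.0, config.jitter_sd, c.shape)
        frames.append(wrap_coords(c, box))
    coords = np.asarray(frames)
    times = np.arange(config.n_frames) * config.dt
    boxes = np.tile(box, (config.n_frames, 1))
    traj = Trajectory(times, coords, boxes, atoms, dict(species))
    return traj, partition
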