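"""GARD accretion flux, homeostasis scoring and compositional screening.

The Graded Autocatalysis Replication Domain (GARD) flux of species *i* in an
assembly of composition ``f`` is

    dn_i/dt = C_i * k_entry_i * (1 + sum_j f_j * beta_entry_ij)
              - k_exit_i * (1 + sum_j f_j * beta_exit_ij)

with environmental concentrations ``C_i`` and basal rates modified by the
mutual-catalysis beta-matrices.  The homeostasis score ``H`` is the cosine
similarity between a composition and its flux: when ``H`` is high the flux
drives the assembly towards its own composition, and compositions with
``H >= 0.9`` are classed as successful self-reproducers.  The default flux
uses the exit term exactly as written above; an alternative mode scales the
exit term by ``f_i`` for consistency with per-monomer stochastic kinetics.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GardModel:
    """Species, environmental concentrations, basal rates and beta-matrices.

    ``beta_entry``/``beta_exit`` are fractional (not percent) probe-by-
    modulator matrices.  ``env_conc`` defaults to equimolar 4 mM.
    """

    species: list[str]
    env_conc: np.ndarray | float = 0.004  # M
    k_entry: np.ndarray | float = 1.0  # 1/(M ns)
    k_exit: np.ndarray | float = 0.001  # 1/ns
    beta_entry: np.ndarray | None = None
    beta_exit: np.ndarray | None = None
    exit_scaled_by_composition: bool = False

    def __post_init__(self):
        s = len(self.species)
        if s < 1:
            raise ValueError("need at least one species")
        for name in ("env_conc", "k_entry", "k_exit"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 0:
                v = np.full(s, float(v))
            if v.shape != (s,):
                raise ValueError(f"{name} must be scalar or length-{s}")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, v)
        for name in ("beta_entry", "beta_exit"):
            b = getattr(self, name)
            b = np.zeros((s, s)) if b is None else np.asarray(b, dtype=float)
            if b.shape != (s, s):
                raise ValueError(f"{name} must be {s}x{s}")
            setattr(self, name, b)


def as_composition(f) -> np.ndarray:
    """Validate a composition vector: non-negative fractions summing to 1."""
    f = np.asarray(f, dtype=float)
    if np.any(f < -1e-12):
        raise ValueError("composition fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    return f


def accretion_flux(f, model: GardModel) -> np.ndarray:
    """Per-species accretion flux dn/dt at composition ``f``."""
    f = as_composition(f)
    entry = model.env_conc * model.k_entry * (1.0 + model.beta_entry @ f)
    exit_ = model.k_exit * (1.0 + model.beta_exit @ f)
    if model.exit_scaled_by_composition:
        exit_ = exit_ * f
    return entry - exit_


def homeostasis_similarity(f, flux) -> float:
    """Cosine similarity H between a composition and its flux.

    Invariant to positive rescaling of either argument.  A zero flux leaves
    H undefined (NaN); callers treat such compositions as non-reproducers.
    """
    f = as_composition(f)
    flux = np.asarray(flux, dtype=float)
    nf, ng = np.linalg.norm(f), np.linalg.norm(flux)
    if ng == 0:
        return float("nan")
    return float(np.dot(f, flux) / (nf * ng))


def enumerate_simplex(n_types: int, step: float = 0.05) -> np.ndarray:
    """All compositions of ``n_types`` species on a grid of resolution ``step``.

    Returns an (N, n_types) array in lexicographic order; N equals the
    stars-and-bars count C(1/step + n_types - 1, n_types - 1).
    """
    m = 1.0 / step
    if abs(m - round(m)) > 1e-9:
        raise ValueError("1/step must be an integer")
    m = int(round(m))
    if n_types < 1:
        raise ValueError("need at least one type")
    rows = []
    for cuts in itertools.combinations(range(m + n_types - 1), n_types - 1):
        prev = -1
        counts = []
        for c in cuts:
            counts.append(c - prev - 1)
            prev = c
        counts.append(m + n_types - 2 - prev)
        rows.append(counts)
    grid = np.asarray(rows, dtype=float) * step
    return grid[np.lexsort(grid.T[::-1])]


@dataclass
class ScreenResult:
    """Outcome of a compositional screen.

    ``percentile`` is the percentage of grid compositions whose Euclidean
    distance to the equimolar composition is smaller than the reproducer
    set's mean distance -- how far from equilibrium-like compositions the
    homeostatic set sits.
    """

    grid: np.ndarray
    h_values: np.ndarray
    threshold: float
    reproducer_mask: np.ndarray
    centroid: np.ndarray | None
    equimolar_distance_percentile: float
    n_zero_flux: int = 0
    species: list[str] = field(default_factory=list)

    @property
    def n_reproducers(self) -> int:
        return int(self.reproducer_mask.sum())

    @property
    def percent_of_grid(self) -> float:
        return 100.0 * self.n_reproducers / len(self.grid)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f_{sp}": self.grid[:, i] for i, sp in enumerate(self.species)}
        cols["H"] = self.h_values
        cols["reproducer"] = self.reproducer_mask
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "n_grid": int(len(self.grid)),
            "threshold": self.threshold,
            "n_reproducers": self.n_reproducers,
            "percent_of_grid": self.percent_of_grid,
            "centroid": None if self.centroid is None else [float(x) for x in self.centroid],
            "equimolar_distance_percentile": float(self.equimolar_distance_percentile),
            "n_zero_flux": int(self.n_zero_flux),
            "species": list(self.species),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def screen_reproducers(
    model: GardModel,
    grid: np.ndarray | None = None,
    threshold: float = 0.9,
    top_k: int = 10,
    step: float = 0.05,
) -> ScreenResult:
    """Score every grid composition and collect the self-reproducers.

    The centroid averages the ``top_k`` compositions with the highest H
    (the typical reproducing composition); with no reproducers the centroid
    is undefined (None).
    """
    if grid is None:
        grid = enumerate_simplex(len(model.species), step)
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty composition grid")
    entry = (model.env_conc * model.k_entry) * (1.0 + grid @ model.beta_entry.T)
    exit_ = model.k_exit * (1.0 + grid @ model.beta_exit.T)
    if model.exit_scaled_by_composition:
        exit_ = exit_ * grid
    flux = entry - exit_
    norms = np.linalg.norm(flux, axis=1)
    gnorms = np.linalg.norm(grid, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.einsum("ij,ij->i", grid, flux) / (gnorms * norms)
    zero_flux = norms == 0
    h[zero_flux] = np.nan
    mask = np.where(np.isnan(h), False, h >= threshold)
    if mask.any():
        order = np.argsort(np.where(np.isnan(h), -np.inf, h), kind="stable")[::-1]
        best = order[: min(top_k, int(mask.sum()))]
        centroid = grid[best].mean(axis=0)
        equi = np.full(grid.shape[1], 1.0 / grid.shape[1])
        dists = np.linalg.norm(grid - equi, axis=1)
        mean_repro_dist = dists[mask].mean()
        percentile = 100.0 * float(np.mean(dists < mean_repro_dist))
    else:
        centroid = None
        percentile = float("nan")
    return ScreenResult(
        grid=grid,
        h_values=h,
        threshold=threshold,
        reproducer_mask=mask,
        centroid=centroid,
        equimolar_distance_percentile=percentile,
        n_zero_flux=int(zero_flux.sum()),
        species=list(model.species),
    )


def binary_homeostasis_point(
    k_a: float, k_b: float, beta_ab: float, beta_ba: float, tol: float = 1e-12
):
    """Composition at which two species' exit rates intersect.

    Solves ``k_A (1 + f_B beta_AB) = k_B (1 + (1 - f_B) beta_BA)`` for the
    modulator fraction ``f_B``; at that composition both lipid types show an
    identical exit flux (perfect binary compositional homeostasis).  Returns
    ``(f_B, valid)`` where ``valid`` flags f_B within [0, 1].
    """
    denom = k_a * beta_ab + k_b * beta_ba
    if abs(denom) <= tol:
        raise ValueError("no unique intersection: k_A beta_AB + k_B beta_BA is zero")
    f_b = (k_b * (1.0 + beta_ba) - k_a) / denom
    return float(f_b), bool(0.0 <= f_b <= 1.0)
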