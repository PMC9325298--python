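# Methods

This note documents the models, estimators, numerical choices and known
limitations of `micellekin`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Cluster detection and tracking

Two lipids are in contact when their minimum inter-atomic distance, over
all atom pairs and under the minimum-image convention in an orthorhombic
box, is at or below the cluster cutoff (default **0.24 nm** — twice the
hydrogen van der Waals radius, i.e. the closest approach of two molecules
in contact). Clusters are connected components of this contact graph
(single linkage). The cutoff is applied to *all* atoms, hydrogens included
when present; for the 4–5 pseudo-atom toy lipids every atom participates.
Neighbour search uses a periodic KD-tree (`scipy.spatial.cKDTree` with
`boxsize`), which is exact — the test suite checks identity with an
all-pairs union-find on random frames, including wrap cases in tight boxes.

Cluster identity over time is assigned by maximal lipid-set overlap with
the previous frame. A fusion product inherits the id of the larger parent;
on fission the id stays with the fragment sharing most members. Both rules
tie-break deterministically towards the parent/fragment containing the
lowest lipid id. Monomers (size-1 sets) carry no cluster id. The mean
cluster-size series excludes monomers, so it starts at 2 when the first
dimer forms.

## Event extraction

A **residence** spans a probe's first to last contact with one tracked
cluster. Contact gaps shorter than the *grace* interval (default 10 ps,
matching noise at 2 ps recording intervals) are bridged when the probe is
monomeric throughout the gap; touching a different cluster id always ends
the residence. Residence-level cluster size and composition are time
averages over the residence **excluding the probe itself**, so modulator
fractions are uncontaminated by the probe species. The exit filter keeps
residences > 1 ns with ≥ 10 resident monomers (time-averaged, not counting
the probe — marginally stricter than counting it).

An **addition** spans two consecutive entries of same-species monomers
into one cluster; by convention the cluster at the second entry includes
the previously entered lipid. The addition time subtracts segments during
which no free probe exists, and the free-monomer concentration
(count/(N_A·V)) is averaged over the counted segments only. Pairing opens
once a cluster has reached the minimum analysis size (10), mirroring the
entry filter; membership in a trajectory's very first frame is not an
observed entry. The composition drift of an addition is the largest range
any species' fraction explores during the interval; reactions drifting
more than 5% of the total are excluded, as are additions ≤ 300 ps.

Event streams from the stochastic simulator are converted to reactions
exactly (`reactions_from_event_log`): durations come from event times and
compositions from closed-form time integrals of the cluster state, which
makes the simulator a ground-truth oracle for the trajectory-route
detectors (`timeline_from_event_log` + `detect_residences` reproduce the
same pairings with durations within one frame interval).

## Rate estimators and their behaviour

The estimators are reciprocal means, applied exactly as defined:
`k_exit = ⟨1/T⟩` (1/ns) and `k_entry = ⟨1/(τ·⟨C⟩)⟩` (1/(M·ns)), with
SEMs taken over the per-reaction reciprocal contributions. The
minimum-duration filters bound the reciprocals; without them ⟨1/T⟩ would
diverge for exponential waiting times.

A consequence worth stating plainly: for exponential waiting times with
rate k and a minimum-duration filter t₀, the estimator converges to
`E[1/T | T > t₀] = k·E₁(k t₀)·e^{k t₀}`, which exceeds k by a factor of
roughly `ln(1/(k t₀))`. Relative *changes* of the estimate with
composition are correspondingly attenuated: the elasticity of the
estimator with respect to k is `(1+x) − 1/(E₁(x)e^x)` at `x = k t₀`, about
0.6–0.8 in the regimes analysed here. β values inferred from these
estimators therefore under-shoot the generating values systematically, by
an amount comparable to (and, at the prescribed event counts of ~500–1000
per composition bin, within three standard errors of) the statistical
uncertainty of the fit. The exit channel (x ≈ 0.02) sits in the benign
part of this trade-off; the entry channel operates at x ≈ 0.3, where the
attenuation (~50%) dominates any plausible standard error, so
truth-recovery round trips are only asserted for the exit channel. The
entry machinery is instead verified against deterministic constructed
reactions where the estimator arithmetic is exact. This is a property of
the estimator definition, kept deliberately for fidelity; survival-style
maximum-likelihood alternatives are out of scope.

Composition-resolved rates are binned on the modulator fraction with bins
centred on multiples of 0.10 (matching the discrete mixture-ratio grid of
the binary systems); the binary analysis restricts to reactions whose
clusters contain probe and modulator species only.

## β-matrix inference

For each probe–modulator pair the binned rates are fitted by weighted
least squares (weights 1/SEM², falling back to event counts when any bin's
SEM is undefined), and β = slope / basal rate with the basal rate measured
in pure (100%-probe) clusters — the two-step procedure, not the fitted
intercept. The diagonal is fixed at 0: same-species modulation *is* the
basal condition. β is also reported as a percentage (exactly 100×), with
star annotations on the weighted R²: 1 star for [0.55, 0.7), 2 for
[0.7, 0.85), 3 for [0.85, 1]. A probe without an estimable basal rate
flags its whole row as absent (NaN), never silently zero. β standard
errors propagate both the slope SE and the basal-rate SE.

## Mechanism analyses

**HIP** (headgroup interaction prevalence): per residence, the fraction of
time steps in which a probe headgroup moiety sits within **0.3 nm** of a
given moiety type in the cluster (minimal distance over that type's
atoms). Fold changes compare mean HIP between long (> 10 ns) and short
(1–2 ns) residences with an unequal-variance two-sample t-test (group
sizes and variances differ; a paired design does not apply); pairs beyond
fold ≥ 2.5 and p ≤ 10⁻⁵ are flagged salient. A zero short-group mean
leaves the fold undefined and flagged.

**Dynamic HIP shift**: reactions are split into modulator-rich (≥ 50%,
ties assigned rich — a deterministic resolution of the open boundary) and
modulator-poor (< 50%) groups by the involved cluster's composition;
per-step interaction prevalence over the first (or last) 0.5 ns of
residence, aligned on first (last) contact, is smoothed with a 10 ps
sliding window and differenced (rich − poor). Only cross-species pairs are
informative; same-species pairs are excluded.

**Probe orientation**: the angle α between the lipid vector (prominent
head atom → terminal tail carbon) and the head-to-cluster-centre vector,
both as minimum-image displacements. The cluster centre is the unweighted
mean of the non-probe members' head-atom positions — stable, cheap and
probe-exclusive. α = 0° is radial (tail towards the centre), 90°
tangential. Orientation shifts between composition groups use the same
split/window/smoothing machinery; only single-moiety probes are analysed
by default (zwitterionic heads make the head reference ambiguous).
Degenerate zero-length vectors skip the step and are counted.

The smoother is a centred moving average, edge-truncated (the window
shrinks near the series ends). Edge truncation means the full-series mean
is preserved only approximately (exactly, for constant series); the
smoothed values never leave the data's range.

## The GARD screen

The accretion flux uses the composition-fraction form
`dn_i/dt = C_i·k_entry,i·(1+Σ_j f_j β_entry,ij) − k_exit,i·(1+Σ_j f_j β_exit,ij)`
with the exit term *not* scaled by the species' own abundance — the
canonical flux expression used here as the default. An alternative mode
(`exit_scaled_by_composition`) multiplies the exit term by f_i for
consistency with per-monomer stochastic kinetics, where total exit scales
with the number of residents; both conventions are exposed because the
choice changes which compositions are homeostatic. The simulator always
uses per-monomer exit propensities (the physically meaningful stochastic
kinetics).

H is the cosine similarity between the fraction vector and its flux —
scale-free in both arguments, so fractions versus counts is immaterial.
Zero flux leaves H undefined (NaN, flagged, non-reproducer). The simplex
is enumerated exactly (stars-and-bars; 10 626 compositions for 5 types at
5%), reproducers are H ≥ 0.9, the typical reproducer is the centroid of
the 10 best, and the distance-from-equimolar percentile is the fraction of
grid compositions whose **Euclidean** distance to equimolar is smaller
than the reproducer set's mean distance (Euclidean being the minimal
metric assumption). The binary homeostasis point solves
`k_A(1+f_B β_AB) = k_B(1+(1−f_B) β_BA)` in closed form, with a validity
flag for f_B ∈ [0, 1] and an error when the denominator degenerates (every
composition, or none, is an intersection).

## The synthetic-data generators

The **Gillespie simulator** implements monomer-exchange kinetics: entry of
a free monomer of species i into cluster c at
`C_i,free·k_entry,i·(1+Σ_j f_j(c)·β_entry,ij)` per cluster, per-monomer
exit at `k_exit,i·(1+Σ_j f_j(c\{probe})·β_exit,ij)`, and dimer nucleation
from free pairs. Compositions in propensities always exclude the moving
probe. Whole-cluster fusion is deliberately absent: the analysed regime is
stepwise monomer accretion, and fusion would contaminate residence
bookkeeping. Configurations whose β-matrices admit a negative propensity
anywhere on the composition simplex (checked at the simplex vertices,
where the affine propensity factor is extremal) are rejected with a
diagnostic naming the probe and offending pure composition.

Defaults emulate the depleted-monomer study conditions: 54 monomers in a
7.4³ nm³ box (~220 mM, well above CMC), `k_entry = 50 /(M·ns)`,
`k_exit = 0.02 /ns` and `k_nucleation = 0.2 /(M·ns)`. The exit/entry
scale puts typical residences (~50 ns) well above the 1 ns filter and
leaves ~10% of monomers free at steady state; the nucleation rate is slow
relative to growth so that monomers deplete within the first ~10% of a
50 ns run into a handful of clusters with aggregation numbers ~12–26 —
the observed plateau regime — rather than a spray of dimers. With these
numbers the *printed* entry and exit coefficients differ by 2–3 orders of
magnitude. Study designs for β recovery (`micellekin.study`) size each
run's duration analytically from the configured rates so the minority
species reaches a target of ~600 filtered exit events per mixture ratio;
durations are fixed by this closed-form design, not adjusted afterwards.

The **toy-frame generator** lays cluster members on a snake-ordered
lattice (0.15 nm spacing) inside each packing radius, so nearest-neighbour
head distances sit below the cluster cutoff by construction while
clusters, free monomers and the box images stay separated by more than the
cutoff plus the lipid extent; the ground-truth partition is therefore
unambiguous in every frame. Probes can be placed at a prescribed
orientation angle to the cluster centre (recovered exactly at zero
jitter). Per-atom Gaussian jitter above 0.01 nm is rejected because it
would void the partition guarantee.

What the generators do **not** emulate: force-field physics, water and
electrostatics, size-dependent exit rates (real micelles hold monomers
more tightly as they grow — the mechanism behind monomer depletion at
fixed rate constants), cluster fusion/fission kinetics, and vesicle
geometry. Passing tests therefore demonstrate the correctness of the
bookkeeping, estimators and inference on data whose generating process is
known — not that any particular chemistry behaves this way.

## Numerical and design choices

- Lipid ids are assigned contiguously per species in the simulator; event
  logs record nucleation partners and dissolution releases explicitly so
  that event times stay strictly increasing and conservation is checkable
  row by row.
- All composition fractions must sum to 1 within 1e-9; cosine similarity
  and the flux evaluation are vectorised over the full grid (the 5-type
  screen completes in well under a second).
- Tie-breaks (cluster tracking, the 50% group split) are documented above
  and deterministic; the whole pipeline is bit-reproducible for a fixed
  seed, which the manifest (parameter echo, seed, per-stage counts, sha256
  checksums) makes verifiable.
- The trajectory route samples free-monomer counts per frame and treats
  them as piecewise-constant; the event-log route integrates them exactly.

## Known limitations

- The reciprocal-mean estimators are biased for heavy-tailed waiting-time
  distributions (see above); comparisons across compositions remain
  monotone, but absolute rates and β magnitudes inherit the attenuation.
- Entry-channel β recovery from simulated streams is additionally
  confounded by composition-dependent free-monomer concentrations across
  mixture ratios (the filter bites differently per ratio), so entry β
  values from event streams should be read as qualitative.
- Multi-cluster simultaneous contacts are resolved by cluster membership
  (single linkage assigns each lipid to exactly one cluster), not by
  contact-atom counting.
- Triclinic boxes, SASA analysis and free-energy estimates are out of
  scope.
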