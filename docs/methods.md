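# Methods

## The sampling scheme

`flycast` implements a zone-based generalized-ensemble sampling method for
ligand–receptor binding, together with the weighted-ensemble statistics
used to characterize binding pathways.  The scheme works in a space of
reaction coordinates (RCs), each defined as the distance between the
centroids of two named atom groups (`rc_zones.RCDef`).  Each RC axis is
divided into ordered, pairwise-overlapping intervals ("zones"); the
Cartesian product over axes forms the zone grid.

A sampling iteration runs many short trajectories in parallel.  Each
trajectory is confined to its current zone by a flat-bottom restraint
(zero inside the zone's box, half-harmonic `½k δ²` per axis outside — once
continuously differentiable across the boundary).  Every `Δτ_trns` steps an
inter-zone transition is attempted: the candidate set is every zone whose
box contains the instantaneous RC value, and the new zone is drawn with
probability proportional to each candidate's **zone-conditional** canonical
density there,

```
P(z | λ)  ∝  Q(λ, z) / (M_z · v_z)
```

where `Q(λ, z)` is the current estimate of the canonical probability mass
of λ's bin inside zone `z`, `M_z` the zone's total mass and `v_z` its bin
volume.  Dividing by the zone mass makes the pairwise zone-hopping rates
symmetric, so when the estimate is exact, the stationary distribution of
zone visits is *uniform* — the flattening property that lets the sampler
cross free-energy barriers that trap plain dynamics.  The within-zone
dynamics remain canonical (restricted to the zone), which is what the
estimator relies on.  This rule is validated empirically by the
canonical-recovery and visit-uniformity tests rather than asserted.

Snapshots (RC value, zone label, state) are stored at a fixed stride, and
are recorded *before* any transition attempt at the same step, so each
recorded pair reflects a maximally relaxed stretch of restrained dynamics.

Three numerical details matter for correctness and were found necessary
during validation:

* **Reflective outer walls.**  The RC coverage bounds act as hard walls.
  With soft walls only, the edge zones accumulate extra stationary mass in
  the restraint tail beyond the coverage, where no competing zone exists,
  which biases zone visits by ~10% and the recovered density with it.
* **Tail excursions are discarded, not clipped.**  When a per-zone RC
  histogram is accumulated, snapshots whose λ lies outside the zone box
  (soft-restraint excursions) are dropped.  Clipping them into the boundary
  bins inflates every zone's edge bins by the wall-tail mass; this was the
  dominant systematic error in early canonical-recovery experiments.
* **Relaxation between attempts.**  The interval between transition
  attempts should be comparable to or larger than the within-zone
  diffusion time; otherwise the distribution conditional on the zone label
  retains memory of the entry point (the overlap region) and the per-zone
  histograms are biased.

## Estimating the canonical density

The estimator (`qcano_estimator`) works on (zone, intra-zone bin) states,
10 bins per axis per zone by default (8 in the bundled double-well study).

1. **Within-zone update.**  `update_q` multiplies the previous density by
   the observed/expected count ratio per bin, with expected counts
   distributing the zone's total according to the previous density.  With
   that definition the update recovers the within-zone restricted-canonical
   shape directly from the histogram (the previous estimate cancels), and a
   uniform surface with uniform counts is an exact fixed point.  Empty
   observed bins receive an add-one pseudo-count so the correction stays
   finite; a zone with no counts keeps its previous values.
2. **Stitching.**  Each zone's scale is arbitrary, so zones are reconciled
   by weighted least squares over *every* overlapping zone pair: each pair
   contributes one observation of the difference of the zones' log scales
   (the log-ratio of mean densities over the shared overlap box, computed
   with exact fractional bin coverage so misaligned bin grids cannot bias
   the link), weighted by the effective counts both zones collected there.
   The normal equations form a graph Laplacian; the first zone pins the
   gauge.  With overlap fractions above one half, zones overlap at lag 2
   and beyond, and these redundant links suppress the scale random-walk
   that a sequential chain of nearest-neighbor ratios accumulates — in one
   dimension this redundancy is the difference between a usable and an
   unusable marginal at desk-scale sample sizes.
3. **GA smoothing.**  `ga_refine` polishes the stitched surface with a
   small genetic algorithm on log-density vectors.  Fitness penalizes
   (i) squared mismatch of mean log density across each overlap,
   (ii) squared second differences along each axis (roughness), and
   (iii) squared deviation from the input (fidelity).  The fidelity term is
   essential: without it a featureless flat surface is the global optimum.
   Selection is tournament (size 3), crossover exchanges whole zones,
   mutation is additive Gaussian at two scales — per-bin jitter (σ 0.02)
   and a common per-zone shift (σ 0.5), which is what lets the GA repair a
   mis-stitched zone within the default 100 generations.  The best
   candidate is carried over unchanged, so fitness never decreases and an
   already-consistent surface is returned exactly.  The roughness weight is
   deliberately tiny (0.001): density peaks adjacent to zone walls carry
   genuine curvature, and a stronger penalty measurably broadens them.
4. **Convergence.**  `e_local` scores each zone by the mean absolute
   log-ratio between consecutive estimates; a zone below the 0.25 gate is
   deemed accurately determined.  An alternative reading — overlap
   consistency of a single surface — is available via `mode="overlap"`.
   Per-zone histograms are pooled across iterations (the within-zone shape
   does not depend on the estimate the sampler ran under, so pooling is
   unbiased), which makes the diagnostic measure genuine stabilization
   rather than single-iteration noise.
5. **Reweighting.**  `snapshot_weights` assigns each snapshot a weight
   proportional to the estimated canonical density at its RC value divided
   by the sampled density there (a λ histogram over all snapshots on a
   zone-independent physical binning).  Because zones overlap, evaluating
   the density at a physical point averages the covering zones; weighting
   per (zone, bin) instead would double-count overlap regions.

## Dynamics backend

The engine is agnostic to the dynamics through a small vectorized contract
(`vcmd_engine.DynamicsBackend`): map states to RC values, pull an RC-space
gradient back onto state coordinates, and advance one step.  The bundled
backend is overdamped Langevin (Euler–Maruyama),

```
x_{t+1} = x_t − (Δt/γ) ∇U(x_t) + √(2 RT Δt/γ) ξ_t ,
```

with the RCs equal to the state coordinates, so the restraint pulls back
through an identity Jacobian.  Each run draws from its own RNG stream
derived from `(seed, iteration, run)`, so results are independent of
execution order and bitwise reproducible.  Euler–Maruyama's stationary
distribution carries an O(Δt) bias that grows where |∇U| is large; at the
bundled Δt = 0.005 (toy units) the bias in the double-well marginal is
below the statistical resolution of the validation targets, and halving Δt
was verified not to change the recovered moments materially.

## Desk-scale double-well study

The canonical-recovery workflow (`pipeline.converge_double_well`) runs the
full loop on a symmetric quartic double well, `U(x) = h((x²−a²)/a²)²` with
barrier `h = 1.8 kcal/mol` (≈3 RT at 300 K) and minima at ±1 Å on the
domain [−2.5, 2.5] Å.  Frozen study conditions (`pipeline.DEFAULT_CONFIG`):
8 zones with overlap fraction 0.75 and 8 bins per zone (the stride is then
exactly 2 bins, so bin grids of overlapping zones align), restraint spring
25 kcal mol⁻¹ Å⁻², 256 runs × 16,000 steps per iteration, transition
attempts and snapshots every 600 steps, 12–18 iterations with the 0.25
convergence gate.  These sizes were chosen so that the statistical power
of the run comfortably resolves the validation targets (L1 distance of the
reweighted marginal to quadrature, and the first two moments against their
quadrature values); the tolerances themselves were fixed first and never
adjusted.

Reported moment uncertainties combine two terms in quadrature: a run-block
standard error over the independent (iteration, run) trajectories, and a
parametric-bootstrap term that redraws the pooled per-zone counts
multinomially and re-runs the update/stitch, propagating
density-estimation noise (dominated by the stitched zone scales) into the
observables.

## Synthetic binding ensembles

`synthetic_models.generate_binding_ensemble` produces weighted snapshot
ensembles with *known* statistical structure so every analysis statistic
can be checked by parameter recovery.  The template system is a rigid
eight-atom receptor frame (the alignment selection), a pocket site, an
11-bead disordered tail (capping group plus ten residues, tip to root), a
12-atom rigid ligand with a planar six-ring core and a sulfonamide-like
appendage, and four dedicated receptor contact-site atoms.  Per snapshot:

* the ligand centroid is drawn from a mixture of a Gaussian at the pocket
  (weight 0.35, σ 4 Å) and a diffuse uniform-radius shell (5–62 Å);
* the tail beads realize exact Bernoulli draws from a per-(slice, residue)
  contact-probability table shaped like a two-basin tip-capture /
  root-capture pattern (contact beads placed 3.0–4.5 Å from a random
  ligand atom, non-contact beads beyond the cutoff plus a margin);
* the ligand orientation is the native pose rotated about a random axis by
  a wrapped-Gaussian angle of width 1/√κ, with κ = 50 inside the pocket
  slices and 0.5 outside — only the limits (κ→0 randomizes, κ→∞ orders)
  and the monotone ordering are relied upon, not an exact directional law;
* the four native contacts form with logistic probability curves in the
  centroid displacement r_bb, realized by placing each receptor site atom
  inside or outside its cutoff;
* finally the whole snapshot receives a random rigid motion, so analyses
  must perform the receptor-frame superposition exactly as with real data.

What the generator does **not** emulate: real energetics (snapshot weights
are uniform by default, not Boltzmann), correlations between the contact
channels (all Bernoulli draws are independent; the receptor-side partner
of the sulfonamide-nitrogen contact is even given its own pseudo-atom so
each formation curve is independently controllable), membrane and solvent,
and internal ligand flexibility.  Passing recovery tests therefore
demonstrates that the *estimators* are correct and unbiased at the stated
sample sizes — not that the synthetic system resembles any particular
receptor's physics.

## Analysis conventions

* All spatial statistics are computed after superposing each snapshot onto
  the reference complex by the receptor alignment group only (batched
  proper-rotation Kabsch); the ligand is never fitted, so ligand RMSDs and
  displacements are measured in the receptor frame.
* Cube fields use 3 Å cubes.  Occupancy densities are max-normalized (peak
  = 1) so contour levels such as 0.5/0.1/0.01 are directly meaningful; raw
  probability mass is available via `normalize="mass"`.
* The r_bb axis is divided into 13 half-open 5 Å slices `[5(k−1), 5k)`; an
  exact boundary multiple belongs to the upper slice.  Native-contact
  profiles use half-open 0.5 Å windows centered at 0.25, 0.75, … Å.
* Contact criteria are minimum heavy-atom distances below 5.0 Å by default
  (hydrogen/deuterium filtered by element, name-prefix fallback), shared
  between tail contacts and native contacts and config-exposed.
* Potentials of mean force are `−RT ln p` with RT from the CODATA gas
  constant at the configured temperature (0.5961 kcal/mol at 300 K).
  Empty cubes, slices and windows are flagged undefined, never imputed:
  the PMF of an unsampled bin is +∞, not a large finite number.
  Per-slice minimum-distance PMFs are shifted so each slice's minimum is 0
  (display convention, switchable).
* The RMSD radial distribution function is the distance distribution
  function divided by the shell volume `4πR²` at bin centers and
  renormalized — a stated convention, consistent with the expected peak
  ordering (RDF peak below DDF peak), not a claimed reproduction of any
  particular definition.
* Orientation-vector anchors are configuration data (two anchor-atom pairs
  inside the rigid ligand core); the bundled synthetic template documents
  a default (ring atoms C1→C4 and C6→C2, perpendicular in-plane
  directions).  Centroids are unweighted by default; mass weighting is a
  flag.

## Known limitations

* The zone-scale estimation error across a barrier is carried entirely by
  the overlap counts in the barrier region; it shrinks as 1/√counts and,
  in one dimension, as the connectivity of the overlap graph grows.  Very
  deep barriers need either more overlap redundancy or more data.
* Euler–Maruyama is first-order; steep potential regions need a small time
  step, and the restraint spring must satisfy `k·Δt/γ ≪ 1` for stability.
* Coordinate snapshots are exchanged as multi-model PDB; atom identity
  across file round trips is by (chain, residue number, atom name), since
  the PDB writer renumbers serials across TER records.
* The bundled backend covers analytic toy potentials only; coupling a real
  MD engine means implementing the backend contract, which is out of scope
  here.
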