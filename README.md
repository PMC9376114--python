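# flycast

Zone-based enhanced sampling with canonical reweighting, and the
weighted-ensemble statistics used to dissect ligand–receptor binding
pathways (fly-casting capture by a disordered tail, ligand sliding,
orientational selection, native-contact formation) — packaged so that every
component is verifiable at desk scale on analytic toy potentials and
synthetic ensembles with known ground truth.

It is aimed at people developing or studying generalized-ensemble methods
for molecular binding: the sampler, the density estimator and every
analysis statistic come with independent oracles (quadrature, brute-force
tallies, parameter recovery), so the package doubles as a reference
implementation and a test bed.

## The method in brief

Reaction coordinates λ are centroid–centroid distances between named atom
groups.  RC space is split into overlapping zones; between transition
attempts (every Δτ_trns steps) the system moves freely inside its current
zone under a flat-bottom restraint.  At an attempt, the zones containing
the instantaneous λ compete with probability proportional to their
zone-conditional canonical density — which makes zone visits uniform when
the density estimate Q_cano is exact, so the sampler crosses barriers that
trap plain dynamics.  Iterating sample → update → smooth, the estimate of
Q_cano(λ) is built from per-zone RC histograms: within-zone shapes come
from the restrained dynamics, zone scales from a count-weighted
least-squares stitch over all overlap regions, and a genetic algorithm
polishes the surface in log space.  A zone is converged when the mean
absolute log change E_local drops below 0.25.  Finally each stored
snapshot gets a canonical weight ∝ Q_cano(λ)/n_sampled(λ), turning the
biased archive into a canonical ensemble at the simulation temperature.

On that weighted ensemble the analysis module computes, in the
receptor-superposed frame: spatial occupancy densities ρ(r_cube) on a 3 Å
cube grid, cube contact ratios c̄ ∈ [0,1], per-residue contact free
energies F(j) = −RT ln ρ_cnt(j) resolved in 5 Å shells Δ_k of the ligand
displacement r_bb, minimum-distance potentials of mean force
PMF(r) = −RT ln P(r), averaged orientation-vector fields v̄ with scalar
products SP = ê(v̄)·v_ref against the native pose, native-contact count
profiles N_cnt(r_bb) ± SD in 0.5 Å windows, RMSD distance/radial
distribution functions, and a Henderson–Hasselbalch neutral-fraction
helper, 1/(1 + 10^(pH−pKa)).

See `docs/methods.md` for the full model description, parameter defaults
and numerical conventions.

## Worked example

The bundled end-to-end study runs the full loop — sample under the current
estimate, update and GA-refine, check E_local, reweight — on a 1-D double
well (barrier ≈ 3 RT) where quadrature ground truth is available:

```python
>>> from flycast.pipeline import converge_double_well
>>> r = converge_double_well(seed=1)       # ~40 s on one core
>>> print(f"converged after {r.iterations_run} iterations; L1 = {r.l1_distance:.3f}")
converged after 12 iterations; L1 = 0.030
>>> print(f"<x>  = {r.mean_x:+.4f} +/- {r.se_x:.4f}   (quadrature {r.quad_mean_x:+.4f})")
<x>  = -0.0011 +/- 0.0172   (quadrature +0.0000)
>>> print(f"<x2> = {r.mean_x2:.4f} +/- {r.se_x2:.4f}   (quadrature {r.quad_mean_x2:.4f})")
<x2> = 0.8940 +/- 0.0026   (quadrature 0.8899)
```

`L1` is the total-variation-style distance between the reweighted λ
histogram and the quadrature Boltzmann marginal on the estimator's own
binning — 0.03 means the recovered equilibrium distribution is accurate to
a few percent of probability mass.  Both moments agree with quadrature
within their (sampling + estimation) standard errors.  The protonation
helper reproduces the standard blood-pH result for a pKa 5.1 sulfonamide
acid:

```python
>>> from flycast.binding_analysis import neutral_fraction
>>> print(f"{100 * neutral_fraction(5.1, 7.4):.1f}%")
0.5%
```

The same workflows are scriptable from the shell:

```bash
flycast sample       --config run.yaml --output out/   # double-well loop
flycast generate-toy --config run.yaml --output out/   # synthetic ensemble
flycast analyze      --config run.yaml --output out/   # binding statistics
```

where `run.yaml` needs at least a `seed:` entry (all other keys have
documented defaults; `flycast sample --help` lists them).  `analyze`
writes the occupancy density as OpenDX (`density_CMb.dx`, loadable in
common molecular-graphics tools) and the contact/RMSD statistics as TSV.

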