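# Methods

## Model and procedure

A coarse protein model is a chain of backbone beads whose fold is maintained
by an interaction network: Go̅-type 12-6 Lennard-Jones contacts
(strength = well depth ε in kJ/mol, geometry = σ in nm, minimum at
2^(1/6) σ) or harmonic elastic-network springs (strength = κ in kJ/mol/nm²,
geometry = equilibrium length r₀).  The network topology is fixed throughout;
only strengths are optimized.  Default construction follows common
structure-based Martini practice: Go̅ contacts for pairs 0.3–1.1 nm apart in
the reference structure with sequence separation ≥ 3 and uniform
ε = 9.4 kJ/mol; elastic springs for pairs within 0.9 nm, separation ≥ 1,
κ = 500 kJ/mol/nm².  Equilibrium geometries can instead be refit to the mean
pair distances of a reference ensemble (σ = r̄/2^(1/6), r₀ = r̄).

The optimization target is the density of the reference ensemble projected
into its *essential subspace* — the span of the leading principal components
of the Cartesian covariance of the aligned trajectory.  The subspace is
computed once from the target and held fixed; every coarse ensemble is
rigid-body fitted (mass-unweighted Kabsch over all beads) to the target mean
before projection.  Superposition uses two passes on the target (fit to the
first frame, then to the resulting mean).

One outer iteration:

1. **Basis.** Evaluate each contact's energy in each frame of the current
   coarse ensemble, in units of k_BT (k_B = 0.00831446 kJ/mol/K, T = 300 K
   by default), and form the weighted mean ⟨L⟩ and covariance C with
   population normalization.  C is symmetrized and eigendecomposed
   (C = UΩUᵀ, eigenvalues clamped at zero below −1e-10); the per-frame
   centered eigenprojections B = Uᵀ(L − ⟨L⟩) make repeated evaluations of
   the estimator cheap.
2. **Search.** The package's sign convention is that λ_k > 0 *strengthens*
   contact k, i.e. the perturbed potential is V + Σ λ_k L_k and the
   second-order log density ratio used for reweighting is
   −λᵀ(L − ⟨L⟩) − ½λᵀCλ.  (`log_density_ratio` itself exposes the
   symmetric-form λᵀ(L − ⟨L⟩) − ½λᵀCλ; `reweight_frames` and the objective
   negate λ, so the estimator and the network update always move the
   ensemble in the same direction — covered by a self-consistency test
   against the sampler.)  A global-best particle swarm minimizes
   χ(λ) = Σ_cells |ln(ρ_target/ρ_cg) − ln(ρ_cg^λ/ρ_cg)| inside the trust
   region ‖λ‖_∞ ≤ 0.3, where ρ_cg^λ is the analytically reweighted density.
   Because the inverse problem is degenerate — many strength patterns
   produce the same projected density — the searched objective carries a
   minimum-norm tie-break: a ridge penalty worth `update_ridge` (default
   0.2) of the *initial* mismatch at the trust-region corner, which selects
   the smallest update among near-equal-χ candidates and, once the densities
   match, pins the preferred update at zero instead of letting it chase
   histogram noise.  The swarm's best is then polished by a bounded
   quasi-Newton (L-BFGS-B) descent, making the chosen update deterministic
   given the sampled ensemble.
3. **Update & sample.** The winning λ* is applied cumulatively
   (ε_k ← ε_k(1+λ_k), floored at 0.5 kJ/mol for Go̅ / 10 kJ/mol/nm² for
   springs) and a fresh ensemble is sampled under the updated network.
4. **Record.** SWD (order 3) between target and coarse projections, RMSIP,
   CO, RMSF average unsigned error, the objective value, the Kish effective
   sample size of the proposing reweighting, and the network snapshot.

The loop stops after 30 iterations or when the SWD has not improved by a
relative 0.02 for 5 consecutive iterations; the *best-SWD* iteration's
network is returned, not the last one.

## Densities and the objective

Eq-style density ratios require densities on a common support.  Projections
are histogrammed on a regular grid (default 30 bins per dimension) covering
the union support of target and current coarse projections padded by 5%,
smoothed with a 1-bin-σ Gaussian kernel, floored at 1e-8 and renormalized.
Cells where either the target or the unperturbed coarse density is at the
floor are excluded from χ: reweighting can only move probability between
visited regions, never create support.  The excluded target mass is logged
per iteration so non-overlap is visible.  Out-of-grid points are dropped
(closed-right convention on the upper edge), and reweighting reuses
precomputed frame-to-bin assignments, so one χ evaluation is a weight
update, a bincount and a smoothing pass.

## Similarity metrics

* **RMSIP** = sqrt((1/n) Σ_{pq} (v_p·w_q)²): geometry of the spans only.
* **Covariance overlap** = Σ_{pq} μ_p ν_q (v_p·w_q)² / (‖μ‖₂‖ν‖₂):
  eigenvalue-weighted overlap, normalized so that identical eigenvectors
  *and* eigenvalues score exactly 1 and orthogonal subspaces 0; the raw
  value is clamped to [0, 1].
* **Weighted 1-D Wasserstein** (order γ ≥ 1): exact merged-quantile
  integration of |Qa(u) − Qb(u)|^γ for step CDFs — no resampling; validated
  against a linear-program transport oracle on small instances.
* **Sliced Wasserstein** (default γ = 3, 1000 slices): mean of per-slice
  WD^γ over unit directions drawn as normalized Gaussians from a mandatory
  seed, then the γ-th root.  Frame weights are respected throughout, so
  reweighted ensembles can be compared without resampling.

Every SWD reported for an optimization is accompanied by the target's
split-half noise floor: the SWD between the first and second halves of the
target ensemble itself, which is the resolution limit of the comparison at
that sampling depth.  Contiguous halves are used deliberately so that
autocorrelation inflates the floor honestly.

## Toy models and the sampler

The built-in sampler exists so the full loop runs and is falsifiable at desk
scale.  `make_toy_protein` builds a 20-bead two-domain fold: two two-turn
helices (radius 0.23 nm, rise 0.15 nm/bead, 3.6 beads/turn) docked
antiparallel on axes 1.45 nm apart, joined by a four-bead arched linker.
The axis separation is chosen so the inter-domain interface is carried by
only a few contacts near the cutoff edge: each domain is internally
cross-linked and semi-rigid, while the dominant principal components — the
inter-domain breathing/hinge motions — are governed by a handful of
load-bearing strengths.  On densely cross-linked single-domain folds a
uniform network at the mean strength reproduces the heterogeneous ensemble
almost exactly (redundant contacts average out), leaving nothing to
optimize; the sparse interface is what makes individual strengths matter.
Backbone bonds are harmonic with k = 5000 kJ/mol/nm² at the reference
spacing.

Sampling is Metropolis Monte Carlo at 300 K mixing two symmetric proposals:
single-bead Gaussian displacements (step auto-tuned during burn-in toward
30–50% acceptance, then frozen to preserve detailed balance) and, with
probability 0.3, pivot moves that rigidly rotate the chain tail about a
random bead by a Gaussian random-axis angle (σ = 0.25 rad).  Pivot moves are
essential: single-bead dynamics relaxes the collective hinge modes only
diffusively, and without them the split-half noise floor sits above the very
signal being optimized.  Energies are tracked incrementally (only terms
crossing the moved bead/pivot boundary are re-evaluated) and checked against
full recomputation.  Monte Carlo is used instead of Langevin dynamics
because only the equilibrium distribution matters here and the Boltzmann
target is then exact by construction.

The recovery fixture draws ground-truth strengths i.i.d. log-uniformly from
[4, 20] kJ/mol, samples the target under the ground truth with a
reference-grade schedule (8×10⁶ moves, 2×10⁵ burn-in, thinning 800 → 9750
frames), and starts optimization from the same topology at the ground-truth
mean strength.  Per-iteration coarse runs use the same length.  These sizes
were chosen so that the sampling noise floor of the SWD estimate sits well
below the typical uniform-vs-heterogeneous mismatch (measured signal/floor
≈ 5–7); the kernel samples millions of moves per second, so a full
three-replicate study still takes only minutes on one CPU.  Because the
strengths are i.i.d., occasional draws put the uniform mean so close to the
heterogeneous ensemble that no measurable mismatch exists; with
`validate=True` the generator enforces its contract — initial SWD above 3×
the target's split-half floor — by redrawing from sub-seeds spawned
deterministically from the input seed (attempts recorded in the ensemble
metadata).

What the toy does *not* emulate: solvent and electrostatics, side chains,
Martini nonbonded physics, barostats/thermostats, and the slow, activated
transitions of real proteins.  Passing recovery tests therefore demonstrates
the correctness and self-consistency of the estimator–objective–update loop
under exact Boltzmann sampling, not force-field accuracy on real systems.

## Numerical choices

* PSO: global-best, constriction-style defaults (inertia 0.729,
  cognitive = social = 1.494, swarm 40, 200 sweeps), box [−0.3, 0.3]^M,
  positions clipped, velocities clamped at half the box width, seeded.
  Inside the outer loop a lighter budget (swarm 24, 60 sweeps) is used — χ
  is smooth and the outer iteration re-linearizes anyway.
* Reweighting guards: log-weights are max-shifted before exponentiation;
  total underflow raises with advice to shrink the trust region; Kish
  ESS below 5% of the frame count triggers a warning.
* Covariance estimation is population-normalized with no shrinkage (M ≪ F
  in intended use); eigenvalues are clamped at zero.
* The essential-subspace dimension is capped at 5 (refused above): higher
  dimensions undersample the density grid at realistic frame counts.
* Degenerate inputs: superposition against collinear/coincident references
  warns but returns the fit; single-frame RMSF warns and returns zeros;
  uniform networks make strength Pearson correlations undefined and raise
  explicitly.
* `.itp` rewriting edits only the σ/ε (or r₀/κ) tokens in place, mimicking
  the original token's decimal count and right-aligning to its column width;
  unchanged values are re-emitted verbatim, so an unedited network
  round-trips byte-identically.  The accepted grammar is the martinize2-style
  Go̅ dialect ([ atomtypes ] names ending in `_<1-based index>` plus
  [ nonbond_params ] rows `type_i type_j 1 σ ε`) and harmonic
  [ bonds ] rows `i j 1 r₀ κ`; other sections pass through untouched.

## Known limitations

* Only strengths are optimized — not equilibrium distances, not topology.
* The second-order estimator is trusted only inside ‖λ‖_∞ ≤ 0.3 per
  iteration; strongly non-Gaussian contact-energy statistics (e.g. a contact
  that breaks bimodally) degrade single-step accuracy, which the iterative
  re-sampling compensates.
* The solution is degenerate by design: many strength patterns encode the
  same essential dynamics, so replicate optimizations agree only partially
  at the network level while being equivalent at the ensemble level.  The
  minimum-norm tie-break makes replicates agree well beyond chance, but it
  biases solutions toward the starting network; the recovered strengths are
  one representative of the solution manifold, not the ground truth.
* The χ objective compares densities cell-wise on the sampled support; it
  cannot reward populating target regions the coarse model has never
  visited.
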