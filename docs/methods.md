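# Methods

This note documents the models and procedures implemented in `conflock`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the field's common
practice leaves room.

## Superposition and stability metrics

All deviation metrics superpose structures with the Kabsch least-squares fit
(SVD of the cross-covariance; the sign of the smallest singular direction is
corrected so the rotation is always proper).  Fits on fewer than three atoms
or on collinear atom sets are rejected as degenerate.

* **RMSD series** fits every frame to a reference on a fit mask and measures
  over a measure mask.  The default reference is the first frame of the
  system, so each series starts at zero; an external reference (e.g. a
  crystal structure) can be passed instead.  Both Cα and backbone masks are
  supported; Cα is the default.  Which of the two a published curve used is
  often ambiguous, so neither is asserted as canonical.
* **Rg** is mass-weighted by default (the standard convention); unit weights
  are available.
* **RMSF** (and every covariance-based analysis downstream) uses *iterative
  mean alignment*: starting from the raw coordinate mean, all frames are fit
  to the running mean and the mean recomputed until it moves by less than
  1e-6 Å RMSD (max 10 rounds).  Starting from the raw mean rather than any
  single frame makes the converged result invariant under frame permutation
  and avoids privileging frame 0.  This removes global drift but, like any
  superposition, it also absorbs a small part of genuinely collective
  internal modes (see the DCCM caveat below).

## Dynamic cross-correlation and domain networks

The DCCM is computed on aligned Cartesian deviations of Cα atoms,
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), without mass weighting.
Zero-variance atoms make the ratio undefined and raise an error naming the
atom (the threshold is relative, 1e-12 of the largest variance, because
exact-zero variance leaves ~1e-30 rounding residue).

Concatenated replicates are analysed with a single global mean; a
per-replicate mode is available.  Domain reduction averages signed C_ij over
residue-set pairs: inter-domain weight = mean over i∈a, j∈b; self-weight =
mean over unordered intra-domain pairs.  Signs are retained (positive and
negative coupling are different biology).  The display threshold defaults to
0.25 — a round value chosen once for legibility, configurable, with no claim
of optimality.  The only built-in domain default is the Sestrin2 C-terminal
domain (residues 339–480) plus Cys125; all other domain boundaries are
config inputs because no standard annotation exists for them.

**Caveat:** superposition partially absorbs collective modes.  When a block
of residues moves coherently, the rigid-body fit assigns part of that motion
to the global frame, shrinking the apparent correlation.  The
planted-correlation validation therefore evaluates the estimator in the
generator's lab frame (`pre_aligned=True`), where the closed-form expectation
holds exactly; on real trajectories, where the lab frame is meaningless,
aligned DCCMs should be read as conservative.

## PCA, DBSCAN census, free-energy landscape

PCA is the eigendecomposition of the 3N-dimensional Cα coordinate covariance
(computed as an SVD of the centred frame matrix), after iterative mean
alignment, per system on its concatenated replicates.  Scores are projections
onto the top two components; each eigenvector's largest-magnitude component
is made positive so projections are reproducible across implementations.
A joint-basis mode (one PCA over several systems' concatenated frames) exists
for strict cross-system comparability of score coordinates.

**DBSCAN** is the package's own implementation, written to the textbook
definition: a point is core iff its closed ε-neighbourhood (Euclidean,
including the point itself) holds ≥ `min_samples` points; clusters are
connected components of density-reachability; border points join the first
cluster that reaches them in index-ordered expansion; everything else is
noise (−1).  Point order can only affect border-point ties, so order
invariance is asserted on the noise set and the partition of core points.
scikit-learn's DBSCAN is used in the tests as an independent cross-check,
never as the implementation.

**ε calibration** follows the k-distance construction (k = 4 by default):
sort every point's distance to its k-th nearest neighbour ascending and take
the elbow.  "Maximum curvature" is operationalised as the Kneedle rule — the
point of maximum perpendicular distance to the chord joining the curve's
endpoints, on axes normalised to [0, 1].  One refinement proved necessary: a
meaningful elbow must separate a sparse regime from the dense bulk, so when
the elbow's k-distance is less than 3× the median k-distance (or the curve is
flat), the curve is treated as a single density regime, a warning is issued,
and ε falls back to the curve maximum — for a unimodal cloud, anything
smaller shreds the distribution's tail into spurious fragments.  The factor 3
sits between the ratios observed for genuinely unimodal projections (≈ 2–2.7)
and genuinely multi-regime ones (≳ 3.3); it is a heuristic and the documented
failure mode of the census (below) lives near this boundary.

The **census** counts distinct non-negative labels (stable states), the
noise fraction, and per-state populations sorted descending; the population
table reports S1..S6 plus an "Other" bar aggregating remaining states and
noise.  The **free-energy landscape** maps the PC1/PC2 histogram to
ΔG = −k_B T ln(P/P_max) with k_B = 0.0019872 kcal mol⁻¹ K⁻¹ and T = 310 K
(the simulated physiological temperature), 100 contour levels.  Referencing
to P_max pins the global minimum at exactly 0 so landscapes are comparable
across systems.  Empty bins carry a finite cap (max finite ΔG plus one
level spacing) instead of infinities so grids stay renderable and
serialisable.

## Contact detection

Geometric criteria are standard-practice defaults, all exposed as config
keys: H-bond donor-heavy–acceptor ≤ 3.5 Å with donor–H…acceptor angle ≥ 120°
when an explicit hydrogen is present (within 1.25 Å of the donor heavy atom);
pure heavy-atom distance otherwise, which is the operative rule for
coarse Cα-level topologies; hydrophobic = any apolar-carbon pair ≤ 4.5 Å;
ionic = opposite formal-charge group centroids ≤ 4.0 Å; water bridge = one
water oxygen satisfying the H-bond distance rule to both partners in the same
frame.  Occupancy is presence-based (≤ 1 per residue, type and frame), so
fractions are comparable across ligands of different sizes.  π-stacking,
π-cation and halogen classes are out of scope.  Role flags (donor, acceptor,
apolar carbon, formal charges) are inferred from atom/residue names by a
documented rule table when reading PDB files, and can be set explicitly on
programmatically built topologies.

## Binding-energy statistics

The MM/GBSA component values are inputs (kcal/mol; components ΔG_bind,
ΔE_vdW, ΔE_Coulomb, ΔG_Lipo, ΔG_SolvGB, E_StrainLig).  Summaries use the
sample SD (n−1).  System comparisons use the independent two-sample *t*-test;
the pooled-variance form is the default — at n = 3 replicates per system it
is the textbook small-sample comparison and reproduces the published
significance levels for the Sestrin2–BCAA systems — with Welch available.
A summary-statistics entry point (mean, SD, n) exists because published
tables usually provide only those.  Zero pooled variance with equal means
returns t = 0, p = 1 by convention; with unequal means it is an error.  Tests
are taken over replicate means (n = 3), not frames, and no multiple-testing
correction is applied to the two planned comparisons.

## The synthetic-trajectory generator

The generator emulates the statistical structure of a replicate MD ensemble
study — it is not an MD engine (no force field, no thermostat, no solvent).
Per system it plants:

* **Geometry.**  A self-avoiding random Cα chain (3.8 Å bonds, 3.0 Å
  self-avoidance).  K basins displace every residue by Δ (default 5 Å) along
  basin-specific directions drawn from a planted two-dimensional "essential
  mode" plane (equally spaced angles on a circle, random offset).  Confining
  basins to a plane makes the dominant coordinate variance genuinely
  two-dimensional, which is the assumption the PC1/PC2 census rests on;
  with per-residue-orthonormal mode fields, every basin displaces each
  residue by exactly Δ and pairwise basin RMSD is 2 sin(π/K)·Δ.
* **Kinetics.**  Dwell segments with geometric length (memoryless — only
  occupancies and noise fractions are analysed, not rates); each new
  segment's basin is drawn i.i.d. from the occupancy vector, so the
  stationary distribution is exact.  A switch between distinct basins
  inserts m (default 6) interpolated transition frames labelled −1.  The
  default dwell is derived from the target noise fraction f via
  d = m·q·(1−f)/f with q = 1 − Σπ² the probability that a new segment is a
  genuine switch.
* **Transition paths.**  Interpolated frames follow a per-switch *bowed*
  path: a transverse offset of amplitude ~N(0, (0.08·|b−a|)²) in the mode
  plane, shaped 4t(1−t).  Purely linear corridors proved unrealistic in an
  instructive way: repeated switches between the same basin pair stack onto
  one line and accumulate enough local density to form spurious 4-point
  clusters, which no real transition ensemble does.  The bow keeps
  transition frames in low-density corridors between basins while
  decorrelating successive switches.
* **Correlated motions.**  Rank-1 blocks: a shared standard-normal latent
  factor times one fixed unit direction, added to every residue of both
  block sides (sign per spec).  With isotropic noise σ the inter- and
  intra-block correlation has the closed form ρ = g²/(g² + 3σ²), inverted to
  choose the factor strength g for a requested ρ.
* **Ligand contacts.**  One dedicated pseudo-ligand atom per requested
  interaction type, placed at ideal contact geometry (H-bond 2.9 Å,
  hydrophobic 4.0 Å, ionic 3.5 Å, water bridge 2.8 Å per leg via a
  pseudo-water) in a Bernoulli(bound_fraction) subset of frames and at ~10 Å
  otherwise.  The realized per-type fraction is recorded as ground truth.

Defaults mirror a scaled-down replicate study: 3 replicates × 1000 frames at
100 ps/frame, 40 residues, Δ = 5 Å = 10σ, 10% target noise.  The real study
design this emulates used 3 replicates × 5000 frames of a ~480-residue
protein; the desk-scale problem sizes keep the full validation suite and the
acceptance script within minutes on one CPU while preserving every
statistical feature the pipeline consumes.  What the generator does **not**
emulate: anharmonic basin shapes, solvent and friction, realistic secondary
structure, gradual (non-interpolated) barrier crossings, and ligand-induced
changes to protein flexibility — so passing tests demonstrate correctness of
the estimators on data satisfying their assumptions, not robustness to every
pathology of real trajectories.

## Validation design and measured behaviour

Every estimator is checked against an independent oracle: brute-force
rotation search for Kabsch; direct-summation re-implementations for RMSD, Rg
and RMSF; a double-loop oracle for the DCCM; an O(n²) union-find
density-reachability oracle (and scikit-learn) for DBSCAN; closed forms for
Rg of simple bodies, the 2:1-occupancy free-energy gap (k_B·310·ln 2 = 0.427
kcal/mol) and DCCM sign limits; and scipy's t-test on raw data for the
summary-statistics t-test.

End-to-end, the pca → k-distance ε → DBSCAN → census chain recovers the
planted basin count exactly and the noise fraction within ±0.02, in
roughly 90–100% of seeded runs per K ∈ {1, 2, 3, 5, 9} (typically 19–20 of
20).  The two known failure modes are: (i) a spurious extra cluster when ≥ 4
transition frames land within ε of each other — a genuine property of a
density-based census at finite sampling, the same sensitivity that makes
published state counts wobble by ±1; and (ii) borderline single-regime
calibration for K = 1, where the elbow-ratio heuristic sits near its
threshold.  Neither is patched post hoc: the census reports what the density
structure supports.

The occupancy-recovery tolerance deserves a note: successive dwell segments,
not frames, are the independent sampling unit, so the test tolerance is four
*segment-level* binomial standard errors.  A frame-level binomial tolerance
would understate the variance by roughly √(dwell length).

## Pipeline and provenance

The `run` pipeline validates its YAML config up front (schema errors name the
offending key and no compute starts), isolates per-system failures, and
writes per-system CSV/JSON artifacts plus a report carrying the package
version, a canonical config hash, the seed and per-stage timings.  Census
JSON files are byte-identical across reruns of the same config and seed.
The four-system demo plants a locking hierarchy — apo-like (9 basins, 11.5%
noise), intermediate (7, 11%), and two locked systems (3 basins at 4.2% and
2.6% noise, with progressively richer planted ligand contacts) — matching
the qualitative pattern of a specific-binder study; at the demo's small
sample size (300 frames/replicate) the most locked system may realise fewer
basins than planted, which is itself the locking phenotype.

## Known limitations

* The ε-calibration heuristics (Kneedle chord rule, regime-ratio fallback)
  are deterministic but heuristic; landscapes without clear density
  hierarchy get a warning, not a refusal.
* Full-scale validation against a real deposited trajectory archive is
  implemented (fixed ε = 1.2, min_samples = 4, per-system census) but
  requires placing the multi-gigabyte archive under `data/deposited/`; the
  corresponding test fails until the data is present, by design.
* H-bond detection without explicit hydrogens cannot apply the angle
  criterion; on heavy-atom-only inputs the distance rule alone decides.
* The domain-network reduction averages correlations; it does not search
  allosteric pathways (no community detection or shortest-path analysis).
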