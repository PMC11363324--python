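# Methods

This note documents the models implemented in `mubridge`, their
assumptions, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Frames, roles and geometry

A *frame* is one structural snapshot (atom records + coordinates in Å),
read and written as multi-model PDB. Functional roles — ligand hydroxyl
oxygen, sodium-site carboxylate oxygens (D^2.50 OD1/OD2), the 7.43
tyrosine phenol ring and hydroxyl, the 2.60 glutamine amide, water
oxygens — are bound to concrete residues by a `RoleMap` config, so
Ballesteros–Weinstein positions are decoupled from any particular
receptor's numbering (the default map uses ASP114/TYR326/GLN124, the μOR
numbering).

**Hydrogen bonds.** Heavy-atom criterion: any inter-residue N/O···N/O
pair with distance in **[2.2, 3.0] Å** (default). The upper part of the
window matches the 2.5–3 Å donor–acceptor distances observed for
ligand–water–aspartate bridges; the 2.2 Å lower bound guards against
counting steric clashes. When explicit hydrogens are present on a
partner, a D–H···A angle ≥ 120° is additionally required; frames without
hydrogens (the common case for reduced snapshots) are scored on distance
alone. No periodic-boundary handling is applied: inputs are assumed
pre-imaged snapshots, not raw trajectories.

**π–π stacking.** Ring centroid = mean of ring-atom coordinates; ring
normal = eigenvector of the smallest covariance eigenvalue with a fixed
sign convention (positive z, tie-broken by x then y), so outputs are
deterministic. A face-to-face contact requires centroid distance ≤ 5.0 Å,
interplanar angle ≤ 30°, lateral offset ≤ 2.0 Å. The 5 Å cutoff is
anchored to the observation that rings farther than 5 Å apart cannot
form a robust stack; the angle and offset cutoffs are common stacking
conventions. All three are configurable, and reported results should
state them.

## Bridge classification

Per frame, the classifier searches the hydrogen-bond graph restricted to
{ligand hydroxyl O} ∪ {water O} ∪ {carboxylate O} and applies an
exclusion hierarchy: `direct` ≻ `water1` ≻ `water2` ≻ `none`. Key
choices:

- The direct ligand–carboxylate contact uses the same distance window as
  bridge links (one criterion, one config key).
- Both carboxylate oxygens are equivalent endpoints; the ligand hydroxyl
  O is the sole start atom (the hydroxyl hydrogen is ignored in
  heavy-atom mode).
- Two-water bridges require two *distinct* waters in consecutive
  hydrogen-bonded links; any qualifying simple path counts in branching
  networks. Paths through ≥3 waters are deliberately unscored.
- A frame with both one-water and two-water paths (and no direct
  contact) is `water1`.

Candidate atoms are visited in serial-number order, so the reported
bonding path is deterministic; the *label* is invariant under atom
reordering. The test suite proves equivalence against a brute-force
simple-path enumeration (networkx) on random frames with up to 30
waters.

Frequencies are fractions of frames per class, computed per simulation
replicate; the summary is the across-replicate mean with SEM = sample SD
(ddof 1)/√R, matching SEM bars over replicate dots. Replicate structure
is explicit input (a manifest), since real studies differ in replicate
counts and lengths. Group comparisons use a two-sided Mann–Whitney U
test: for ≤ 8 replicates per group the p-value comes from the exact
permutation distribution of U over all C(n+m, n) group assignments
(ties handled exactly; p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))); larger
groups use the tie-corrected normal approximation.

## APEX proximity-proteomics stage

**Spatial deconvolution.** For each receptor sample (time point ×
replicate), the vector `y` of indicator-protein intensities is regressed
on the reference profile matrix `X` (mean reference intensity per
indicator × location): `min‖y − Xβ‖²` subject to `β ≥ 0` (NNLS).
Receptor fractions at a location cannot be negative, hence the
nonnegativity default; unconstrained least squares is available behind a
flag for comparison. Coefficients are normalised to sum to 1 for
reporting (the normalisation makes them invariant to common positive
rescaling of `y` or of the reference columns). Rank-deficient reference
matrices are rejected with the collinear locations named. Each
(time, replicate) column is solved independently.

**Time-course statistics.** Intensities are log2-transformed after
adding a pseudocount of half the smallest positive intensity in the
matrix. Per protein, log2 intensity is regressed (OLS, statsmodels) on a
polynomial of degree 2 (default) in time, and the overall F-test against
the intercept-only model — df (d, N − d − 1) — measures change over
time. The polynomial is evaluated on the *time-point index* by default
rather than raw minutes: the 0/1/5/10/30-min sampling grid is
approximately log-spaced, and a quadratic in raw minutes has severe
lack-of-fit for transient recruitment dynamics concentrated in the first
minutes, costing most of the test's power; the index axis (≈ log-time)
weights early and late dynamics evenly. `time_scale="minutes"` restores
the raw axis; degree and axis are config values that should be reported.
Degenerate cases: a constant series returns F = 0, p = 1; an exactly
polynomial series (zero residual) is flagged and reported at the
smallest positive float instead of p = 0.

Log2 fold changes are computed per replicate against that replicate's
pre-stimulation (t = 0) baseline, then averaged across replicates. A
protein is a hit iff max |log2FC| > 0.58 **and** p < 0.001, strict
inequalities, with no multiple-testing correction (the thresholds are
used as published conventions for this assay).

## Pharmacology

**4PL concentration-response.** Least squares on
`y = baseline + (Emax − baseline)/(1 + 10^((log10 EC50 − log10 c)·h))`.
For agonist-mode BRET data normalised to a reference full agonist the
baseline is fixed at 0 and Emax, pEC50, h are free, with h ∈ [0.3, 5].
The fit multi-starts over a 5-point pEC50 grid spanning the observed
concentration range to avoid local minima; parameter SEs come from the
scaled covariance at the optimum and CIs are t-based. Responses above
100% of reference are legitimate (high-efficacy agonists in
low-amplification readouts). Activity flags: `no_detectable_activity`
for exactly flat zero responses; `not_measurable` when the fitted Emax
CI includes 0 or the span is below 3× the residual SD (the published
tables leave this criterion unstated; ours is recorded here). EC50 is
reported in nM alongside pEC50 (EC50[nM] = 10^(9 − pEC50)).

**ED50.** %MPE is bounded in [0, 100] by definition, so the model is the
two-parameter log-logistic `%MPE = 100/(1 + (ED50/dose)^s)` fitted to
subject-level records on the log10-dose axis. The 95% CI is the
delta-method t-interval on log10(ED50), back-transformed; the CI method
is recorded in the result object. All-0 or all-100 response sets are
rejected as "no intermediate response". The estimate is equivariant
under dose rescaling (mg/kg vs g/kg differ by exactly the unit factor).

**Brain:plasma ratio** is the plain concentration ratio, reported
rounded to one decimal alongside full precision, as conventionally
quoted.

## Synthetic-data generators

All generators take explicit integer seeds (`numpy.random.default_rng`,
no global state); identical seeds give byte-identical outputs.

- **Frames** are built in a local axis system with the carboxylate at
  the origin — classification depends only on relative geometry — and
  contain only the atoms relevant to classification plus off-path decoy
  waters (> 4.5 Å from the bridge path). Designed geometries place
  bridge links at 2.7–2.75 Å, comfortably inside the window. Gaussian
  coordinate jitter is applied to the mobile atoms and re-sampled
  whenever it would change the frame's class (rather than clamped, which
  could silently invalidate the truth labels); an unrealisable request
  (jitter too large) raises an explicit error.
- **Concentration-response**: 8 concentrations log-spaced over
  0.1 nM–100 μM, 4 replicates, additive Gaussian noise of 5 % response
  units by default — the design of the published TRUPATH/BRET
  experiments (2–3 biological × 4 technical replicates) at a typical
  noise level. Hill slope defaults to 1.
- **APEX**: 3 locations × 10 exclusive indicator proteins; reference
  samples express each location's indicators at full intensity with
  ~0.8 % background elsewhere; receptor indicator intensities are the
  mixing-weighted combination of the reference profiles (default mixing:
  100 % plasma membrane at all times — the no-internalization phenotype
  of an arrestin-inactive partial agonist). 500 background proteins with
  log2-normal baselines, 3 truly changing on a transient profile
  (log2FC 0 → 0.75 → 1.0 → 0.75 → 0 over 0/1/5/10/30 min — a
  recruitment-and-release shape with the planted peak at 1.0), nulls
  with mean-zero log2 noise of SD 0.15, 3 replicates.
- **%MPE**: subject-level log-logistic responses with Gaussian noise
  (default SD 10 %MPE), clamped to [0, 100]; doses 3/10/30 mg/kg, 8
  subjects per dose.

What the generators do *not* emulate: force-field energetics or actual
MD (frame counts/strides and 5-replicate conventions are ours, not
reproductions), correlated frames, raw mass-spectrometry effects
(missing values, normalisation artefacts, shared peptides), receptor
reserve/system bias in BRET readouts, or within-subject correlation in
behavioural data. Passing tests therefore demonstrate correctness of the
*estimators and classifiers* under the stated noise models, not
robustness to every artefact of real data.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design:
ensembles of 100–1000 frames, 8×4 concentration-response designs,
300–500-protein APEX matrices, 200-simulation bias sweeps and
1000-protein null-uniformity checks. Recovery checks at noisy designs
are single simulate-and-fit realisations with fixed seeds; their values
scatter around the generating truths with, e.g., SD ≈ 10–15 % for a
single-run EC50 at the 8×4/5 %-noise design. Property tests
(hypothesis) are derandomised for reproducibility.

## Known limitations

- Donor/acceptor directionality is undetermined in heavy-atom-only
  frames; bonds are reported as symmetric pairs.
- The exact Mann–Whitney enumeration is O(C(n+m, n)) and is used only up
  to 8 replicates per group.
- The deconvolution assumes reference profiles measured in the same
  intensity space as receptor samples; no cross-run normalisation is
  performed.
- The 4PL standard errors are asymptotic (curvature-based); profile
  likelihood is not implemented.
- Three-or-more-water bridges are intentionally out of scope of the
  classifier's label set.
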