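# Methods

This note records the models implemented in `oxycav`, the parameter
conventions, the synthetic-data assumptions, and the numerical choices
made where the design was genuinely open.

## Binding isotherm (`oxycav.isotherm`)

**Model.** Single-site binding in fast exchange: the observed shift is
the population-weighted average of free and bound states, so
Δδ([O₂]) = Δδ_max · θ with occupancy θ = K[O₂]/(1 + K[O₂]). The model
assumes one effective site per nucleus, exchange much faster than the
shift difference, and ligand in large excess (free ≈ total dissolved
concentration — valid for a gas equilibrated against a reservoir).

**Units.** Concentrations are carried in mM (the natural scale for
dissolved O₂, 0.27 mM at atmospheric pressure) and converted to M
inside the model, so K is in M⁻¹ and K_d = 1000/K is in mM. Shifts are
signed ppm relative to the lowest concentration; an opt-in flag fits
magnitudes instead.

**Fitting.** `global_fit` minimises the unweighted sum of squared
residuals over every point of every series, with one shared K and one
Δδ_max per series. K is parameterised as exp(θ) to enforce positivity,
started at 1/(median concentration in M) — scale-free and robust over
several orders of magnitude. The Levenberg–Marquardt solver runs at
tight (1e-14) tolerances so noiseless round trips are exact to ~1e-6
relative. Standard errors come from the Gauss–Newton curvature
s²(JᵀJ)⁻¹ with s² = SSE/(n − p), mapped to the K scale by the delta
method. Residuals are unweighted across ¹H/¹³C/¹⁵N series by default;
per-series weights are accepted, and with inverse-noise weights the
±1-s.e. interval covers the truth in roughly the nominal fraction of
simulated replicates (the unweighted interval is slightly
anticonservative because the pooled s² averages heteroscedastic
nuclei).

A series needs at least two points and the whole problem at least as
many points as parameters; a single shared concentration is rejected.

## Multi-site PRE model (`oxycav.premodel`)

**Model.** ΔR₁(p) = Σᵢ cᵢ·10⁵·rᵢ(p)⁻⁶ + f. The 10⁵ Å⁶/s scale is part
of the model definition so fitted coefficients are of order one. The
linear 1/r⁶ form is the point-dipole distance dependence of
paramagnetic dipolar relaxation with all spectral-density and
constant factors absorbed into the occupancy-proportional cᵢ; no
correlation-time or field dependence is modelled. The baseline f
(s⁻¹) captures distance-independent contributions (surface-diffusing
paramagnet, spin diffusion).

**Fitting.** Coefficients and baseline are constrained non-negative
and solved by non-negative least squares (occupancies cannot be
negative; data that do not support a site should drive its
coefficient to exactly zero rather than below it). Coefficients below
1e-10 (relative to the largest) are snapped to exact zero so an
active constraint reports a clean zero. Requires at least
n_parameters + 1 non-excluded observations. Excluded observations
(e.g. resonances lost to severe broadening) are carried with their
reasons, never enter the objective, and still receive predictions.

**Statistics.** R² is the squared Pearson correlation between observed
and predicted ΔR₁ over the fitted points (reported as 0 when either
side is constant); SEE is the root-mean-squared prediction residual.
Per-site contribution shares split (prediction − f) proportionally to
the cᵢ·10⁵·rᵢ⁻⁶ terms, so shares plus baseline reconstruct the
prediction exactly (a proton with all site terms zero is
baseline-only). The cavity occupancy ratio is the ratio of
coefficient sums over the sites of each cavity; the
binding-probability bound divides an observed ΔR₁ by the 6200 s⁻¹
rate of a proton in permanent van der Waals contact with O₂, giving
the occupancy that would explain the observation if the ligand sat at
contact distance whenever bound — an upper bound, since real bound
ligand samples larger distances.

**Broadening screen.** A row is flagged when its minimum raw
proton–site distance is strictly below the threshold (default 6 Å).
The comparison is strict at the boundary; the threshold is
configurable.

## Structures and distances (`oxycav.structures`)

PDB input is parsed with gemmi (first model only); HETATM records are
retained so xenon sites can ride along in the structure file, or sites
can come from a plain `site_id x y z cavity` table — both paths
produce the same geometry object. Coordinates are Å and PDB residue
numbers are used verbatim. Hydrogen building is deliberately not
implemented: a structure without hydrogens raises an error directing
the user to an external protonation tool, because silently guessed
proton positions would corrupt a model whose signal scales as r⁻⁶.

Methyl groups (Ala β, Val γ1/γ2, Leu δ1/δ2, Ile γ2/δ1, Thr γ2, Met ε)
are one NMR resonance each, so by default each methyl contributes one
distance-table row whose per-site 1/r⁶ value is the arithmetic mean
over its three hydrogens — the natural per-resonance reduction of a
prediction that is linear in 1/r⁶. The stored effective distance is
(mean 1/r⁶)^(−1/6); the raw minimum proton–site distance is kept
separately because the broadening screen is about the closest actual
proton. Per-proton tables are available by flag.

## Trajectory analysis (`oxycav.trajmd`)

**Density.** Frames are binned into cubic voxels over the trajectory's
bounding box padded by one voxel; every frame lands in exactly one
voxel, so counts are conserved for any voxel size. Hotspots are voxels
whose count exceeds `factor` (default 4) times the mean count over
*occupied* voxels: normalising against sampled density keeps the rule
independent of how much empty padding surrounds the region (an
all-box mean, available by flag, would shrink with padding).

**Cavity events.** Each frame is labelled with the cavity of its
nearest site when that distance is within the cutoff (default 5 Å,
roughly a first solvation shell around a site), else "outside".
Events are label-change boundaries after optional debouncing: runs
shorter than the minimum dwell (given in ps, so event detection is
invariant to frame-rate changes) are absorbed into the preceding run.
Cavity→cavity changes are transitions, cavity→outside egress, and
outside→cavity binding (rebinding once any cavity has been visited).
The default debounce of 0 reports every raw change.

**Rotational ACF.** C_ℓ(τ) = ⟨P_ℓ(u(t)·u(t+τ))⟩ using all n − lag
overlapping origins. Rank defaults to 2, the Legendre order governing
dipolar relaxation and pseudocontact-shift averaging; rank 1 is
available. Decay fitting: single model C = exp(−τ/τ₁); bi-exponential
C = A·exp(−τ/τ_fast) + (1−A)·exp(−τ/τ_slow) with A ∈ [0,1],
amplitudes summing to one (no constant offset — the curves fitted
here decay to ~0), and τ_fast ≤ τ_slow enforced by swapping after the
fit. Time constants are optimised in log space under box bounds from
three starting points, including a start degenerate at the
single-exponential solution, so the nested bi-exponential never ends
with a larger SSE than the single model; if the optimiser still
returns a (numerically) worse value the degenerate solution itself is
reported. Both models are always fitted and their SSEs recorded so
model preference can be stated per curve.

## Synthetic data (`oxycav.synthdata`)

Every generator is a pure function of (parameters, seed) with the true
values echoed into a metadata dictionary; recovery tests read truth
from metadata only. Defaults encode the study conditions: the
five-point concentration grid 0.27–8.9 mM; K = 48 M⁻¹; the twelve
tracked nuclei with their saturation shifts; five sites split 3/2
between the large and small hydrophobic cavity; amide coefficients
(1.3, 1.1, 1.5, 0.11, 0.10; f = 1.1) and methyl coefficients
(1.8, 0, 3.1, 0, 0.046; f = 0.79); rotational time constants 0.164
and 1.41 ps.

Noise is Gaussian, homoscedastic per data type: 0.01 ppm for ¹H shift
series and 0.05 ppm for ¹⁵N/¹³C (reflecting the relative precision of
shift measurement in each dimension), and the fitted residual scales
(0.74 s⁻¹ amide, 3.0 s⁻¹ methyl) calibrate ΔR₁ noise. Synthetic
geometries place protons on uniform-random shells (3–20 Å) around
randomly chosen sites, which makes the 1/r⁶ design matrix generically
full-rank; the site layout uses stand-in coordinates, not the
crystallographic ones. Orientation data come either as the analytic
bi-exponential ACF plus noise (to test the fitter in isolation) or as
unit-vector frames from wobbling-in-a-cone superposed on slow
isotropic rotational diffusion — the physical picture behind bimodal
small-molecule rotation (fast inertial/librational motion inside a
restricted volume, slower diffusive reorientation) — whose rank-2 ACF
is approximately bi-exponential and collapses to a single exponential
with τ = 1/(6D) when the cone closes.

What the generators do **not** emulate: real chemical-shift
heterogeneity (exchange contributions, temperature drift),
correlated or non-Gaussian noise, actual protein coordinates (the
structure fixture is an idealised extended Ala/Val/Leu chain),
protein breathing that modulates distances, or genuine MD forces.
Passing tests therefore demonstrate that the estimators recover known
truth under the stated statistical model at realistic noise — not
that the physical model is correct for any particular protein.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale problems:
50-proton geometries, 100 Monte-Carlo titration replicates, 50 ACF
replicates of 1001 lags, trajectories of 10³–10⁴ frames. All
randomness flows through `numpy.random.default_rng` seeds;
per-replicate seeds are derived with `SeedSequence` so replicates are
independent but fully reproducible.

## Known limitations

- The PRE fit reports no per-coefficient standard errors (the
  active-set NNLS solution makes naive curvature-based errors
  misleading near constraint boundaries); goodness of fit is carried
  by R² and SEE.
- The isotherm assumes ligand excess; it is not a two-state
  depletion-corrected quadratic isotherm.
- Cavity assignment is purely geometric (nearest site within a
  cutoff); it knows nothing about barriers or pathways.
- The ACF estimator uses the biased (n − lag) normalisation, standard
  for correlation times but slightly smoothing at the longest lags;
  keep max_lag well below the trajectory span.
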