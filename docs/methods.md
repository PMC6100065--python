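# Methods

This note records the models, numerical choices and known limitations of
the package, in the order the workflow runs them.

## Data model and units

Properties are fixed in kelvin (Tc), megapascal (Pc) and dimensionless (ω);
the compound-table header carries the unit (`tc_K`, `pc_MPa`) and readers
reject any other annotation instead of converting. Missing values are real
missing values (`None` / NaN), never sentinels, because the descriptor
pre-filter must distinguish "not computable for this structure" from zero.
Record order is file order and is the reference for every deterministic
tie-break downstream. The train/validation split is seeded uniform
sampling without replacement; an optional stratified mode allocates the
training quota proportionally to user-supplied group labels
(largest-remainder rounding), but plain random is the default since
nothing in the workflow requires stratification.

## Descriptor engine

**Geometry.** Conformers come from RDKit ETKDG distance-geometry embedding
with a fixed seed followed by MMFF94 minimisation (UFF fallback). This
replaces semi-empirical quantum-chemical optimisation: no open
semi-empirical engine is a package dependency, and for the descriptor
families implemented here (composition, connectivity, mass distribution,
surface/charge combinations) force-field geometries are adequate. The
consequence — absolute descriptor values differ from those of
quantum-chemistry-based engines — is deliberate; the modelling layers never
assume engine-identical values, only internally consistent ones.

**Charges.** Gasteiger electronegativity-equalisation charges (RDKit).
They conserve net charge and give symmetry-equivalent atoms identical
charges (graph-based scheme). Provenance is tagged per descriptor column.

**Surface areas.** Shrake–Rupley quadrature over golden-spiral sphere
lattices: each atom's sphere of radius r_vdw + probe is sampled with
`n_sphere_points` points (default 960; single-atom SASA converges to the
closed form 4π(r+p)² within ~0.3% at that density) and the accessible
fraction times the sphere area is the atomic SASA. Probe radius defaults
to 1.4 Å (water); 0 gives the bare van der Waals surface.

**Catalogue conventions** (full formula list in `qspr/descriptors.py`):

- "Relative" constitutional descriptors divide by the total atom count
  including hydrogens (heavy-atom normalisation is configurable);
  "relative molecular weight" is MW / atom count. Ring count is SSSR size.
- Randić ¹χ sums (δᵢδⱼ)^(−1/2) over heavy-atom bonds with δ = heavy-atom
  degree. Kier–Hall ²χᵛ sums (δᵛᵢδᵛⱼδᵛₖ)^(−1/2) over length-2 heavy-atom
  paths with δᵛ = Zᵛ − h for second-row atoms and δᵛ = (Zᵛ − h)/(Z − Zᵛ − 1)
  beyond (the standard higher-row extension). SIC₀ is the Shannon entropy
  of the element partition over all atoms divided by log₂(atom count),
  defined as 0 for single atoms.
- Principal moments of inertia are labelled by sorted magnitude
  I_A ≤ I_B ≤ I_C (amu·Å²). Molecular volume is RDKit's grid-estimated
  van der Waals volume.
- CPSA descriptors follow the 1 = charge-weighted sum / 2 = plain surface
  sum convention: PNSA₃/PPSA₃ are Σ qᵢ·SAᵢ over negative/positive atoms,
  FPSA₃ = PPSA₃/TMSA, HASA₁ (HDSA₁) are charge-weighted and HASA₂ (HDCA₂)
  plain surface sums over H-bond acceptors (donor hydrogens). RNCS/RPCS
  divide the extreme atom's SASA by its relative charge q_ext/Σq_same-sign.
  The HASA/HDSA/HDCA variants are reconstructions: several published CPSA
  conventions exist and the implemented formulas are stated here rather
  than assumed to match any particular code. Donors are H on N/O/S,
  acceptors N/O/F (both configurable).
- Topographic electronic indices Σ|qᵢ−qⱼ|/rᵢⱼ² are emitted in both
  all-pairs and bonded-pairs variants as separate descriptors.
- A molecule with no negative atoms gets PNSA₃ = RNCS = 0 (not an error);
  a zero TMSA is an error.

The matrix builder records per-molecule failures as missing cells and the
pre-filter then drops any column with a missing value or with range below
1e−12 (constant), reporting the reason per column.

## Heuristic multi-linear selection

OLS statistics are the standard ones: R² = 1 − SSE/SST, overall
F = (R²/k)/((1−R²)/(n−k−1)), per-coefficient t = aᵢ/SE(aᵢ) with unbiased
σ² = SSE/(n−k−1). Rank-deficient designs and n ≤ k+1 are rejected.

The search: (1) one-parameter screen with floors F ≥ 1.0, R² ≥ 0.1,
|t| ≥ 1.5; (2) greedy de-correlation of the survivor ranking at pair
correlation 0.1 — only the higher-R² member of a collinear pair stays, and
this pruned list seeds the search; (3) beam expansion (beam width 10) in
which a candidate may join a model only if its pair correlation with every
included descriptor is below 0.99 and, among descriptors that are
t-significant in the expanded fit, below 0.8. Expansion candidates are all
screening survivors: the 0.1 cut thins only the seed ranking, while the
0.99/0.8 thresholds define "non-collinear" during growth. An accepted
expansion must keep every |t| ≥ 1.5, satisfy the F floor, and be *more
significant* than its parent. Significance is compared via the p-value of
the overall F-test, evaluated in log space with an asymptotic
incomplete-beta tail once the p-value underflows. The raw F statistic is
not used for this comparison: adding a genuinely informative descriptor
typically *lowers* overall F (the numerator degrees of freedom grow faster
than R² can), so a raw-F-must-increase rule freezes the search at one
descriptor; the p-value ordering is the statistic that actually captures
"more significant" across model sizes. The final model is the highest-R²
member of the ten-best-by-F list over all sizes (cap ten descriptors).
Every tie anywhere breaks by descriptor column order, making the whole
search deterministic; the trace records one-parameter statistics,
eliminations with reasons, per-size beams and both ten-best lists.

The "significant pair correlation" reading — the pair correlation between
descriptors both t-significant in the current model — is an
interpretation (the term is used in the field without a published
formula); it can be switched off in the config.

## RBF network

Inputs are z-scored on training statistics (Euclidean distance across
mixed-unit descriptors is meaningless otherwise) and the target is
standardized during training, so the *goal* (MSE stop threshold) is in
standardized-target units squared. The shared width derives from a spread
parameter as b = √(ln 2)/spread (basis value 0.5 at distance `spread`);
the default spread is the median pairwise distance of the standardized
training inputs — the usual kernel-width heuristic — which adapts to the
input dimension. Per-neuron widths are accepted by the data model.

Training evaluates, at each step, *every* unused training input as a
candidate centre with a full least-squares refit of the output layer, and
keeps the candidate that lowers training MSE most (ties by training-row
order). The implementation performs the candidate scan through an
orthonormal-basis update that is algebraically identical to the per-
candidate refit but costs one matrix product per step; the final output
weights of any prefix are refit directly by `lstsq`. Candidates whose
basis column is numerically collinear with the current design (residual
norm² < 1e−12) are skipped, which also guards the b → 0 degeneracy where
all basis columns approach the constant column. Construction stops at the
goal or at ceil(0.30 × n_train) neurons; the 30% cap is interpreted
against the training set (the conventional choice; the cap is
configurable). Because the greedy path does not depend on the goal, the
goal grid (default 12 log-spaced values in [1e−4, 1] × standardized-target
variance) is scanned from a single construction run by cutting prefixes;
the network with the lowest validation MSE wins, ties preferring larger
goals (fewer neurons). Tuning the goal against the same validation set
that is later reported reproduces the workflow's historical shape but is a
mild leakage; a third split can be managed by the caller via the split
utilities.

## Evaluation

AD%ᵢ = 100·|ŷᵢ−yᵢ|/|yᵢ|; AAD% is its mean; RMSE divides by n (not n−1),
consistent with its use as a fit-quality metric. Bucket counts use strict
inequalities, so AD% exactly 5 or 10 falls in the middle bucket and the
three buckets always partition the set. A zero experimental value is an
error (AD% undefined); compounds with |y| < 0.05 — relevant for acentric
factors near zero, where percent deviations are unstable — are flagged in
the report rather than dropped.

## Synthetic generators

The generators exist because the workflow's real inputs (experimental
critical-property databases, commercial descriptor values) are not
redistributable; they emulate the statistical structure the modelling
stages rely on, not the joint distribution of real descriptors.

- Descriptors are drawn from a seeded multivariate normal. True-support
  descriptors are equicorrelated (ρ = 0.3 by default) with positive
  coefficients — real descriptor families are strongly inter-correlated
  and a property loads on several related descriptors — which also gives
  every true descriptor an unambiguous one-parameter signal (with
  mutually orthogonal equal-weight descriptors, ten marginal R² values
  cannot all clear the 0.1 screening floor: the shares must sum to 1).
  Named decoy correlations can be planted; the covariance is
  Cholesky-checked and infeasible requests are rejected.
- The default linear instance mirrors the historical study scale: 306
  compounds, 400 candidate descriptors, a 10-descriptor support, noise set
  by SNR = 10 (noise_sd = √(signal var/SNR)); an absolute noise_sd
  overrides. A heavy-tail option skews the marginals, since real
  descriptors are far from normal.
- RBF instances plant Gaussian bumps in the *empirically standardized*
  space of the support columns, by default anchored on well-separated
  sample rows (greedy max-min selection). Anchoring on rows keeps a
  zero-noise instance exactly representable by a network whose centres are
  training inputs, which is what makes exact-recovery tests meaningful.
- The default *nonlinear workflow* instance combines a linear trend over a
  4-descriptor support (among 50 candidates) with three bumps of width 2.0
  scaled to the linear signal's spread, at SNR 20. The curvature is
  deliberately low-dimensional: from ~200 training points no
  isotropic-kernel regressor can learn a bump field spread over ten
  standardized dimensions, so a ten-dimensional nonlinearity would make
  the linear and nonlinear models indistinguishable by construction rather
  than by merit. Bump width 2.0 keeps the field smooth at the scale of
  typical inter-compound distances (~√(2d)).

What passing tests on these instances show: the selection rules and the
greedy construction behave as specified, recover planted structure at
realistic size/noise, and the nonlinear regressor beats the linear one
when learnable curvature exists. What they do not show: accuracy on real
critical-property data, robustness to heavy-tailed or discretised
descriptors, or extrapolation outside the training cloud.

## Problem sizes and determinism

Default test/workflow sizes (306×400 linear instances, 306×50 nonlinear
workflow, RBF instances of 80–300 points) keep any single experiment under
a few seconds while staying at the dimensions the method is meant for.
All randomness flows through explicit integer seeds (numpy Generator);
identical config + seed reproduces byte-identical workflow artifacts,
which the manifest verifies by SHA-256.

## Known limitations

- Gasteiger charges are crude for unusual valence states; elements without
  parameters make a molecule's electrostatic cells missing.
- Distance-geometry conformers are single minima; descriptor values for
  very flexible molecules depend on the embedded conformer (seeded, hence
  reproducible, but still one conformer).
- The CPSA variant formulas are documented reconstructions (see above).
- The heuristic's stage-one 0.1 pair-correlation cut is extremely strict
  for real descriptor sets, where nearly everything correlates above 0.1;
  it governs only the seed list here, and the threshold is configurable.
- Greedy centre selection is O(steps × n²) per construction; fine at
  hundreds of compounds, not tuned for tens of thousands.
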