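# Methods

`crowdsolv` implements the analysis layer of a molecular-crowding solution
study: given trajectories, pressure-tensor series, and box compositions for
water/PEG-4/protein systems, it estimates transport coefficients with
finite-size corrections, compares their concentration dependence against the
Enskog hard-sphere reference, and computes structural solvation observables.
Because realistic crowding trajectories require nanosecond-scale MD, every
estimator here is validated instead on synthetic inputs with analytically
known ground truth; this note records the models, conventions, defaults, and
their limits.

## Units and constants

Internal units are nm, ps, K, elementary charge e, kJ/mol, and g/mol; bar
for raw pressure input. Reported units follow the solution-MD convention:
mPa·s for viscosity, 1e-5 cm²/s for diffusion. All conversions route through
`crowdsolv.constants`, which is the single home of k_B = 1.380649e-23 J/K,
N_A = 6.02214076e23/mol, the electric conversion factor
f = 138.935458 kJ·mol⁻¹·nm·e⁻², and the cubic-lattice hydrodynamic constant
ξ = 2.837297. A test asserts this single-definition property.

Only orthorhombic periodic boxes are supported; triclinic input raises an
explicit unsupported-feature error. Atom indexing is 0-based internally;
GRO/PDB serial numbers exist only at the file boundary.

## Composition construction

A target crowder concentration c in % w/v (grams PEG-4 per 100 mL solution)
is realized in a box of volume V as

    N_peg = floor(c/100 · V · N_A / M_peg),

with M_peg = 194.23 g/mol (C8H18O5) and M_water = 18.015 g/mol — standard
molar masses, since solution tables typically omit them. Water then fills
the volume left by the realized PEG molecules at its pure-liquid density
(1.00 g/mL; PEG-4: 1.12 g/mL), floored again. Two conventions are the
package's own choices where the field's tables underdetermine the rule:

* **Pure-crowder clamp.** At c = 100·ρ_peg (112 % w/v), the solution is the
  pure crowder liquid and contains no water by definition, even though count
  quantization leaves ~0.07 nm³ of nominally unfilled volume in a 64 nm³
  box (enough for 2 water molecules under the flooring rule).
* **Ideal-mixing solution volume.** The realized % w/v, volume %, and
  weight % are computed against the sum of pure-component molar volumes
  rather than the box volume. This keeps v% = 100 exactly at the
  pure-crowder limit and reproduces the integer unit columns of the
  reference grid after flooring. The crowder volume fraction φ (input to
  the Enskog curve) keeps the box-volume denominator,
  φ = N_peg·M_peg/(N_A·ρ_peg·V); the two differ by at most one percentage
  point on the standard grid.

The exact water-count rule behind published composition tables is not
recoverable from the printed integers; reconstructions here land within ±2
molecules of the reference counts on every row (and the tests allow ±7),
with exact agreement at the pure-water and pure-crowder endpoints.

## Diffusion

The mean squared displacement uses the Einstein relation over **all sliding
time origins**, computed per particle with the FFT autocorrelation identity
in O(T log T); paths are centered first to suppress cancellation error
(the result is shift-invariant). An O(T²) brute-force implementation is kept
as an oracle and the two agree to ~1e-14 relative. Multi-atom species
diffuse as mass-weighted molecular centers of mass — the physically standard
choice for PEG-4 and protein, where single-atom MSDs mix internal motion
into translation.

`D_PBC` is slope/6 of an ordinary least-squares fit of MSD vs lag over a
window of 10–50 % of the maximum lag by default. The lower bound excludes
the short-time regime; the upper bound avoids the poorly averaged long lags
(only T − τ origins at lag τ). A negative fitted slope — possible on short
noisy windows — clamps to D = 0 with a warning rather than raising.
Trajectories must be unwrapped; a single-step displacement beyond half a box
length trips a heuristic error advising `unwrap()`.

Finite-size corrections add the periodic-image hydrodynamic term

    D_0 = D_PBC + k_B·T·ξ/(6π·η·L)          (point-like species)
    D_0 = D_PBC + k_B·T/(6π·η·L)·(ξ − 4πR²/(3L²))   (solute of radius R)

with R the hydrodynamic radius (1.87 nm for lysozyme) and validity
restricted to R < L/2. At R → 0 the second form recovers the first exactly.

Concentration series are normalized to 1 at a dilute reference (0 % w/v for
water and protein, 1 % w/v for the crowder itself, where that point exists),
and compared against the Enskog hard-sphere decline

    D_HS/D_HS0 = (1 − φ)³ / (1 − φ/2),

which captures excluded volume only. The decline of protein diffusivity is
summarized by a nonlinear least-squares fit of y = exp(−k·c) — constrained
through (0, 1) because the series is normalized before fitting — with R²
reported on the linear scale (R² = 0 with a warning when SS_tot = 0).

Uncertainties come from five-block averaging: the series (or trajectory) is
split into five contiguous equal blocks, remainder frames dropped from the
end, and the sample standard deviation of block means is reported. Fit
standard errors are used only when a trajectory is too short to block.

## Shear viscosity

**Periodic perturbation (non-equilibrium).** A cosine acceleration
a_x(z) = A·cos(2πz/l_z), with the standard forcing amplitude
A = 0.05 nm/ps², drives a steady cosine velocity profile. Atoms are binned
along z, the mass-weighted mean x-velocity per bin is projected onto
cos(2πz_c/l_z) (the discrete projection is orthogonal to uniform drift;
a least-squares fit cross-checks it and substitutes when empty bins break
the uniform quadrature), and

    η = ρ·A·(l_z/2π)² / v.

The solution density ρ defaults to system mass over box volume. The
estimator is exact on noiseless profiles by construction and recovers the
target within 2 % at 10 % velocity noise with 1e4 atoms.

**Einstein–Helfand (equilibrium).** From the six off-diagonal pressure
components, the running integral W_ij(t) = ∫ P_ij dt′ (trapezoidal
cumulative sum) gives the mean squared Helfand displacement
G(t) = (1/6)Σ_ij⟨[W_ij(t0+t) − W_ij(t0)]²⟩, averaged over non-overlapping
time origins (default stride 10 samples; overlapping origins bias the
late-time variance estimate). Then η = V/(2·k_B·T) × the least-squares
slope of G over a late-time window (default 20–80 % of the maximum lag).
This form is the time-domain equivalent of the Green–Kubo stress
autocorrelation integral; a brute-force discrete Green–Kubo sum on the same
samples serves as the estimator-equivalence oracle.

The maximum Helfand lag is capped at 0.5 % of the series length (floor 100
samples): G(t) is linear once t exceeds the stress correlation time, while
the origin-averaging noise grows with lag, so short late-time windows are
both accurate and far more stable. On 2e5 samples of an exponentially
correlated stress (closed-form η = V·σ_P²·τ/(k_B·T)), recovery is within
~7 % across seeds; the documented tolerance is 15 %.

Three-column pressure input (one per tensor plane) is mirrored into six
components, matching the symmetric-virial convention of MD engine output.
A convergence report tabulates the running η versus window end and flags
non-convergence when the values one decade apart in window length differ by
more than 10 % — viscosity convergence is the slowest part of real crowded
solutions, and the flag makes silent non-convergence visible.

## Structural observables

**Superposition.** Kabsch SVD with reflection correction; mass weights by
default. RMSD series superpose each frame onto the reference over the
backbone selection (N, CA, C). RMSF superposes frames onto the raw mean
structure, rebuilds the mean from superposed frames (one refinement pass),
and reports per-residue mass-weighted averages of per-atom fluctuations.
An independent quaternion-eigenvalue RMSD oracle backs the tests. Note that
superposition absorbs O(1/N) of any isolated atomic displacement into the
fitted rigid transform; hand values for single-atom motion hold only for
large N.

**Solvation shells.** Non-normalized RDFs report the local number density
n(r) = ⟨ΔN(r)⟩/(4πr²Δr) of shell molecules around the protein — not divided
by bulk density, so the far-field plateau reads off the bulk solvent density
directly (33.3 nm⁻³ for pure water). The protein–solvent distance is the
minimum over protein atoms of the minimum-image distance to the shell
molecule's reference site: the oxygen for water, the mass-weighted center
of mass for PEG-4. This convention is configurable because published peak
positions depend on it and the exact published choice is not recoverable.
The coordination number is the time-averaged count of shell molecules
within a radius (default 1.87 nm, the solute hydrodynamic radius), with
five-block errors; it agrees with the cumulative RDF within binning error.

**Hydrogen bonds.** Geometric criterion: donor–acceptor distance
≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30°, the convention of the
standard MD analysis tools; both cutoffs configurable. Donors are N/O heavy
atoms with attached hydrogens (hydrogens attach to the most recent
preceding heavy atom in their residue, the standard file ordering);
acceptors are all N/O atoms. Counts are filtered by molecule-class pair
(protein–protein, protein–water, protein–PEG) and both donor directions of
a cross-class pair are counted.

**Interaction energies.** Pairwise Coulomb f·q_i·q_j/r plus Lennard-Jones
with Lorentz–Berthelot combination, minimum-image distances, and a plain
1.0 nm spherical cutoff matching the real-space truncation of the MD
protocol. No reciprocal-space (Ewald) term is included: engine-reported
energies include full electrostatics, so absolute values are not comparable
to engine output — only trends across compositions are.

**SASA.** Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 0.14 nm, Bondi element radii). Per-atom area is
the exposed-point fraction times 4π(r_i + w)². The hydrophobic part sums
atoms with |q| < 0.2 e, the hydrophilic part the rest; the split is exact
by construction (partition identity holds to machine precision). Doubling
the point count moves totals by < 0.5 %.

## Synthetic generators

The generators replace MD production runs at desk scale; each embeds its
seed and target parameters in metadata so tests are self-describing.

* **Brownian trajectories**: per-axis Gaussian increments of variance
  2·D·dt. Overdamped dynamics is deliberate — the MSD is linear from the
  first step, so fit-window logic is tested without modeling the ballistic
  short-time regime of real MD. Real trajectories also carry hydrodynamic
  self-interaction across periodic images; free Brownian motion does not,
  so generator targets need no finite-size correction.
* **Cosine flows**: velocities V·cos(2πz/l_z) + Gaussian noise with V the
  exact inversion of the periodic-perturbation relation at prescribed η.
* **Stochastic stress**: six independent AR(1) (discretized
  Ornstein–Uhlenbeck) series with stationary sd σ_P and correlation time τ;
  the closed-form Green–Kubo viscosity V·σ_P²·τ/(k_B·T) is recorded. With
  dt = τ/20 the discrete/continuous mismatch in the Helfand slope is below
  0.1 %.
* **Toy solutions**: a compact protein-bead cluster (N/H/C/O pattern with
  charges −0.40/+0.25/+0.05/−0.50 e straddling the 0.2 e threshold), rigid
  3-site waters (−0.834/+0.417 e — the common 3-site convention, a fixture
  choice, not a force-field claim), and 15-bead PEG-4 chains with hydroxyl
  charges above and carbon charges below the threshold. Rejection sampling
  keeps non-bonded sites ≥ 0.15 nm apart.

What passing these tests shows: the estimator chain is unbiased and
correctly unit-converted on processes that satisfy its assumptions exactly.
What it does not show: force-field accuracy, sampling adequacy, or the
behavior of estimators on correlated, inhomogeneous real solutions — the
synthetic processes have no structure beyond what each estimator assumes.

## Problem sizes and reproducibility

Default validation sizes — 1000 particles × 2000 steps for diffusion,
1e4 atoms for flow profiles, 2e5 samples for the stress series, ~1e5
shell-molecule samples for RDFs — are chosen so each estimator's stochastic
error sits well inside its documented tolerance while the full validation
suite runs in minutes on one core. Every generator is deterministic given
its seed; sweep CSVs are written with fixed 6-significant-digit formatting
and are byte-identical across reruns with the same seed.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Electrostatics are cutoff-truncated; no PME/Ewald.
* No rotational diffusion, anomalous-diffusion exponents, or
  velocity-autocorrelation (Green–Kubo) diffusion route.
* Secondary-structure assignment (DSSP) is out of scope.
* The water-count rule of published composition tables is reproduced to
  ±2 molecules, not exactly (the published rounding rule is unrecoverable).
* Published RDF peak positions depend on an unstated distance convention
  and are not asserted.
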