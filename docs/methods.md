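# Methods

This note documents the models implemented in `ensdyn`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Coordinate handling

Author residue numbering is canonical everywhere.  The expected construct
carries the purification tag at `seq_num <= 0` (a 13-residue His-tag,
`GSSHHHHHHSQDP`, ending at residue 0) and the mature chain runs 1–114; this
keeps loop labels (12–18, 48–54, 64–70) aligned across crystal forms, NMR
models and synthetic data.  Ensembles are flat lists of monomers — one per
(file, model, chain) — because all comparisons treat crystallographically
independent copies and NMR models on the same footing.  Alternate locations
collapse to the highest-occupancy conformer (ties: first in file order);
non-standard residues and HETATM records are dropped with a logged count.
Files are parsed with gemmi (PDB and mmCIF); ensembles are written back as
multi-model PDB, which round-trips coordinates to the format's 10⁻³ Å.

Missing-residue accounting partitions construct positions absent from a
model into the leading run (N-terminal), trailing run (C-terminal) and the
remainder (internal); the triple always sums to the total absent count.

## Sequence- and cell-derived constants

Extinction coefficients use the Pace coefficients (5500 Trp, 1490 Tyr,
125 cystine, M⁻¹cm⁻¹).  Average masses are residue masses plus one water.
The Matthews coefficient is `V_M = V_cell/(Z·M_asu)` with the general
triclinic cell volume; solvent content is `1 − 1.23/V_M`, the constant
corresponding to a protein partial specific volume of 0.74 cm³/g.  Whether
a reported solvent content used the Met-bearing or Met-cleaved monomer mass
changes the answer by well under a percentage point, which is why the
package does not attempt to distinguish the two conventions.

## Ensemble superposition and RMSD profiles

Superposition is the closed-form Kabsch solution (SVD of the covariance,
determinant correction so a reflection is never returned).  Atoms pair by
(residue number, atom name) over residues present in both models.  Defaults
follow the conventions of ensemble statistics for this fold family:
backbone N, CA, C, O (CA-only by flag) and a superposition mask of the
ordered core {1–47, 56–112}, excluding the flexible termini and the two
loops whose conformations vary; full-chain masks are selectable.

Per-residue profiles superpose each model pair globally on the masked
backbone and then evaluate the RMSD residue by residue.  A residue
unmodeled in either member contributes a fixed placeholder (default 10 Å)
for that pair, so crystallographic disorder appears as maximal divergence
rather than silently dropping out; the profile records how many pairs
triggered the placeholder at each position, and the placeholder is never
used where both members model the residue.

`rmsd_to_mean` superposes all members onto a running coordinate average
(first member as the initial reference, two refinement passes; atoms
modeled in fewer than half the members are excluded from the average) and
reports each member's RMSD to the final average with the ensemble
mean ± sd.  Within- and cross-ensemble comparisons treat every monomer
independently; which monomers represent an ensemble (e.g. one chain from an
NCS-restrained crystal form) is the caller's choice via the member list,
not hard-coded.

## Crystal contacts and burial

Symmetry mates are enumerated over the space-group operators (gemmi's
tables, so any Hermann–Mauguin symbol works) times lattice translations in
{−1,0,1}³; copies with at least one heavy-atom pair within 5.0 Å of the
reference chain count as contacting.  The 5 Å heavy-atom cutoff is a
PISA-style default; the underlying burial metric is insensitive to it as
long as it exceeds the SASA contact range (two carbon radii plus two probe
radii ≈ 6.2 Å) only modestly.

SASA is Shrake–Rupley with Bondi radii, a 1.4 Å probe and 960 test points
per atom placed on a deterministic golden-spiral lattice — no RNG, so
repeated runs are bit-identical and halving/doubling the point count
changes totals by under 1%.  Per-residue burial at an interface is
SASA(chain alone) − SASA(chain in the pair), residue-wise.

Interfaces are deduplicated by a canonical key invariant to the viewing
direction (the pair seen from either chain) and to conjugation by lattice
translations, `(g, v) ~ (g, v + (I − R_g)s)`.  Each unique interface record
keeps burial maps for both participating chains, so per-chain profiles lose
nothing by deduplication: a chain's profile sums its own map where it is
the record's subject and the partner map where it is the partner (both for
self-contacts through the lattice, covering both faces).  Interfaces
between chains of the same asymmetric unit — the biological dimer
interface — are included but flagged `intra_asu`, so lattice-only profiles
(the crystal-packing question) can exclude them; both modes are exposed
because which partners a packing analysis should count is a genuine choice.

## ¹⁵N relaxation and tumbling

Rates come from unweighted (or duplicate-scatter-weighted) nonlinear least
squares of `I(t) = I₀e^(−Rt)`; start values from a log-linear fit.  Errors
are covariance standard errors, or are derived from duplicate-pair scatter
when duplicates exist (the hetNOE error is half the absolute difference of
the duplicate ratios).  Fits with non-positive or vanishing rates are
flagged and excluded downstream.

The rotational correlation time uses the isotropic large-molecule closed
form `τ_c = √(6⟨R2/R1⟩ − 7)/(4π ν_N)`, valid when ⟨R2/R1⟩ > 7/6 and
relaxation is dominated by overall tumbling.  ν_N derives from the proton
frequency via |γ(¹⁵N)/γ(¹H)| = 0.101329.  "Most ordered regions" is
operationalized (it has no unique definition) as: hetNOE ≥ 0.65, then one
pass removing residues whose R2/R1 deviates more than 1 sd from the 10%
trimmed mean; all three knobs are arguments.  An anisotropic diffusion
tensor would shift τ_c by a few percent for a mildly anisotropic dimer;
this closed form is the documented model, not an approximation of another
program's output.

## Titration mapping

CSP uses the combined shift `Δδ = √(Δδ_H² + (Δδ_N/w)²)`; the nitrogen
weight defaults to 6.51 and is a config value, since several conventions
for the ¹⁵N scale factor circulate.  Intensity ratios I_bound/I_free get a
5-residue centered sliding mean with truncated edge windows.  Residues
observed in only one spectrum are missing (NaN), never zero.  Hotspots are
residues above mean + k·sd (k = 1 default) of either the combined shift or
the windowed intensity drop.  The analysis point of a multi-step titration
is the 1:1 stoichiometric point; later points are retained but not pooled,
because aggregation of the complex can corrupt them.

## DLS

Correlograms fit the Siegert relation with `g₁ = Σ aᵢe^(−Γᵢτ)`, amplitudes
kept non-negative and normalized via a softplus parameterization, rates on
a log scale, three fixed multi-start initializations (rate splits 3/10/30
around a half-decay estimate) to avoid local minima.  A second component
below a 1% intensity fraction, or degenerate with the first (rates within
5%), collapses the fit to one component with a note.  `D = Γ/q²` with
`q = 4πn₀sin(θ/2)/λ` (defaults n₀ = 1.331, λ = 632.8 nm, θ = 90°, a
standard He–Ne goniometer setup) and `R_h = k_BT/(6πη(T)D)` with a
Vogel-type water viscosity valid for 273–373 K; buffers are treated as
water.  The R_h→MW calibration constants (0.7429, 0.3599) are the common
globular-protein DLS calibration and are config values.  Whether a quoted
DLS "characteristic time" refers to the g₁ or the g₂ decay differs between
instruments; the fit reports Γ of g₁ and the convention is documented here
rather than guessed from data.

## CD and ESI-MS

Mean residue ellipticity evaluates `[θ] = θ·Mw/(N·c·l)` with θ in degrees,
c in g/ml and l in cm, then divides by 10 to convert the resulting
deg·cm²·mol⁻¹ to the conventional deg·cm²·dmol⁻¹ (equivalently:
θ_mdeg·Mw/(10·N·c_mg/ml·l_cm)).  Charge-ladder deconvolution assumes
adjacent peaks carry charges z and z+1, infers z = round((m₂−m_p)/(m₁−m₂))
with m_p = 1.00728 Da, demands the pairwise estimates chain consistently,
and reports the mean ± sd of the per-peak masses.  On noiseless ladders
this is exact to float precision for any mass in the protein range.

## SAXS

Guinier fits are weighted linear fits of ln I vs q², starting at the
lowest measured q and extending while qR_g ≤ 1.3, iterated until R_g
stabilizes below 0.5%.  Theoretical curves use the Debye formula on one
bead per residue at CA with a uniform form factor — adequate for comparing
conformers and for ensemble selection, but not for absolute χ values
against experiment, since hydration-shell and atomic form-factor effects
are omitted; absolute χ comparisons with shell-aware predictors are out of
scope by design.  χ is computed with an analytically fitted scale.  The
minimal ensemble search enumerates all subsets of up to five candidates
(pool capped at 40 for exhaustiveness), fits non-negative weights by NNLS
on σ-weighted intensities with the global scale absorbed into the
coefficients, and returns the smallest subset whose χ is within a factor
1.05 of the global best — preferring parsimony over marginal χ gains.
SAXS q is in Å⁻¹ throughout; DLS q stays in m⁻¹ (different instruments).

## Synthetic data

Generators draw all randomness from one integer seed through numpy's PCG64
(`default_rng([seed, stream])`, a fixed stream id per generator), so
fixtures are bit-reproducible across platforms.

The structural template is an idealized solenoid backbone (3.8 Å CA
spacing, N/C/O placed from the local Frenet frame): geometrically
protein-like (finite width, non-collinear, realistic atom density) but
chemically schematic — no side chains, no secondary structure, no physical
packing.  Ensembles perturb every atom with isotropic Gaussian noise,
σ = 2.0 Å inside the three mobile loops and 0.2 Å elsewhere by default,
matching the contrast between loop and core variability such ensembles
show; optional rigid transforms exercise superposition invariance and
optional deletions exercise the disorder placeholder.  Toy crystals either
bump a loop outward and size a P1 cell (by bisection on the true minimum
image distance) so a lattice translate touches it, or face two copies'
loops across a 4 Å gap for a cleanly localized designed contact.

Relaxation decays use the standard delay grids (R1: 100–1500 ms, R2:
10–210 ms, ten delays each) with core values R1 = 0.9 s⁻¹, R2 = 21.4 s⁻¹,
NOE = 0.82 — the regime of a ~30 kDa dimer at 600 MHz (R2/R1 ≈ 23.7,
τ_c ≈ 15 ns) — mobile loops at 1.6×R1, 0.6×R2, NOE 0.45, and 2% Gaussian
intensity noise with full duplicates.  Titrations emulate fast exchange: a
hyperbolically saturating bound fraction over eight steps to 1:2, shift
endpoints up to 0.12/0.65 ppm (¹H/¹⁵N) with random signs inside a composite
site (loop S1–S2 plus two strand segments), site intensity dropping to 0.45
versus 0.85 background at the 1:1 point.  Correlograms follow the Siegert
relation exactly with multiplicative Gaussian noise on g₂ − B (1% default)
for a 2.6 nm particle at 293 K.  SAXS fixtures include an exact Guinier
curve (R_g = 23.09 Å, 0.5% noise), a pool of ten conformers with genuinely
distinct compactness (a mixture search is only identifiable if the pool is
distinguishable), and a known 0.5/0.3/0.2 three-member mixture with 1%
noise.

What passing these tests shows: the estimators are unbiased and correctly
localized under their own model assumptions at realistic noise.  What they
do not show: robustness to baseline drift, peak overlap, chemical exchange
broadening, inter-particle interference, radiation damage, or any other
systematic real-data artifact — none of which the generators emulate.

## Numerical choices and degenerate inputs

Superposition requires ≥ 3 non-collinear paired atoms (collinearity
detected via the second singular value) and raises otherwise.  Exponential
fits flag rather than raise on degenerate (constant) series.  Guinier fits
raise on non-negative slopes ("no Guinier regime").  The DLS fit raises
when g₂ never exceeds its baseline.  Charge-ladder deconvolution raises on
inconsistent ladders, listing the offending implied charges.  Profile
outputs use NaN for missing values, never 0.  Tabular CLI outputs are
formatted to 6 significant digits; reruns with the same config and seed are
bit-identical.

## Problem sizes

Default test and acceptance runs use 8–100 member ensembles of 114-residue
chains, 240–960 SASA points, 200-point correlograms, 150-point scatter
curves and 200-replicate rate-recovery studies — sizes chosen so every
statistical check is well converged while the whole suite runs in well
under a minute per module on a single core.

## Known limitations

No model-free (Lipari–Szabo) analysis or anisotropic diffusion tensors; no
CONTIN-style inverse Laplace DLS inversion; no CD secondary-structure
deconvolution; no p(r)/ab-initio SAXS reconstruction; no interface
thermodynamics (ΔG, assembly significance); no symmetry-aware geometry
validation or refinement.  The Debye bead model underestimates scattering
contrast detail at q ≳ 0.3 Å⁻¹.
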