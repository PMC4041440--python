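# ensdyn

Comparative structure/dynamics analysis for small dimeric proteins that have
been characterized by several techniques at once — X-ray crystallography,
solution NMR, DLS, CD, SAXS and ESI mass spectrometry.  The motivating use
case is a bacterial toxin–antitoxin ribonuclease (a MazF-family dimer, 114
residues plus an N-terminal His-tag) whose functionally relevant mobility is
confined to three loops, but every stage is generic and works on any
monomeric or dimeric chain.

The package answers the questions such a study asks:

- **How do the X-ray and NMR ensembles differ, residue by residue?**
  After global Kabsch superposition of every model pair on a masked ordered
  core, the per-residue RMSD track is summarized as mean/min/max over pairs;
  residues without coordinates in one member of a pair (disordered in the
  crystal) enter as a fixed 10 Å placeholder so disorder registers as
  divergence.
- **Which loops are pinned by crystal packing?**  Symmetry mates are
  generated from the unit cell and space group, unique lattice interfaces
  are extracted, and the solvent-accessible surface area (Shrake–Rupley,
  deterministic golden-spiral points) each residue loses at those interfaces
  is summed into a per-chain burial profile.
- **How fast does it tumble and which residues are mobile?**  ¹⁵N R1/R2
  rates come from monoexponential fits `I(t) = I₀ e^(−Rt)`, the hetNOE from
  `I_on/I_off`, and the rotational correlation time from the rigid-core mean
  R2/R1 through the isotropic closed form
  `τ_c = √(6⟨R2/R1⟩ − 7) / (4π ν_N)`.
- **Where does the antitoxin bind?**  Titration chemical-shift perturbations
  `Δδ = √(Δδ_H² + (Δδ_N/6.51)²)` and cross-peak intensity ratios (5-residue
  sliding window) are thresholded at mean + k·sd to call the binding site.
- **Is it a well-behaved dimer in solution?**  DLS correlograms are fit with
  the Siegert relation `g₂(τ) = B(1 + β|g₁(τ)|²)`,
  `g₁ = Σ aᵢ e^(−Γᵢτ)`, giving `D = Γ/q²` and the Stokes–Einstein radius
  `R_h = k_BT/(6πηD)`; an empirical globular calibration
  `R_h(nm) = 0.7429·M(kDa)^0.3599` converts radii to apparent masses.
  CD spectra convert to mean residue ellipticity, and ESI charge ladders
  deconvolve to a neutral mass.
- **Do the ensembles explain the SAXS data?**  Guinier fits
  (`ln I = ln I₀ − q²R_g²/3`, window `qR_g ≤ 1.3`), one-bead-per-residue
  Debye curves, χ goodness-of-fit with fitted scale, and an exhaustive
  Minimal Ensemble Search over weighted subsets of ≤ 5 candidate models.
- **Crystallographic bookkeeping** — Matthews coefficient and solvent
  content (`solvent = 1 − 1.23/V_M`), missing-residue accounting against the
  expected construct, per-residue B-factor tracks, extinction coefficients
  and average masses from sequence.

A seeded synthetic-data module generates every input the pipeline consumes
(coordinate ensembles with mobile loops, toy crystals with designed
contacts, relaxation decays, titration peak lists, correlograms, scatter
curves) together with its ground truth, so the whole pipeline is testable
without any downloads.

## Worked example

Everything below is self-contained — the inputs are generated first:

```sh
ensdyn synth all --seed 7 --out fixtures
ensdyn relax --r1 fixtures/r1.csv --r2 fixtures/r2.csv \
             --noe fixtures/noe.csv --out out
ensdyn dls  --correlogram fixtures/correlogram.csv --components 1 --out out
ensdyn saxs --curve fixtures/saxs_guinier.dat --out out
ensdyn ensemble-rmsd --xray fixtures/ensemble.pdb --out out
ensdyn report --dir out
```

which prints

```
wrote all fixtures to fixtures
tau_c = 15.2445 ns (<R2/R1> = 23.7582)
R_h = 2.59628 nm -> 32 kDa (fraction 1)
R_g = 23.1486 A over 25 points
RMSD outputs in out
```

Reading: the synthetic relaxation data encode a rigid core with
R2/R1 = 23.7, and the closed form turns the fitted mean ratio into a 15.2 ns
tumbling time — the value expected for a ~30 kDa dimer with flexible
termini.  The correlogram was generated for a 2.6 nm particle; the Siegert
fit recovers it and the globular calibration reports the corresponding
32 kDa apparent mass of the dimer.  The scatter curve encodes
R_g = 23.09 Å, recovered by the iterative Guinier window.  The RMSD profile
in `out/rmsd_profile_within_a.tsv` is flat near 0.5 Å in the core and rises
above 4 Å in the three mobile loops (residues 12–18, 48–54, 64–70).

The same commands run unchanged on real inputs: multi-model PDB/mmCIF files
for the ensembles, CSV peak lists and relaxation tables, CSV correlograms
and 3-column `.dat` scatter curves.

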