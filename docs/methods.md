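# Methods

`mscscreen` implements a rational-design screen for thermostabilizing
mutation sites in the active centre of nattokinase (AprY, a subtilisin-family
fibrinolytic serine protease), together with the enzyme-characterization
math used to rank the mutants the screen produces. This note documents the
models, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the known limits of the approach.

## The screening model

A residue is a good mutagenesis candidate for thermostabilization when it
(i) becomes disproportionately mobile at elevated temperature, (ii) does not
participate in substrate binding along the substrate's exit path, and
(iii) is not evolutionarily locked. The screen encodes this as three
sequential filters over a set of residues around the catalytic triad
(Asp32/His64/Ser221):

1. **Flexibility** — keep residues with ΔRMSF = RMSF(328 K) − RMSF(298 K)
   strictly greater than 0.05 Å. RMSF is the per-residue Cα
   root-mean-square fluctuation about its time-mean position over the
   post-equilibration half of a trajectory.
2. **Substrate contact** — remove residues whose apolar atoms stay within
   5.0 Å of any apolar ligand atom for at least 50% of a steered-pull
   trajectory ("prolonged hydrophobic contact").
3. **Conservation** — remove strictly conserved residues
   (grade 9 on the 1–9 scale; 9 = most conserved).

Each filter only removes; the report records every input residue exactly
once, kept or removed with a reason. A contact residue that already failed
the flexibility filter is logged but not double-counted — on the packaged
AprY table this is residue 222, which is why 20 stage-1 survivors minus 4
flagged contacts minus 4 conserved sites nevertheless yields 13 (not 12)
final candidates: only 3 of the 4 contacts are among the 20. On that table
the screen keeps {33, 62, 63, 67, 68, 93, 94, 95, 127, 216, 217, 218, 224}.
Residue 220 (ΔRMSF 0.084 Å) passes the literal > 0.05 Å rule and is carried
through stage 1; it is then removed at stage 3 as grade 9.

### RMSF details

* Equilibration fraction defaults to 0.5 (the first half of each trajectory
  is discarded, mirroring a 50-of-100 ns convention).
* With superposition enabled (default), each retained frame is rigid-body
  aligned (Kabsch, via `scipy`'s `Rotation.align_vectors`) to an iteratively
  refined time-mean reference: align to the first frame, take the mean,
  realign to that mean, re-take the mean. The reference choice is a design
  decision; RMSF is then invariant under any global rigid motion applied to
  the ensemble.
* The analysis atom set is Cα only. Closed-form checks against the
  synthetic generator are run with superposition disabled, because the
  generator plants pure positional jitter with no rigid-body motion to
  remove; fitting a rotation to noise would otherwise absorb a few percent
  of the fluctuation.

### Steered pull and the adaptive controller

The pull simulator integrates a mobile ligand over a rigid receptor with
velocity-Verlet, a 12-6 Lennard-Jones receptor–ligand potential
(Lorentz–Berthelot combination, 10 Å cutoff), harmonic intra-ligand bonds,
and no electrostatics. A constant external acceleration is applied to every
ligand atom along the receptor→ligand centre-of-mass unit vector, updated
every step. The controller:

* starts at the minimum acceleration 2000 pm/ps²;
* adds 500 pm/ps² whenever the maximum COM separation has not strictly
  increased for 400 consecutive steps (the stagnation counter resets on any
  strict increase; tolerance 0 Å);
* every 20 steps, if the maximum separation grew faster than 4000 m/s
  (measured as growth over the 20-step window — the measurement window is a
  design decision), multiplies the acceleration by 1 − (1 − 4000/v)²;
* never lets the acceleration drop below the minimum;
* stops when the ligand COM has moved 15 Å from its pull-start position.

Forces are reported in pN via F = m·a with the conversion constant
0.00166 pN per Da·pm/ps² (so the 624.24 Da reference ligand at the minimum
acceleration corresponds to 2072.48 pN); work is the path integral of that
force along the pull direction, in pN·Å.

Numerical choices: a single 1.25 fs timestep (a multiple-timestep scheme
buys nothing at toy scale and the controller is timestep-scheme-agnostic);
NVE with Maxwell–Boltzmann initial velocities at 298 K drawn from the seed
(no thermostat/barostat — their internals belong to the original MD engine
and a 3 ps + few-ps toy run does not need them); a 3 ps force-free
equilibration precedes the pull. Runs are bit-reproducible for a fixed seed
and timestep, and a hard step cap guards against non-termination (which the
unbounded stagnation escalation makes unreachable in practice).

Free-particle runs agree with the constant-acceleration closed forms
(t* = √(2d/a), W = m·a·d) to better than 1%, limited only by the discrete
termination check.

"Hydrophobic contact" is an apolar–apolar heavy-atom pair within 5.0 Å and
"prolonged" means present in ≥ 50% of pull steps; neither constant has a
published definition, so both are explicit, configurable defaults.

### Conservation scoring

ConSurf-style grading rests on phylogenetic rate estimation (Rate4Site),
which is out of scope; the stand-in scorer is per-column Shannon entropy
over amino-acid frequencies with gaps excluded: s = 1 − H/ln 20, graded as
1 + round(8s). Anchoring is absolute (all-identical → 9, uniform → 1) rather
than percentile-based so that "grade 9 = strictly conserved" is meaningful
on any alignment. Columns with > 50% gaps are flagged low-confidence and
all-gap columns get no grade. Published grade tables are consumed as data
when replaying a published selection — the stand-in cannot and does not try
to reproduce ConSurf's exact grades (the underlying alignment is unknown
anyway). One convention conflict is resolved deliberately: descriptions of
the 1–9 scale disagree on direction in places; this package fixes 9 = most
conserved, matching how the grade-9 exclusion rule is actually applied.

Missing grades default to "keep" (exclusion requires positive evidence of
strict conservation); a conservative "drop" policy is available.

## Enzyme characterization

* **Michaelis–Menten**: nonlinear least squares on v = Vmax·S/(Km+S)
  (`scipy.optimize.curve_fit`, data-driven initial guesses, positivity
  bounds) rather than a Lineweaver–Burk linearization, which distorts the
  error structure. kcat = Vmax/[E] when the enzyme concentration is known.
* **Thermal inactivation**: single-exponential A(t) = A0·exp(−kt), log-linear
  seed then nonlinear refinement; t½ = ln 2/k exactly by construction.
  Non-decaying data are an error, not a fit.
* **Comparisons**: fold = mutant/reference and percent = 100·(fold − 1),
  rounded to one decimal only at reporting time.
* **Fibrin plate**: the urokinase standard curve is modelled as
  log10(activity) linear in clear-zone area (the usual radial-diffusion
  convention; no published standard-curve data exist to fit an alternative),
  inverted to map zone areas to U/ml.
* Variant presets (`VARIANT_PRESETS`) store Km (μmol/L), kcat (s⁻¹),
  half-life at 55 °C (min) and specific activity (U/mg) for rAprY, A216E,
  A216K and A216R. The enzyme concentration behind the published kcat values
  is not available, so presets store kcat directly and the Vmax→kcat
  conversion is exercised on synthetic data only.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (spec, seed).

* **Trajectories**: residue *i* jitters about a fixed helical backbone with
  iid per-coordinate Gaussian sd σᵢ (scaled by a per-residue factor at the
  high temperature). The RMSF expectation is exactly σᵢ√3, which is what the
  recovery tests need. This is *not* protein dynamics: no correlations
  between residues or frames, no anharmonicity, no global motion. Passing
  the recovery tests shows the estimator is unbiased and precise on
  uncorrelated jitter, not that 100 ns of real MD would be converged.
* **Alignments**: columns sampled independently with a prescribed modal
  residue and frequency (remaining mass uniform over the other 19). Real
  families have phylogenetic correlation between rows, which entropy scoring
  ignores by design.
* **Pull systems**: a polar receptor blob with optional "sticky" apolar
  residues — three-atom rails along the ligand exit path at ~4 Å lateral
  offset with Lennard-Jones wells of 4000 Da·Å²/ps² (~16 kBT at 298 K, deep
  enough to survive thermal equilibration). The planted residues, and only
  they, must be recovered by the prolonged-contact detector. Defaults: total
  ligand mass 624.24 Da, well depths set per atom class (apolar deep, polar
  shallow).
* **Kinetic series**: Michaelis–Menten rates at 8 log-spaced substrate
  levels over 0.05–5 and residual activities at 10–100 min in 10-min steps,
  with optional multiplicative Gaussian noise. One unit note: published Km
  values are printed in μmol/L while the assay substrate range is quoted in
  mM; the generator treats concentrations on a single common numeric scale
  so the design grid spans the preset Km — otherwise Km would sit far below
  the lowest design point and be unidentifiable under noise.

Problem sizes used by the test suite and the acceptance script — 2000-frame
trajectories of 40 residues, 200 noisy kinetic replicates, 20-residue
receptors with 5-atom ligands — were chosen as the smallest sizes at which
the statistical tolerances above are comfortably met; they are the
package's own study conditions, fixed once.

## Known limitations

* Absolute all-atom trajectory summaries (RMSD, Rg, SASA, hydrogen-bond
  counts of the real protein) are not reproducible here: they require the
  original all-atom solvated trajectories. The module computes these
  quantities correctly on the structures it is given (closed-form and
  convergence tests), but its hydrogen-bond criterion is geometric
  (D···A ≤ 3.5 Å, D–H···A ≥ 120° when hydrogens exist), not the original
  engine's energy-based one, so absolute counts will differ.
* Which residues of real AprY contact the real tetrapeptide substrate
  cannot be re-derived without the docked complex; the pull module instead
  proves the detector on planted ground truth.
* ConSurf's exact conservation grades are not reproducible (different
  scorer, unknown alignment); published grades are replayed as data.
* All wet-lab numbers (activity assays, yields, measured kinetics) are
  inputs, never outputs: the kinetics module fits and compares them, it
  cannot re-measure them. Where published counts disagree internally (an
  intermediate "16 candidates" that is arithmetically inconsistent with the
  printed table), the pipeline applies the stated rules literally and flags
  the discrepancy in the report notes.
* The Shrake–Rupley SASA uses a deterministic golden-spiral point set
  (default 960 points, probe 1.4 Å); accuracy is ~1–2% at that density
  (verified against the closed form for an isolated sphere and by
  point-count convergence).
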