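# Methods

## The fitting problem and the algorithm

Flexible fitting refines an atomic structure into a cryo-EM density map by
running molecular dynamics under a biasing potential derived from the map
(`U_EM`): the map is rescaled so its densest voxel sits at zero energy and
its floor at `gscale` kcal/mol, and each selected (non-hydrogen) atom feels
this potential weighted by its mass, with forces from the analytic gradient
of the trilinear interpolant. The total potential is
`U = U_MD + U_EM + U_SS`, with `U_SS` harmonic restraints on the backbone
torsions of helix/strand residues that protect secondary structure from
overfitting.

The mode-excited variant (`method="mdff_nm"`) augments this with a
stochastic conformational search along elastic-network normal modes. One
replica iterates:

1. compute the reference cross-correlation `c.c_ref` between the
   structure's synthetic map and the target map;
2. build an all-atom elastic network for the current structure and solve
   for its low-frequency modes under the rotation-translation-block (RTB)
   reduction, one residue per block;
3. draw `k` distinct modes (default 3) from the lowest-frequency pool
   (default: the bottom 1% of the spectrum, never fewer than `k`) with
   probability `p_i ∝ 1/λ_i`;
4. combine them with uniform random coefficients `α ∈ [−0.5, 0.5]` and
   mass-normalise the result `Q` so `QᵀMQ = 1`;
5. displace the structure along `Q` (mass-weighted RMS amplitude 0.5 Å by
   default), in both signs, and accept the combination only if the
   correlation improves (`Δc.c > 0`); otherwise redraw (bounded at 50
   attempts per cycle, after which the cycle runs unbiased);
6. scale `Q` to carry exactly `Ek` kcal/mol of kinetic energy
   (`λ_exc = sqrt(2·Ek/QᵀMQ)` in internal units) and add `λ_exc·Q` to the
   atomic velocities;
7. run a short biased MD segment (default 1 ps) and re-measure `c.c_ref`
   from its last frame.

A replica stops when `c.c_ref` fails to increase for two consecutive
cycles (the MD segment is not gated, so the correlation can decrease; the
best-scoring structure seen is tracked and returned alongside the final
one). `M` replicas run independently with seeds `master_seed + replica_id`,
so results are identical whether they execute serially or concurrently.

Two baselines share the same cycle and convergence skeleton: plain biased
MD (`mdff`, the loop minus the mode machinery) and cascade fitting
(`cmdff`), which runs fixed-length plain-MD stages against maps blurred to
a schedule of coarser resolutions (e.g. 9→5 Å in 1 Å steps) before a full
run against the native map. A single-entry schedule at the native
resolution is bitwise identical to plain fitting.

## Units

Internal units are Å, fs, amu and kcal/mol. The single conversion constant
is `1 amu·(Å/fs)² = 1e7/4184 kcal/mol`; it lives in `nmfit.units` and is
exercised by an independent SI round-trip test.

## Density maps

Simulated maps place an isotropic Gaussian, integrating to the atomic
mass, on every non-hydrogen atom. The kernel convention is
FWHM = nominal resolution, i.e. `σ = R/(2·sqrt(2 ln 2))`; the
`"sigma=R/2"` and `"sigma=0.356R"` conventions are available wherever a
resolution is accepted, because published map-simulation tools differ and
the package's contracts are self-consistency, not bit-compatibility with
any one tool. The default voxel size for simulated maps is 1 Å.

Cross-correlation defaults to the overlap form
`Σab/sqrt(Σa²·Σb²)` over voxels where the target density is at or above a
threshold (default 0, i.e. all voxels of a non-negative map — simulated
maps carry no solvent noise); the Pearson (mean-subtracted) form is a
flag. Blurring to coarser resolution is performed in Fourier space, where
Gaussian transfer functions compose exactly; this makes one-step and
multi-step blurs to the same final width agree to round-off, at the price
of periodic wrap-around that is negligible for maps padded by the default
8 Å.

Two numerical properties of the trilinear `U_EM` are worth knowing.
First, the interpolant is only C0: its gradient jumps across voxel
planes, so an atom exactly on a grid plane has a one-sided force (tests
probe forces at generic positions). Second, atoms outside the grid feel a
harmonic restraint toward the nearest grid face with stiffness
`gscale·mass` per Å², which keeps forces continuous across the boundary
and prevents escape.

## Elastic network and RTB

The network connects every atom pair within 10 Å with spring constant
`k(r) = C·r⁻⁶`, calibrated so `k(5 Å) = 1 kcal/mol/Å²`. Published
all-atom elastic networks differ in their spring-constant calibrations,
so the law is a pluggable callable on `ENMParams`. The
mass-weighted Hessian is either solved in full (dense below 3N = 1500,
shift-invert sparse above) or projected onto per-residue rigid
translations/rotations (6 DOF per block, 3 for single-atom blocks, with
degenerate rotations of collinear blocks dropped automatically).

A connected network has exactly six zero eigenvalues. Distorted mid-fit
conformations can have genuinely soft internal modes approaching the
`1e-8·λ_max` near-zero threshold, so rigid-body stripping removes only
modes that are both below the threshold and among the six smallest; a
warning reports any unexpected count.

## The surrogate force field

The reference vacuum engine replaces a physical force field with a
structure-based surrogate: harmonic springs restrain bonds
(covalent-range pairs plus consecutive-residue Cα-Cα pseudo-bonds,
k = 100 kcal/mol/Å²), 1-3 distances of the bond graph (k = 20), and a
soft short-range network (k = 10, i.e. 0.1× bond) limited to pairs within
6 Å *and* within four residues in sequence. The sequence cap is the load-
bearing choice: long-range pairs restrained to the starting geometry
would freeze exactly the interdomain motions the method must sample,
while the local network preserves stereochemical cohesion. `U_SS`
restrains φ/ψ where a full backbone is present and four-consecutive-Cα
pseudo-torsions on Cα-only models (k = 200 kcal/mol/rad², only within
contiguous segments of a single helix/strand code). Chirality restraints
(improper torsions) are off by default — the toy fixtures are achiral.
The surrogate has no excluded-volume term; on the toys, the map bias and
the local network keep conformers sensible, but steric traps of real
proteins are not reproduced (see Limitations).

Integration is velocity Verlet; the Langevin thermostat uses the BAOAB
splitting with exact Ornstein-Uhlenbeck velocity updates (defaults 300 K,
γ = 1 ps⁻¹, 1 fs). Measured kinetic temperature carries an O(dt²)
discretisation bias that is amplified by anharmonic coupling of the
distance springs at weak damping (~+5% at 1 fs on a 20-residue helix);
the equipartition test therefore integrates at 0.5 fs, where the bias is
~1%, and averages 150 ps. Minimisation is L-BFGS on the analytic
gradient, recording a monotone per-iteration energy trace. Heating
assigns Maxwell-Boltzmann velocities at 50 K, ramps the thermostat target
linearly to 300 K, and decays an initial 10 kcal/mol/Å² positional
restraint to zero over the first half of equilibration.

An external all-atom engine can replace the surrogate by implementing the
`md_segment` signature (`EngineAdapter` documents the contract).

## Toy fixtures

`make_two_domain_toy` builds a 33-residue, Cα-only two-domain protein:
each domain is a compact antiparallel two-helix hairpin (strand axes
7.5 Å apart, so the strands cross-brace each other within the network
cutoff), joined by a three-residue linker laid on a circular arc with
proper ~3.6 Å Cα steps. A seeded 0.1 Å jitter breaks the exact helical
symmetry of the analytic trace — without it the network has
constraint-rank-deficient zero-energy mechanisms — and the jitter draw is
redrawn deterministically until both forms are free of sub-3.1 Å
non-bonded contacts. The open and closed forms come from one scaffold by
rigidly rotating the linker-plus-domain-2 group about the y axis through
the last domain-1 residue (60° vs 10° by default).

Because domain 1 is bitwise identical in both forms, the generator
reports the *frame* Cα RMSD between them (no superposition; 7.1 Å at the
defaults). The same convention holds during fitting: the target map fixes
the laboratory frame, so the driver's RMSD-to-target is computed without
superposition. (Kabsch-superposed RMSD, the convention for comparing
crystal structures, saturates near 0.43·Rg ≈ 2.8 Å for any two-body hinge
of 15-residue domains and would under-report the conformational gap.)

`make_benchmark_case` simulates the 5 Å target map from the closed form
and docks the open form by *local* rigid refinement from its generation
pose — mirroring the common practice of locally optimising a roughly pre-placed
structure — because a global principal-axes search on a quasi-symmetric
two-lobe toy can select a domain-swapped pose with higher overlap.

## Toy benchmark conditions

Two of the default parameters are extensive or size-coupled and are
rescaled for the 33-atom toy; the FitConfig defaults themselves stay at
the values appropriate for protein-sized systems (Ek = 50 kcal/mol,
300 K):

* **Excitation energy.** Ek is injected into the whole system; 50
  kcal/mol is sized for a ~200-residue protein (~1700 heavy atoms,
  ~0.03 kcal/mol per atom) but would double the toy's entire kinetic energy.
  The benchmark uses the same per-atom intensity: Ek = 50·33/1656 ≈ 1
  kcal/mol.
* **Bath temperature.** The correlation gate compares Δc.c against
  thermal c.c fluctuations, whose relative size scales like sqrt(T/N).
  At 300 K the toy's fluctuations are ~7× those of a protein-sized
  system and the two-cycle stop rule fires on noise; the benchmark runs
  at 100 K to restore a comparable gate signal-to-noise. Equipartition
  and drift tests still run at 300 K.

Convergence *speed* between methods is compared by first passage of the
RMSD trace into the fitted regime (< 1.5 Å, capped at the cycle budget),
the quantity convergence is usually judged by in descriptor-versus-time
plots;
the stop-rule cycle count is reported separately. On the toy, plain
biased MD usually fits within a cycle or two but is occasionally trapped
several Å away (a wrong-basin pull that the gated mode kicks escape),
which is what separates the methods at this scale.

## What the toys do and do not show

Passing the desk-scale suite demonstrates the mechanics of the method —
the gate only accepts correlation-improving directions, excitation
injects exactly Ek, RTB reproduces the full spectrum where it should,
the ensemble machinery is internally consistent — on a system whose
energetics are simple and whose density is noise-free. It does not
demonstrate behaviour under experimental map noise, sterically crowded
transitions, force-field accuracy, or hour-scale sampling on
protein-sized systems.

## Problem sizes

The shipped tests use 20-33 residue toys, 10-replica ensembles, 1 ps MD
segments, ≤ 20 cycle budgets, and a 150 ps thermostat check; the
acceptance script runs the same 10 + 10 replica benchmark. These sizes
were chosen so the entire suite completes on one CPU in minutes while
every contract above is still sharply testable.

## Known limitations

* The surrogate force field has no excluded volume and restrains geometry
  to the *starting* structure; fitted conformers inherit starting-model
  local geometry rather than force-field preferences.
* The trilinear map potential has gradient discontinuities at voxel
  planes (shared with grid-force implementations generally).
* Rigid-body docking is moment-based plus local refinement, not an
  exhaustive FFT search; strongly symmetric targets can dock into
  equivalent-overlap poses.
* Kinetic-temperature bias at 1 fs and weak damping is a few percent on
  very small systems (see above); it is irrelevant to the fitting loop
  but visible in thermometry.
* The convergence rule ("no c.c increase for two cycles") is
  noise-sensitive when c.c fluctuations rival per-cycle gains; the toy
  benchmark addresses this with the temperature scaling above, real
  systems by their sheer size.
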