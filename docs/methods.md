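# Methods

## Scope and model

`labelsim` predicts inter-label distance distributions for nitroxide
spin labels and maleimide dye conjugates attached to rigid protein
structures, and converts FRET and DEER readouts to distances. The
protein backbone is always fixed: label flexibility is the only degree
of freedom, which is the regime where rotamer-style analyses are valid
and where the comparison between sampling strategies is meaningful.

## Label templates and forward kinematics

Each label is a Z-matrix-style template anchored on the site's N/Cα/Cβ
atoms: per atom a bond length, bond angle, dihedral and a reference
triplet. Cartesian conformers are built by natural-extension (NeRF)
placement, so covalent geometry is exact for every dihedral vector and
only the listed rotatable dihedrals (5 for R1, 11 for the dyes) move
atoms. Angles are degrees, IUPAC dihedral sign, wrapped to [−180°, 180°).

The shipped templates use standard covalent geometry (C–S 1.81 Å, S–S
2.03 Å, planar five-ring for the pyrroline, N–O 1.28 Å). They are the
package's own constructions, documented in the JSON files themselves:
the R1 template omits the gem-dimethyl groups (they carry no reporter
information), and the dye templates reduce the multi-ring chromophores
to a single rigid planar six-ring at the end of an eleven-rotatable-bond
linker. The reporter point — N–O bond midpoint for R1, ring centroid for
dyes — is what every distance in the package refers to. Exact chromophore
chemistry is irrelevant to the method-level behavior (linker reach and
steric reweighting), which is what the tests exercise.

Glycine sites get a Cβ constructed at ideal tetrahedral geometry
(N–Cα–Cβ 110.5°, branch dihedral +122.5°, 1.53 Å).

## Energy model

Label–protein scoring is a per-element 12-6 Lennard-Jones sum,
E = ε[(f·r_min/r)¹² − 2(f·r_min/r)⁶], with Lorentz–Berthelot
combination, a 10 Å cutoff, and the forgive factor f ∈ (0,1] scaling the
equilibrium distance (default 1.0; values around 0.9 soften clashes to
emulate the side-chain flexibility a rigid-protein calculation cannot
express). The per-element table (ε in kcal/mol: H 0.03, C 0.08, N 0.17,
O 0.12, S 0.45; r_min/2 in Å: 1.20–2.00) is a reduced, package-own
parameter set of force-field-scale magnitudes — it is not a port of any
published force field, and no claim of numerical equivalence to
CHARMM-class energies is made. Protein atoms of the labeled residue
itself and the adjacent peptide atoms (everything within two covalent
bonds of the anchor) are excluded. Overlapping pairs (r < 0.1 Å) are
clamped to a finite 10⁶ kT clash energy so sums stay well-defined.
An optional screened Coulomb term q_iq_j/(ε_r·r) with ε_r = 80 is
available when partial charges are supplied; it is off by default
because the templates ship without charges.

Internal energy unit: kT at 298 K. Boltzmann factors at other
temperatures use exp(−E·298/T).

## Monte Carlo sampler

State: the label's dihedral vector. Proposals draw per-dihedral
perturbations from a symmetric uniform window (±60° default) and redraw
until the wrapped root-mean-square deviation from the current state
exceeds the minimum jump size — 20° for spin labels, 50° for
fluorophores — scaling the window up if 100 redraws fail, so the
proposal remains symmetric and the call terminates. Acceptance is the
Metropolis criterion at 300 K. With `minimize_steps = 0` (the default)
the chain is plain Metropolis and samples exp(−E/kT) exactly; this
exactness is what the calibration tests verify (uniform marginals on a
flat landscape, quadrature-matched Boltzmann histogram on a cosine
landscape, 3:1 double-well occupancy). A greedy dihedral relaxation of
each proposal (`minimize_steps > 0`) is available to emulate protocols
that minimize each putative state before the acceptance test; it biases
the stationary law toward minima and is therefore opt-in, and it relaxes
only the label's dihedrals — the protein stays rigid, a deliberate
desk-scale simplification of whole-protein conjugate-gradient
minimization.

Default trajectory length is 50,000 steps. Distance distributions use
the non-synchronous sliding-window pairing (all N² distances between the
two labels' frames); because N² at 50,000 frames is 2.5·10⁹ pairs, the
default stride subsamples each trajectory to ≤ 3,000 frames (≤ 9·10⁶
pairs), which is statistically equivalent for well-mixed chains —
`stride=1` forces the exact pairing. The accessed-volume diagnostic
voxelizes label atom positions (1 Å default grid) and reports the
cumulative distinct-voxel volume, a convergence check on conformational
sampling.

## Rotamer library analysis

Published precalculated rotamer libraries are not redistributable here,
so the package generates its own: flat-landscape MC on the free label
(whose stationary distribution is uniform on the dihedral torus)
supplies samples; k-means on the (cos, sin) torus embedding partitions
them; each cluster's medoid (member sample nearest the centroid) becomes
a rotamer with intrinsic population equal to the cluster weight. Default
size 210 rotamers. This is a functional substitute with the same
structure (discrete conformers + intrinsic populations), not a numerical
clone of any published library; k-means with medoid extraction stands in
for k-medoids, which the installed clustering stack does not provide.

At a site, each rotamer's N/Cα/C anchor is superposed onto the backbone
by least-squares (Kabsch), the placed side chain is scored with the
energy model, and probabilities are p_i = p0_i·e^(−E_i/kT)/Z (T default
298 K). A site where every rotamer clashes raises an explicit
"unlabelable" error rather than returning an underflowed distribution.
The χ1/χ2 class selection (m: [−120°,0°), p: [0°,120°), t: wrapped
remainder — standard gauche−/gauche+/trans boundaries) keeps {m,m} and
{t,p}, the dominantly populated R1 rotamers at helical sites in protein
crystals, and renormalizes; it applies only to sites flagged helical.
The pair distribution weights each rotamer-pair distance by p_i·p_j.
The RLA reporter is the N–O midpoint, consistent with the MC reporter.

## FRET conversions

E = (1 − I_DA/I_D)/f_A, where f_A is the acceptor labeling efficiency
(dye-to-protein concentration ratio); dividing the apparent efficiency
by f_A is the standard ensemble correction for the unlabeled-acceptor
fraction, adopted here as the correction operator. r = R0(1/E − 1)^(1/6)
and its inverse; R0[Å] = 0.2108(κ²n⁻⁴Φ_D·J)^(1/6) with J in
M⁻¹cm⁻¹nm⁴. The A350/A488 pair uses the manufacturer R0 = 50 Å at all
temperatures. The FRET-expected distance of a simulated distribution
averages the efficiency, not the distance, so the 1/r⁶ weighting of
short distances is respected. Reported distances round to the nearest
Ångström, matching how such tables are printed.

## DEER forward model and inversion

Kernel: K(t,r) = ∫₀¹cos[(3x²−1)ω_dd·t]dx with ω_dd = 2π·52.04 MHz/(r/nm)³
(free-electron dipolar constant), evaluated in closed form with Fresnel
integrals (exact; no quadrature truncation at fast oscillations).
Forward signal: V(t) = [(1−λ) + λ·K̄(t)]·e^(−k·t) + noise.

Background correction fits B₀e^(−kt) to the trace tail by log-linear
least squares. On short traces the dipolar oscillation has not decayed
in the tail, which biases the plain fit, so on effectively noiseless
data (noise estimated from second differences, threshold 10⁻³) the fit
is refined: a Nelder-Mead search over (λ, k), multi-started over the
background rate, minimizing the full-model residual with the
distribution re-solved by NNLS at each candidate (inner α = 10⁻⁷, kept
tiny so the inner solve adds no bias). The (λ, scale, distribution-mass)
degeneracy is closed afterwards by renormalizing to unit distribution
mass. Fitted rates below 10⁻⁶ µs⁻¹ are treated as exactly zero. This
refinement is *not* attempted on noisy data: with appreciable noise the
residual cannot distinguish a background exponential from broad
long-distance components (the classic DEER background ambiguity), and
the plain tail fit with a user-chosen fit window — exactly the
established practice — is more robust; its residual ~1 Å systematic
uncertainty at noise SD 0.005 is a documented limitation, not hidden.

Inversion solves min ‖KP − S‖² + α‖LP‖², P ≥ 0, L the second-difference
operator, as a stacked NNLS problem, with S = (F − (1−λ))/λ. The default
distance grid is 15–80 Å at 0.5 Å: the window an X-band trace of a few
microseconds actually constrains — allowing shorter/longer distances
lets fast-oscillation components fit noise and slow components mimic
background. α defaults to the maximum-curvature (corner) point of the
L-curve over a 20-point log ladder spanning 10⁻³–10³. The output is
non-negative and normalized to Σp = 1.

## Synthetic data

The generators define the study conditions with known ground truth:

- *Helix scaffolds*: ideal poly-alanine α-helices (φ = −57°, ψ = −47°,
  ω = 180°, standard backbone geometry; rise ≈ 1.5 Å/residue, Cα(i)→
  Cα(i+7) ≈ 10.8 Å), one or two chains at a stated axis separation
  (default 30 Å), sites flagged helical, no side chains beyond Cβ. Fully
  deterministic.
- *FRET intensities*: I_D = 1, I_DA = 1 − f_A·E_true + Gaussian noise —
  the exact inverse of the efficiency estimator at zero noise.
- *DEER traces*: Gaussian-mixture truths (defaults in the 25–59 Å range
  with 6–11 Å widths, the regime of well-defined experimental
  distributions), modulation depth 0.3, background rate 0.05 µs⁻¹,
  noise SD 0.005, 8 ns sampling; trace length defaults to 2 µs, and
  longer-range truths should use windows long enough for the slowest
  dipolar period, as an experimenter would.

What the scaffold does *not* emulate: real side-chain packing, loops,
crystallographic solvent, or backbone motion. Passing tests therefore
demonstrate method correctness (sampling laws, weighting formulas,
inversion fidelity), not force-field accuracy on real proteins; the
published full-protein distance tables require the original force fields
and libraries and are out of desk-scale reach.

## Numerical choices and degenerate inputs

- Parsing keeps model 1 only; altlocs resolve to highest occupancy,
  ties alphabetical.
- Sites in unresolved regions (missing residues) raise; no loop
  rebuilding.
- Attachment rejects initial conformers within 0.8 Å of any retained
  protein atom (configurable or off) instead of silently fixing them.
- FWHM of multimodal distributions spans the outermost half-maximum
  crossings of the global maximum, linearly interpolated; this assigns
  one width to structured distributions.
- All-zero distributions, empty placements, unlabelable sites, and
  traces without modulation depth raise explicit errors; a flat trace
  inverts to a flat distribution with a "no dipolar modulation" warning.
- One seedable generator (numpy PCG64) per run; fixed seed gives
  bit-identical MC trajectories and noise realizations.

## Known limitations

- The energy model is deliberately reduced; predicted distributions on
  real proteins carry force-field-level uncertainty beyond the method's
  own.
- Automated DEER background fitting on noisy short traces has ~1 Å
  systematic mean uncertainty (see above); fit windows matter, as in
  established analysis tools.
- The generated rotamer library reproduces the structure, not the
  numerical populations, of published libraries; intrinsic populations
  from a flat landscape are close to uniform by construction.
- No orientation selection, multi-spin effects, or excitation-bandwidth
  corrections in the DEER kernel; κ² = 2/3 is assumed for FRET (valid
  for freely rotating dyes, as low anisotropies indicate).
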