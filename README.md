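# labelsim

Site-directed spin labels (the MTSSL-derived R1 side chain) and
fluorescent dyes (Alexa-type maleimide conjugates) report inter-residue
distances through DEER/PELDOR and FRET experiments — but the label sits
at the end of a flexible linker, so the measured label–label distance can
differ from the backbone Cα–Cα distance by 10 Å or more. `labelsim`
models that offset *in silico*: it attaches label side chains to a
protein structure, samples their conformations, predicts the inter-label
distance distribution, and converts raw experimental readouts (FRET
intensities, DEER dipolar traces) into distances so that prediction and
experiment can be compared on the same axis.

## What it computes

**Conformer sampling.** Labels are internal-coordinate templates with
rotatable dihedrals (5 for the nitroxide, 11 for the dyes) anchored on
the backbone N–Cα–Cβ triad. Two samplers are provided:

- *Metropolis Monte Carlo* over the label dihedrals: uniform jump
  proposals constrained to a minimum total dihedral RMSD per jump (20°
  spin / 50° dye), Metropolis acceptance at 300 K against a pairwise
  Lennard-Jones energy in a dielectric continuum (ε = 80), protein
  rigid. Distance distributions come from the non-synchronous
  sliding-window pairing: all N² inter-reporter distances between the
  two trajectories.
- *Rotamer library analysis (RLA)*: a discrete rotamer set with
  intrinsic populations p0 is superposed onto the site backbone and
  Boltzmann-reweighted by the label–protein interaction energy,
  p_i ∝ p0_i·exp(−E_i/kT), with an optional *forgive factor* f ∈ (0,1]
  that scales the Lennard-Jones equilibrium distance to soften clashes.
  At α-helical sites an optional crystallographic selection keeps only
  the {m,m} and {t,p} χ1/χ2 rotamer classes. The pair distribution is
  the p_i·p_j-weighted histogram of reporter–reporter distances.

The *reporter point* is the N–O bond midpoint for the nitroxide and the
chromophore centroid for dyes.

**Experimental conversions.**

- FRET: E = (1 − I_DA/I_D)/f_A with acceptor labeling efficiency f_A;
  r = R0·(1/E − 1)^(1/6); R0[Å] = 0.2108·(κ² n⁻⁴ Φ_D J)^(1/6).
  A predicted distribution is turned into the distance a FRET experiment
  would report via ⟨E⟩ = Σ p_k/(1+(r_k/R0)⁶), honoring the 1/r⁶ bias.
- DEER: forward model V(t) = [(1−λ) + λ·Σ p_k K(t,r_k)]·e^(−k_bg·t) with
  the Fresnel closed form of the dipolar kernel; exponential background
  fitting; Tikhonov inversion with second-difference smoothing,
  non-negativity, and L-curve selection of the regularization parameter.

Summaries follow the field convention "mean/width": center of gravity
and full width at half maximum (outermost half-max crossings).

## Worked example

Convert measured FRET efficiencies (as donor intensity pairs) into
distances with the A350/A488 Förster radius R0 = 50 Å:

```
$ labelsim fret meas.csv --out fret_out.csv
$ cat fret_out.csv
pair,efficiency,distance_A,distance_nearest_A
Rpo4G63-Rpo7V49,0.6799999999999999,44.09711548008669,44
Rpo4G63-Rpo7S65,0.42000000000000004,52.763442330662194,53
Rpo4G63-Rpo7K123,0.38,54.25061757976625,54
```

An efficiency of 0.68 means the donor is quenched to 32% of its
unquenched intensity; at R0 = 50 Å that corresponds to a 44 Å
donor–acceptor separation.

Predict a spin-pair distance distribution on the synthetic two-helix
scaffold (backbone separation 30 Å) by rotamer analysis, and invert a
simulated DEER trace:

```
$ labelsim predict --site A:10:helical --site B:10:helical \
      --method rla --n-rotamers 60 --seed 1 --out rla_dist.dat
site A:10: Z = 54.24
site B:10: Z = 54.24
mean/width: 30.4/0.6 A  (seed=1, method=rla)

$ labelsim simulate --kind deer --seed 3 --out trace.dat
ground truth mean = 40.0 A (seed=3)
$ labelsim deer trace.dat --fit-start 1.2 --out deer_dist.dat
lambda = 0.248, k = 0.0926/us; mean/width: 39.5/6.6 A
```

The predicted label–label mean (30.4 Å) sits at the backbone separation
because both labels project symmetrically from facing helices; the DEER
inversion recovers the 40 Å ground-truth mean within 0.5 Å from a noisy
trace (the fitted modulation depth and background rate carry the usual
uncertainty of automated background correction at this noise level).

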