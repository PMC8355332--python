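# Methods

`gomech` quantifies how graphene-oxide (GO) nanosheets change the mechanics
of adherent cells, through four measurement channels that share one design:
every analysis operation has a seeded synthetic generator producing inputs
with known ground truth, so each estimator can be validated by parameter
recovery rather than by eye.

## Hertz fitting of AFM force curves (`gomech.afm`)

**Model.** A spherical probe of radius R indenting an elastic half-space
follows F = (4/3) · E/(1−γ²) · √R · δ^{3/2}, with Young's modulus E,
Poisson ratio γ and indentation δ. Defaults are γ = 0.4, R = 10 nm
(20 nm probe diameter) and a 500 nm depth window — the conditions of the
AFM experiments the pipeline emulates. Internals are SI (Pa, m, N); the
interface speaks nm / nN / kPa because that is what instruments export.

**Contact point.** Approach curves have an unknown contact offset z₀. We fit,
for every candidate sample, the piecewise model "flat baseline for z < z₀,
baseline + c·(z−z₀)^{3/2} beyond", both coefficients in closed form, and take
the global residual minimum. This grid search is deterministic and exact on
noiseless data (the true z₀ is a sample by construction in the generator);
no optimizer tuning is involved. A curve whose maximum force does not rise
3 baseline-noise SDs above the pre-contact mean is rejected as contactless;
a contact point at the very first sample is flagged with a warning because
the baseline is then unobserved.

**Modulus.** With z₀ fixed, F = c·δ^{3/2} is linear in c, solved by least
squares over 0 < δ ≤ 500 nm after baseline subtraction, and
E = 3c(1−γ²)/(4√R). Noiseless generated curves are recovered to ≤ 1e-6
relative error; under 5% force noise the estimator is unbiased within
Monte-Carlo error (50 replicates). Deflection-mode curves
(δ = z − z₀ − F/k) are supported behind a flag; the default assumes force
files with the spring constant already applied. Group summaries report
mean ± sample SD in kPa and the percent change vs a named control,
100·(E_ctrl − E_grp)/E_ctrl.

## Nematic order of the actin network (`gomech.actin`)

The image is tiled into overlapping square blocks (default 32 px, 50%
overlap — the source images state no block geometry, so these are exposed
as flags). Per block, after mean subtraction and a Hann taper, the centred
2D power spectrum (DC removed, radially windowed to the usable annulus) is
summarised by its second-moment tensor; the director is the axis orthogonal
to the spectral major axis, and coherence is the normalised eigenvalue
anisotropy. Blocks that are constant (zero anisotropy) or have < 50% of
their pixels inside the intensity mask are unset.

The nematic order parameter of block i is q_i = ⟨2(cos²Δθ − ½)⟩ =
⟨cos 2Δθ⟩ over director differences Δθ to set neighbours within Chebyshev
radius 1 (8-connected ring, centre excluded); differences are folded into
[0, π/2] because directors are axial. q = 1 for locally parallel directors
and has expectation 0 for random ones; ⟨q⟩ is the unweighted mean over set
blocks. Properties verified: invariance under global director rotation,
equivariance under image rotation by 90°, and monotone growth of ⟨q⟩ with
the generator's von Mises concentration κ (rank correlation > 0.9 across
five κ levels).

Masking is Otsu (or fixed-threshold) with small components removed;
viability counts connected components per live/dead channel and reports
100·n_green/(n_green+n_red).

## Migration statistics (`gomech.migration`)

Cells transit straight microchannels, so velocity is defined as *net*
displacement projected on the channel axis (+x by default) between a
track's first and last samples, divided by elapsed time, in µm/h; net
motion against the axis stays negative and is not clipped. A path-length
speed exists behind a flag for comparison. Cohorts report per-cell
velocities, mean, sample SD, median and quartiles, and
inhibition = 100·(v_ctrl − v_treated)/v_ctrl.

## Coarse-grained GO/actin observables (`gomech.cgmd`)

The GO sheet is a honeycomb lattice (two beads per cell, spacing 0.24 nm)
whose beads are graphene-like SG4 except for a uniformly random fraction
(default 0.48) relabelled oxidised SP1 — exactly round(0.48·N) beads,
seeded. Bonds join nearest neighbours.

Trajectory observables live in a cubic periodic box (default 25 nm):

- **Minimum image.** Component-wise nearest-copy displacement; verified
  against a 27-image brute-force oracle to 1e-10 relative.
- **Group COM.** Beads are unwrapped relative to the first group member,
  averaged (equal masses by default; CG beads are near-equal mass), and
  re-wrapped. A group spanning more than box/2 after unwrapping raises an
  ambiguity error rather than returning a meaningless centroid.
- **Native contacts.** Inter-group pairs within 0.6 nm in a reference
  frame (the cutoff is a package default, exposed as a flag; counting uses
  the same cutoff with no tolerance factor).
- **Energies.** LJ 4ε[(σ/r)¹² − (σ/r)⁶] truncated at 1.2 nm, by default
  shifted to zero at the cutoff; a GROMACS-style force-switch mode
  (switched on [0.9, 1.2] nm) and a bare truncated check mode are provided.
  Coulomb uses the infinite-dielectric reaction field with ε_r = 15 and
  f = 138.935 kJ·mol⁻¹·nm·e⁻², which vanishes at the cutoff — a
  deterministic desk-scale electrostatics model appropriate for group-sum
  energies (no lattice summation is performed here). All pair sums match
  double-loop oracles to 1e-10 relative on ≤ 100-bead frames.
- **Free-energy landscapes.** F = −k_B T ln(P/P_max) over a 2D histogram
  of collective variables (k_B = 0.0083145 kJ/(mol·K), T default 300 K);
  the occupied minimum is exactly 0 and empty bins carry a NaN sentinel,
  never interpolated. Minima are occupied bins strictly below all occupied
  8-neighbours and at least `depth_threshold` (default 1 kJ/mol) below the
  neighbourhood maximum. An optional `min_count` occupancy floor (default
  1) treats sparsely sampled bins as empty: in Boltzmann-inverted
  histograms, tail bins with a handful of samples otherwise generate
  spurious strict minima through Poisson noise. For mixture-detection
  tests we use bin width equal to the component SD with min_count = 10,
  which gives true minima a ~2.5 kJ/mol neighbourhood depth while noise
  minima stay below threshold.

## Synthetic generators (`gomech.synth`)

Every generator is a pure function of (parameters, seed) and attaches a
`GroundTruth` record. What they emulate — and what they deliberately do
not:

- **Force curves**: flat pre-contact baseline, sharp Hertzian onset,
  i.i.d. Gaussian force noise. No hydrodynamic drag, adhesion, tilt or
  viscoelastic creep — passing recovery tests shows estimator correctness,
  not robustness to those instrument artefacts.
- **Filament images**: anti-aliased straight segments with axial von Mises
  orientations (a standard von Mises draw halved — the textbook nematic
  construction; κ = 0 is the uniform axial law, κ ≥ 1e6 collapses to the
  mean), uniform positions/lengths, Gaussian background noise set by SNR.
  No PSF, no filament curvature, no intensity variation along filaments.
- **Tracks**: constant per-cell speed along +x drawn from a zero-truncated
  normal (negative speeds are meaningless here), isotropic positional
  jitter. No persistence-time dynamics or cell-cell interaction.
- **CV samples**: exact bivariate normals (covariance checked by Cholesky).
- **Dimer frames**: two rigid uniform-sphere bead clusters whose template
  COMs are exactly zero, placed at requested minimum-image separations,
  optionally jittered. Not a physical actin model — a geometry fixture.

The reported CG anchor values (COM minima near 3.22–3.5 nm, contact minima
near 650–1400) come from microsecond-scale Martini simulations that this
package does not rerun; the generators reproduce the *statistical
structure* of those observables so the analysis chain can be validated,
and the landscape/minima tests are parameter-recovery checks, not
re-simulations.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — 200-point curves, 50 Hertz
noise replicates, 192–256 px images, 200–500-cell cohorts, 10⁵ landscape
samples, ≤ 100-bead frames against O(N²·27) oracles — were chosen so every
statistical assertion sits at ≥ 3 standard errors of resolution while the
whole suite runs in seconds. Landscape bin edges in the acceptance script
are aligned so the generator mean is a bin centre, removing the systematic
half-bin offset from the argmin location (stochastic scatter of one bin
remains). GRO coordinates round-trip at the format's 3-decimal nm
precision; multi-frame XYZ is used where tests need full-precision
round-trips. Sample SDs use ddof = 1; a single-member group reports SD 0.

## Known limitations

No viscoelastic AFM models (Ting/JKR/DMT), no adhesion analysis, no
per-cell segmentation or stress-fiber tracing, no tracking from video, no
MD propagation, thermostats or PME, and no ANOVA — group outputs are
descriptive mean ± SD by design.
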