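# Methods

This note documents the models behind each `flexsas` stage, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices a user may want to override.

## Composition

Mass, volumes, ν̄ and A280 are additive over residues.  The embedded
tables give, per amino-acid and per glycosyl residue: the average residue
mass (monomer minus one condensation water), a consensus crystallographic
residue volume (Å³) for the unhydrated ("dry") volume, and a partial
specific volume (ml/g) whose mass-weighted mean is ν̄.  The tables are
transcriptions of the standard consensus-volume compilation used in
solution scattering of glycoproteins (amino-acid values of the
Chothia/Zamyatnin consensus lineage; hexose/hexosamine/fucose/sialic-acid
values for the sugars).  A280 (1 % w/v, 1 cm) uses molar extinction
coefficients 5500 (Trp), 1490 (Tyr) and 125 (cystine) M⁻¹cm⁻¹, with all
cysteines assumed paired — appropriate for an antibody.

Hydration: the bound-water count is round(h·M/18.015) with h = 0.3 g/g by
default, and each bound water contributes an electrostricted 0.0245 nm³;
the hydrated volume is dry + count × 0.0245.  These two constants are the
standard glycoprotein hydration parameters and are exposed as arguments.

The embedded IgA1 reference (`flexsas.data.iga1`) uses the canonical human
α1 heavy-chain and κ light-chain constant regions under the canonical
numbering (hinge Pro221–His243, Asn263, Pro455, Asn459, Tyr472).  Serum
IgA1 is polyclonal, so no single V-domain sequence exists; the V domains
shipped here are *synthetic stand-ins* whose residue composition was
adjusted so the whole-molecule aggregates reproduce the published IgA1
values (164 kDa, 205.7/272.5 nm³, 0.724 ml/g, 12.7).  They are suitable
for composition and geometry bookkeeping only.  Both the six-O-glycan and
three-site variants can be generated; the published mass is consistent
with either within its rounding.

## Guinier and cross-sectional analysis

`guinier_fit` regresses ln *I* on *Q*² (weights 1/σ²_lnI when σ is
present) and reports R_g = √(−3·slope), I(0) = exp(intercept), flagging
windows whose max *Q·R*g exceeds the validity bound (default 1.5).
Non-positive intensities are dropped with a warning; a non-negative slope
raises, since a low-*Q* upturn signals aggregation.  `cross_section_fit`
does the same on ln(*I·Q*) with R_xs = √(−2·slope).  Default windows
(overridable; they are instrument choices): X-ray *R*g 0.13–0.25, *R*xs-1
0.28–0.51, *R*xs-2 0.56–1.01 nm⁻¹; neutron *R*g 0.18–0.28, *R*xs-2
0.56–1.04 nm⁻¹.

A point worth knowing: for a uniform sphere the exact ln *I* carries a
*negative* quartic term (ln I = −x²/5 − 0.00286 x⁴, x = QR), so Guinier
fits over wide windows overshoot √(3/5)·R by 1–2%; the analytic-limit
test therefore fits at *Q·R*g ≤ 0.65.  Conversely, for extended particles
the truncation bias runs the other way.  Because the same estimator is
applied to model and experimental curves, these biases cancel in the
selection stage.

## P(r) indirect transform

P(r) is expanded on a uniform grid over [0, dmax] and fitted to I(Q) by
non-negative least squares with a second-difference smoothness penalty
(weight α, default 10⁻³ on normalized data) and hard P(0) = P(dmax) = 0
constraints.  Non-negativity plus smoothness is the classic regularization
choice; the exact criterion of reference indirect-transform programs is
not reproduced, and α is deliberately a visible knob.  Reported: L, the
smallest r beyond which |P| stays below 1% of the maximum (a stable proxy
for "where P(r) intersects zero"); R_g from the second moment; up to two
peak positions (M1, M2) by prominence-filtered peak search.  A dmax
auto-scan looks for a χ² plateau over a geometric sweep and fails
explicitly when none exists.  Grid size 101 points by default.

## Zero-concentration extrapolation and difference curves

I(Q)/c is regressed on c at every Q and the intercept taken, with the
intercept variance propagated from the per-point σ when all curves carry
uncertainties (far more stable than residual-based variance at 3–6
concentrations; the unweighted residual form is the fallback).  Difference
curves subtract after matching forward intensities (Guinier I(0), falling
back to the lowest-Q mean), combining σ in quadrature.

## Sphere models

Coarse-graining lays an axis-aligned cubic grid (origin at the
bounding-box minimum, so results are reproducible) and emits one sphere
per cube holding ≥ cutoff atoms, at the cube centre, carrying the cube's
volume; the sphere radius is set so one sphere's volume equals one cube's
(total volume = count × side³ exactly).  `optimize_grid` scans sides
0.40–0.65 nm (step 0.005) and cutoffs 1–5 to reproduce the composition
dry volume, ties resolved toward the conventional 0.530 nm/4.  Hydration
adds candidate spheres at empty face-adjacent grid positions (growing in
shells when needed) and prunes outermost-first by distance from the model
centroid until the composition's hydrated volume is matched; equivalence
with the reference shell procedure is claimed for total volume only, not
per-sphere placement.

## Debye curves and the R factor

I(Q)/I(0) = g(Q)[1/N + (2/N²)Σ_d n(d)·sin(Qd)/(Qd)] with g the squared
uniform-sphere form factor (series-expanded below x = 10⁻² to avoid
cancellation).  The pair-distance histogram uses 0.02 nm bins with
*per-bin mean* distances, which cancels the first-order binning error;
agreement with the exact O(N²) sum is then ≲ 0.1% everywhere, comfortably
inside the 0.2% oracle bound the tests enforce.  `bin_width=None` runs the
exact sum.

The R factor matches each experimental point to the nearest-Q theoretical
point and minimizes Σ| |I_e| − η|I_t| | / Σ|I_e| over η by bounded
golden-section search bracketed at the peak-intensity ratio ± 50% (the
objective is piecewise-linear convex in η, so this is safe).  Default
X-ray scoring range 0.13–1.25 nm⁻¹.  Hydrated models are scored against
X-ray curves and dry models against neutron curves; theoretical neutron
curves receive a flat incoherent background of 1.5% of I(0) by default
before scoring.

## Conformer sampling

`sample_hinge` is a Markov-chain random walk: each model perturbs every
listed hinge/tailpiece residue's φ and ψ by uniform draws within the step
limits (defaults 10°/30°) *from the previous accepted model*, rotates
everything C-terminal of the pivot rigidly (IUPAC φ/ψ, ideal Engh–Huber
backbone geometry preserved exactly), and rejects models with heavy-atom
clashes (< 0.22 nm between pairs that are inter-chain or > 1 residue
apart; redraw or discard policy behind a flag).  Draws are keyed on
(seed, model index), so a seed reproduces the chain byte-for-byte.  The
walk accumulates diversity — 500 models span roughly half to the full
starting R_g on the toy antibody — which is what makes downstream
filtering informative.  `attach_conformers` takes the Cartesian product
of an ensemble with a rigid fragment library, placing each fragment by
Kabsch superposition on named anchor atoms (skip-with-warning above a
0.05 nm residual).  `add_o_glycans` superposes a template's backbone + Cβ
on each Ser/Thr site and appends only the sugar atoms.

## Selection, PCA and clustering

Filtering keeps models with R ≤ ceiling (default 7%) and |R_g − ref|/ref,
|R_xs-1 − ref|/ref ≤ 10%, bounds inclusive.  The reference values should
be computed with the same (unweighted) estimator as the model values —
the pipeline does this — because weighted and unweighted window fits can
differ systematically on curves without a clean linear regime.  Survivors
are superposed on a rigid anchor (the Fc-like core by default), PCA is
run on flattened Cα coordinates, and the first three PCs are clustered by
average linkage (k = 4 by default, or `auto` = cut at the largest
merge-height gap; linkage and cut rule are declared choices, not
inherited ones).  Each cluster reports its medoid, the model minimizing
summed pairwise Cα RMSD within the cluster.

## Hydrodynamics

The frictional coefficient comes from the Kirkwood double-sum over equal
beads, f = N f₁ / (1 + (a/N) Σ_{i≠j} 1/R_ij), applied to the *surface*
spheres of the model (interior spheres — six face-adjacent neighbours —
are removed first).  On a filled model the sum is dominated by short
interior distances and f collapses unphysically; on the surface shell it
converges to the Stokes value for a sphere.  Finite bead size still
leaves a ≈ 2% low bias (f/f₀ ≈ 0.98 for a discretized sphere), and for
multi-lobed shapes Kirkwood is known to underestimate friction relative
to full hydrodynamic-interaction matrix methods, so absolute s values for
extended toys run high; the exact anchors are the single-sphere Stokes
limit and the closed-form touching dumbbell (f/f₀ = (4/3)/2^{1/3}).
s = M(1 − ν̄ρ)/(N_A f); f₀ uses the sphere with the model's full hydrated
volume.  Solvent presets: water at 20 °C (0.99823 g/ml, 1.0016 cP) for
s°₂₀,w and PBS in light/heavy water (1.00543/1.11238 g/ml, 1.019 cP).

## Hinge span

The "maximum length" of a flexible segment is defined as the geometric
upper bound on its Cα(first)–Cα(last) span: (n−1) virtual Cα–Cα bonds of
the trans peptide (3.804 Å under ideal geometry, computed at run time)
laid collinearly.  Any realizable set of dihedrals gives a shorter span —
the planar φ=ψ=180° zigzag reaches only ≈ 8.0 nm for the 23-residue IgA1
hinge versus the 8.37 nm bound — so the bound is the honest reading of a
"maximally extended" hinge length.

## Synthetic data generator

`make_toy_antibody` builds two "Fab" ellipsoids and one "Fc" ellipsoid of
lattice pseudo-atoms (0.35 nm spacing — clash-free by construction and
cheap to scatter from) joined by two 21-residue backbone linkers tagged
`hinge`.  The default preset is antibody-like: semi-axes 2.4/1.8/1.4 and
2.1/1.7/1.35 nm, arms 50° off vertical, starting hinge dihedrals
(−60°, −50°), chosen once so the preset's Guinier R_g is ≈ 5.9 nm, the
value reported for monomeric IgA1.  `simulate_curve_series` emits X-ray
(441 points, 0.13–2.10 nm⁻¹) or neutron (45 points, 0.18–1.6 nm⁻¹) grids;
at concentration c the per-unit-concentration intensity is
(1 − f_d)·I_mono + 2 f_d·I_dimer with f_d = slope·c (default slope
0.03/mg/ml over 0.25–1.02 mg/ml, i.e. ≤ 3% dimer — the "trace dimer"
regime), the dimer being a side-by-side C2 duplicate at minimal
non-clashing separation and the factor 2 its per-mass forward scattering.
Gaussian noise σ(Q) = a + bQ starts at 0.1% of I(0) and triples across
the grid.

What the generator does *not* emulate: instrument smearing and detector
geometry, radiation damage, inter-particle structure factors beyond the
linear dimer blend, atomic-level contrast (pseudo-atoms are uniform), and
a true two-chain antibody topology (the toy is a single chain, so both
hinge walks propagate C-terminal-ward through the Fc).  Passing the
recovery tests therefore demonstrates the *estimators and bookkeeping*
are right under the assumed noise model, not that real instrument data
will behave as cleanly.  The toy's compact Y shape also lacks a flat
outer cross-section region, so R_xs-2 fits can legitimately fail on it
(the pipeline treats that as absent, not as an error).

## Problem sizes used by the test suite

The suite runs everything at desk scale: brute-force oracles at 120–800
atoms/spheres, the exact-vs-binned Debye check at 500 spheres, dihedral
distribution checks at 3000 models of a 10-residue segment, and the
end-to-end recovery at a 500-model ensemble of the ~1800-atom toy.  The
ensemble bookkeeping check exercises the exact published product counts
(57611 × 3, 36621 × 4) on minimal dummy fragments.

## Known limitations

- Composition accuracy is bounded by the consensus tables and by the
  stand-in V domains (see above); per-residue volumes differ between
  published compilations at the percent level.
- The P(r) solver's α and grid are fixed defaults, not evidence-based
  per-curve choices; very noisy curves may need a manual dmax.
- Kirkwood hydrodynamics is a few-percent-level approximation, and worse
  for strongly segmented shapes (see Hydrodynamics).
- The sampler never re-minimizes geometry; it is a rigid-geometry
  conformational search, so it cannot heal strained starting structures.
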