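# Methods

This note documents the models, numerical choices and known limitations of
funnelmd: what each component computes, why its defaults are what they
are, and what the synthetic study systems do and do not establish about
real protein data.

## The funnel restraint

The restraint region is the classic cone-plus-cylinder construction of
funnel metadynamics. Along a user-supplied egress axis (origin inside the
pocket, unit direction outward) the accessible radius is

    R(z) = R_cyl + (Z_cc − z) tan α   for z < Z_cc,
    R(z) = R_cyl                      for z ≥ Z_cc,

with defaults Z_cc = 0.5 nm, R_cyl = 0.1 nm, α = 1.1 rad. Outside the
funnel a one-sided harmonic wall E = k_wall/2 (ρ − R(z))² applies; the
force includes the z-dependence of R on the cone side so it is the exact
negative gradient. The axis is never inferred from a structure: in the
receptor application it follows the H3–H7–H11 channel found by RAMD, and
placing it is the analyst's decision.

k_wall defaults to 10⁴ kJ mol⁻¹ nm⁻². A harmonic wall is soft: at 300 K a
confined particle penetrates it to a thermal depth
σ_wall = sqrt(k_BT/k_wall) ≈ 0.016 nm, and with a tube radius of only
0.1 nm the boundary layer holds ~10% of cylinder-dwelling frames. That is
restraint physics, not leakage. "Outside the funnel" therefore means
penetration beyond three thermal widths (wall energy > 4.5 k_BT); under
that definition biased runs keep fewer than 0.1% of frames outside, which
is what the containment test asserts. No finite harmonic stiffness could
push the *any-penetration* fraction below 0.1% at this tube radius, and
stiffer walls would force smaller timesteps for no physical gain.

## Collective variables

CV1 is the mass-weighted ligand–protein COM distance (nm). CV2 is the
logistic native-contact score S(X) = Σ 1/(1 + e^{β(r_i − λ r₀)}) with
β = 50 nm⁻¹, λ = 1.8, r₀ = 0.45 nm over a pair list identified once on
the reference crystal structure and then frozen — native-contact
semantics; the list is never recomputed per frame. Identification uses
heavy atoms only (crystal structures carry no hydrogens) and a 0.45 nm
cutoff; each term is 1/2 at r = λr₀ = 0.81 nm. The identification cutoff
(0.45 nm) and the logistic midpoint (0.81 nm) are deliberately different
numbers and are used exactly as stated; no attempt is made to reconcile
them. The switching function saturates through `expit`, so extreme
arguments return exactly 0 or 1 rather than overflowing, and its analytic
derivative feeds the biased forces of the toy simulator.

## The toy simulator

BAOAB Langevin splitting integrates a single particle (default mass
40 amu, 300 K) on a registered analytic potential. BAOAB is used because
its configurational sampling error is small at practical timesteps, which
is what matters for free-energy work. Stable timesteps are documented per
preset (0.004 ps for the 1-D presets, 0.002 ps in 3-D). One seeded
generator drives each run; identical seed and configuration give
bit-identical hill logs.

Well-tempered deposition follows the production schedule: initial height
1.0 kJ/mol, period 2 ps, bias factor γ = 16, Gaussian widths 0.1 (CV1,
nm) and 10 (CV2). Heights are tempered by exp(−V(s)/((γ−1)k_BT)) with
V(s) evaluated from a grid cache refreshed at every deposition; at node
spacing ≤ σ/8 the cache agrees with the exact hill sum to better than
0.01 kJ/mol (tested). In toy systems any smooth function of position can
be registered as a second CV, so the two-CV protocol is exercised without
a protein.

The RAMD rule applies a constant force (16 kcal mol⁻¹ Å⁻¹ production
default) along a direction that is kept at each 100 fs checkpoint only if
the COM moved strictly more than 0.025 Å since the last one, and is
otherwise re-drawn uniformly (normalized Gaussian triple). The equality
case re-draws — a strict reading of "exceeds". Toy egress runs use weaker
forces scaled to the toy barrier heights.

## Free-energy reconstruction and the ΔG estimator

The surface is recovered as F(s) = −(γ/(γ−1)) V(s), shifted to min 0; as
γ→∞ this reduces to −V. The instantaneous hills sum carries a slowly
varying residue from the walker's current position (it deposits where it
sits), which on the 1-D double well fluctuates by a few kJ/mol between
basins. `reconstruct_fes(..., time_average=f)` therefore implements the
standard time-averaged estimator — the mean of aligned reconstructions
over the final fraction f of depositions — which suppresses that residue
without biasing the converged profile. The headline double-well recovery
uses f = 0.6 with 40 checkpoints.

Basins are grid local minima (8-neighborhood in 2-D) found by a watershed
flood: cells are visited in order of increasing F and merged by
union-find; the level where two catchments meet is the minimax saddle
value between their minima, and a basin's depth is its persistence (the
global minimum is measured against the surface maximum). Minima on the
grid boundary are clipped regions, not basins, and are excluded. The
reporting threshold defaults to 2 kcal/mol so that only pronounced minima
are labeled. Bound/unbound flags come from a caller-supplied CV1
threshold — on real surfaces that boundary is a judgment call, so it is
an explicit input.

The absolute binding free energy uses the funnel correction

    K_b = π R_cyl² ∫_bound e^{−β(W(z) − W_u)} dz,
    ΔG⁰ = −k_BT ln(K_b C⁰ N_A),  K_d = C⁰ e^{ΔG⁰/RT},

with W_u the mean of the axial PMF over an unbound window that must lie
in the cylinder; a plateau excursion beyond 1 kJ/mol sets a convergence
warning on the result instead of raising. Two-dimensional (CV1, CV2)
surfaces are first marginalized onto CV1 by −k_BT ln Σ e^{−F/k_BT},
because the correction is one-dimensional while the sampling surface is
not; CV1 serves as the axial proxy. Defaults C⁰ = 1 M and T = 300 K are
echoed in every output. The K_d/ΔG pair is validated for mutual
consistency (1 ppm) at construction, so the conversion convention is
explicit and cannot drift. Uncertainties come from block averages
(5 contiguous blocks by default), the standard choice for autocorrelated
series.

## Ensemble analytics

DCC is computed on Cα atoms: DCC_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)
with deviations about the (weighted) ensemble mean. Zero-variance
residues yield NaN (reported missing, never 0). Frames must share a
common orientation; `superpose_ensemble_to_mean` (iterated mean-fit, two
passes) provides it when the input carries rigid motion. Note an
estimator artifact that the synthetic tests respect: when the planted
collective motion of an elongated chain is two blocks moving in
antiphase, a Kabsch refit absorbs part of it as an apparent rigid
rotation and attenuates the recovered correlation (−0.42 instead of
−0.6 in our fixture); recovery tests therefore evaluate DCC in the
generator's common frame, and superposition is validated separately by
rigid-transform invariance tests.

Helicity is a pure dihedral-window criterion — φ ∈ [−100°, −30°],
ψ ∈ [−67°, −7°] per frame — chosen over DSSP-style methods so the
definition is exact, dependency-light and testable to machine precision.
Chain termini lacking a dihedral are reported missing. Contact occupancy
counts a frame when any heavy-atom pair across two residues is within the
cutoff (0.45 nm default), matching the CV2 convention, and is monotone in
the cutoff. ΔRMSF = (Σ RMSF_mut − Σ RMSF_wt)/N over main-chain heavy
atoms of the analyzed region, sign preserved, exactly antisymmetric; RMSF
is taken about each ensemble's own mean after superposition on a stable
core (caller-specified). Cα anchor statistics report the population (not
sample) standard deviation, stated in the output. Distances and
fluctuations are reported in Å, the unit these observables are quoted in;
everything internal is nm.

## Synthetic study systems and what they establish

The generators define the test conditions; their defaults are fixed and
their ground truth is computed at construction, never hand-copied.

* `harmonic` — equipartition closed form ⟨x²⟩ = k_BT/k.
* `double_well_1d` — quartic wells at ±0.5 nm, 20 kJ/mol barrier, with
  the tilt *calibrated by root finding at construction* so the Boltzmann
  quadrature basin ΔF equals the requested asymmetry (3 kJ/mol default)
  exactly at the run temperature. The headline recovery runs 2×10⁶ steps
  (≈30 s on one CPU), friction 1 ps⁻¹ — low friction speeds barrier
  recrossing, which is what converges the deposition.
* `square_well_axial` — ideal square well on the funnel axis with the
  closed form K_b = πR_cyl²L e^{βD}; an analysis-only preset (its edges
  are discontinuous, so it is not integrated).
* `funnel_trap_3d` — a Gaussian well at the funnel origin with soft axial
  caps; its axial PMF comes from radial quadrature over the funnel
  cross-section, and the ΔG test compares the package's 1-D funnel
  integral against an independent Cartesian 3-D integration (they agree
  to ~0.2%, asserted at 5%).
* `two_channel_exit` — a trap inside a ring barrier with a wide and a
  narrow angular gap, for RAMD channel-choice statistics (40 replicas
  checked against a 5× reference set within the binomial 95% interval).

The planted-ensemble generator builds backbones residue by residue from
ideal dihedrals — helix (−57°, −47°) or coil (−120°, +120°) with 5°
Gaussian jitter, values chosen to sit unambiguously inside/outside the
helicity window — then adds rigid per-residue displacements carrying
block correlations through a factor model (cross-correlation −ρ between
blocks implies within-block +ρ; that trade-off is what keeps the planted
covariance positive semi-definite), realizes contacts by rigid
translation of one residue (which perturbs the backbone dihedrals of its
neighbors; the ground truth lists the affected residues so helicity tests
exclude them), and finally adds iid per-atom Gaussian noise whose RMSF is
σ√3 per atom. The ground truth records *realized* helix fractions and
contact occupancies, so estimator checks are exact rather than bounded by
binomial sampling noise.

What passing these tests shows: the estimators are unbiased and exact on
data whose generating process matches their assumptions, and every
formula agrees with an independent route. What they do not show: real
protein ensembles have correlated backbone and side-chain motion, solvent
friction, anisotropic fluctuations and force-field error that no planted
Gaussian model emulates; the receptor-scale observables themselves
(Table-level ΔG/K_d of real ligands, protein helicity and DCC maps)
require cluster-scale solvated MD and are outside what this package can
certify.

## Numerical conventions

* Units: nm, kJ/mol, ps, amu, K internally; Å at the PDB boundary; ΔG in
  kcal/mol (factor 4.184 fixed), K_d in nM; RAMD parameters keep
  kcal mol⁻¹ Å⁻¹ / fs / Å.
* k_B = 0.0083144626 kJ mol⁻¹ K⁻¹; N_A = 6.02214076×10²³; 1 M =
  0.602214 molecules nm⁻³.
* Writers use fixed `%.6f` formatting and stable ordering, so well-formed
  HILLS/COLVAR/FES files round-trip byte-exactly.
* Ties in the watershed flood are broken by stable sort order; overlapping
  basin extents during frame assignment resolve to the deeper basin.
* Degenerate inputs: empty hill logs, empty selections, missing residues
  and non-finite forces raise with the offending entity named; a
  two-point collinear fit is superposable (its RMSD is well defined) while
  a fully coincident fit set is rejected.

## Known limitations

* The toy engine is a single particle; there is no solvent, no force
  field, and no replica parallelism.
* The inverse hills generator cannot represent walls steeper than its
  Gaussian kernel, so its residual is reported over the thermally
  relevant region (F within 25 kJ/mol of the minimum) — exactly as a real
  metadynamics bias never resolves regions it cannot sample.
* Frame weights within a basin are uniform by default; biased-frame
  reweighting (Tiwary-style estimators) is deliberately not implemented —
  conformational observables are computed on basin-assigned frames.
* The native-pair count on the real AR-LBD structure (m = 254 with the
  production parameters) needs the 1T5Z download
  (`scripts/fetch_1t5z.py`) and is therefore outside the offline suite.
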