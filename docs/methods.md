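# Methods

This note documents the model implemented by `hexsaxs`, its assumptions,
the numerical choices behind the forward calculation and the sampler, and
what the synthetic-data tests do and do not demonstrate.

## The structural model

An inverted hexagonal (H_II) lipid phase is modeled as a bundle of long
hexagonal prisms on a 2D hexagonal lattice (lattice parameter `a`, `n`
rings, `N_hex = 1 + 3n(n+1)` unit cells). Each prism consists of a
cylindrical water core coated by a lipid monolayer (headgroups facing the
water) with a hydrophobic filler (cis-9-tricosene) occupying the
interstitial corners between the inscribed lipid cylinder and the hexagon
boundary.

### Wedge parametrization

A single lipid occupies a wedge (cylinder sector) of the unit cell,
parsed radially into three shells: headgroup H (phosphate +
ethanolamine), backbone BB (glycerol + carbonyls) and hydrocarbon HC (all
CH/CH2/CH3 groups). The geometry is fixed by four molecular parameters —
intrinsic curvature `C0 = -1/R_0`, shell widths `d_H` and `d_BB`, and the
lipid volume `V_lipid` — plus the lattice parameter `a`, which is not
fitted but determined in advance from the Bragg peak positions
`q_kl = (4π/√3 a)·√(k² + kl + l²)`.

The neutral plane (where bending and stretching decouple) is assumed at
the center of the backbone shell, consistent with bending/compression
experiments that place it in the backbone region. The radii follow as
`r_H,out = R_0 − d_BB/2`, `R_W = r_H,out − d_H`, `r_BB,out = R_0 + d_BB/2`.
The HC shell spans `[r_BB,out, a/2]` and is assumed water-free, which
closes the system: the sector mantle area per unit radius is
`A_u = 2·V_HC/((a/2)² − r_BB,out²)` with `V_HC = V_lipid − V_H − V_BB`
(`V_H = 110 Å³`, `V_BB = 135 Å³`, overridable). Shell volumes are
`(A_u/2)(r_k² − r_{k−1}²)`; the water content of the H and BB shells is
whatever volume the fragment does not fill, in units of `V_W = 30 Å³`.
Negative water content is unphysical — the shell cannot be smaller than
its molecular group — and terminates the prior support.

Electron densities are fragment electron counts (plus 10 e per water)
over shell volumes; all contrasts are relative to water
(`ρ_W = 0.33 e/Å³`). The filler density comes from volume-averaged
CH/CH2/CH3 group volumes (configuration data in `data/lipids.yaml`, from
the volumetric literature: `V_CH2 = 27.1 Å³`, `V_CH3 ≈ 2·V_CH2`,
`V_CH ≈ 0.8·V_CH2`).

Derived quantities: hydrocarbon length `d_HC = a/2 − r_BB,out`,
head-to-head distance `d_HH = a − 2 R_W` (exact by construction),
neutral-plane area per lipid `A_0 = A_u·R_0`, and the molecular shape
parameter `s = V_HC/(A_0·d_HC)` (1 for cylinders, > 1 for H_II-forming
inverted cones). The neutral-plane area is used in `s`; it reproduces the
published shape parameters of all four reference lipids within their
printed uncertainties, which is why it was adopted over the polar/apolar
interface area.

### Scattering

The powder intensity decouples form and structure factors (valid for
prisms much longer than wide):

    I_hex(q) = ∫₀^{π/2} S(q,θ) |F_CS + F_int|²(q,θ) sinθ dθ

- `S(q,θ) = 1 + exp(−q²Δ)/N_hex · Σ_{j≠k} J₀(q sinθ |R_j − R_k|)` — the
  in-plane-averaged lattice sum with a Debye–Waller factor for lateral
  lattice disorder Δ. The damping uses the full `q` (not `q sinθ`),
  matching the usual convention for this model. The `1/N_hex`
  normalization is degenerate with the intensity scale Γ; the per-cell
  convention is adopted.
- `F_CS` — the analytic core–shell cylinder amplitude
  (`J₁`-based), with all shell boundaries rigidly translated by a
  Gaussian shift `x ~ N(0, σ_fluc²)` to represent molecular smearing of
  the interfaces; the average uses 15-node Gauss–Hermite quadrature
  (nodes that would push the innermost radius below zero are clipped and
  the weights renormalized — this cannot occur for physical parameter
  sets). The outermost boundary (a/2) shifts with the rest; the
  resulting sub-Å mismatch with the fixed hexagon is a modeling
  approximation, not tracked.
- `F_int` — the amplitude of the hexagon-minus-disc interstitial region
  with uniform filler contrast, computed by Gauss–Legendre quadrature
  over 1/12 of the hexagon (12-fold symmetry) and cached per lattice
  parameter: it never changes during a fit.

A coexisting planar bilayer accounts for the diffuse scattering that
unoriented H_II samples show between the 10 and 11 reflections, where the
prism form factor has a deep minimum. It is a symmetric two-slab profile
(hydrocarbon half-thickness `d_C = V_HC/A_L`, head slab
`(V_H + V_BB + n_W,lam·V_W)/A_L`) with the flat-sheet powder factor
`|F_lam(q)|²/q²` and no interlamellar structure factor (the term models
positionally uncorrelated diffuse scattering; a finite-stack factor would
be a straightforward extension). The two contributions are combined per
lipid — the hexagonal term divided by the `2πL/A_u` lipids of a prism of
length L, the lamellar term multiplied by `A_L/2` — so the mixing weight
`c_lam` reads as a lipid fraction; any residual convention is absorbed by
Γ. The measured curve is `I(q) = Γ·I_mod(q) + I_inc`.

Twelve parameters are adjustable: Δ, n, σ_fluc, C0, d_H, d_BB, V_lipid,
c_lam, A_L, n_W,lam, Γ, I_inc.

### Orientational average

The prisms are long (`L = 2500 Å`, fixed), so the axial factor
`[2 sin(qL cosθ/2)/(q cosθ)]²` concentrates the θ-integral at θ = π/2
while oscillating on the scale `2π/L`. Brute-force Gauss–Legendre in θ
cannot resolve this oscillation together with the sharp lattice-sum
structure at practical node counts. The integral is instead computed
exactly in two parts (substituting `u = q cosθ`):

1. the singular oscillatory kernel integrated in closed form,
   `K(q, L) = 2[L·Si(qL) − (1 − cos qL)/q]`, multiplying the integrand at
   θ = π/2;
2. the remainder `2∫₀^q [g(q_s) − g(q)]·q_s (q² − q_s²)^{−3/2} dq_s`
   (`g = S·|F_cross|²`, `q_s = q sinθ`), computed by product
   integration: `g` is evaluated on a dense shared `q_s` grid (the data
   grid, oversampled 2× by default, plus 48 points covering `(0, q_min)`)
   and interpolated piecewise-linearly in `φ = q² − q_s²`, against which
   the kernel integrates analytically. The endpoint singularity is
   integrable because `g − g(q)` vanishes linearly in `φ`. The weights
   form a precomputed matrix, so a model evaluation costs one
   matrix–vector product. The neglected oscillatory cross term is
   `O(1/qL)` relative to the remainder (≲10⁻⁵ of the total).

The remainder term is the physically real orientational tail of each
Bragg sheet (the 2D-powder `1/(q²−q_kl²)^{1/2}` tail). It is
L-independent in absolute terms while the coherent peaks scale with L, so
*pointwise* relative L-sensitivity is large exactly at deep diffraction
minima where the total intensity is near zero. Convergence and
L-insensitivity are therefore quoted intensity-weighted (L2 over the
curve): doubling the `q_s` resolution changes the reference curve by
4×10⁻⁴, and doubling L (2500 → 5000 Å) changes it by 0.8% for the radii
occurring here. A decoupled long-rod mode (`I ≈ πL/q · S|F|²`) is
available as a cross-check; it agrees with the full integral at the Bragg
maxima to ~1% and is exactly L-free.

This scheme was validated against brute-force adaptive θ-quadrature at
representative q points (agreement 0.05–0.15%, limited by the oscillatory
reference integral itself) and evaluates 600 q-points in ~5 ms.

## Bayesian estimation

The posterior is `p(x|I) ∝ p(I|x)·p(x)` with a uniform box prior times
the molecular constraints (wedge validity, non-negative shell water).
Γ carries a log-uniform density inside its box and is sampled in log
space. The default boxes span the published structural ranges of PE H_II
phases with wide margins: C0 ∈ [−0.1, −0.001] Å⁻¹, d_H, d_BB ∈ (0.1, 15] Å,
V_lipid ∈ [800, 1600] Å³, Δ ∈ [0, 100] Å², n ∈ [1, 30], σ_fluc ∈ [0, 10] Å,
c_lam ∈ [0, 1], A_L ∈ [40, 120] Å², n_W,lam ∈ [0, 30],
Γ ∈ [10⁻⁸, 10⁴] (log-uniform), I_inc ≥ 0. All are overridable; the I_inc
upper bound defaults to the data maximum (the background cannot exceed
the measured signal).

The error bars σ_i are trusted only up to a global scale η with the
Jeffreys prior `p(η) ∝ 1/η`. Marginalizing η analytically gives

    ln p(I|x) = −(N_q/2)·ln χ²(x) + const,
    χ² = Σ (I_obs − I_mod)²/σ²,

which is the likelihood used for sampling (exact normalization retained,
verified against numeric η-quadrature to 10⁻⁹). An explicit-η mode
samples ln η alongside x with the same marginal posterior for x; the two
modes agree within Monte-Carlo error on synthetic fixtures and η
recovers ≈ 1 when the noise is as reported.

### Sampler

Random-walk Metropolis–Hastings with three phases, all of which precede
(and are excluded from) the stored chain:

1. **Width tuning** (3000 steps): single-parameter (random-scan) updates;
   each parameter's Gaussian proposal width starts at 2% of its prior-box
   width and adapts per-parameter toward 20–40% acceptance. Scan updates
   rather than joint 12-dim proposals are essential here: posterior
   widths span many orders of magnitude relative to the boxes.
2. **Covariance adaptation** (2 × 4000 steps): the sample covariance of
   the accumulated adaptation history drives correlated joint proposals
   (`2.38/√d`-scaled Cholesky steps) that follow the strong
   (C0, d_H, d_BB) posterior ridge; the kernel is frozen after the last
   round, so the main chain satisfies detailed balance exactly.
3. **Main run** (20 000 steps by default): 50/50 mixture of scan and
   joint-correlated proposals. `n` moves by ±1 integer steps throughout
   (or is pinned). Non-finite model evaluations reject the proposal and
   are logged, never fatal.

The first 20% of the main run is discarded (burn-in; the conservative end
of the usual 10–20%), and the remainder is thinned by the largest
integrated autocorrelation time (Sokal-window estimator) over χ² and the
parameter series — χ² alone underestimates the ridge directions. Every
stored state's χ² is kept. Summaries report posterior means, standard
deviations, the minimum-χ² sample as the MAP solution (no separate
optimizer), on-demand 2D marginal histograms and pair correlations.
Chains persist as CSV plus a JSON sidecar (seed, thinning, acceptance,
configuration hash).

## Synthetic data

No experimental patterns ship with the package; the generator emulates
them: q-grid 0.03–0.8 Å⁻¹ (600 points, the compact-camera range),
hexagonal Bragg ladder, diffuse lamellar fill between 10 and 11,
incoherent background, and Gaussian noise with σ_i = max(floor, 2%·I_i)
by default (photon-dominated statistics; absolute and Poisson-like noise
models available). The reported σ column always equals the generating σ.

The reference parameter sets (DOPE 308 K, POPE 308 K, DMPE 353 K,
diC16:1PE 308 K) reproduce the published intrinsic curvatures, lipid
volumes and lattice parameters of these systems. The published posterior
means are, however, *not jointly realizable* as a single wedge: with
DOPE's C0 = −0.0409 Å⁻¹ and V_lipid = 1142 Å³ the hydration constraints
cap the water-core radius ≈ 1 Å below its published value. This is
expected — d_H and d_BB have broad, strongly correlated marginals, so the
published means of nonlinear derived quantities need not coincide with
the derived quantity at the means. The reference sets therefore use
values inside the published uncertainty bands (e.g. DOPE C0 = −0.0400)
with d_H, d_BB close to the constraint boundary, where the derived
water-core radius is maximal and falls inside the published band. The
remaining parameters (Δ, n, σ_fluc, c_lam, A_L, n_W,lam, Γ, I_inc) are
plausible fixed choices, not literature values.

### What the tests show — and what they do not

Parameter recovery is demonstrated at study scale: 2% noise, 350 points
on 0.05–0.5 Å⁻¹ (the default fit window; the model is not expected to
track data above ~0.5 Å⁻¹, and the very-low-q structure-factor ripple is
a known finite-domain artifact), 20k-step chains started at the
generating truth. Well-determined parameters (C0, V_lipid, Γ, Δ) come
back within 3 posterior σ; d_H/d_BB show the expected broad ridge, with
headgroup width anticorrelated with curvature *magnitude* (equivalently,
positive Pearson correlation between the negative-valued C0 and d_H).
Starting at truth makes this a posterior-coverage check, not a global
search — with real data, where the truth is unknown, multiple seeds
and starts should be compared (the cost-function landscape has a weakly
defined global minimum; that is the reason for the Bayesian treatment).

Synthetic patterns share the forward model with the fit, so these tests
validate the inference machinery, not the model's adequacy for real
samples: instrumental resolution smearing, lattice-parameter
polydispersity (available as an optional Gaussian average, off by
default, affecting only low q), strained/tricosene-free samples and any
chemistry the three-shell SLD cannot express are outside what passing
tests demonstrate.

## Numerical conventions and edge cases

- `q = 0` is excluded from grids (powder factors diverge); `q_s → 0` and
  θ → π/2 limits of all amplitudes are analytic, not epsilon-guarded.
- Lattice pair distances are computed once per ring count and cached in
  units of `a`; structure-factor lattice sums are cached per `n` on the
  fixed quadrature grid, so integer moves of `n` cost one extra setup.
- χ² = 0 (an exact fit) caps the marginal log-likelihood with a warning.
- Bit-identical reproducibility: a fixed seed and configuration reproduce
  chains exactly; every artifact records the configuration hash and seed.
- Problem sizes used in the shipped tests (220–600 q-points, 1.5k–20k
  chain steps, reduced quadrature in sampler unit tests) were chosen as
  desk-scale defaults; production analyses can raise them freely.
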