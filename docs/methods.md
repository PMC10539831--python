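# Methods

## Model

The package treats one peptide plane as a rigid planar unit carried by an
axially symmetric rotational diffusor whose unique axis lies in the plane.
The orientational memory of two unit vectors u, v fixed in the plane is the
time correlation function C(t) = ⟨P2(u(0)·v(t))⟩ with P2(x) = 1.5x² − 0.5;
its cosine transform is the spectral density J(ω) sampled by spin
relaxation.  For a symmetric top C(t) is a sum of three exponentials,

    C(t) = Σₖ Aₖ(u,v) exp(−t/τₖ),      τₖ = [6D⊥ + k²(D∥−D⊥)]⁻¹,  k = 0,1,2,

with Woessner amplitudes A₀ = P2(cosθᵤ)P2(cosθᵥ), A₁ = ¾ sin2θᵤ sin2θᵥ,
A₂ = ¾ sin²θᵤ sin²θᵥ for coplanar vectors (the azimuthal phase factors are
±1 in a plane and are absorbed into the signs of the polar angles θ).  The
amplitudes obey the sum rule ΣAₖ = P2(cos(θᵤ−θᵥ)) ∈ [−0.5, 1].

Fast internal motion is folded in at the crudest level that still respects
that sum rule: a single order parameter S² weights the three anisotropic
terms and a fourth Lorentzian with amplitude (1−S²)P2(cos∠(u,v)) and

    τ₃⁻¹ = τ_int⁻¹ + 4D⊥ + 2D∥ = τ_int⁻¹ + τ_eff⁻¹

carries the isotropic internal contribution.  This single-S² interpolation
is exact only in the rigid (S²=1) and fully isotropic (S²=0 or D∥=D⊥)
limits; in between it is an approximation that deliberately ignores
k-dependent order parameters and any difference in local dynamics between
the two spin pairs.  No 2/5-type prefactor is carried inside J(ω), so J(0)
is literally the area under C(t); the absolute rate convention compensates
(see below) and every quantity the package reports is a ratio or an
inversion that is insensitive to the choice.

## Rates and the Q ratio

Two CSA–dipole interference pathways are modelled.  For the ¹⁵N CSA
(axially symmetric, anisotropy ΔN) with the N–Hᴺ dipole:

    Γxy = k ΔN [4J(0) + 3J(ωN)],     Γz = k ΔN · 6 J(ωN),

where J is the cross spectral density of the N–H bond vector with the CSA
unique axis.  For the fully anisotropic carbonyl CSA with the C′–Cα dipole
the same structure holds per in-plane principal axis:

    Γxy = k [(σxx−σzz)(4Jxx(0)+3Jxx(ωC)) + (σyy−σzz)(4Jyy(0)+3Jyy(ωC))]
    Γz  = k [(σxx−σzz)·6Jxx(ωC) + (σyy−σzz)·6Jyy(ωC)]

(σzz is normal to the plane and does not couple to in-plane reorientation
at this level).  The 4/3/6 coefficient pattern is what makes
Γxy − ½Γz = 4k·(weighted J(0) sum) an exact zero-frequency isolator, and is
applied uniformly to both axes of the carbonyl tensor — each principal
value multiplies its own axis in both rates.  The prefactor is

    k = (2/5)(1/12)(μ0ħ/4π)(γ₁γ₂/r³)(B0 γcsa) × 10⁻⁶,

with the ppm→dimensionless conversion applied once inside k.  The absolute
scale of k is convention-dependent (it must match the J-normalisation
above); the ratio

    Q = (Γxy − ½Γz)_C′/C′Cα / (Γxy − ½Γz)_N/NH

depends only on the prefactor ratio k_C/k_N = γc³ r_NH³ / (γn² γh r_C′Cα³)
≈ 0.486, which is pure constant arithmetic.  B0 cancels exactly, and at
fixed anisotropy the overall tensor size cancels too, so Q is a function of
geometry, anisotropy, axis orientation β and the S²/τ weighting only.  For
isotropic dynamics Q reduces to

    Q_iso = (k_C/k_N)·[(σxx−σzz)P2(cos29°) + (σyy−σzz)P2(cos61°)]
            / (ΔN·P2(cos20°)) = 0.310,

which the full pipeline reproduces to machine precision at S²=0 or D∥=D⊥.

## Geometry conventions

The plane is built in 2-D: C′ at the origin, C′→Cα(i) along +x, N at +114°,
O at −121°, trans peptide, amide proton on the side of the C′–N bond
opposite Cα(i+1).  All dipole and CSA orientations are signed angles from
C′→Cα; with these conventions N–H sits at +57°, the ¹⁵N CSA unique axis at
+37° (20° from N–H, tilted towards N–C′), the carbonyl xx axis at α_C−66°
(α_C from the C′–N bond line, between C′→Cα and N→C′), yy = xx + 90°, and
the virtual Cα(i)→Cα(i+1) vector at 157.8°.  The xx convention is fixed by
requiring the P2 projection windows onto C′–Cα over α_C ∈ [30°, 44°]
(max/min 0.79/0.48 for xx and 0.02/−0.29 for yy) to come out of a single
orientation rule; it must not be changed silently.  Defaults: bond lengths
Cα–C′ 1.53 Å, C′–O 1.24 Å, C′–N 1.32 Å, N–Cα 1.47 Å, N–H 1.04 Å; angles
121/114/125° around C′ and 123/123/114° around N; ΔN = 170 ppm, α_N = 20°;
σxx/σyy/σzz = 249.4/191.1/87.9 ppm, α_C = 37°; B0 = 18.8 T.  All are
overridable through `PlaneParams` (JSON config with the same key names);
σyy is treated as a fixed calibration constant, not re-derived.

The orientation scan measures β from C′→Cα rotating towards N–Hᴺ (i.e.
counterclockwise in the construction frame), 0–180° with 1° steps by
default; Q(β) has period 180°.  The default dynamics grids — τ_eff ∈
{1, 2.5} ns, τ_int ∈ {100, 500} ps, S² ∈ {0, 0.1, …, 1}, D∥/D⊥ ∈
{1.5, 2.5} — bracket the tumbling and internal timescales typically
reported for disordered chains (τ_eff ≥ 1 ns > τ_int).  On this grid the
rigid anisotropy-2.5 curve has its maximum at β = 162° (4° from the Cα–Cα
direction) and its minimum at β = 75° (18° from N–H); the extrema are
reported at grid resolution, with no continuous refinement, because only
their association with the two landmark orientations matters.

## Experimental-side arithmetic

A longitudinal CCR rate is extracted from doublet component intensities as
Γ = ln(Ia/Ib)/(2T) (natural log; valid while |Γ|·2T stays small enough that
the doublet decays mono-exponentially — the synthetic generator warns of
nothing but the tests exercise |Γ|·2T ≤ 5).  First-order error propagation
gives σ_Γ = σ_I/(2T)·√(Ia⁻² + Ib⁻²).  The N/NH rate pair inverts exactly:
J(ωN) = Γz/(6kΔN), J(0) = (Γxy − ½Γz)/(4kΔN).  The carbonyl channel only
yields the composite (σxx−σzz)Jxx(0) + (σyy−σzz)Jyy(0); the two axes cannot
be separated from two rates, and no attempt is made to.

The synthetic doublet generator emulates ideal mono-exponential doublet
relaxation with multiplicative Gaussian intensity noise (default study
condition: T = 50 ms, 1% relative noise, 200 residues).  It does not
emulate peak overlap, lineshape distortions, remote-carbon CCR
contamination, cross-relaxation leakage, or baseline artefacts — passing
recovery tests therefore demonstrates the correctness of the arithmetic and
the error propagation, not robustness to real spectra.

## Brownian rotor oracle

The closed-form spectral densities are validated against an independent
stochastic simulation: a body frame is propagated by small random rotations
about its own axes with per-step variances (2D⊥dt, 2D⊥dt, 2D∥dt), composed
in a random order each step, with Gram–Schmidt re-orthonormalisation
keeping drift below 10⁻⁹.  The step bound dt ≤ 0.02/(6·max(D∥, D⊥)) keeps
the per-step angular variance below 2% of the fastest relaxation rate.
TCFs are estimated by lag averaging over all time origins; block averaging
over contiguous origin blocks provides Monte-Carlo error bars.  Agreement
is measured as the maximum deviation on the P2 correlation scale (all TCFs
normalised so an auto-correlation starts at 1): normalising by a cross
pair's own amplitude would diverge near magic-angle geometries however
accurate the dynamics.  At 2×10⁶ steps of 6 ps (τ_eff = 1 ns,
D∥/D⊥ = 2.5) the measured deviations are 0.7–2.4% for the peptide-plane
pairs, inside the 5% acceptance band; a deliberately wrong geometry fails
by an order of magnitude.  The simulation covers rigid tumbling only — the
S² < 1 internal term is validated analytically (sum rules, isotropic
collapse, numeric cosine-transform agreement to 0.1%), not stochastically.

## Numerical choices and problem sizes

- Angles are stored in degrees and wrapped to (−180°, 180°]; P2 rejects
  arguments outside [−1, 1] beyond 1e-12.
- The Lorentzian amplitude sum is validated against [−0.5−1e-9, 1+1e-9].
- Magic-angle denominators (|P2| < 1e-9) and vanishing Q denominators
  (< 1e-15 s⁻¹) raise explicit errors; the scan attaches grid coordinates
  to any failure it propagates.
- The numeric J oracle uses Simpson quadrature on a strictly increasing
  grid truncated at 10× the slowest correlation time (truncation error
  < 5×10⁻⁵ relative).
- Default test sizes: full default scan 181×11×2×2×2 ≈ 16k grid points
  (a few seconds), rotor validation 2×10⁶ steps (tens of seconds including
  JIT compilation), Monte-Carlo doublet recovery 200 draws.

## Limitations

- Single shared S² and τ_int for both spin pairs, no k-dependent order
  parameters, no extended model-free, correlation-time distributions or
  detector analyses: Q divides J(0) into "oriented" and "isotropic" area,
  nothing finer.
- The peptide plane is ideal and flat; CSA magnitudes and orientations are
  site-independent constants, while real carbonyl CSAs vary by residue.
- The symmetric-top picture is a sensitivity model, not a fit model:
  extracting D∥/D⊥ from measured Q profiles is out of scope.
- Auto-relaxation rates, dipole–dipole CCR between remote spins, and
  ¹³C′–¹³Cβ interference (a known experimental contaminant of the doublet
  method) are not modelled.
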