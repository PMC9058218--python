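# Methods

## Scope and model

`radscav` post-processes the thermochemical output of quantum-chemical
antioxidant studies. Its inputs are, per scavenger and solvent, a *mechanism
network*: the acid–base forms of the compound, and for every candidate
pathway the reaction free energy ΔrG (kJ mol⁻¹), optionally an activation
free energy ΔG‡, a reaction-path degeneracy σ, and flags/fields describing
barrierless channels, Eckart tunneling parameters and vertical
electron-transfer energies. Electronic structure itself (optimisations,
frequencies, IRC, spin densities) is out of scope; those quantities enter
only as numbers.

The pipeline is deterministic: validate → screen → rate → aggregate.

## Exergonicity screening

A single-step pathway enters kinetics iff ΔrG < 0, with a sharp boundary
(ΔrG = 0 rejects — mildly endergonic channels, even a few kJ mol⁻¹, are
excluded, consistent with how such tables are used in practice). Two-step
channels (SPLET, SET-PT) are retained only if *both* steps are exergonic;
rejections name the offending step. Pathways whose reactant is a downstream
radical rather than the scavenger itself are screened identically but tagged
`secondary`, so aggregation can include or exclude them by policy.

## TST with Eckart (ZCT-0) tunneling

Activated HAT/RAF channels use the Eyring expression at 1 M standard state,

    k = σ · κ · (k_B T / h) · exp(−ΔG‡ / RT),

assembled in log space (exact to the last ulp for barriers up to hundreds of
kJ mol⁻¹). ΔG‡ inputs are taken as already referenced to 1 M — tabulated
activation energies are conventionally paired directly with 1 M rate
constants — so no Δn correction is applied. Rate rows are *per unique
transition state*; σ multiplies only in aggregation, which makes k_overall
invariant under splitting a σ-fold degenerate pathway into σ unit copies.

ZCT-0 is read as zero-curvature tunneling through a one-dimensional
asymmetric Eckart barrier fitted to (V_f, V_r, ν‡). The transmission
probability uses the classic closed form with α_i = 2πV_i/(hν‡); the cosh
terms are evaluated in log space so stiff barriers (small hν‡, large V)
cannot overflow. κ is the Boltzmann average of P(E), integrated adaptively
(relative tolerance 10⁻⁶) from the higher asymptote to 20 RT above the
barrier top, plus the analytic classical tail beyond. κ ≥ 1 is enforced only
against quadrature noise (the integrand is bounded below by the classical
step). When ν‡ is absent the row is computed with κ = 1 and flagged
`TST_PLAIN`, so published-table comparisons never silently mix conventions.
Published reference tables typically print k but not ν‡ or κ; such k values
are therefore carried as `REFERENCE` rows and never recomputed.

## Marcus electron transfer and diffusion

Electron-transfer steps have no transition state; their barrier is the
Marcus quadratic ΔG‡ = (λ/4)(1 + ΔG/λ)², zero at ΔG = −λ and rising again
beyond it (inverted region). The reorganization energy is λ = ΔE_vert − ΔG,
an input derived from vertical/adiabatic energies (it cannot be recovered
uniquely from a printed k, and no inversion is attempted). The thermal rate
(k_BT/h)·exp(−ΔG‡/RT) is merged with the encounter rate k_D by the
Collins–Kimball harmonic combination k_app = k_D·k_act/(k_D + k_act), which
guarantees k_app ≤ min(k_act, k_D); a hard `min` clip is available behind a
flag for sensitivity checks.

Encounter rates use Smoluchowski theory with Stokes–Einstein diffusivities,
D = k_BT/(6πηa), k_D = 4π(a_A + a_B)(D_A + D_B)N_A, with default contact
radii of 2.0 Å and handbook viscosities (water 8.91×10⁻⁴, benzene
6.04×10⁻⁴ Pa s at 298.15 K). A per-solvent override exists because aqueous
HO•-scavenging work conventionally assigns 1.91×10⁹ M⁻¹ s⁻¹ to barrierless
channels; the water solvent object pins that value.

## Scan classification and spin crossings

A relaxed-scan profile (energy vs approach distance) is BARRIERLESS iff no
forward step rises by more than `noise_tol` and the global maximum sits at
the start (within the same tolerance); otherwise ACTIVATED with barrier
max(E) − E[start]. `noise_tol` defaults to 0.5 kJ mol⁻¹, a chemical-accuracy
noise floor for scan grids; the literature states no numerical criterion for
"continuous decrease", so this tolerance rule is a reconstruction. The
result is invariant to energy offsets and traversal direction. Barrierless
profiles feed the diffusion assignment; they never yield a TST row.

Spin crossings between two spin-state profiles are located on the union grid
of the overlapping range, refined by linear interpolation of the energy
difference; the crossing energy averages the two interpolants so the
operation is exactly symmetric in its arguments. With several sign changes
the crossing at the largest distance — the first met along the approach,
where spin inversion becomes possible — is returned.

## Speciation

Molar fractions by protons removed follow f_j ∝ 10^(j·pH − Σ_{i≤j} pKa_i),
accumulated in log space (scipy `logsumexp`) and renormalised exactly.
Microspecies (which hydroxyl deprotonates first) are not resolved.
`dominant_forms` keeps every form at or above a 5 % threshold — chosen as a
round midpoint of the range consistent with common practice of retaining
~20 % species while dropping ~2.5 % ones — and never returns empty.

## Aggregation

k_overall = Σ_f w_f Σ_i σ_i k_i over radical-consuming steps only (HAT, RAF,
SET, ET); proton-transfer steps consume hydroxide, not the scavenged
radical. w_f is the form's molar fraction when `weight_by_fraction` is true
(aqueous convention) and 1 otherwise (non-polar solvents host a single
neutral form — this degeneracy-weighted rule exactly reproduces reference
non-polar totals). Branching ratios are per unique site,
Γ_i = 100·w_f·k_i/k_overall, so Σ σ_iΓ_i = 100 and degenerate sites each
carry the per-site share. r^T = k_overall/k_ref. Both `PRIMARY_ONLY`
(secondary chemistry excluded) and `ALL_PATHWAYS` policies are exposed: for
the aqueous reference compounds no single obvious rule recovers the
published totals from the printed per-pathway constants, so the published
aqueous k_overall values are stored in the fixtures as pinned reference data
and both policies are reported rather than guessing one.

## Synthetic data

The generator emulates the *structure* of the study conditions, not their
quantum-chemical values. Defaults (kJ mol⁻¹): HAT ΔrG ~ N(−100, 30²); RAF
~ N(−30, 15²); first steps of the two-step channels ~ N(+300, 100²) in
non-polar solvents and N(+50, 80²) in water — reproducing the qualitative
pattern that electron-transfer channels are prohibitive in non-polar media
(< 1 % of synthetic channels survive screening there) but often viable in
water; second steps ~ N(−450, 50²); ΔG‡ for exergonic activated channels
from a truncated normal (mean 35, sd 15) on (0, 80]; 20 % of exergonic
channels barrierless; λ truncated-normal (mean 60, sd 15, > 0). These are
loose caricatures of typical phenolic-scavenger tables, documented as such
and not fitted. A ring template with n sites yields n adduct candidates and
⌈n/2⌉ H-abstraction candidates (hydroxyls on alternating positions); a σ
parameter groups sites into symmetry classes sharing one transition state.

Scan profiles use a sigmoidal descent into the product well; ACTIVATED adds
an interior Gaussian bump, and CROSSING_PAIR offsets a second surface
linearly in distance so exactly one crossing exists at a recorded
coordinate. Jitter is uniform and bounded (±`noise_sd`), so a stated noise
amplitude cannot manufacture a spurious barrier. All generation is seeded
through one `numpy` Generator per call; identical seeds give byte-identical
written files.

What passing tests on synthetic data do *not* show: real scan profiles have
correlated (not independent) noise, real ΔrG values correlate across sites
and mechanisms, and real two-step channels share intermediates across forms;
none of that structure is emulated.

## Numerical choices and problem sizes

- Quadrature: `scipy.integrate.quad`, relative tolerance 10⁻⁶, with the
  barrier top listed as a breakpoint; failure to converge raises rather than
  returning a silent value.
- Test-suite and acceptance problem sizes: 50 synthetic networks for
  parameter recovery, 100 seeded crossing pairs, a few hundred
  Hypothesis examples per property (derandomised) — sizes at which every
  statistical check is far from its decision boundary.
- Rounding for published-table comparison: computed rate constants are
  compared at three significant digits (relative tolerance 5×10⁻³, one unit
  in the last printed digit) because published totals derive from unrounded
  per-pathway values; branching ratios are compared to 0.1 percentage point.
- Report serialisation rounds k to 3 significant digits and Γ to 0.1 %,
  matching the conventional table formatting.

## Known limitations

- No variational TST, small-curvature tunneling, or partition-function
  evaluation from frequencies; κ is strictly one-dimensional Eckart.
- Marcus rates omit electronic-coupling prefactors and nonadiabatic
  corrections; λ must be supplied.
- Spin-crossing location is geometric only (no Landau–Zener probability,
  no true minimum-energy crossing point optimisation).
- pKa values are inputs; no prediction, no temperature dependence.
- Aqueous aggregation of secondary radical chemistry is policy-driven, not
  derived; see Aggregation above.
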