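# Methods

## Model

The chain is the minimal flexible weak polyelectrolyte: `n_sites`
identical protonatable sites placed every `spacing` bonds (default 3),
rigid bond length 0.2 nm and valence angle 120°, one rotatable bond per
inter-site segment with three rotational isomeric states (trans = 180°,
gauche± = ±60°; the states are 120° apart).  The remaining bonds are
frozen trans.  A chain with `spacing = 1` degenerates to the rigid rod
used as the reference case, with collinear sites separated by the bond
length `b`.

All energies are reduced and kept in decimal-log units throughout
(statistical weight = 10⁻ᶠ), so pK arithmetic is exact and the proton
chemical potential is simply pH − pK.  Temperature enters only through
the default Bjerrum length (0.7 nm, water at 298 K); there is no
explicit temperature parameter.

The reduced free energy of a roto-microstate (s, c) is additive:

* conformational: pσ = −log σ per gauche bond, plus ψ/ω couplings for
  consecutive gauche pairs (same/opposite orientation, following the
  standard RIS weight matrix; both are 1 in the minimal model);
* protonation: (pH − pK) per bound proton, plus ε_t or ε_g per adjacent
  protonated pair according to the state of the connecting rotatable
  bond (u_g = 0, i.e. ε_g → ∞, encodes a forbidden configuration and is
  represented as +∞ energy / zero weight rather than an excluded state,
  so enumeration and Monte Carlo share one energy function);
* long-range: the Debye–Hückel pair term φ(d) = (ℓ_B/d)e^(−κd)/ln 10
  summed over site pairs separated by **two or more** sites.  Adjacent
  sites interact exclusively through ε_t/ε_g — the LR sum starts at
  j ≥ i+2 in the solver, the Monte Carlo moves and the enumeration
  oracle alike, so nothing is double-counted.  κ⁻¹ [nm] = 0.304/√I.

### Geometry conventions

Coordinates are built by natural-extension (NeRF) placement with the
signed-dihedral convention checked by explicit tests (rotating a bond by
+120° changes its dihedral by +120°; g+ and g− are mirror images).  The
rotatable bond is the **middle** bond of each three-bond inter-site
segment, a symmetric choice; the repeat-unit assignment only affects
inter-site distances, not the short-range bookkeeping, and is validated
through the enumeration oracle.  The chain start is oriented by two
fictitious trans bonds, which makes every segment geometrically
identical; inter-site distances are independent of that choice.

## Exact short-range engine

Partition functions are ordered products of one repeated transfer
matrix: 2×2 for the rigid site-binding chain, 3×3 for the neutral RIS
chain, 6×6 super-matrices (ionization ⊗ conformation) for the combined
model, with the short-range diagonal block diag(u_t, u_g, u_g) scaling
the protonated–protonated block.  The first site's activity is absorbed
into the left boundary vector (q, z·q); this end convention is fixed by
requiring equality with brute-force enumeration on small chains, which
is a release-blocking test (≤ 4 sites, randomized parameters, relative
error ≤ 1e−10).

Numerics: every matrix product is accumulated with running
renormalization (per-checkpoint max-normalization with log scales), so
50-site chains remain finite at any pH.  Site- and bond-resolved
observables (θᵢ, per-bond gauche probabilities, ⟨sᵢs_j⟩, and the
second moments Var n, Cov(n,g), Var g needed for the solver Jacobian)
are exact projector insertions — one matrix of the product replaced by
its protonated- or gauche-selecting part.  Finite differences of ln Ξ
survive only as cross-checks in the tests.

Mean squared inter-site distances ⟨d_ij²⟩₀ under the full (s, c)
ensemble are computed by an exact dynamic program over the 6-state
chain: per state it carries the statistical weight, the local-frame
partial displacement vector and the partial squared norm, updated with
per-state rigid-body operators (rotation + displacement) extracted once
from the homogeneous segment geometry.  This is the protonation-
decorated analogue of the classical generator-matrix contraction; no
sampling enters the solver path.  The ⟨d_ij²⟩₀ average is taken over
the **full** unperturbed ensemble, not conditioned on both end sites
being protonated: the working approximation
φ₀ ≈ Σ φ(√⟨d_ij²⟩₀)·⟨sᵢs_j⟩₀ reads as independent averages.  The
protonation-conditioned variant is exposed as an option
(`conditioned=True`) for sensitivity checks; on small chains it shifts
⟨d²⟩ by a few percent in the transition region.

## The effective-parameter (LEIP) solver

Splitting the free energy as H = H₀(shifts) + ΔH with
H₀ the short-range model at pK − x and pσ + x_σ (rigid chains: ε + x_ε)
and ΔH/ln10 = Σ φᵢⱼ sᵢs_j − x Σ sᵢ − x_σ·(gauche count), the
Gibbs–Bogoliubov inequality Ω ≤ Ω̃ = Ω₀ + ⟨ΔH⟩₀ holds and Ω̃ is
minimized over the shifts.  Stationarity yields the 2×2 system
J·(x, x_σ)ᵀ = (∂φ₀/∂x, ∂φ₀/∂x_σ)ᵀ with J the exact Jacobian of
(ν₀, g₀) from fluctuation formulas — equivalently x = (∂φ₀/∂ν₀)|_g₀,
x_σ = (∂φ₀/∂g₀)|_ν₀: x is the mean LR cost of binding one more proton,
x_σ the mean LR cost of rotating one more bond into gauche.  Note the
sign convention: pK_eff = pK − x with x ≥ 0 for repulsive interactions,
which makes protonation harder, as it must.

Numerical choices:

* the φ₀ partial derivatives use central finite differences with step
  1e−4 log-units; the (ν₀, g₀) Jacobian is exact;
* the solver is a damped Newton iteration (step from the exact J, step
  halving on residual growth, step-norm cap 2 log-units), with a
  bracketed-bisection fallback on the x-component for cold starts deep
  in the saturated regime where Var(n) ≈ 0;
* convergence is declared at a residual below 1e−7·max(1, φ₀) — the
  relative scaling matters because φ₀ reaches O(10²) log-units on the
  50-site chain at low ionic strength and the FD noise floor on its
  gradient is then ≈ 1e−6; small systems converge to ≈ 1e−9;
* titration grids are solved by continuation from high pH (where the
  shifts vanish) downward, warm-starting each point from the previous
  one.  This keeps the solver on a single branch across the sharp
  spurious transition of the pK-only correction — that artifact is a
  published feature of the method and must be reproducible, not hidden.
  When θ(pH) comes out non-monotone the rows still record their own
  convergence diagnostics (residual, iteration count).

In rigid mode φ₀ is exact (Σ φ(|j−i|b)·h_ij⁰), so Ω̃ ≥ Ω is a theorem
and is asserted against 2ᴺ enumeration.  In flexible mode φ₀ carries
the √⟨d²⟩ approximation, so the inequality is no longer guaranteed
mathematically; the flexible solver is instead validated directly
against full-LR roto-microstate enumeration (3-site chain: θ and
gauche probabilities within 0.02) and against Monte Carlo.

Measured accuracy of the rigid pK-only correction against exact
enumeration (pK = 9, ε = 1.5, b = 0.2 nm, pH 3–12, I = 1…0.001 M):
maximum |Δθ| = 0.0087 at N = 14 and 0.0104 at N = 10, the worst point
sitting at the low-pH/intermediate-screening corner.

## Monte Carlo simulator

Semi-grand canonical Metropolis sampling with explicit coordinates.
Defaults are the full-scale protocol (5×10⁷ equilibration + 4.5×10⁸
production configurations, bond/site trial probabilities 0.999/0.001,
eight replicas); scaled-down runs pass smaller step counts explicitly.
Choices the protocol leaves open, fixed here: the initial state is
all-trans and fully deprotonated (the reproducible high-pH reference);
observables are sampled with a configurable stride (default 100 steps);
replica seeds are base seed + replica index and are written to the run
log.  A bond move rotates all downstream nodes rigidly about the bond
axis (Rodrigues rotation) and re-sums only the before×after cross
pairs of the LR energy; a site toggle re-sums only that site's pairs.
Acceptance uses 10^(−ΔF) with energies clamped at 10³ log-units, so
forbidden moves (u_g = 0) underflow to acceptance probability exactly 0.
There is no excluded volume: overlapping nodes carry no penalty.
Kernels are numba-compiled; the incremental ΔF is tested against
from-scratch total-energy recomputation to 1e−9, and geometry integrity
(bond lengths, rebuild-consistency of coordinates) is asserted along
trajectories.

## What the tests do and do not show

All validation inputs are generated by the package itself (the chain
builder, the enumeration oracle, the MC simulator); there are no
external datasets.  The minimal model isolates the coupling mechanism —
identical sites, one rotatable bond type, ψ = ω = 1, Debye–Hückel
screening, no excluded volume — so agreement between LEIP, enumeration
and MC demonstrates the correctness of the statistical mechanics and
the quality of the variational approximation *for this model class*.
It does not establish accuracy for heterogeneous sites, polyampholytes,
excluded-volume chains or specific polymers, which are outside the
scope of the package.

Problem sizes used by the shipped tests and the acceptance script were
chosen to keep everything desk-scale: enumeration cross-checks run at
≤ 4 sites (SBRIS) / ≤ 14 sites (rigid), MC validation at 20 sites with
2×10⁶-step replicas, and the 50-site LEIP curves on pH grids of step
0.05–0.1.  The MC comparison tolerances are three cross-replica
standard errors plus a 0.01 allowance for the LEIP method error at
I = 1 M.

## Known limitations

* Triplet and higher cluster terms are carried at type level only and
  fixed to zero; no next-nearest-neighbour effective corrections.
* φ₀ uses the second distance moment only; higher moments of d_ij would
  refine the flexible-mode average.
* Heterogeneous per-site pKs, polyampholytes and branched chains are
  not supported; one rotatable bond type per repeat unit.
* The MC simulator is a validator, not a production sampler: single-bond
  moves only, no reaction-ensemble variant, no explicit ions.
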