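# Methods

This note documents the models, estimators, numerical choices and known
limitations of poreflux. Units are kcal·mol⁻¹, Å, ps and kelvin throughout;
kB = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and the default temperature is 303.15 K
(kBT ≈ 0.6024 kcal·mol⁻¹).

## Ground-truth potentials

Free-energy estimators can only be validated against data whose answer is
known. The `potentials` module therefore defines analytic potentials of mean
force as sums of Gaussian features, U(z) = Σ hᵢ exp(−(z−cᵢ)²/2wᵢ²), with an
optional harmonic radial term ½κb² in 2D mode. Widths are chosen so every
shipped fixture is below 10⁻³ kcal·mol⁻¹ for |z| ≥ 24 Å: "free energy
relative to bulk solvent" then holds by construction and the anchoring step
(below) removes nothing but the gauge constant.

Shipped fixtures: `flat`; single barriers of height {1, 3.5, 3.8, 7.6} at
z = −6 (width 2.5 Å) — heights spanning the range of barriers relevant to
small-molecule pore passage — and `three_well`, whose summed terms place
minima at z ≈ −12, −5 and +6 Å with two interior barriers, the qualitative
layout of a pore with a convex-side binding site, a constriction site and a
concave-side site. The fixtures echo that layout only; they are not claimed
to equal any published profile.

## Brownian-dynamics generator

Full molecular dynamics is out of scope; for testing the estimators only the
statistics of the collective variables matter. Windows are therefore sampled
with overdamped Langevin (Euler–Maruyama) dynamics,

    x ← x + (D/kBT)·F(x)·dt + √(2·D·dt)·ξ,  ξ ~ N(0,1),

on U_total = U_pmf + ½k(z−z₀)² + flat-bottom cylinder walls (zero inside
z ∈ [−28, 28], b ≤ 15; harmonic with wall stiffness 10 kcal·mol⁻¹·Å⁻²
outside). Defaults: D = 0.2 Å²·ps⁻¹, dt = 0.02 ps, 2×10⁴ steps and stride 2
per window (10⁴ retained samples). With k = 5 the z relaxation time is
kBT/(Dk) ≈ 0.6 ps ≈ 30 steps, far below the window length, and the
first-order discretization bias of the stationary variance
(factor 2/(2−θ), θ = Dk·dt/kBT ≈ 0.033) is ~1.7%, far below the statistical
errors at this scale. A single step moving |Δz| > 5 Å aborts with advice to
reduce dt.

The radial coordinate b is a distance from an axis, whose equilibrium
density carries the entropic measure ∝ b. Rather than integrating b in one
dimension with the singular Jacobian drift +D/b·dt (which is numerically
unstable near the axis under an Euler scheme), b is propagated as two
Cartesian components (bₓ, b_y) with the radial force applied along the
radial unit vector; b = √(bₓ²+b_y²) then has exactly the ∝ b measure with no
singular term. Walkers start at the window center with b drawn uniformly in
[0, b_max/2]; analyses sensitive to the radial distribution should discard
an initial equilibration span, as the shipped tests do.

Randomness: numpy's PCG64, seeded explicitly. Window i of a dataset uses
master_seed + i, and the batched integrator draws per-walker streams exactly
as a per-window run would, so batch and single-window execution are
bit-identical. Free "ions" are unbiased walkers (umbrella term absent,
cylinder kept), each an independent simulation; the number of ions is an
input parameter, since it derives from a box-to-cylinder volume ratio that
is not reconstructable here.

The synthetic hexamer-pore ensemble plants a known effect for the
contact-conditioned diameter analysis: three six-fold rings of
single-heavy-atom pseudo-residues (Arg11 at z = −10, the Ser39 constriction
at z = 0, Lys36 at z = +5), ring radius breathing as N(3.0, 0.6) Å around
defaults chosen to give constriction diameters spanning roughly 1–6 Å, and a
metabolite particle that in a chosen fraction of frames (default 0.3) sits
2.6–3.4 Å from the designated residue — placed radially outside the ring so
it never itself narrows the pore — while the constriction diameter is
shifted by `contact_dilation`. The generator records per-frame true
diameters and contacts. What this emulates, and what it does not: frames are
exchangeable (no autocorrelation in time), residues are single spheres (no
side-chain rotamers, no hydrogens, so contact detection exercises its
distance-only fallback), and the dilation is planted directly rather than
arising from mechanics. Passing tests therefore demonstrate that the
measurement and statistics recover a known conformational coupling — not
that any real protein behaves this way.

## WHAM

Histogram bins default to 0.5 Å over [−26, 26], matching the window spacing.
The self-consistent equations for unbiased bin probabilities and window free
energies are iterated until max|Δfᵢ| < tol·kBT with tol = 10⁻⁷ (tighter than
any statistical error at shipped scales; max_iter 10⁵, exceeded → error with
residual). Preconditions checked: one temperature across windows, and every
adjacent window pair sharing at least one occupied bin (violations name the
gap's location). Empty bins are masked NaN, never ±∞. Profiles are shifted
so the mean of G over occupied bins with |z| ∈ [24, 25] is zero; datasets
that never reach bulk (toys) fall back to the occupied-bin mean, recorded in
the profile's `anchor` field. The umbrella convention is fixed to
½k(z−z₀)² in both generator and estimators; only this consistency matters to
correctness.

The 2D variant bins (z, b) jointly (the bias depends on z only). With
`jacobian_correct` the reported surface is −kBT·ln(p/b_center), removing the
distance-from-axis measure so a flat landscape is flat in b; without it, G
falls as −kBT·ln b. Both variants are exposed because published 2D surfaces
do not always state which convention was used.

## DHAM

Transition counts between bins at lag 1 sample interval are collected per
window and combined into one unbiased Markov matrix,
M_jk = Σᵢ cⁱ_jk / Σᵢ nⁱ_j exp(−(w_ik − w_ij)/2kBT) — the symmetric
square-root unbiasing — then row-normalized; G = −kBT·ln π from the
stationary eigenvector. Unvisited bins are removed from the chain (masked in
the output); a disconnected transition graph raises a connectivity error.
The bias-factor exponent is clipped at ±700 to avoid overflow for bin pairs
that no transition ever links.

## Errors and diagnostics

Standard errors follow the 5-segment convention: each window's series is cut
into n_blocks (default 5) equal contiguous segments, the estimator runs per
segment, and per-bin mean ± SEM across segments is reported (bins not
occupied in every segment are masked). The integrated autocorrelation time
uses the initial-positive-sequence rule, τ = Δt·(1 + 2Σ acf(k)) summed to
the first negative ACF value, floored at one sampling interval; for an AR(1)
process this reproduces (1+φ)/(1−φ) intervals.

Unbiased densities (free ions) become G = −kBT·ln(density) with the same
anchoring; an optional per-sample weight vector supports importance-sampled
input, which is how high barriers (unreachable by direct sampling) are
validated.

Extremum readout: local extrema after an optional 3-bin moving-average
smoothing (reported G values are unsmoothed); an extremum falling exactly
between two equal bins is assigned to the first. Each maximum reports both G
relative to bulk and ΔG‡ above the lower adjacent minimum (bulk zero if
there is none). Rate ratios take ΔG‡ values as explicit inputs,
k_a/k_b = exp(−ΔΔG‡/kBT), under the stated constant-prefactor assumption; no
Kramers prefactor is estimated.

## Pore geometry

PDB input goes through biotite (fixed-width records pre-validated so
malformed lines fail with their line number); only blank/'A' altlocs are
kept. Van der Waals radii come from a bundled element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80 Å; unknown elements get 1.70) — any
constriction diameter quoted from this code should state that radius set,
since different sets shift diameters by ~0.1–0.3 Å.

The pore-radius profile finds, per z-slice, the center (x, y) maximizing
r = minᵢ(|pᵢ−(x,y,z)| − vdwᵢ) over atoms within a ±6 Å slab, by evaluating
an n_starts×n_starts grid over ±2 Å (default 5×5) and refining the best
three starts with Nelder–Mead — a deterministic multi-start scheme in place
of the original tool's simulated annealing, with correctness defined against
a dense-grid oracle (agreement within 0.05 Å on randomized ring fixtures).
Radii are clamped at a 10 Å escape cap and undefined (NaN) where the slab is
empty; the minimum constriction reports the smallest diameter, ties broken
toward z = 0. Frames are analyzed independently.

Superposition is closed-form least squares (Kabsch with determinant
correction); RMSF is √⟨|r−⟨r⟩|²⟩ per atom after an optional initial-fraction
discard, averaged per residue and per chain. The pore-entrance hexagon area
fits a least-squares plane, orders the six vertices by polar angle, and sums
the six centroid-fan triangle areas — for planar convex hexagons identical
to any triangulation, and for near-planar input independent of vertex input
order.

Contacts: heavy-atom pairs across the metabolite/residue selections within
3.5 Å; when the frame contains hydrogens, a hydrogen covalently bound
(≤1.25 Å) to either partner must make a D–H…A angle within 30° of linearity.
Frames with no hydrogens at all (e.g. coarse probes such as O₂/CO₂
represented without explicit H) fall back to the distance criterion and are
flagged `distance_only` — the angle criterion is undefined for such species
and the flag makes the fallback auditable.

## Statistics

The contact/no-contact diameter comparison uses the two-sided Wilcoxon
rank-sum test with midranks: exact by enumeration when n_x+n_y ≤ 12 with no
ties, otherwise a tie-corrected normal approximation with continuity
correction (two-sided because the comparison is non-directional). Rows where
either category is empty are flagged insufficient and get no p-value. Raw
p-values are reported per pair; a Benjamini–Hochberg option exists but is
off by default. Violin summaries use a Gaussian KDE with Silverman's
bandwidth on a grid extending 4 bandwidths past the data; constant samples
are returned as flagged degenerate spikes.

## Pipeline

`run_pipeline` executes stages in dependency order inside a run directory,
logging per-stage timing to stderr and writing a manifest with the full
configuration echo, package version and SHA-256 checksums of every output;
identical configuration and seed reproduce identical files. Defaults follow
the study conditions above (105 windows, k = 5, b_max = 15, T = 303.15 K,
5 blocks, 2500-frame ensembles, 3.5 Å/30°); the default run simulates 10⁴
samples per window and geometrically re-measures a 250-frame equidistant
subset of the pore ensemble, sizes chosen to keep a full run in the
tens-of-seconds range on one CPU while leaving every recovery check
well-powered. Seeds are mandatory — there is no wall-clock seeding.

## Known limitations

* The generator's Euler–Maruyama scheme has O(dt) stationary-distribution
  bias; the shipped dt keeps it ~1.7% of kBT-scale quantities, visible only
  to tests far more sensitive than the estimators' statistical errors (the
  stationarity test uses a smaller dt for exactly this reason).
* DHAM is implemented in 1D only; 2D surfaces come from the 2D WHAM.
* Block errors with 5 segments are themselves noisy (χ²₄-distributed); they
  calibrate recovery bands, not precise confidence intervals.
* The contact model treats any hydrogen bound to either heavy atom as a
  candidate donor; tautomer- or charge-state-specific donor/acceptor typing
  is out of scope.
* Selections are simple and-joined clauses (chain/resname/resnum/name/
  element, negatable) — not a full selection language.
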