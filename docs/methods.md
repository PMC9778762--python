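# Methods

## The mechanical model

The molecule is a chain of n base pairs; each base is a disk rotating about
the sugar-phosphate backbone of its strand.  State variables are the 2n
angular deflections φ₁ᵢ, φ₂ᵢ and their velocities.  Equilibrium is
φ₁ᵢ = 0, φ₂ᵢ = π (bases facing each other), and every simulation starts
there at rest with all bonds intact.

Torques on base i of chain j:

* **Backbone**: K<sub>ji</sub>(φ<sub>j,i−1</sub> − 2φ<sub>ji</sub> + φ<sub>j,i+1</sub>),
  one-sided for i = 1 and i = n.  The torsion constant is per base; for a
  uniform chain this is exactly the gradient of the link energy
  ½K(φ<sub>i+1</sub> − φ<sub>i</sub>)².
* **Pair coupling**: −∂V<sub>i</sub>/∂φ<sub>ji</sub> with

  V<sub>i</sub> = k₁₂ᵢ [R₁(R₁+R₂)(1−cos φ₁ᵢ) + R₂(R₁+R₂)(1+cos φ₂ᵢ) + R₁R₂(1+cos(φ₁ᵢ−φ₂ᵢ))]

  Every bracketed term is non-negative, so V ≥ 0 globally with V = 0 only
  at equilibrium, and the linearised stiffness matrix
  k₁₂·[[R₁(R₁+2R₂), −R₁R₂], [−R₁R₂, R₂(2R₁+R₂)]] is positive definite
  (det = 2k₁₂²R₁R₂(R₁+R₂)²).  Published torque expressions for this family
  of models are typographically inconsistent between the two chains; we
  therefore *define* the dynamics through this single potential, which
  reproduces the conventional chain-1 torque exactly and guarantees a
  conservative, stable system — a property the test suite verifies by
  finite differences and by energy conservation, whereas a typographic
  reading cannot be verified at all.
* **Damping**: −β<sub>ji</sub> dφ/dt, modelling the aqueous environment.
* **Forcing**: F₀cos(ωt), a deterministic external torque applied to every
  base (no thermal noise).

## Bond automaton

Pair i carries a flag δᵢ ∈ {0, 1}.  After every integration step the
binding energy V<sub>i</sub> — always evaluated with the full stiffness,
also for broken pairs, since restoration must be testable — is compared
with the pair's critical energy: V > E<sub>cr</sub> breaks the bond,
V < E<sub>cr</sub> restores it, exact equality leaves the flag unchanged
(the rules are strict inequalities).  δᵢ = 0 removes the coupling torque
from the equations of motion and nothing else.

A single deuterium substitution at pair i scales that pair's k₁₂ and
E<sub>cr</sub> by k_D = 1.05 (a deuterium bond is 5 % stronger), regardless
of whether the pair has two (A-T) or three (G-C) hydrogen bonds — the
substitution rule is per pair, not per bond.  k_D = 1 is an exact identity:
the trajectory is bitwise equal to the baseline.

## Integration

Classical fixed-step RK4 on all 4n variables, with δ frozen within a step
and the automaton applied once after each full step.  The step guard
dt ≤ 0.05/ω_char, ω_char = maxᵢ √((K + k₁₂R(R+R'))/I), keeps the fastest
oscillation well resolved; the default dt = 10⁻¹⁴ s satisfies it for the
default coefficients.  The integrator is deterministic; non-finite states
abort with the offending step and pair.  Diagnostics: with β = 0, F₀ = 0
and no break events the total energy (kinetic + backbone link energy +
intact pair potential) drifts by less than 10⁻⁶ relative over 10⁴ steps,
and small-amplitude oscillations of a single pair match the analytic 2×2
generalized-eigenvalue frequencies to better than 1 %.

## Probabilities and sampling

States are sampled at t<sub>j</sub> = jT/m (t = 0 excluded).  q<sub>j</sub>
is the fraction of broken pairs at t<sub>j</sub>; the open-state
probability is their arithmetic mean.  m defaults to 1000 — the estimator's
resolution is 1/(m·n), and a site is a closed state (CSNB) iff no break was
sampled at any of the m times, making "P = 0" exact in floating point (a
mean of non-negative terms is zero iff all are zero), so no zero tolerance
is needed.  A substitution scan runs 1 + n independent simulations per
critical energy; each is re-simulated in full because break events feed
back on the motion through the coupling gate, so re-thresholding one
trajectory would be wrong.

## Site classification (modified Basov–Jimack algorithm)

At each critical energy, with Pimax = max P<sub>i</sub>, Pimin = min
P<sub>i</sub>, and provided Pimax > P₀ ≥ Pimin ≥ 0:

* branch 1, if Pimax − (1/10)(Pimax − Pimin) ≥ P₀ + (1/2)(Pimax − P₀):
  threshold Pimax − (1/10)(Pimax − Pimin);
* branch 2 otherwise: threshold Pimax − (1/4)(Pimax − P₀);
* membership is P<sub>i</sub> ≥ threshold; if Pimax ≤ P₀ or P₀ < Pimin the
  range "Maximum" is empty (saturated energies legitimately produce
  n_max = 0 rows).

CSNB sites (P<sub>i</sub> = 0) are counted per gene part and pair class.
The new-approach weighting n_x·(1 − n_gCSNB/n_g)² multiplies a part's raw
count by the squared fraction of the gene still open, discounting closed
states that appear only because the whole molecule is saturating.  Reported
sums truncate each weighted part total toward zero before summing (the
convention that reproduces the reference sums 105 and 51); the continuous
values are retained because the rank correlations are computed on them.
Class-restricted weighted counts (e.g. G-C only) keep the *whole-gene*
count in the damping factor.  The Q₂–Q₄ minimum rule
(P<sub>i</sub> ≤ Pimin + (3/4)(P₀ − Pimin)) is implemented as a separate
operation for the sub-saturation regime but is not part of the default
classification, where P₀ = 0 makes it coincide with the CSNB rule.

## Statistics

Yates-corrected χ² for 2×2 tables uses
N(|ad − bc| − N/2)²/(N_A N_B N_S N_F) with the continuity correction
clamped at zero; Pearson χ² for r×2 grids reports p·k (capped at 1) for a
caller-chosen Bonferroni family size k; Kruskal–Wallis uses pooled mean
ranks with the tie correction and defines H = 0 when all observations are
equal.  Two Spearman variants are exposed because both conventions occur in
practice: the d² formula with mean ranks, and the Pearson correlation of
mean ranks (exact under heavy ties; the two agree exactly on tie-free
data).  Spearman p-values use the t approximation with n − 2 degrees of
freedom; exact permutation tests are out of scope.

## Synthetic genes and the packaged tables

The generator produces a gene from per-part lengths and A-T contents
(fractions round half away from zero to pair counts: 72.2 % of 327 → 236);
positions and strand orientation (A-T vs T-A) are drawn from a seeded PCG64
stream, so identical specifications reproduce identical sequences.  The
packaged composition preset (327/326/327 pairs with 163/186/236 A-T) mirrors
the three-part structure and base composition of the 980-bp interferon
alpha 17 gene studied in this line of work; it does **not** reproduce that
gene's actual base order, which is not shipped.  Consequently the synthetic
data reproduce composition-driven effects but not sequence-position
effects, and passing simulation tests demonstrate the machinery's
correctness, not agreement with any specific gene's absolute counts.

The three packaged CSV tables are verbatim transcriptions of published
per-part counts and probability columns, kept as evidence including their
known internal inconsistencies (the part-II unweighted column sums to 1365
while 1371 was printed alongside it; one printed single-energy ratio, 1.42,
is not recoverable from the table, while its sibling 1.69 is).  Derived
statistics pinned in the tests are only those consistent with the tables
themselves.

## Default parameters

| quantity | default | unit | note |
|---|---|---|---|
| inertia I (A/T/G/C) | 7.61/4.86/8.22/4.11 ×10⁻⁴⁴ | kg·m² | literature-typical |
| radius R (A/T/G/C) | 5.8/4.8/5.7/4.7 ×10⁻¹⁰ | m | literature-typical |
| torsion K | 6.0×10⁻¹⁹ | N·m | uniform default |
| k₁₂ (A-T / G-C pair) | 0.055 / 0.085 | N/m | G-C stiffer (3 H-bonds) |
| β | 7.0×10⁻³⁴ | J·s | damping time ≈ 10⁻¹⁰ s; calibration knob |
| F₀ | 0.526×10⁻²² | N·m | forcing amplitude |
| ω | 0.4×10¹² | s⁻¹ | forcing frequency |
| k_D | 1.05 | — | deuterium bond 5 % stronger |
| dt | 10⁻¹⁴ | s | under the 0.05/ω_char guard |
| m | 1000 | — | sampling count |

The per-base coefficient set is a placeholder of realistic magnitude, not
an authoritative table — quantitative studies must supply their own via the
`mechanics:` config section.  Critical energies are quoted in 10⁻²² N·m
user-facing and stored in joules internally.

## Problem sizes used in the shipped studies

The test suite's end-to-end study uses a 60-pair synthetic gene (three
20-pair parts at 49.8/57.1/72.2 % A-T), a full 60-site scan at three
critical energies bracketing the reachable binding-energy range, m = 500
samples over T = 3×10⁻¹¹ s at dt = 10⁻¹⁴ s — small enough to iterate on
while exercising every stage at full fidelity.  The critical-energy
bracket is derived from a baseline probe run (maximum binding energy of an
unbreakable trajectory), which guarantees a regime with openings and a
regime provably without any.

## Known limitations

* No helical/3D geometry, stacking beyond per-base coefficients, thermal
  noise, or DNA-protein interactions; forcing is deterministic.
* The substituted pair's strengthening is uniform in k₁₂ and E_cr; no
  per-hydrogen-bond resolution.
* With the default placeholder coefficients the substitution effect on P
  is small and mostly negative (strengthening a bond reduces its opening);
  reproducing published absolute counts would require the original
  sequence and coefficient table.
* β is not experimentally constrained here; it sets the transient decay
  and should be treated as a calibration parameter.
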