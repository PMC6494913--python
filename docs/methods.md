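# Methods

This note documents the models implemented in `premix`, the assumptions they
make, the synthetic study conditions used to validate them, and the numerical
choices that were genuinely open.

## 1. From peak intensities to PRE rates

The PRE contribution Γ₂ to a methyl group's transverse relaxation is measured
as differential line broadening between the paramagnetic and diamagnetic
states of a nitroxide-labeled sample. For an HMQC readout,

    I_para / I_dia = exp(−Γ₂ t_HMQC) · R₂ᵈⁱᵃᴴ R₂ᵈⁱᵃᴴᶜ / [(R₂ᵈⁱᵃᴴ + Γ₂)(R₂ᵈⁱᵃᴴᶜ + Γ₂)]

where R₂ᵈⁱᵃᴴ and R₂ᵈⁱᵃᴴᶜ are the diamagnetic ¹H single-quantum and ¹H–¹³C
multiple-quantum rates of that methyl and t_HMQC (default 6.9 ms) is the
transfer time. The right-hand side is strictly decreasing in Γ₂, so the
observed ratio is inverted by Brent root finding (relative tolerance 1e−9,
bracket grown geometrically).

Edge cases, which the equation itself does not define:

* ratio ≥ 1 (apparent negative PRE, a noise artifact): Γ₂ = 0, flagged
  `nonpositive`; kept for plotting, excluded from fitting.
* ratio ≤ 0, or I_para below 3 σ_para (broadened beyond detection): Γ₂ is a
  lower bound, reported at a configurable cap (default 80 s⁻¹), flagged
  `unresolved` and excluded from Q-factor sums. Both the 3 σ floor and the
  cap are parameters of `invert_eq1`.

Uncertainties are propagated to first order: σ_ratio by the quotient rule
from the two spectral noise levels, then Γ₂ error bars by re-inverting at
ratio ± σ_ratio (asymmetry is symmetrized; when ratio − σ crosses zero the
upper excursion is mirrored).

Relative intensities I_with/I_free use the same quotient-rule errors; the
0.80 level is kept as the conventional coloring threshold for significant
broadening. Combined methyl chemical-shift distances use
Δδ = [(Δδ_H)² + (Δδ_C/5.9)²]^½. Significant PREs are classified by strict
inequality Γ₂ > 5 s⁻¹ ("over" a threshold is strict; both threshold and
comparison site are configurable).

## 2. Forward PRE model

Γ₂ is back-calculated from coordinates with the Solomon–Bloembergen
point-dipole form with a single effective correlation time,

    Γ₂(r) = K · r⁻⁶,
    K = (1/15)(μ₀/4π)² γ_H² g² μ_B² S(S+1) · [4τ_c + 3τ_c/(1 + ω_H²τ_c²)],

S = 1/2 for a nitroxide, CODATA constants, r in Å. Assumptions: pure dipolar
relaxation, isotropic effective τ_c, no order-parameter scaling for internal
label motion, and a static-limit treatment of label flexibility — r⁻⁶ is
averaged *unweighted* over the label's conformer ensemble (default five
conformer positions per site). Contributions from the symmetric subunit
copies of a site are summed, since relaxation rates add over independent
paramagnetic centers. The methyl probe position is a single representative
¹H coordinate (centroid of the methyl protons where available, else the
carbon position; the sub-Å difference is far below the conformer spread).

τ_c and the field are configuration parameters (`PREModelParams`; defaults
50 ns / 600 MHz, the order of magnitude of a ~400 kDa complex at the fields
used for methyl-TROSY work).

## 3. Candidate pool generation

**Linker randomization.** The mobile unit (C-terminal helix plus the docked
partner) hangs off a short flexible backbone stretch. φ/ψ pairs of the linker
residues are drawn uniformly in (−180°, 180°] (no Ramachandran bias — the
distribution of the *pool* is not a prior, it only has to cover the
orientations the reweighting chooses from); the backbone is rebuilt by
forward kinematics with idealized geometry (trans ω), and the mobile unit is
carried rigidly by the frame of the last linker residue. Conformations whose
mobile unit approaches the fixed body within 2.5 Å (heavy-atom) are
discarded; an optional membrane half-space exclusion exists but is off by
default, matching the practice of filtering membrane-incompatible
orientations at interpretation time. Only the engaged subunit's linker is
randomized; the other subunits stay at base geometry.

**Rigid-body docking.** The docking stage minimizes
E = w_PRE·Σᵢ(Γ₂ᵒᵇˢ − Γ₂ᶜᵃˡᶜ)² + soft-sphere repulsion + a label-exclusion
term (which keeps the partner off the spin-label conformers, replacing an
explicit label-displacement restraint stage). Search is Cartesian Metropolis
simulated annealing over the 6-DOF pose rather than torsion-angle dynamics:
same restraint physics, desk-scale. Because r⁻⁶ restraints produce narrow
basins, each annealing run (i) screens a set of restraint-informed start
poses — the probe with the strongest observed PRE is placed at its implied
distance r = (K/Γ₂)^{1/6} from a copy of its site, facing it, with random
approach direction and spin — (ii) polishes the best start by derivative-free
Powell minimization, (iii) anneals (geometric cooling, shrinking move
amplitudes), and (iv) polishes again. Poses are returned sorted by energy;
rank 1 is the selected structure. Everything is deterministic given the
seed.

## 4. Ensemble reweighting

Population weights p_k ≥ 0 minimize

    Q_ens = sqrt( Σᵢ (Γ₂ᵒᵇˢ(i) − Σₖ p_k Γ₂ᶜᵃˡᶜ,ᵏ(i))² / Σᵢ Γ₂ᵒᵇˢ(i)² )

over the observables with usable rates (flag `ok`). Weights are *not*
constrained to sum to one: the observed rates are transferred PREs scaled by
the unknown bound fraction, so the overall scale belongs in the weights;
they are renormalized only for visualization.

The stepwise funnel: (1) disjoint random groups of 100 members are optimized
independently; (2) ten groups at a time are merged and re-optimized starting
from 1/10 of the previous weights; (3) the top 10 % of members by weight
survive each super-group; (4) the survivors (up to 1000) are jointly
optimized from damped weights. Group sizes, merge factor, survivor fraction
and damping are `FitConfig` parameters with those defaults.

Each group optimization runs a short simulated-annealing stage over latent
variables q (p = q² enforces nonnegativity; single-coordinate Gaussian
moves, incremental residual updates, geometric cooling) followed by a
quasi-Newton polish (L-BFGS-B with analytic gradient; member fingerprints
are scaled to unit norm first, because their raw norms span orders of
magnitude and cripple the conditioning), and finally an active-set
refinement (Lawson–Hanson-type restricted least squares with removal of
negative members and admission by residual correlation). The refinement is
needed because the constrained optimum sits at a vertex of the feasible
region that gradient methods approach only asymptotically: without it the
noiseless fit stalls around Q ≈ 1e−3; with it, Q reaches ~1e−11 and the
recovered weights are exact. Ties in top-fraction selection break by member
index; group partitions are disjoint (maximizing pool coverage).

**Noise and support selection.** With noisy data the unconstrained optimum
*overfits*: Q drops below the noise floor while population spreads onto
decoy members that merely absorb noise. When Γ₂ uncertainties are available
the fit therefore adds: (5) re-estimation of the final member set with an L1
(total-population) penalty λ = 2·median(σ_Γ)·median‖Γ₂ᶜᵃˡᶜ,ᵏ‖ and an
unpenalized refit on the selected support; and, on top, *stability
selection* — the whole funnel is repeated with three independent random
partitions and only members selected in every replicate keep weight, refit
unpenalized. Noise-fitting decoys differ between partitions; genuinely
required members persist. The reported Q_ens is always the unpenalized
Eq.-above value of the returned weights; `q_ls` (the stage-4 optimum, the
quantity the plain stepwise minimization produces) is kept in the
provenance and used when comparing fits across pool sizes, because the
support-selected Q is deliberately biased toward the noise floor and its
value tracks decoy density rather than ensemble adequacy.

The best-single-structure fit allows one free nonnegative scale per
candidate (closed form, clipped at zero) and reports the argmin — the
quantitative "one structure is not enough" diagnostic.

## 5. Density maps

Each heavy atom of member k deposits the member's (ensemble-renormalized)
weight through an isotropic Gaussian kernel; maps from several independently
fitted ensembles are averaged. Kernel width σ equals the voxel size (2 Å
default) — no physical kernel is implied by the observable, this choice
gives visually continuous envelopes at typical rendering scales. Two
normalizations are emitted: unit-max (map maximum = 1; the ρ = 0.05 contour
refers to this convention) and unit-integral. By default the kernel sum is
exact (every atom contributes to every voxel), which is what the map tests
verify; a truncation radius (in σ) is available for large grids and
introduces relative errors below ~1e−3 at 6σ. Only heavy atoms contribute.
Output formats: CCP4/MRC (via gemmi) and OpenDX text, plus the fixed-frame
PDB for overlay.

## 6. Synthetic study conditions

The toy complex emulates the experimental geometry: a four-fold symmetric
receptor core (exact 90° copies), two label sites on each subunit's core and
one on each subunit's C-terminal helix (site names Q344C/V351C/L366C follow
the experimental attachment points), a six-residue flexible linker on one
subunit, and a rigidly attached ligand carrying 60 methyl probes within a
~13.5 Å radius. Intensities are simulated through the forward chain —
ensemble-averaged Γ₂ from the planted members, the ratio equation, then
Gaussian noise with σ = I_dia/snr added independently to both intensities —
so the inversion's nonlinearity is exercised exactly where measurement noise
enters in reality. Diamagnetic rates are drawn once per methyl (20–50 and
30–70 s⁻¹; typical methyl-TROSY magnitudes for very large complexes).

Choices made so that population recovery is a well-posed question (all fixed
in the generator defaults, with the reasoning here):

* **Effective τ_c = 4 ns for the toy.** PREs are informative about pose only
  where Γ₂ varies sharply across the pool. With long-range smooth restraints
  the positive cone of thousands of decoy fingerprints contains the true
  ensemble signal almost exactly, and no estimator can recover the planted
  weights under noise. A short τ_c places *measurable* contacts (Γ₂ of tens
  of s⁻¹ at the detection limit) in the 8–15 Å near field, where footprints
  are sharp. The analysis back-calculates with the same parameters, as it
  must in any synthetic-recovery study.
* **Per-member contribution window.** Each planted member's peak ensemble
  contribution w_k·max Γ₂ must fall in 20–45 s⁻¹: large enough to stand far
  above the propagated Γ₂ noise (~0.5–1 s⁻¹ at snr = 50), small enough that
  its key peaks are not broadened beyond detection (which would delete
  exactly the observables that identify the member).
* **Mutual distinctness of planted members** (centroids ≥ 15 Å apart,
  fingerprint cosine ≤ 0.5): a member whose footprint duplicates another's
  carries no separable population information.
* **Decoy floors.** Decoys come from the same linker sampler the analysis
  uses (realistic degeneracy), but a decoy is rejected if its fingerprint is
  within 0.15 relative distance of a planted member's (a near-duplicate
  would merely split the weight) or points within cosine 0.8 of one (a
  same-direction decoy is an equivalent substitute at a rescaled
  population — the loophole that distance floors alone cannot close).

The docking validation uses a separate two-body toy (single subunit, one
copy of each site, τ_c = 50 ns, true pose at a standoff giving balanced
~2–120 s⁻¹ restraints from all three sites): it emulates the *docking* stage
of the analysis, where PREs act as long-range distance restraints and the
pose is triangulated by three non-collinear sites.

What passing these tests does and does not show: the generator reproduces
the statistical structure the analysis assumes (intensity-level noise,
r⁻⁶ physics, conformer-averaged labels, symmetric copies, clash-filtered
pose pools) but not the full messiness of real data — imperfect diamagnetic
references, anisotropic tumbling, label order parameters, assignment errors,
exchange contributions to line broadening, or model error in τ_c. Recovery
of planted weights therefore validates the *machinery*, not the uniqueness
of any experimentally fitted ensemble; on real data the fitted weights
should be read through the density map, not member by member.

## 7. Problem sizes and determinism

The validation suite uses pools of 10,000 members (30,000 for the
enlargement check) with 3 sites × 60 probes, five random seeds, and both
noiseless and snr = 50 conditions; the acceptance script runs three seeds.
These sizes reproduce the qualitative regime of the full-scale analysis
while keeping a complete run in minutes on one CPU. All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`; equal seeds
give byte-identical outputs, which the pipeline's SHA-256 manifest makes
checkable.

## 8. Known limitations

* The Γ₂ equation assumes the two-state (bound/free) contribution enters as
  a single effective rate; exchange-regime corrections are not modeled.
* A single global scale links observed and calculated Γ₂ (absorbed in the
  weights); per-site scale differences (e.g., unequal labeling efficiency)
  are not fitted.
* The active-set refinement returns one vertex of the (possibly degenerate)
  optimal set; weight uncertainties are not quantified beyond seed-to-seed
  spread and the stability-selection consensus.
* The docking search is tuned for restraint sets that actually localize the
  pose; with a single effective site it will return a member of the
  degenerate optimum family, not a unique pose.
* PDB round trips quantize coordinates to 1e-3 Å (format precision).
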