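# Methods

## Model

`crowdnn` treats RNA duplex formation as a two-state bimolecular
equilibrium described by the nearest-neighbor (NN) model: the standard
free energy of duplex formation is the sum of contributions from the
n − 1 adjacent base-pair stacks of an n-bp duplex, one helix-initiation
term, a penalty per A·U-closed terminus, and a +0.43 kcal·mol⁻¹ symmetry
correction for self-complementary strands. Ten canonical Watson–Crick
stacks exist for RNA; a stack read from the complementary strand
(X₁X₂/Y₁Y₂ → Y₂Y₁/X₂X₁) is the same physical object and canonicalizes to
the same label. ΔCp is taken as zero, so ΔG°(T) = ΔH° − T·ΔS° at any
temperature; this is well justified only near 37 °C, and
`free_energy_at` warns beyond ±25 K. Melting temperatures follow
Tm⁻¹ = R·ln(Ct/s)/ΔH° + ΔS°/ΔH° with Ct the total strand concentration,
s ∈ {1, 4} the symmetry factor, and R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹.

The bundled parameter set was measured in 40 wt% PEG200 with 100 mM NaCl
(122 mM total Na⁺ counting buffer sodium) — a deliberately cell-like
condition. Its ΔG°₃₇ values decompose, parameter by parameter, into
bulk (value at 10 mM Na⁺), cation (the 122 mM Na⁺ increment),
excluded-volume and water-activity components; recomposing these terms
with condition-specific excluded-volume and water-activity values
generalizes the set to other cosolutes, concentrations and Na⁺ levels.

### Excluded volume

Cosolutes excluded from the vicinity of the RNA shift the equilibrium
toward the more compact state. At the duplex level,
ΔG°₃₇,ev,dup = (−0.019·n − 0.070)·C·N kcal·mol⁻¹, a linear fit in duplex
length n established over 6–12 bp (the implementation warns outside that
range). C is cosolute molality and N its monomer count; the per-NN share
is ΔG°₃₇,ev,dup/n, charged to each stack and to initiation (n terms in
total, so predicting an n-bp duplex with a set composed at the same n
reconstitutes the duplex-level term exactly) but never to the terminal
A·U penalty, whose share is already inside initiation. The generic
cylinder relation (V = N·l²·N_A·k·10⁻²⁷ L·mol⁻¹,
ΔG°ev = R·T·ρ·ΔV·C) is exposed for users with their own geometry, e.g.
for hairpins.

### Water activity

Cosolutes depress water activity and thereby destabilize duplexes;
per parameter, ΔG°₃₇,NN,wa = m_cs·Δa_w with
Δa_w = a_no-cosolute − a_cosolute. Two chemical classes of cosolute share
prefactor columns: ethers without vicinal hydroxyls (PEGs,
2-methoxyethanol, 1,2-dimethoxyethane) and vicinal-diol-like molecules
(ethylene glycol, glycerol, 1,3-propanediol), whose column is the PEG
column scaled by a constant slope ratio ≈0.411. A custom cosolute
supplies its own slope ratio. Δa_w can be given directly, converted from
a measured osmolality, or looked up from a small bundled table
(40 wt% PEG200 → 0.0489, back-inferred consistently from all 12
decomposition rows; 20 wt% ethylene glycol → 0.047). A missing Δa_w is
an error — never silently zero.

Osmolality converts to water activity via the water-potential relation
Ψ = (RT/M_w)·ln a_w with Ψ = osmolality(mmol·kg⁻¹)×10³/(−400)
interpreted in kPa. The kPa reading is the only dimensionally consistent
one (taken literally in MPa it would give −2500 MPa at 1 osmol·kg⁻¹) and
reproduces the physical benchmark a_w ≈ 0.982 at 1 osmol·kg⁻¹, matching
the ideal-solution value exp(−0.018·m) to 2×10⁻⁴.

### Cations

The cation component is anchored at exactly two Na⁺ concentrations:
zero at 10 mM (bulk by construction) and the tabulated column at 122 mM;
terminal A·U pairs carry no cation term. Other Na⁺ concentrations
require a user-registered per-parameter model — interpolation is
refused, because the underlying concentration dependence is not part of
the shipped tables. K⁺ and intracellular cation mixtures are handled at
the whole-duplex level by affine transfers of the Na⁺ prediction
(0.93·ΔG + 0.45 and 0.92·ΔG − 0.12 kcal·mol⁻¹ respectively), as they
were calibrated — on whole-duplex stabilities under 40 wt% PEG200
crowding; applying them under other crowders extrapolates and can be
flagged.

### Motifs beyond perfect duplexes

G·U wobbles (two hydrogen bonds, like A·U) are scored by substituting
A for the wobble G before parameter lookup; a G·U-closed terminus then
counts as a terminal A·U — an extrapolation, flagged in prediction
warnings. Hairpin stability assembles the wobble-normalized stem from
condition-composed parameters (without the bimolecular per-NN
excluded-volume share), user-supplied dilute-solution loop penalties
rescaled by (1 − 11.8·Δa_w) — hairpin and internal loops alike, since a
single empirical rule is available — one helix-initiation term, and a
unimolecular excluded-volume term if folded/unfolded cylinder geometry
is supplied (omitted with a warning otherwise). The terminal A·U penalty
applies at the open terminus only, never at the loop-closing pair. No
loop tables are bundled; bulges, mismatches, dangling ends and coaxial
stacking are out of scope.

## Parameter fitting

The 12 free parameters (10 stacks, initiation, terminal A·U) are
estimated by ordinary least squares on the duplex count matrix, fitting
ΔG°₃₇ and ΔH° independently; the symmetry parameter is fixed at its
dilute-solution value (it depends on sequence complementarity, not the
solution) and subtracted from the responses first. ΔS° is derived from
the fitted ΔG°₃₇ and ΔH°, inheriting both fits' noise. OLS is the
default because the reference procedure states no weighting; a weighted
variant sits behind the `weights` argument. The design builder reports
rank and condition number and fails on rank deficiency, naming the
unidentifiable parameter combinations. Identifiability needs at least 12
linearly independent rows.

## Synthetic panels — what they emulate and what they do not

`simulate_duplex_set` generates panels mirroring the design of the
measured panel behind the bundled tables: 45 duplexes by default
(25 non-self-complementary + 20 self-complementary), lengths 6–12 bp,
unbiased coverage of all 10 stacks (each stack in ≥5 duplexes, full-rank
design), and rejection of candidates with true ΔG°₃₇ > −4 kcal·mol⁻¹ —
too-unstable duplexes would give no analyzable two-state melting
transition, and their near-zero ΔG°₃₇ makes relative residuals
meaningless. Default measurement noise is relative and calibrated from
the duplicate-measurement reproducibility of same-NN-set sequence pairs
in the measured panel (mean absolute duplicate differences of 4.0% on
ΔG°₃₇ and 5.2% on ΔH°, divided by E|X₁−X₂|/σ = 2/√π for independent
Gaussian errors: σ ≈ 3.5% and 4.6%). Melting series use 10–12
concentrations log-spaced over a ~100-fold range, as in practice.

These panels carry *measurement* noise but no *model* error: responses
are exact NN sums. Refit residual summaries on them therefore sit
slightly below the residuals reported for real measurements (which
include any NN-model inadequacy): typically ~2.6% mean ΔG°₃₇ difference
versus 3.5% measured, while the Tm residual (~1.1 °C) matches. Passing
the recovery and residual tests shows the estimator and pipeline are
correct and correctly calibrated to the stated measurement
reproducibility — not that the NN model is exact for real RNA.

## Numerical choices

- Entropies convert from printed cal·mol⁻¹·K⁻¹ to internal
  kcal·mol⁻¹·K⁻¹ exactly once, at table load.
- Hess-law closure (ΔG°₃₇ = ΔH° − 310.15·ΔS°) is enforced on every table
  row at load with 0.015 kcal·mol⁻¹ tolerance — the rounding slack of
  2-decimal printed values. Consequently a predicted ΔG°₃₇ (the sum of
  the printed ΔG°₃₇ column) can differ from ΔH° − 310.15·ΔS° of the same
  prediction by up to ~n·0.015; both are reported, and the breakdown
  always sums exactly to the reported ΔG°₃₇ (`math.fsum`).
- wt% means grams of cosolute per 100 g water (C = 10·w/M); the
  mass-fraction reading would shift the 11-mer excluded-volume example
  from −0.45 to −0.50 kcal·mol⁻¹ and is not used.
- PEG monomer counts: round((M − 18)/44), so PEG200 → 4, which makes the
  length-averaged per-NN excluded-volume share match the tabulated −0.22
  kcal·mol⁻¹; the small ether/diol cosolutes count as one monomer.
- van't Hoff standard errors are first-order propagations of the
  slope/intercept errors without their covariance — adequate for the
  near-centered log-concentration designs used here, and the point
  estimates are exact on noiseless input regardless.
- Tie-breaks/degenerate inputs: all-equal concentrations are a hard
  error in the van't Hoff fit; Ct = s reduces Tm to ΔH°/ΔS° exactly;
  ΔH° ≥ 0 has no defined bimolecular melting and is refused.

## Known limitations

- Composed (non-reference) conditions are ΔG°₃₇-only; Tm prediction
  under them is refused rather than approximated, because the
  decomposition exists only for ΔG°₃₇.
- The cation model knows two Na⁺ anchors; everything else is the user's
  responsibility via the registration hook.
- The excluded-volume length fit, the K⁺/intracellular transfers and the
  loop-rescaling rule are empirical relations calibrated under specific
  conditions (6–12 bp; 40 wt% PEG200); the implementation warns rather
  than refuses outside those domains.
- Only fully complementary duplexes plus declared G·U wobbles are
  accepted; DNA, hybrids and mixed-cosolute solutions are out of scope.
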