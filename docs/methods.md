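# Methods

## Precursor masses

Every UDP-linked precursor is modelled as an ordered chain of building
blocks joined by condensation bonds, each bond releasing one water. The
neutral elemental composition is the element-wise sum of the free-molecule
formulas minus (n−1)·H₂O for n blocks, and the monoisotopic mass is the sum
of per-element monoisotopic atomic masses (¹²C = 12 exactly; H 1.00782503,
N 14.00307400, O 15.99491462, P 30.97376163, Na 22.98976928), embedded as a
single constants table so no external lookup happens at run time.

Free-molecule block formulas: UDP C₉H₁₄N₂O₁₂P₂, GlcNAc C₈H₁₅NO₆, MurNAc
C₁₁H₁₉NO₈, Ala C₃H₇NO₂, Glu C₅H₉NO₄, meso-DAP C₇H₁₄N₂O₄, Lys C₆H₁₄N₂O₂,
Ala–Ala C₆H₁₂N₂O₃, enolpyruvate C₃H₄O₃. MurNAc is a single block rather
than GlcNAc + lactyl so that bond counting stays uniform (exactly one water
per inter-block bond). Substituting Lys for meso-DAP changes any species
mass by exactly one CO₂ (43.9898 Da) — the decarboxylation relating the two
stem-peptide chemotypes. Stereochemistry is metadata only: mass spectrometry
cannot distinguish optical isomers, so L/D labels never affect a mass.

The default ladder holds the five ligase-pathway species (UDP-GlcNAc,
UDP-MurNAc-Ala, -dipeptide, -tripeptide, -pentapeptide). The MurA/MurB
intermediates (UDP-GlcNAc-enolpyruvate, UDP-MurNAc) sit behind flags and
default off, since the reference identifications do not include them.

## Ion enumeration and matching

Negative-mode ions are (m + k·Na − z)/z species: m/z = (M − z·m_H +
k·(m_Na − m_H))/z with z ∈ {1,2,3} and k ∈ {0..3} sodium-for-hydrogen
exchanges (each worth +21.9819/z). The hydrogen mass subtracted per charge
is the **atom** mass (1.0078250 Da), neglecting the electron; this
convention reproduces the reference table's printed values to ≤ 0.0005 Da,
whereas proton-mass subtraction is ~1 ppm high per charge. A `proton`
switch is provided for instruments calibrated the other way.

Matching assigns each observed peak independently to the candidate ion
minimizing |ppm error| = |(obs − theo)/theo|·10⁶, if within tolerance.
Exact ties break to lower charge, then lower k, for determinism. The
default tolerance is 30 ppm: the reference instrument was calibrated to
< 1 ppm but the printed observed-vs-expected offsets run ≈ +10 to +25 ppm
(no recalibration is applied — the systematic offset is taken as a property
of the acquisition), and 30 ppm accepts every printed identification while
the nearest decoys remain orders of magnitude further. Intensities are not
used (the reference table prints none).

**Identification rule.** A precursor is identified when it has at least
`min_ions` (default 1) matched ions **and**, by default, at least one of
them is a sodium-free deprotonated (k = 0) ion (`require_base_ion=True`).
The base-ion requirement encodes standard adduct-annotation practice —
satellite adducts corroborate an identification but cannot establish one —
and is load-bearing here for a numerical reason: two Na-for-H exchanges add
43.9639 Da, within 26 mDa of the CO₂ (43.9898 Da) separating DAP- from
Lys-containing species, so a Lys ion with k+2 sodiums lies only ≈ 22–25 ppm
below the DAP ion with k sodiums. Without the rule, a Lys-only search of
the reference peaks would pick up a handful of such adduct coincidences;
with it, the negative control is clean, because the nearest sodium-free Lys
ion is a full CO₂/z ≥ 14.66 Da away. Every species identified in the
reference table has a k = 0 ion among its matches, so the rule changes
nothing on the positive side. In the combined DAP+Lys search the rule is
not even needed: nearest-|ppm| assignment already sends every such peak to
the closer DAP ion.

## Kinetics

**Trace → rate.** The coupled assay consumes one NADH per ADP released, so
v₀ = (−slope of A₃₄₀ vs t)/(ε·l)/[E] in mol ADP·mol ligase⁻¹·s⁻¹. Defaults
ε = 6220 M⁻¹cm⁻¹ and l = 1 cm are the universal literature constants for
NADH at 340 nm (config-overridable). The slope is an ordinary
least-squares fit over the chosen window (≥ 3 points); negative computed
rates are flagged, never clamped.

**Rate models.** Michaelis–Menten v = Vmax·S/(K_M + S) and substrate
inhibition v = Vmax·S/(K_M + S·(1 + S/K_i)) — the uncompetitive-by-substrate
form used by standard curve-fitting software; the SI curve peaks at
S* = √(K_M·K_i) and reduces to MM as K_i → ∞. The pH dependence is the
diprotic bell v(pH) = v_opt/(1 + 10^(pK₁−pH) + 10^(pH−pK₂)), optimum at the
pK midpoint; other pH forms are out of scope. All fits are trust-region
nonlinear least squares (scipy `curve_fit`, bounded positive) with
deterministic multi-start initialization (Vmax₀ = max v; K_M₀ = S at
half-max; K_i₀ ∈ {max S, 10·max S, 10⁷}); the best-SSE start wins, and
non-convergence from every start raises a diagnostic error rather than
returning defaults. Parameter SEs come from the linearized covariance;
confidence intervals use t quantiles with n − p degrees of freedom.

Since v₀ is already per mol enzyme, k_cat = Vmax (s⁻¹) and k_cat/K_M is
reported in µM⁻¹s⁻¹. Every constant is labelled "apparent": ATP and the
UDP-MurNAc-dipeptide are fixed, not saturating by proof.

**Model comparison.** Both R² (the field's conventional criterion) and
small-sample AICc are reported. SI nests MM, so R² alone always favours SI
on noisy data; the headline selection follows R² (with an exact-tie
declaration at ΔR² ≤ 1e−9) while AICc — which charges 2 parameters' worth
of penalty for K_i — is the advisory to trust when the curves are close.
Simulations in the test suite show AICc recovers an MM truth ≥ 95% of the
time at 5% noise, and R² selects an SI truth (K_i = 5·K_M) essentially
always.

**pH-bell identifiability.** If the empirical activity maximum sits on a
boundary of the pH grid the data cover only one flank and both pKa's are
not estimable; the fitter raises `UnidentifiableProfileError` instead of
returning an arbitrary bell.

**Controls and specificity.** Coupling-enzyme independence is a paired
ratio test: mean 2×/1× rate ratio with a t-CI; "independent" iff the CI
contains 1. The specificity panel reports per-substrate means with 95%
t-CIs and unpaired two-tailed t-tests against the reference substrate and
against zero. Welch's unequal-variance form is the default (the safer
choice when replicate counts differ); classic Student is a flag, as is
Holm adjustment — unadjusted p-values are the default to match field
convention. Groups with fewer than two replicates are excluded and
flagged.

## Sequence utilities

The DAP-specificity motif scanner searches the named set {DNPR, DNPK,
DNPA, DNSR, DDPR} plus the generalized class [D][ND][PS][RKA],
non-overlapping and left-to-right, with 1-based coordinates throughout
(matching residue-numbering convention, e.g. mature moss MurE starting at
Leu63 after transit-peptide trimming). Percent identity is a global
Needleman–Wunsch alignment (match +1, mismatch 0, gap open −2, extend
−0.5) scored as identities over alignment columns; this is a documented
self-contained measure and deliberately does **not** reproduce identity
percentages from multiple-alignment web services, which depend on their own
parameters and databases.

## Synthetic data

Generators mirror the structure of the real inputs with known truth and a
mandatory seed (single `numpy.random.default_rng` stream per dataset;
identical seed + parameters ⇒ bit-identical output):

- **Peak lists**: observed m/z = theoretical · (1 + (µ + N(0,σ))·10⁻⁶)
  with defaults µ = +15 ppm, σ = 5 ppm — the offset structure of the
  reference table; deprotonated ions included with probability 1, adducts
  0.5; decoys uniform over the spanned range avoiding ±3σ of true ions.
  Multiplicative error is instrument-like.
- **Rate series**: model curve + i.i.d. N(0, (σ·Vmax)²), default σ = 5%,
  on a log-spaced S grid — the shape of a substrate-curve experiment.
- **Traces**: A₃₄₀(t) = A₀ − v₀·[E]·ε·l·t + drift·t + N(0, σ_A²), truncated
  at 0; additive detector-like noise; A₀ default 1.244 (0.2 mM NADH).
- **pH profiles**: bell values + Gaussian noise on a 0.25-unit grid.

Not emulated: isotopologue envelopes, peak shapes and intensities,
chromatographic elution, coupled-enzyme lag and substrate-depletion
curvature. Passing round-trip tests therefore demonstrates correctness of
the enumeration/matching/fitting logic under realistic error magnitudes,
not robustness to every artefact of real spectra or plate-reader traces.

## Problem sizes and numerical choices

Simulation-based validation uses 500 replicates for CI coverage (5% noise,
10 concentrations), 200 for model-selection rates, and 100 for pH-optimum
recovery — sizes chosen so Monte-Carlo error on the checked proportions is
≈ 1–3%, well inside the asserted margins. Matching tolerances, tie-break
rules and the 30-ppm default are fixed a priori as described above; m/z is
printed to 4 decimals everywhere, matching the reference precision.

## Known limitations

- The bundled observed-value table is a transcription of printed values
  (checksum-locked); raw spectra are not processed (no mzML, centroiding
  or deisotoping).
- Printed kinetic constants of the reference enzymes live in a figure and
  are not machine-checkable; the kinetics stack is therefore validated by
  parameter-recovery simulation, not against published numbers.
- Lipid-linked intermediates and polymerized peptidoglycan are out of
  scope, as are phylogenetic inference and alignment-service identity
  values.
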