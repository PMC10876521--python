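# Methods

## Exact-mass arithmetic

Monoisotopic masses (Da): ¹H 1.0078250319, ²H 2.0141017779, ¹²C 12 (exact),
¹⁶O 15.9949146221, ¹⁴N 14.0030740052, ³²S 31.97207069, ³¹P 30.97376151,
electron 0.0005485799 (`src/befa/data/isotope_masses.json`; CODATA/NIST
values). Deuterium is a distinct element symbol so that labeled-formula
arithmetic is integer-exact; the derived D-for-H shift is Δm = 1.0062767460
Da. Ion m/z includes the electron mass — m/z([M−H]⁻) = M − m(¹H) + mₑ —
which many casual calculators omit; it is required to reproduce 4-decimal
high-resolution values (dropping it shifts C11H19O2⁻ from 183.1391 to
183.1396). Only singly charged [M−H]⁻/[M+H]⁺ adducts are supported; the
metabolites in scope ionize as singly charged species. m/z is kept in full
double precision and rounded to 4 decimals only for display. Isotope-pattern
envelopes (natural-abundance ¹³C etc.) are not simulated; only monoisotopic
and explicit-D masses.

One known tension: the fully processed D11 dihydroxy species computes to
215.1289 + 11·Δm = 226.1979, about 1.3 ppm below the 4-decimal value read off
spectra (226.1982). Agreement is therefore asserted within 2 ppm rather than
at 4-decimal equality; sub-2-ppm discrepancies are within routine Orbitrap
calibration error.

## Feature tables

Tables are dense (post peak-filling): a missing intensity cell is an ingest
error and true zeros are kept. Retention times are stored in seconds
(readers accept a minutes flag). Ion modes are not mixed within one
analysis: each mode is normalized to a different internal reference, so
cross-mode operations are rejected. Delimited text (CSV/TSV, sniffed
delimiter) is the only on-disk format. Degenerate features (adducts,
isotopes of one analyte) are retained, except for the reference's own
degenerates (below).

## Differential pipeline

Stage order: RT cull → blank subtraction → intensity filter → reference
normalization → Welch → BH. Defaults: RT window 180–1080 s (a 60–1080 s
variant is a config change), blank fold 5, intensity floor 10,000 AU on the
pooled animal group, *q*\* = 0.15, 3 ppm windows. All thresholds are closed
(≥): "threshold" is read inclusively since the rule's source does not state
the boundary convention.

Decisions where the design was open:

* **Blank subtraction pools all animal samples** (both genotypes) against
  the blank, and precedes genotype regrouping. A zero blank mean is replaced
  by a 1 AU pseudo-intensity so features detected only in animals always
  survive the keep-rule.
* **Normalization** divides sample *s* by ref_s / geomean(ref). Anchoring to
  the geometric mean preserves the AU scale. Note the exact arithmetic of
  the anchor is a choice: plain division by ref_s would make normalized
  values strictly invariant to per-sample rescaling but destroys the AU
  scale; the anchored form preserves scale at the cost of a global
  c^(1/n_samples) factor when one sample is rescaled by c (all intensity
  *ratios* remain invariant). The reference feature, plus any feature within
  3 ppm of reference m/z + a configured offset (¹³C +1.00336 by default;
  adduct deltas addable) and within ±5 s of the reference RT, is flagged
  excluded-from-testing — the automated equivalent of removing the
  reference's isotopes and adducts by hand.
* **Welch's t** is computed vectorized (Welch–Satterthwaite df, two-sided p
  from the t distribution); it equals `scipy.stats.ttest_ind(equal_var=False)`
  to machine precision, with explicit handling of zero-variance features
  (equal means → t = 0, p = 1; unequal → p = 0). Note Welch's test is
  intrinsically slightly conservative at small equal n (true size ≈ 0.0465
  at n = 6/6 even for normal data) — a property of the test, not of this
  implementation.
* **log2 fold changes** use a 1 AU pseudo-intensity floor in both means to
  keep volcanoes finite.
* **BH** is the standard step-up via statsmodels
  (`multipletests(method="fdr_bh")`), q = min over larger p of m·p₍ⱼ₎/j,
  clipped at 1. BH controls the *expected* FDR; individual experiments can
  exceed q\*, and with 10 strong effects among 200 features the expected
  false-discovery count at q\* = 0.15 is ≈ 1.6 per experiment.
* Technical replicates may be modeled as independent experiments by listing
  them as separate samples in the manifest; the package does not do this
  silently.

Out of scope: multi-factor designs, mixed models, batch correction.

## Tracer matching

For each feature u and each n in the candidate range (default 1–13),
partners are features within 3 ppm of u.mz + n·Δm whose RT shift lies in a
signed window, default [−10, +2] s — deuterated species elute slightly
earlier on reversed phase, so the window is asymmetric. The best candidate
per (u, n) minimizes |ppm error| (ties by |ΔRT|), and labeled features are
assigned one-to-one greedily by mass error so one feature cannot satisfy
several n hypotheses. Enrichment verdicts use a 10,000 AU detection floor:
"enriched" when the partner is detected in the labeled condition and either
absent from the control or ≥ 5-fold higher; a partner detected in both at a
ratio between 2 and 5 is "ambiguous", below 2 "not-enriched". The 2-fold
ambiguity bound is this package's choice — it separates "clearly shared"
from "possibly enriched" where the source procedure gives no rule.
Partial-labeling isotopologue distributions and natural-abundance
deconvolution are out of scope: only full-shift species are scored.

## Label-fate model

Chains are tuples of carbons with explicit H/D slot occupancy validated
against valence after every operation (carboxyl C1: 0 slots; sp³ interior:
2; olefinic: 1; terminal methyl: 3; +1 slot lost per branch/bridge/OH).
Abstractions remove D preferentially when present — no kinetic isotope
effect — except 2-hydroxylation during α-oxidation, which takes H first (an
OH replaces a specific pro-R hydrogen; C2 is unlabeled in every pathway
modeled, so the preference is moot in practice). β-oxidation collapses the
dehydrogenation/hydration/thiolysis intermediates into a single rule: remove
C1–C2, strip the new carboxyl carbon's hydrogens. This reproduces every
diagnostic deuterium count of the D13 feeding design, including the single
residual D at product carbon 5 of the methylation route. The model refuses
double bonds within the first three carbons during β-oxidation
(enoyl-isomerase chemistry is not modeled) and treats a branch or ring at
C2/C3 as a hard block — the termination condition that makes β-branched
acids accumulate. The D13-vaccenate label pattern defaults to C13–C17 ×2 D
plus C18 ×3 D and is a constructor parameter so alternative patterns are
testable. All species are free acids; CoA thioesters, enzyme kinetics and
flux are out of scope. Stereochemistry is not tracked beyond double-bond
geometry (which gates the cis-specific +CH₂ enzymes); the distal
hydroxylation position is a parameter (default ω−1) because the deuterium
count is identical for any deuterated distal carbon.

## Synthetic data

The differential generator draws per-feature base means log-uniform over
10^4.3–10^5.8 AU (so null features comfortably clear the 10,000 AU filter
and the filter is exercised by construction, not by noise), multiplies
group-B means by the planted fold change, and applies multiplicative
log-normal noise with σ = 0.2 on the natural-log scale (≈ 20% CV, a
realistic replicate-to-replicate spread for nematode liquid cultures
measured by LC-HRMS). Blank-stratum features get a blank mean at 0.5–3× the
animal mean, straddling the 5-fold rule from below; all other features carry
a 10⁻³ trace in blanks. The internal-reference feature has σ = 0.02 and mean
10⁶ AU. m/z is uniform over the 117–1000 scan range, RT uniform over the
analysis window. The tracer generator plants partners at exact n·Δm offsets
with Gaussian ppm jitter and a fixed RT shift, intense only in the labeled
condition (a 10 AU floor elsewhere).

What the generators do *not* emulate — correlated degenerate features
(adducts/isotopes of a common analyte), RT drift, heteroscedastic noise
floors, missing values, and ionization suppression — bounds what passing
tests show: they validate the statistics and bookkeeping on clean,
independent features, not robustness to real-data pathologies.

Simulation sizes used in the test suite (1,000-feature nulls × 200 seeds;
200-feature planted tables × 100 seeds; 100–150-feature tracer tables) keep
the full suite in the tens of seconds while making Monte-Carlo standard
errors small relative to the asserted tolerances.

## Reporter quantification

GFP: per experiment, background = mean of the *minimum* intensities of all
outlined animals; corrected = mean − background, floored at 0 with a warning
(an animal dimmer than the pooled background is physically possible);
normalized = corrected / mean(corrected over control animals). The control
mean is exactly 1 per experiment by construction. ddCt: technical replicates
averaged first; ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the
*arithmetic mean* ΔCt of the control samples (equivalently the geometric
mean of control folds is 1); fold = 2^(−ΔΔCt). No amplification-efficiency
correction.

## Command-line interface

`befa diff|tracer|predict|simulate|gfp-quant|ddct`. Every run logs the tool
version and SHA-256 checksums of its inputs to stderr; `diff` logs per-stage
survivor counts. YAML configs mirror `PipelineConfig` fields; flags override
config values; defaults are the standard thresholds above.
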