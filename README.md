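# befa

Comparative untargeted metabolomics and deuterium tracer-fate analysis of
β-branched fatty acids.

## The problem

In *C. elegans*, two structurally similar C11 fatty acids regulate the
stearoyl-CoA desaturase FAT-7 through the nuclear receptor NHR-49/PPARα: a
β-cyclopropyl acid (becyp#1) derived from dietary bacterial cyclopropane
lipids, and an endogenous β-methyl acid (bemeth#1) installed by the
methyltransferase FCMT-1. Establishing their biosynthesis and degradation
relies on three computational pieces that this package implements as a
tested library with a CLI:

1. **Feature-table differential statistics** for two-group LC-HRMS
   comparisons: retention-time culling (180–1080 s), solvent-blank
   subtraction (keep features ≥ 5-fold over blank), a 10,000 AU mean
   intensity filter, internal-reference normalization (ascr#3-style anchor),
   per-feature unpaired two-sided Welch's *t*-test, and Benjamini–Hochberg
   FDR at *q*\* = 0.15.
2. **Stable-isotope tracer analysis**: detecting labeled isotopologue
   partners at exact *n*·Δm offsets, where Δm = m(²H) − m(¹H) = 1.0062768 Da
   (so a CD₃ methyl contributes a 3.0188 Da shift), within 3 ppm and a
   signed co-elution window, with enrichment verdicts against the unlabeled
   control condition.
3. **A deterministic tracer-fate model** of fatty-acid transformations with
   per-carbon H/D bookkeeping: SAM-dependent methyl transfer to a *cis*
   double bond (branch at Cᵢ, bond migration to *trans* Cᵢ₊₁–Cᵢ₊₂, one H/D
   abstracted from Cᵢ₊₂), cyclopropanation (+CH₂ bridge, nothing abstracted),
   β-oxidation rounds (net −C₂, new carboxyl carbon stripped of H/D, blocked
   by a β-substituent), α-oxidation (2-hydroxylation then C1 removal), and
   hydroxylation. From the model, product formulas, deuterium counts and
   [M−H]⁻ / [M+H]⁺ m/z values follow by exact monoisotopic-mass arithmetic
   (electron mass included: m/z([M−H]⁻) = M − m(¹H) + mₑ).

A seeded synthetic-data module generates feature tables with planted
differential features, blank contamination, an internal-reference feature
and labeled isotopologue partners, so every stage is testable with known
ground truth and no raw data.

## Worked example

Predict the deuterium fate of D13-*cis*-vaccenic acid through methylation
and four rounds of β-oxidation:

```bash
befa predict --label d13_cis --route methylation --beta-rounds 4 --out pred.csv
```

prints

```
        name    formula  n_d adduct       mz                              trace
D12-bemeth#1 C11H8D12O2   12 [M-H]- 195.2144 D13-cis-VA -> methyl transfer ...
```

One of the 13 deuteriums is abstracted during methyl transfer (from the
carbon the double bond migrates onto), leaving 12 D, with a diagnostic single
D at product carbon 5 after the four β-oxidation rounds. Running the same
command with `--label d13_trans` fails with "not a substrate": the
methyltransferase acts only on *cis* double bonds, which is exactly the
discrimination the labeling experiment exploits. The unlabeled methylation
and cyclopropanation routes both yield C11H20O2 at m/z 183.1391 — the
isomeric bemeth#1/becyp#1 pair.

The full simulated workflow lives in `analysis/`:

```bash
python analysis/01_predict_metabolites.py    # metabolite family predictions
python analysis/02_differential_volcano.py   # simulate -> full cascade -> volcano.csv
python analysis/03_tracer_recovery.py        # simulate label feeding -> pair matching
python analysis/04_reporter_quantification.py
```

`02_differential_volcano.py` (seed 17: 200 features, 10 planted at 8-fold,
n = 6/6) reports each stage's survivor count and recovers all 10 planted
features at *q* ≤ 0.15; `03_tracer_recovery.py` recovers all 27 planted
D3/D11 partners with verdict "enriched" and zero spurious matches, and
annotates D11 pairs with the model-predicted D11 species. Outputs land in
`results/`.

## Layout

```
src/befa/          library (chem_mass, feature_io, pipeline, tracer,
                   biosynth, routes, simulate, reporter, cli)
analysis/          numbered driver scripts writing tables to results/
tests/             pytest suite (unit, property, end-to-end)
docs/methods.md    model assumptions, parameter defaults, limitations
```
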