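# spliffkit

Quantification and temporal interaction calling for **SPLIFF** split-ubiquitin
cleavage-reporter microscopy, with FRAP recovery fitting and a synthetic
trace simulator for end-to-end validation.

## The problem

SPLIFF is a time-resolved protein-fragment complementation assay in budding
yeast. A bait protein carries an mCherry-Cub-GFP (CCG) reporter; when a
Nub-tagged prey binds, reconstituted ubiquitin triggers cleavage behind Cub,
the GFP moiety is released and rapidly degraded, and the local green/red
ratio drops. Following both channels through a cell cycle therefore reports
*when* the bait-prey interaction occurred — at the site of cell fusion
(PCDI), during bud-site assembly and growth (PCDII), and at the bud neck
through cytokinesis (PCDIII).

Turning microscope ROI measurements into phase-resolved interaction calls
takes several statistical steps, and complementary FRAP experiments report
the exchange dynamics of the same proteins. `spliffkit` implements this
analysis as a tested, reusable pipeline:

1. **quantify** — per timepoint and channel, the localized fluorescence
   intensity FI = I_fluorescence − I_cytosol; per channel, the relative
   intensity RFI(t) = FI(t)/FI(t_ref) normalized to the last pre-fusion
   frame; and the conversion statistic

   FD(t) = 100 · (RFI_red − RFI_green) / RFI_red  [%]

   which is 0 at fusion and approaches 100% as the reporter is consumed
   (values ≥ 80% carry an interpretability-caveat flag).
2. **inference** — single-cell FD(t) traces pooled across replicates, a
   locally weighted quadratic regression (loess, tricube weights, pointwise
   95% band) for the population curve, and a sliding window of two sampling
   intervals in which a linear trend on the pooled replicate values gives a
   slope (%/min) and two-sided P-value. A window is called an interaction
   when the slope is ≥ 1 %/min and P < 0.05 (below 70% conversion) or
   positive and significant (above 70%), and the same criterion is *not*
   met by a non-interacting control in that window.
3. **frap** — double normalization (reference ratio, then pre-bleach mean
   → 1 and first post-bleach frame → 0), one-phase association fit
   F(t) = P·(1 − e^(−kt)) with t_1/2 = ln 2 / k, and normality-routed group
   statistics (D'Agostino–Pearson, then t test / Mann–Whitney U /
   ANOVA / Kruskal–Wallis).
4. **simulate** — a linear three-species kinetic model of the reporter
   (intact CCG, cleaved red fragment, cleaved GFP) driven by an interaction
   schedule, sampled into realistic two-channel ROI traces with
   photobleaching, background and noise, plus FRAP trace generation — so
   every stage can be validated against known ground truth.

The fit-shaped pieces are scikit-learn-style estimators
(`ConversionQuantifier`, `LoessCurve`, `InteractionCaller`,
`OnePhaseAssociation`) with `get_params`/`set_params` and trailing-underscore
fitted attributes; module-level functions are thin wrappers.

## Worked example

Recover a known interaction schedule from simulated cells (20 cells,
2-min sampling, one interaction window per phase):

```sh
$ spliffkit benchmark --n-cells 20 --seed 1
{
  "f1": 1.0,
  "precision": 1.0,
  "recall": 1.0,
  "tp": 8,
  "fp": 0,
  "fn": 0,
  "tn": 31,
  "n_windows_scored": 39,
  "seed": 1,
  "n_cells": 20
}
```

All 8 unambiguous truly-active windows are called and none of the 31
inactive ones (windows straddling a true window boundary ± one frame are
excluded from scoring: there the truth is blurred by cell-to-cell timing
jitter and the GFP-degradation lag).

Fit and compare FRAP groups (simulated wild type t_1/2 = 8.82 s vs a
faster-exchanging binding mutant at 4.48 s, 12 cells each):

```sh
$ spliffkit frap --traces frap_demo.csv --out-dir frap_out
binding_mutant: t_half = 4.46 +/- 0.04 s (n=12)
wild_type: t_half = 8.75 +/- 0.07 s (n=12)
t test: P = 2.755e-25 ***
```

Both generating half-times are recovered within the SEM, both groups pass
normality, and the comparison is routed to a t test.

The full pipeline on files:

```sh
spliffkit simulate --n-cells 20 --seed 0 --out-dir sim/
spliffkit analyze --traces sim/traces.csv --out-dir results/
```

writes `conversion.csv` (per-cell FD traces), `slopes.tsv` (per-window
slope, P-value, call and stars), `profile.json` (phase-partitioned
interaction intervals) and the conversion-curve / call-matrix figures.
Every output directory carries a `manifest.json` (seed + config hash);
re-running a manifest reproduces the tables bit-for-bit.

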