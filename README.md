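# dscout

Analysis toolkit for **multiplex real-time digital PCR (dPCR)
quantification of circulating tumor cell (CTC) biomarkers** in
hepatocellular carcinoma (HCC) liquid biopsies — for assay developers and
computational biologists working with chip-partitioned, per-cycle-imaged
dPCR data.

The assay it models partitions a blood-derived lysate over ~20,000
microwells in two chip regions — surface proteins converted to countable
oligo tags by immuno-PCR, and reverse-transcribed mRNAs — each read every
cycle in three dye channels, giving six markers: EpCAM, GPC-3 and ASGPR
proteins; EpCAM, GPC-3 and PD-L1 mRNAs. `dscout` implements the full
computational chain:

* **Well calling** — each well x channel trace is fitted with a
  four-parameter logistic on a drifting baseline,
  `F(c) = F0 + drift·c + A/(1 + e^(−k(c−c50)))`; a well is positive only
  if curve shape (r²), amplitude vs baseline noise, threshold-crossing
  `Ct = c50 − ln(1/f − 1)/k` and normalized growth rate `k/4` all pass.
* **Poisson quantification** — with M positive of N wells, copies per
  reaction `X = −N·ln(1 − M/N)`, with a Wilson-propagated 95% interval.
* **Assay analytics** — nonparametric limit of blank, probit-regression
  limit of detection at 95% detection, %CV, standard curves,
  amplification efficiency, and a 2^−ΔΔCt comparison utility.
* **Digital scoring** — per-marker `z = (log2(x+1) − μ)/σ`, weights from
  the Analytic Hierarchy Process (principal eigenvector + consistency
  ratio), composite `score = Σ wⱼ zⱼ`, logistic combination, and rank
  (Mann-Whitney) ROC with Youden-optimal operating points.
* **2D molecular profiling** — per-cell calibration of EpCAM/GPC-3 by
  ASGPR protein, SVC (linear/poly/rbf or Gaussian naive Bayes) P1/P2
  region boundaries, per-cohort region proportions, and pre→post
  treatment *efficacy vectors* with magnitude and direction.
* **Synthetic data** — seeded generators for plates, dilution series and
  clinical-style cohorts with known ground truth, so every stage is
  testable end to end.

## Worked example

From `examples/01_plate_to_copies.py` — simulate a 20,000-well protein
region with 500 template molecules per channel, call every well, and
invert the positive-well counts:

```
 region channel   M     N   ct_mean    ct_sd  rate_mean  rate_sd
protein     CY5 493 20000 25.820957 1.290570   0.242512 0.072931
protein     FAM 494 20000 26.796964 0.895090   0.388529 0.074424
protein     VIC 496 20000 26.487477 0.865147   0.670137 0.221108

FAM: M=494 positive wells (truth 494) -> 500.2 copies/reaction (95% CI 458.0-546.3; loaded 500)
VIC: M=496 positive wells (truth 496) -> 502.3 copies/reaction (95% CI 459.9-548.4; loaded 500)
CY5: M=493 positive wells (truth 493) -> 499.2 copies/reaction (95% CI 457.0-545.2; loaded 500)
```

Every called count matches the ground truth exactly; the positive-well Ct
means sit on the configured channel distributions (26.83/26.46/25.73
cycles) and the growth-rate means on 0.39/0.66/0.25 per cycle; all three
copy estimates bracket the 500 loaded molecules. Scoring a simulated
three-cohort study (`examples/03_cohort_scoring.py`) then yields:

```
           HD: composite Z = -0.85 +/- 0.06 (n=24)
 advanced_HCC: composite Z = +1.02 +/- 0.45 (n=22)
    early_HCC: composite Z = -0.07 +/- 0.28 (n=31)

HCC vs healthy: AUC 0.994, Youden cutoff -0.70 (sensitivity 98.1%, specificity 100.0%)
```

The composite digital Z-score rises with disease stage and separates
disease from healthy donors; the other examples cover assay validation
(LOB/LOD/%CV) and 2D profiling with efficacy vectors.

A thin CLI wraps the same functions:

```bash
dscout run --seed 1 --out results/          # full pipeline on synthetic data
dscout call --traces traces.csv --out calls/
dscout lod --hits hits.csv
```

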