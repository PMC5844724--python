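# larctex

First-order MRI texture analysis for predicting the response of locally
advanced rectal cancer (LARC) to neoadjuvant chemoradiotherapy (nCRT).

## The problem

After nCRT a substantial fraction of LARC patients reach pathological
complete response (pCR, ypT0N0), which can only be confirmed on the
resected specimen. An imaging biomarker that predicts response *before or
early during* treatment would support organ-preserving ("watch-and-wait")
strategies. One candidate family of biomarkers are first-order texture
parameters of the tumor on T2-weighted MRI: statistics of the intensity
distribution within a manually drawn region of interest (ROI) on the
single largest tumor slice.

`larctex` implements that analysis workflow as a tested, reusable Python
library for radiologists and imaging scientists: feature extraction,
interobserver agreement, group statistics, and ROC/logistic response
modeling — plus a phantom generator, because studies of this design rarely
deposit patient images and the pipeline must be verifiable without them.

## The statistics at its core

For ROI intensities $X(i)$, $i = 1..N$, and a histogram with bin
probabilities $P(i)$ after resampling the intensities into equally spaced
bins (default 32):

- mean $\bar X = \frac1N \sum_i X(i)$ and SD
  $\big(\frac1{N-1}\sum_i (X(i)-\bar X)^2\big)^{1/2}$
- skewness $m_3/m_2^{3/2}$ and (non-excess) kurtosis $m_4/m_2^2$, with
  $m_k$ the population central moments of the raw intensities
- uniformity $\sum_i P(i)^2$ and entropy $-\sum_i P(i)\log_2 P(i)$ (bits)
- energy $\frac1N\sum_i \tilde X(i)^2$, where $\tilde X$ is min-max
  normalized to $[0,1]$ within the ROI, so the value is bounded and
  comparable across patients

Downstream: ICC(2,1) (two-way random effects, absolute agreement) with
McGraw–Wong confidence intervals for two-rater agreement; Wilcoxon
signed-rank (pre vs early nCRT, paired) and Mann–Whitney U (responder vs
nonresponder) tests; per-feature ROC curves with DeLong CIs and
Youden-index cutoffs; a backward-elimination logistic regression combining
the univariately significant features; and paired DeLong tests of the
combined predictor against each single feature. All reported performance
is apparent (in-sample).

Response is labelled by two reference standards: Mandard tumor regression
grade (TRG 1–2 = responder) and pCR (ypT0N0).

## Worked example

Extract features from a single synthetic tumor slice whose ROI histogram
concentrates 60% of its mass in one bright level:

```python
from larctex import PhantomSpec, TargetMarginal, extract_features, generate_phantom

spec = PhantomSpec(target=TargetMarginal.peaked(concentration=0.6), seed=42)
img = generate_phantom(spec, patient_id="demo", timepoint="pre")
print(extract_features(img, n_bins=32).as_dict())
```

```
ROI pixels: 1420, bins: 32
        mean: 278.8897
          sd:  63.4271
    skewness:  -1.4579
    kurtosis:   3.7243
  uniformity:   0.3802
      energy:   0.5906
     entropy:   2.8818
```

The dominant level makes the histogram ordered — uniformity well above
the 1/32 floor, entropy well below the 5-bit maximum — and, because the
peak sits near the top of the intensity range, energy is high and the
leftover uniform floor drags skewness negative and kurtosis above 3.

Running the full study on the default 59-patient phantom cohort
(`examples/05_response_prediction.py`) prints, among others:

```
        parameter  cutoff direction   auc  ci_low  ci_high  sensitivity_pct  specificity_pct
   pre-uniformity   0.307         > 0.888   0.804    0.972           80.000           84.091
      pre-entropy   3.214        <= 0.889   0.806    0.973           86.667           79.545
logistic_combined   0.221         > 0.895   0.816    0.975           93.333           75.000
```

i.e. responders are predicted by *high* pre-treatment uniformity and *low*
entropy, and the logistic combination is numerically but not significantly
better than the best single feature (paired DeLong p ≈ 0.53 here) — the
qualitative pattern this study design exhibits.

The `examples/` directory walks through each capability; the `larctex`
CLI (`simulate`, `extract`, `agree`, `analyze`, `roc`, `report`) exposes
the same stages for shell use, each restartable from intermediate CSVs.

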