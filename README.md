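# metabmr

A two-sample Mendelian randomization (MR) screening pipeline for panels of
exposures — built for the setting where hundreds of blood metabolites,
measured in one GWAS sample, are tested for causal effects on a disease
outcome measured in a second, non-overlapping sample, using only published
summary statistics.

## The method

For each exposure, genetic variants serve as instrumental variables.  An
instrument j contributes a Wald ratio

    theta_j = Gamma_j / gamma_j,    se(theta_j) = sigma_Yj / |gamma_j|,

where gamma_j is the SNP-exposure effect (per SD of the metabolite) and
Gamma_j the SNP-outcome effect (log-odds of disease).  Five estimators
combine the ratios under different assumptions about horizontal pleiotropy:

* **IVW** (primary): inverse-variance-weighted mean,
  `beta = sum(w_j theta_j) / sum(w_j)` with `w_j = gamma_j^2 / sigma_Yj^2`;
  multiplicative random-effects SE with dispersion floored at 1.
* **MR-Egger**: weighted regression of Gamma on gamma with a free intercept;
  the intercept estimates average directional pleiotropy.
* **Weighted median**: the median of the weighted empirical ratio
  distribution; consistent while valid instruments hold >50% of the weight.
* **Simple / weighted mode**: the kernel-density mode of the ratios
  (zero-modal-pleiotropy assumption), bandwidth
  `1.06 * min(sd, 1.4826*MAD) * J^(-1/5)`.

Instruments pass a four-stage filter before estimation: exposure association
P < 1e-5; LD clumping at r^2 = 0.001 within a 10,000 kb window; removal of
SNPs instrumenting two or more exposures; removal of disease/confounder-
associated SNPs from a user-supplied exclusion list.  Exposures keeping
fewer than 3 or more than 100 instruments are dropped.  Sensitivity
diagnostics cover Cochran's Q (IVW and Egger fits), the Egger-intercept
pleiotropy test (|intercept| < 0.1 and P > 0.05), MR-PRESSO (global,
per-SNP outlier, and distortion tests), and leave-one-out IVW.

An exposure is a **candidate** causal feature when its IVW p-value is below
0.05, at least three of the five models are significant (IVW among them),
and all five effect estimates share a sign.  A Bonferroni threshold
`0.05 / M` over the M exposures screened marks the strong-evidence tier.

Because real metabolome and disease GWAS downloads are large, the package
ships a synthetic two-sample generator (`metabmr.simulate`) that produces
summary statistics, LD panels, and multi-exposure studies with known ground
truth, so the whole pipeline is testable offline.

## Worked example

Generate a planted study (20 exposures x 500 SNPs; one truly causal
exposure with log-odds effect 0.2 per SD, one outlier instrument, one
exposure with only two instruments, one shared instrument, one palindromic
SNP, one LD pair) and run the batch screen:

```sh
metabmr simulate --scale small --seed 5 --out-dir study
metabmr batch study/config.yaml --out-dir out
head -4 out/results.tsv
```

prints

```
Metabolite  nSNP  Beta   SE    P         OR (95%CI)        Candidate  BonferroniSignificant
E01         11    0.23   0.05  3.23E-07  1.26 (1.16-1.38)  True       True
E06         11    -0.02  0.01  4.74E-02  0.98 (0.96-1.00)  False      False
E05         11    -0.02  0.01  7.41E-02  0.98 (0.96-1.00)  False      False
```

The planted exposure E01 tops the ranking: its IVW estimate 0.23 log-odds
per SD (OR 1.26, true value 0.20) is nominally and Bonferroni significant,
while the null exposures scatter around OR 1.0.  `out/candidates.tsv` holds
the per-method detail:

```
Metabolite  Method           nSNP  P         OR (95%CI)        P_Heterogeneity  P_HorizontalPleiotropy
E01         MR Egger         11    1.13E-01  1.34 (0.97-1.85)  0.00             0.74
E01         Weighted median  11    1.53E-29  1.21 (1.17-1.25)
E01         IVW              11    3.23E-07  1.26 (1.16-1.38)  0.00
E01         Simple mode      11    2.07E-18  1.20 (1.15-1.25)
E01         Weighted mode    11    2.55E-23  1.21 (1.16-1.25)
```

Four of five models are significant with consistent positive effects, so
E01 is flagged a candidate.  The heterogeneity P of 0.00 is the planted
outlier instrument showing up in Cochran's Q; `out/sensitivity.tsv` shows
MR-PRESSO flagging it by name (rs000001), and `out/skipped.tsv` records the
two-instrument exposure E02 excluded by the IV-count rule.  Library use is
one call: `metabmr.run_batch(exposures, outcome, panel, exclusion, config)`.

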