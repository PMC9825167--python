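# telosas

Quantitative analysis of **survivor-associated senescence (SAS)** in
telomerase-negative budding-yeast survivors, plus a stochastic simulator of
the clonal dynamics that generate the data.

Type II survivors maintain telomeres by homology-directed repair (HDR)
instead of telomerase, the yeast counterpart of ALT cancer cells.  When a
single survivor clone is propagated by daily dilution, its tracked telomere
erodes a few bp per population doubling (PD), the culture's replicative
potential falls as the telomere gets critically short, TERRA (the telomeric
lncRNA) accumulates, and an HDR event eventually re-extends the telomere and
restores growth — a senescence cycle that repeats.  `telosas` implements the
measurements used to quantify this behaviour:

- **Population doublings & replicative potential** — PDs per day as
  log2(OD_end/OD_start); percent replicative potential of each clone
  relative to its reference (empty-vector) culture's first OD600 reading.
- **SAS rate** — the number of PDs from the start of propagation to the
  selected local minimum of the potential profile: the profile is smoothed
  by averaging consecutive pairs, a position is a local minimum only if no
  value in a ±k neighbourhood (default k = 4) undercuts it, minima in the
  erratic first days (default 3) are excluded, and a manual override is
  available for curve-similarity-based selection.
- **Telomere shortening rate** — two estimators on length-vs-PD series:
  the mean of consecutive difference quotients ΔL/ΔPD, and the negated OLS
  slope of length on PD; plus treatment/control rate fold changes.
- **Gel densitometry** — band detection on 1-D lane-intensity profiles and
  relative telomere length (longest band set to 1).
- **TERRA RT-qPCR** — percent of the actin reference as 100·2^−ΔCt with
  ΔCt = Ct_TERRA − Ct_actin, and fold change to a reference group.
- **ChIP-qPCR** — percent input (IP over dilution-corrected input), fold
  change to the same-day wild-type, and tagged/untagged (TAP) background
  correction.
- **Simulator** — per-PD truncated-normal telomere attrition; HDR only
  below a critical length (type I: fixed gain; type II: lognormal gain);
  daily doublings monotone in telomere length; TERRA fold rising
  logistically from 1 to 6 as the telomere approaches the critical length;
  realistic multiplicative OD/ChIP noise, additive Ct and band-position
  noise.  Every generated table carries its ground truth, so all estimators
  are testable by parameter recovery.

## Worked example

Simulate a paired cohort — four clones, each propagated with an empty
vector (EV) and with RNase H1 overexpression (RNH1, which removes telomeric
RNA–DNA hybrids and accelerates shortening 1.6-fold):

```sh
telosas demo --seed 1 --outdir demo_out --n-clones 4
```

prints (abridged):

```json
{
  "mean_pd_to_min_EV": 83.94,
  "mean_pd_to_min_RNH1": 48.32,
  "pd_to_min_difference": 35.62,
  "p_value": 5.9e-06,
  "mean_rate_fold_change_regression": 1.592,
  "terra_fold_short_vs_long": 6.024,
  "mean_chip_fold_change_telomeric": 0.480
}
```

Reading: EV clones need ~84 PDs to reach their lowest replicative
potential, while hybrid-depleted clones senesce after only ~48 PDs —
RNA–DNA hybrids slow SAS.  The regression estimator recovers the 1.6-fold
faster shortening of the RNH1 arm, TERRA is ~6-fold higher at critically
short telomeres than at long ones, and the ChIP chain recovers the halved
telomeric binding built into the simulated dataset.  `demo_out/` contains
the full potential, SAS, rate, TERRA and ChIP tables plus a manifest with
output digests (reruns with the same seed are bit-identical).

The individual stages are available as subcommands (`simulate`, `growth`,
`sas`, `telolen`, `qpcr`, `chip`) over plain TSV/CSV tables, and as library
functions (`telosas.analyze_series`, `telosas.rate_regression`, …).

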