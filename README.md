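# fishrhythm

Rhythm analysis for annotated fish call sequences — from Raven Pro selection
tables to per-sequence rhythm statistics and between-site comparisons.

Several Mediterranean fish, most prominently the brown meagre (*Sciaena
umbra*), produce reproductive calls with a strikingly regular, metronome-like
temporal structure: trains of short pulsatile elements repeated at a
near-constant rate (the "R-pattern"). Passive acoustic monitoring studies
annotate these trains by hand and then ask quantitative questions: How
regular is a sequence? What is its underlying beat? Do beats differ between
sites, seasons, or individuals? `fishrhythm` implements that analysis chain
for anyone working with onset-annotated animal call sequences.

## What it computes

For a sequence of element onsets $t_1 < t_2 < \dots < t_n$ (with $n \ge 3$):

* **Inter-onset intervals (IOIs)**: $\mathrm{IOI}_i = t_{i+1} - t_i$, and
  their histogram.
* **Coefficient of variation**: $\mathrm{CV} = s_{\mathrm{IOI}} /
  \overline{\mathrm{IOI}}$ with the sample ($n-1$) standard deviation.
  CV near 0 means isochrony.
* **Best-fitting isochronous beat**: the frequency $f$ (Hz, elements per
  second) of a perfect grid $\{\varphi + k/f\}$ minimizing the mean
  normalized deviation

  $$d(f,\varphi) = \frac{1}{n}\sum_{i=1}^{n}
    \frac{\min_k\,\lvert t_i - \varphi - k/f \rvert}{1/(2f)} \in [0,1],$$

  i.e. each onset's distance to the nearest grid point scaled by half the
  beat period ("ugof"-style goodness of fit; 0 = perfect). A beat of 5 Hz
  means one element every 200 ms. Because any integer multiple of the true
  frequency also threads every onset, the search is anchored at
  $f_0 = 1/\mathrm{median}(\mathrm{IOI})$ and restricted to $\pm 50\%$
  around it, at 1 mHz resolution, with ties broken toward $f_0$.
* **Sequence building**: element streams are segmented into sequences of at
  least three elements, terminated by 10 s of silence (long recordings) or
  spanning the whole excerpt (1-minute protocol), and attributed to presumed
  individuals by matched signal-to-noise ratio.
* **Group statistics**: dataset-wide 3-SD outlier screening, one-way ANOVA
  across sites, pairwise Welch t-tests with Bonferroni correction and
  Cohen's d, and the intra- vs inter-individual beat range size
  ($\max - \min$ of beats).
* **Synthetic data**: a seeded pulse-train generator producing
  jittered-isochronous sequences (site-specific beat distributions, IOI
  jitter CV) and exponential-IOI random controls, so the whole pipeline is
  validated by parameter recovery.

The package reports statistics only; it deliberately imposes no isochrony
classification threshold. Isochrony is a joint judgement (unimodal IOI
histogram plus low CV) best left to the analyst.

## Worked example

```python
from fishrhythm import best_fit_beat, coefficient_of_variation, compute_iois

onsets = [0.0, 2.78, 5.56, 8.34, 11.12, 13.90]   # seconds
iois = compute_iois(onsets)
print(f"CV: {coefficient_of_variation(iois):.3f}")
fit = best_fit_beat(onsets)
print(f"beat: {fit.beat_hz:.4f} Hz  deviation: {fit.deviation:.4f}")
```

prints

```
CV: 0.000
beat: 0.3597 Hz  deviation: 0.0000
```

— one element every 2.78 s is a perfectly isochronous train whose best
fitting beat is $1/2.78 \approx 0.36$ Hz with zero deviation, the typical
R-pattern rate outside the Venice lagoon.

An end-to-end synthetic run from the command line:

```sh
fishrhythm run -c config.yaml -o run/
```

simulates each configured site, analyzes every recording and writes
`summaries.csv`, `aggregates.csv`, `comparisons.csv`, `discards.csv`,
`model_table.csv` and `report.md`. With two sites generated at beat means
0.46 Hz ("venice", 20 sequences) and 0.36 Hz ("trieste", 20 sequences),
seed 11, `aggregates.csv` reads

```
site_name,n_sequences,beat_mean_hz,beat_sd_hz,beat_min_hz,beat_max_hz,cv_mean,cv_sd,cv_min,cv_max
trieste,20,0.368156,0.071615,0.224722,0.535946,0.185628,0.029193,0.130400,0.245184
venice,20,0.475084,0.126626,0.309089,0.783296,0.182863,0.031856,0.119276,0.261271
```

and `comparisons.csv` shows the recovered site contrast (Welch
t = −3.10, df = 31.3, Bonferroni-adjusted p = 0.004, Cohen's d = 1.00) —
the faster Venice beat is detected with a large effect size, while the CV
(~0.18 everywhere) reflects only the generator's within-sequence jitter.

The covariate CSV schema (one row per recording) is: `source_id`,
`site_name`, `year`, `month`, `day`, `hour`, `water_temp_c`,
`acoustic_richness`, and `vessel_density_{total,trade,fishing,recreational,passenger,other}`
(AIS traffic, hours·km⁻²·month⁻¹). `model_table.csv` joins these with the
per-sequence rhythm statistics and is the ready-made input for downstream
regression modeling (e.g. a GAM of beat on season and noise covariates),
which is outside this package's scope.

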