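# kinevar

Movement scientists quantify *motor variability* not only by how much a
body segment fluctuates, but by how those fluctuations are organised in
time. `kinevar` implements that analysis for 3D kinematic sensor traces
(e.g., electromagnetic tracking of the hand during static postures and
slow tracking movements): it reduces each trial to a scalar
resultant-distance series and reports the **amount** of variability (SD)
and its **structure** (fuzzy entropy and the DFA scaling exponent),
together with the repeated-measures statistics used to compare task
conditions and sensor sites. A synthetic-trial generator with known
statistical structure (fractional Gaussian noise, sinusoid/noise
mixtures, simulated task conditions) makes every stage verifiable
without access to laboratory data.

## The measures

For one trial with axis traces $x_n, y_n, z_n$ (cm, $n = 1..N$), all
metrics operate on the resultant distance from the trial-mean position:

$$RD_n = \sqrt{(x_n-\bar{x})^2 + (y_n-\bar{y})^2 + (z_n-\bar{z})^2}$$

computed after down-sampling 240 → 100 Hz (anti-aliased, polyphase),
zero-phase 1 Hz high-pass filtering (removes the voluntary movement of
the dynamic tasks), and a central trim to $N = 2000$ samples.

* **SD** — sample standard deviation of $RD$ (cm): the amount of
  variability.
* **Fuzzy entropy** ($m = 2$, $r = 0.2 \cdot SD$, gradient $n = 2$) —
  regularity: the negative log conditional probability that length-$m$
  templates similar within tolerance $r$ (graded by
  $\exp(-d^n/r)$ on the SD-standardised series, Chebyshev distance,
  template means removed, self-matches excluded) remain similar at
  length $m+1$. Lower = more regular.
* **DFA $\alpha$** — long-range correlation: the slope of
  $\log F(n)$ vs $\log n$ for window sizes $4 \le n \le N/10$, where
  $F(n)$ is the RMS fluctuation of the integrated series around
  per-window linear trends. $\alpha = 0.5$ uncorrelated, $> 0.5$
  persistent, $< 0.5$ anti-persistent; fractional Gaussian noise with
  Hurst exponent $H$ yields $\alpha \approx H$, which is the package's
  calibration anchor.

Per-condition cell means (participants × conditions) feed a one-way
repeated-measures ANOVA with partial $\eta_p^2$, Lilliefors normality
screening (Monte-Carlo null), and Bonferroni-corrected pairwise paired
t-tests.

## Worked example

Simulate a small study (6 participants, 2 trials per condition) and run
the full pipeline:

```python
from kinevar import RunConfig, run_study

result = run_study(RunConfig(seed=7), simulate=True,
                   n_participants=6, trials_per_condition=2,
                   outdir="demo")
hand = result.summary[result.summary["site"] == "Hand"]
print(hand.pivot(index="metric", columns="condition", values="mean")
      [["HoS", "ARelax", "A90", "UpDown", "Circle"]].round(3))
```

prints

```
condition    HoS  ARelax    A90  UpDown  Circle
metric
alpha      0.533   0.528  0.535   1.552   1.139
fe         1.363   1.368  1.359   0.084   0.659
sd         0.002   0.005  0.005   0.277   0.074
```

The three static postures (HoS, ARelax, A90) carry low-amplitude,
near-uncorrelated positional noise: small SD, irregular structure
(FE ≈ 1.4), $\alpha \approx 0.5$. The two tracking tasks (UpDown,
Circle) show the direction the method is built to detect: more
variability, far more regular short-term structure (the residual of the
slow voluntary oscillation), and strong long-range persistence. The
condition effect is confirmed inferentially, e.g. for SD:

```
F(4,20) = 29875.48, p = 1.9e-37, partial eta^2 = 1.000
```

The same analysis runs from the shell on directories of trial CSVs
(`t,x,y,z` per sample):

```bash
kinevar run --simulate --seed 7 --participants 6 --trials 2 --out demo
kinevar simulate --seed 7 --out trials/   # or stage by stage
kinevar preprocess trials/ --out rd/
kinevar metrics rd/ --out metrics.csv
kinevar stats metrics.csv --out report/
```

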