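# apcmort

Bayesian age-period-cohort (APC) analysis of perinatal mortality
disparities between white-collar and blue-collar workers in Japan,
1995-2015.

## The problem

Japanese vital statistics report perinatal deaths (fetal deaths after the
22nd week of pregnancy plus neonatal deaths within one week of birth) and
births by maternal occupation every five years. Aggregating occupations
into a white-collar / blue-collar dichotomy yields a Lexis table of counts
over 7 five-year maternal age groups (15-19 … 45-49) and 5 periods
(1995 … 2015), whose diagonals are 11 maternal birth cohorts (1946-1950 …
1996-2000). The question is how the mortality gap between the two worker
classes is structured over age, period, and cohort.

`apcmort` implements the full analysis pipeline for such data:

* **descriptive** — crude rates per 1,000 of (births + deaths), and direct
  age standardization with the combined 1995 exposure distribution as the
  standard population;
* **model** — a Bayesian Poisson APC model fitted jointly to both strata:

  D[w,a,p] ~ Poisson(n[w,a,p] · λ_w(a,p)),
  log λ_w(a,p) = μ_w + α_w[a] + β_w[p] + γ_w[k],  k = p − a + 6,

  with sum-to-zero constraints Σα = Σβ = Σγ = 0 per stratum, first-order
  random-walk (RW1) smoothing priors on each effect vector, half-normal(0,1)
  hyperpriors on the RW scales, and N(0, 10²) on the intercepts. Sampling
  uses a purpose-built MCMC scheme (Laplace independence-MH block updates
  interwoven with centered/non-centered conditional scale updates) with
  split-R̂ / ESS convergence checks;
* **selection** — DIC comparison across the seven admissible effect subsets
  {A, P, C, AP, AC, PC, APC};
* **disparity** — draw-wise posterior blue/white rate ratios
  RR[level] = exp((μ_B + e_B[level]) − (μ_W + e_W[level])) with equal-tailed
  95% credible intervals;
* **simulate** — a synthetic-table generator with known APC structure for
  parameter-recovery and coverage experiments.

The published counts ship with the package
(`src/apcmort/fixtures/perinatal_counts_japan_1995_2015.csv`).

## Worked example

```python
import apcmort as am
from apcmort.disparity import rate_ratio_summary

table = am.load_bundled()

# crude + age-standardized rates
rt = am.rate_table(table)
print(rt.to_frame().head(2).to_string(index=False))

# joint age-cohort fit and the age-specific disparity
draws = am.fit(table, am.ModelSpec.from_code("ac"), am.MCMCConfig(seed=1))
print(rate_ratio_summary(draws, "age").round(2).to_string(index=False))
```

prints (abridged):

```
 worker_type  year  15-19  20-24  25-29  30-34  35-39  40-44  45-49  age_standardized
white_collar  1995   19.7    9.1    6.1    6.2    9.0   12.1   29.4               6.9
white_collar  2000   20.8    7.3    5.0    5.0    5.4   12.2   24.1               5.5

dimension level  median  lower  upper  excludes_one
      age 15-19    0.58   0.26   1.37         False
      age 20-24    0.83   0.62   1.13         False
      age 25-29    1.49   1.17   1.92          True
      age 30-34    1.34   1.04   1.74          True
      age 35-39    1.70   1.30   2.23          True
      age 40-44    2.08   1.44   2.92          True
      age 45-49    2.80   1.10   7.78          True
```

The first block is the descriptive table: e.g. white-collar mothers aged
15-19 in 1995 had 19.7 perinatal deaths per 1,000, and 6.9 per 1,000 after
age standardization. The second block is the core result: the blue/white
rate ratio rises from below 1 at the youngest ages to 2.1 (95% CrI
1.4-2.9) at 40-44, with the interval excluding 1 from age 25-29 onward —
the disparity grows markedly with maternal age.

The command line mirrors the library:

```bash
apcmort describe                  # descriptive rates
apcmort compare                   # DIC over the seven models (AC wins)
apcmort fit --model ac --seed 1   # posterior summaries + draws
apcmort disparity --model ac      # blue/white rate ratios
apcmort reproduce --seed 1 --out out/   # Table2-Table5 + diagnostics
```

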