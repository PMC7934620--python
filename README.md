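# sfsi — soil fertility susceptibility analysis for crop trials

`sfsi` is a Python package for screening crop genotypes for tolerance to low
soil fertility from two-treatment field trials. It was built around a
published two-year split-plot trial of 21 white Guinea yam (*Dioscorea
rotundata*) genotypes — 20 breeding lines plus the landrace check "Amula" —
grown under unfertilized, nutrient-depleted soil (LF) and NPK-fertilized soil
(HF) at Ibadan, Nigeria; the trial's genotype-mean tables are packaged as
reference data. The same pipeline applies to any crop trial that contrasts a
stressed and a non-stressed treatment.

For a genotype with mean trait values x̄_lf and x̄_hf under the two
treatments, the package computes the percent reduction, the trial-level
stress (soil fertility) intensity, and the Fischer–Maurer-type soil fertility
susceptibility index:

```
PR   = (x̄_hf − x̄_lf) / x̄_hf × 100
SI   = 1 − Ȳ_lf / Ȳ_hf            (grand means over genotypes)
SFSI = (1 − x̄_lf / x̄_hf) / SI
```

SFSI < 1 marks a genotype that loses proportionally less than the trial
average under stress; SFSI > 1 marks above-average susceptibility. Genotypes
are classified against the check: *tolerant* if their SFSI is below the
check's and their reduction is below the table average, *susceptible* if
SFSI ≥ 1.25 (configurable). Supporting statistics — the split-plot linear
mixed model with Wald chi-square analysis of deviance, per-genotype Welch
t-tests of LF vs HF, Dunnett many-to-one comparisons against the check, and
Pearson correlations between traits — live in `sfsi.inference` and
`sfsi.indices`. A synthetic split-plot trial generator with analytically
known truth (`sfsi.synthetic_trial`) supports validation and power/recovery
experiments.

## Worked example

Compute the index table for the packaged tuber-yield reference data:

```bash
sfsi compute --fixture tuber_yield --out demo
```

prints (abridged):

```json
{
 "traits": {
  "tuber_yield": {
   "si": 0.5191958191643176,
   "mean_sfsi": 0.9791746411532504,
   "sfsi_min": 0.6432895678559625,
   "sfsi_max": 1.3437704508541022,
   "tolerant": ["R034", "R041", "R050", "R052", "R060", "R100", "R125"],
   "susceptible": ["R109", "R119", "R131"]
  }
 }
}
```

SI = 0.519 means the unfertilized treatment cut mean tuber yield by 51.9%
across the trial. `demo/index_tuber_yield.csv` holds the per-genotype table
(sorted by SFSI, with a Mean row):

```
genotype,x_lf,x_hf,pr_percent,sfsi
R125,908.3,1363.8,33.4,0.64
R052,1034.6,1604.2,35.5,0.68
...
R119,755.8,2500.0,69.8,1.34
Mean,850.4,1768.6,50.8,0.98
```

R125 loses only 33.4% of its yield without fertilizer (SFSI 0.64, the most
tolerant entry), while R119 loses 69.8% (SFSI 1.34). The seven entries with
SFSI below the check's 0.87 and below-average reduction are the low-fertility
tolerant selections; the three entries with SFSI ≥ 1.25 are susceptible but
strongly fertilizer-responsive.

The same API is available as a library:

```python
from sfsi import load_reference_means, compute_sfsi_table, classify_tolerance

idx = compute_sfsi_table(load_reference_means("tuber_yield"))
report = classify_tolerance(idx, check_id="Local variety")
```

Other CLI verbs: `sfsi compute <trial.csv> --trait <name> --check <id>` for
your own plot-level data (adds the mixed-model deviance table, Welch tests
and Dunnett comparisons), `sfsi simulate` / `sfsi recover` for synthetic
trials and SFSI recovery experiments, and `sfsi reproduce-reference` (below).

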