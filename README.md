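# cjsdecline

Estimating the decline of species populations from dated occurrence records —
museum specimens, literature citations, field observations — is confounded by
imperfect and time-varying recording effort: a locality without recent records
may be extinct, or merely unvisited. `cjsdecline` treats the *localities* of a
species as the individuals of an open-population capture-recapture study.
Record years are binned into decade occasions, each locality yields a binary
detection history, and a Cormack-Jolly-Seber (CJS) model estimates, per
decade,

- **population persistence** Phi — the probability that an extant local
  population survives to the next decade, and
- **population detectability** p — the probability that an extant population
  is recorded at least once in a decade,

separating real population loss from changes in recording intensity, which
the naive cumulative-locality curve (also provided) cannot do. The package
was built for long-run occurrence databases of declining grassland insects,
but applies to any species-locality-year table.

## The model

The CJS likelihood conditions on each locality's first detection. A history
first detected at occasion *f* and last detected at *l* contributes

```
prod_{i=f}^{l-1} [ Phi_i * p_{i+1}^{y_{i+1}} (1-p_{i+1})^{1-y_{i+1}} ] * chi_l
```

where `chi_i`, the probability of never being seen after occasion *i*,
satisfies `chi_T = 1`, `chi_i = 1 - Phi_i (1 - (1-p_{i+1}) chi_{i+1})`.
Internally the data are reduced to the m-array (released at *i*, next
recaptured at *j*) whose multinomial likelihood is identical and cheap to
evaluate, with an analytic gradient.

Both parameters take a logit link with constant (`.`), linear (`Time`),
quadratic (`Time^2`) or fully time-dependent (`t`) structure — MARK's
notation. Candidate models (by default all 16 crossings) are ranked by the
small-sample-corrected AIC,
`AICc = -2lnL + 2K + 2K(K+1)/(n_eff - K - 1)`, with delta-AICc and Akaike
weights; `n_eff` is the number of release events. When both parameters are
fully time-dependent the terminal `Phi_{T-1}` and `p_T` are confounded and
only their product is estimable; `K` accounts for this and the product is
reported as a single derived quantity.

A synthetic-data module simulates the whole system — staggered locality
entry, absorbing extinction, imperfect detection, record counts per decade —
so every stage is testable end to end and parameter recovery is measurable.

## Worked example

```python
import numpy as np
from cjsdecline import (
    generate_study, default_study_configs, filter_by_years, summarize,
    build_detection_histories, model_selection, persistence_over,
)

records, truth = generate_study(default_study_configs(7), seed=7)
records = filter_by_years(records, 1900, 2019)
counts = summarize(records)
print(f"{counts.n_records} dated records at {counts.n_localities} localities")

notata = records.subset(records.frame["species"] == "Jordanita notata")
hist = build_detection_histories(notata)          # 12 decade occasions
table = model_selection(
    hist, [(".", "."), (".", "Time"), (".", "Time^2"), ("Time", ".")],
    seed=np.random.default_rng(7),
)
print(table.to_markdown())
best = table.best
print(f"best: {best.spec.name}, phi = {best.phi_hat[0]:.2f}")
print(f"10-decade persistence: {persistence_over(best.phi_hat[0], 10):.1e}")
```

prints

```
3132 dated records at 1635 localities
| Model | Parameters | -2lnL | AICc | deltaAICc | Weight |
|---|---|---|---|---|---|
| Phi(.)p(.) | 2 | 329.57 | 333.60 | 0.00 | 0.40 |
| Phi(Time)p(.) | 3 | 327.93 | 334.01 | 0.40 | 0.33 |
| Phi(.)p(Time) | 3 | 329.14 | 335.21 | 1.61 | 0.18 |
| Phi(.)p(Time^2) | 4 | 328.30 | 336.42 | 2.82 | 0.10 |
best: Phi(.)p(.), phi = 0.46
10-decade persistence: 4.3e-04
```

For this simulated species the most parsimonious model has constant
persistence 0.46 per decade: fewer than one locality in a thousand keeps its
population over a century. The model table mirrors the standard MARK layout;
weights quantify relative support within the candidate set.

The same pipeline runs from the shell on any delimited species/locality/
country/year table:

```sh
cjsdecline simulate --seed 3 --out study.csv
cjsdecline summarize study.csv
cjsdecline curves study.csv
cjsdecline run --input study.csv --out results/
```

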