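# schoolfeed

An individual-based simulator of feeding competition and growth in an
aquaculture tank. A school of rainbow trout is modeled as boid-style
agents in a cylindrical tank (3.0 m diameter, 1.5 m deep); once per day a
ration of sinking feed pellets is scattered over a square at the water
surface, each fish's intake emerges from the behavioral scramble for those
pellets, and intake drives body-mass growth over a 90-day rearing period.
The tool is for aquaculture researchers and farm planners who want to
compare feeding strategies — here, the size of the feed-distribution area —
without running a months-long rearing trial.

## Model in brief

Each fish obeys Newtonian motion `W·a = ΣFₙ` (semi-implicit Euler,
Δt = 0.025 s) under six unit-magnitude steering rules — separation (w₁=0.6),
cohesion (w₂=0.4), alignment (w₃=0.4), boundary avoidance (w₄=1.0), feed
attraction (w₅=3.0 while hungry and feed is present, else 0), and a random
wander (w₆=0.2) — with perception limited to a sphere of radius 2·TL minus
a 30° rear blind cone. Speed is capped at `Cᵥ·TL` (1.5 s⁻¹ cruising,
7.0 s⁻¹ feeding), so larger fish are faster. A fish eats a pellet on
contact until its daily satiation cap Smax = 0.04·W; daily growth is
ΔW = S·FCE with FCE = 1, and length follows the allometry
`W = 0.0209·TL^2.843` (g, cm). The daily ration is 1.86% of school
biomass as 0.065 g pellets; feeding squares of side 1.5 / 1.0 / 0.5 m are
methods A / B / C.

The headline phenomenon: narrower feeding squares leave mean growth
essentially unchanged but inflate the variance and right-skew of final
body mass, because fast (large) first arrivals dominate a small feed patch
and compound their advantage day after day.

## Worked example

```python
import numpy as np
from scipy import stats as sps
from schoolfeed import ExperimentConfig, run_methods_comparison, summarize_masses

cfg = ExperimentConfig(rng_seed=1)          # 100 fish at 38.53 g, 90 days
results = run_methods_comparison(cfg, ("A", "B", "C"), master_seed=1)
vectors = [r.masses_on(90) for r in results]
for name, m in zip("ABC", vectors):
    print(summarize_masses(m, name))
print("Bartlett p =", sps.bartlett(*vectors).pvalue)
```

prints

```
A: mean 202.3 g, SD 27.4 g, skewness 0.688 (n=100)
B: mean 202.3 g, SD 43.5 g, skewness 1.058 (n=100)
C: mean 202.3 g, SD 78.6 g, skewness 1.314 (n=100)
Bartlett p = 1.9424224929821257e-23
```

All three methods reach the same mean — every pellet is eventually eaten,
and with a ration of 1.86% of current biomass at FCE = 1 the mean is
pinned at the compound-growth ceiling 38.53·1.0186⁹⁰ ≈ 202.4 g — but the
spread and skew of the final masses grow sharply as the feeding square
narrows (A → C), and Bartlett's test rejects equal variances decisively.
The per-day, per-fish history behind these numbers is in each result's
`ledger` (a pandas DataFrame: day, fish_id, mass_g, total_length_cm,
intake_g, pellets).

The same experiment from the shell:

```bash
schoolfeed compare --methods A,B,C --seed 1 --outdir out/
schoolfeed run --method C --days 90 --seed 7 --randomize-daily --fast
schoolfeed summarize out/ledger_A_rep0.csv out/ledger_C_rep0.csv
```

Every output directory contains a `manifest.json` (config, seed, version)
sufficient to reproduce the run byte-for-byte.

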