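# c14pop

Demographic inference from radiocarbon date densities.

Archaeologists use the density of ¹⁴C dates through time as a relative
proxy for past population size: more people leave more datable contexts.
`c14pop` implements the full inferential pipeline around that proxy:

- **Calibration** of conventional radiocarbon ages (CRA ± 1σ) into
  probability distributions over calendar years BP, by direct numerical
  integration against a calibration curve (IntCal plain-text files are read
  natively):
  `p(t) ∝ φ(y; μ(t), √(σ_lab² + σ_curve(t)²))`.
- **Summed probability distributions (SPDs)** with site-level binning:
  within each site, dates are clustered on their CRAs by complete linkage
  cut at `h = 200` ¹⁴C yr, and each bin contributes the pooled mean of its
  members' calibrated densities — correcting the over-representation of
  intensively dated sites.
- **Null-model envelope tests**: the observed SPD is compared against
  uniform or exponential nulls via Monte-Carlo back-calibration — calendar
  years drawn from the fitted null are pushed back through the curve into
  synthetic CRAs, recalibrated and summed.  Per-year z-scores against the
  simulations give a 95% envelope for local deviations; the total area
  outside the envelope gives a global p-value with the (s+1)/(n+1)
  correction.
- **A bin-label permutation test** for comparing the SPD *shapes* of two or
  more regions: whole bins are randomly reassigned to regions (preserving
  each region's bin count), which is insensitive to differences in research
  intensity between regions.
- **Synthetic data generation** from known demographies (uniform,
  exponential, rise-and-fall, custom) so every stage is testable with a
  known ground truth and no downloads.

## Worked example

Simulate two regions sharing a rise-and-fall demography over 7,000–3,000
cal BP, carve a 500-year gap (5,500–5,000 cal BP) out of region B, and ask
the permutation test whether the regions diverge:

```python
import numpy as np
from c14pop import (DemographicCurve, perm_test, toy_wiggly_curve,
                    two_region_scenario)

curve = toy_wiggly_curve(8000, 2000)          # IntCal-like toy curve
shared = DemographicCurve("rise_fall", (7000, 3000))
a, b = two_region_scenario(shared,
                           {"window": (5500, 5000), "multiplier": 0.0},
                           n_per_region=400, calcurve=curve,
                           sites_per_region=40, seed=10)
res = perm_test(a + b, curve, nsim=500, seed=11)
print("p(B) =", res.sets["B"].pvalue)
print("negative intervals for B:", res.sets["B"].neg_intervals[:2])
```

Output:

```
p(B) = 0.001996007984031936
negative intervals for B: [(5455.0, 5007.0)]
```

Region B's SPD shape diverges globally (p ≈ 0.002, the smallest value
nsim = 500 permutations can resolve is 1/501), and the significant negative
interval 5,455–5,007 cal BP recovers the carved gap.  The same dates tested
individually against a uniform null (`model_test(..., kind="uniform")`)
reject as well, flagging the tent peak as a positive deviation.

The `c14pop` command exposes the same stages on files:

```sh
c14pop simulate  --curve intcal13.14c --kind rise_fall --n 400 --seed 1 --out dates.csv
c14pop spd       --curve intcal13.14c --dates dates.csv --outdir out/
c14pop modeltest --curve intcal13.14c --dates dates.csv --model exponential \
                 --nsim 10000 --range 7000 3000 --seed 1 --outdir out/
c14pop permtest  --curve intcal13.14c --dates dates.csv --nsim 10000 --seed 1 --outdir out/
```

Every run writes a `manifest.json` echoing the resolved configuration;
identical config + seed reproduces byte-identical outputs.

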