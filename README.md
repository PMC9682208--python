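# matefit

Sex-specific selection analysis for competitive mating assays in a
flour-beetle-style experimental design. Given a tidy per-focal fitness table
(or a built-in synthetic generator), the package estimates:

* **selection coefficients** against diet-stressed individuals,
  `s = 1 − mean(W_stressed) / mean(W_control)`, with percentile-bootstrap
  confidence intervals and a stratified permutation test for the sex
  difference in `s`;
* the **opportunity for selection** `I`, the sample variance of relativized
  reproductive success (values divided by the cell mean), with bootstrap CIs;
* the **variance decomposition of male reproductive success** into genetic
  mating success (MS), partner fecundity (Fec) and paternity share (PS):
  variances, pairwise covariances and an explicit higher-order remainder that
  sum *exactly* to the male `I_total`;
* conventional **GLM treatment contrasts** (Gaussian body mass, quasi-Poisson
  offspring and mating-success counts) with Benjamini–Hochberg FDR
  adjustment, and Yates-corrected chi-squared mortality tests.

A synthetic-data module emulates the mating-group design (1 focal + 1 marked
competitor + 2 partner females per group; two assay variants, focal-only
treated vs whole-group treated; negative-binomial fecundity, mating failure,
beta-binomial competitive paternity, treatment effects on body mass and
female mortality), so every stage runs and is tested without external data.

## Data format

One CSV row per focal individual:

```
focal_id,sex,flour,yeast,assay,genotype,body_mass_mg,survived,
p1_total,p1_sired,p2_total,p2_sired,laying_week
```

* `sex`: `male|female`; `flour`: `wheat|whole_wheat`;
  `yeast`: `control_5pct|low_1pct|none` (`low_1pct` only with whole-wheat);
  `assay`: `focal_only|whole_group`.
* Males: `p{j}_total` is partner *j*'s total adult offspring, `p{j}_sired`
  the offspring assigned to the focal by the dominant marker
  (`sired ≤ total`). A totals-only dialect (all `p*_total` empty,
  `p1_sired` = total sired) is accepted; the decomposition is then disabled.
* Females: own clutch in `p1_total` with `p1_sired = p1_total`, `p2_*` empty.
* Dead females keep their observed counts (`survived=false`) and are included
  in fitness analyses by default (`--exclude-dead` to drop them).

## CLI

```bash
# synthetic dataset (defaults, or --params params.yaml)
matefit simulate --out data.csv --seed 1

# full pipeline: selection_coefficients.csv, opportunity.csv,
# decomposition.csv, glm_contrasts.csv, mortality.csv, run_manifest.json
matefit analyze --input data.csv --out results/ --seed 1
matefit analyze --simulate --out results/ --n-boot 10000 --n-perm 10000

# schema/invariant validation with a per-row violation report
matefit validate data.csv
```

Runs are deterministic given `(config, seed)`: every analysis cell draws from
its own labelled substream, so adding a cell never perturbs another's draws.

## Library

```python
from matefit import (
    SimulationParams, simulate_both_assays,
    estimate_selection, estimate_opportunity, sex_difference_in_s,
    decompose, bootstrap, permutation_test,
)

ds = simulate_both_assays(SimulationParams(seed=1))
est = estimate_selection(ds, "focal_only", "female", "wheat", "none", seed=1)
dec = decompose(ds.select(assay="whole_group", sex="male",
                          flour="wheat", yeast="none"), seed=1)
```

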