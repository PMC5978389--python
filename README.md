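# oefish

Observed/expected (O/E) biomonitoring for riverine fish assemblages.

River managers need to know not just *which* fish are in a reach, but which
fish *should* be there.  `oefish` builds that benchmark: it fits one boosted
regression tree (BRT) per species to presence/absence survey records,
converts predicted capture probabilities into presence calls with
Kappa-optimal thresholds, predicts each reach's assemblage twice — under
current covariates and under a declared near-natural *reference condition*
(full native cover, no pasture, pre-human riparian shade, nutrients capped
at 0.11 mg/L nitrate-N and 0.006 mg/L DRP) — and scores every reach with

    O/E = |current ∩ reference assemblage| / |reference assemblage|  ∈ [0, 1]

so that 1 means the reach still supports the species expected under
near-natural conditions.  A second BRT then attributes O/E deviations to
anthropogenic pressures (nutrients, downstream dams, riparian loss, exotic
species), and an NMDS ordinates species by their influential environmental
drivers.  Because the real survey databases are not redistributable, the
package ships a synthetic river-network generator with known ground truth,
so the entire pipeline is testable end to end.

The intended users are freshwater ecologists and biomonitoring teams who
have reach-scale environmental covariates and electric-fishing survey
records, and want a reproducible reference-condition index rather than a
raw richness count.

## Worked example

Run the full pipeline on the built-in demo world (2,000 reaches, 8 species
across an anthropogenic gradient; a few minutes on one CPU):

```bash
oefish demo --out demo_out --seed 42
```

which ends by printing the O/E stage summary:

```json
{
 "n_reaches": 1812,
 "n_defined": 1762,
 "mean_ratio": 0.7082292849035188
}
```

Of the 2,000 generated reaches, 1,812 fall in river classes with enough
survey sites to be predicted at all; 1,762 of those expect at least one
native species under reference conditions, and on average a reach retains
71% of its expected natives.  `demo_out/model_summary.csv` holds the
per-species fits:

```
species  native  cv_auc  n_trees  learning_rate  threshold  kappa
   sp01    True   0.916     1772          0.005      0.465  0.801
   sp02    True   0.972     1586          0.005      0.515  0.915
   sp03    True   0.907     1145          0.005      0.470  0.760
   sp04    True   0.989     1717          0.005      0.585  0.953
   sp05    True   0.958     1494          0.005      0.565  0.867
   sp06    True   0.973     1080          0.010      0.510  0.925
   sp07   False   0.916     1323          0.002      0.725  0.785
   sp08   False   0.992     1566          0.005      0.420  0.964
```

Every ensemble carries at least 1,000 trees (the learning rate is halved
from 0.01 until 10-fold cross-validation selects that many), cross-validated
AUC is 0.91–0.99, and each species gets its own Kappa-optimal presence
threshold.  `demo_out/attribution.json` reports how the pressure BRT
explains the O/E surface — here nutrient concentrations dominate, followed
by riparian loss, with exotic species nearly irrelevant:

```
cv_correlation: 0.654   (n = 1762 reaches)
relative influence (%):  no3n_mgl 39.7, rip_oe 31.5, drp_mgl 19.3,
                         ds_dam 5.0, exotic_sp08 4.2, exotic_sp07 0.2
```

The same stages are available individually (`oefish simulate`, `filter`,
`fit`, `threshold`, `oe`, `attribute`, `agree`, `nmds`, `run`) and as
library functions:

```python
from oefish import (SyntheticConfig, generate_reaches, make_truth,
                    apply_reference_transform, default_reference_scenario)

cfg = SyntheticConfig(n_reaches=500, n_sites=400, n_species=6, seed=1)
reaches = generate_reaches(cfg)
reference = apply_reference_transform(reaches, default_reference_scenario())
```

See `docs/methods.md` for the model details, the synthetic world's design,
and known limitations.

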