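# nicheshift

Climate-driven species distribution modeling for marine megafauna, built as a
tested, reusable pipeline: occurrence quality control → environmental variable
selection → presence/pseudoabsence ensemble niche models → climate-scenario
projection → range-change and hotspot accounting → conservation-gap overlay
against protected areas, economic zones, and vessel-traffic density.

The package targets conservation biogeographers who want the standard marine
SDM workflow — thin-plate occurrence cleaning, TSS-gated weighted ensembles,
threshold-optimized binary maps, protected-area gap analysis — as composable,
seed-reproducible Python functions rather than a GUI or an R monolith.  A
built-in synthetic-world generator produces environmental stacks, species with
known Gaussian niches, contaminated occurrence sets, zone masks, and shipping
lanes, so every stage of the pipeline can be validated against a known ground
truth at desk scale.

## The model

For each species, presences are modeled against `n` randomly placed
pseudoabsences (default 5000 × 3 replicates) with a small family of learners
(regularized logistic regression with quadratic terms, a rectilinear surface
range envelope, and gradient-boosted trees).  Each learner × replicate × fold
combination is evaluated on a stratified 25% hold-out by

- ROC AUC — the probability a random presence outscores a random pseudoabsence;
- TSS = sensitivity + specificity − 1, maximized over all candidate thresholds.

Members with held-out TSS > 0.75 form a committee with weights `w_i ∝ TSS_i`;
the ensemble suitability is `Σ w_i p_i(x)` and is binarized at its own
TSS-optimal threshold.  Projections onto warmed climate stacks yield
per-species counts of pixels lost / stable / gained, latitudinal density
profiles, and per-pixel net richness change.  Multi-species hotspots are cells
whose min-max-standardized summed suitability exceeds 0.80 (strict), and are
intersected with MPA masks, EEZ labels, and the above-mean square-root
vessel-density mask using exact spherical cell areas.

## Worked example

```python
from nicheshift import RunConfig, run_pipeline

cfg = RunConfig(seed=1)                      # default synthetic world
res = run_pipeline(cfg, write=False)

r = res.species["sp04"]
print(r.selected_variables[:2], round(r.ensemble_auc, 3), round(r.ensemble_tss, 3))
print(r.range_changes["SSP5-8.5_2100"])
print(round(res.overlaps["current"].total_km2), round(res.overlaps["current"].pct_protected, 1))
```

prints

```
['temperature', 'chlorophyll'] 0.984 0.895
RangeChange(n_lost=1551, n_stable=103, n_gained=1836, pct_loss=93.77...,
            pct_gain=111.00..., pct_net=17.23...)
2823752 9.8
```

meaning: for the fourth synthetic species the selector recovered the two true
niche drivers, the ensemble separated held-out presences from pseudoabsences
with AUC 0.984 and TSS 0.895; under the high-emission scenario for 2100 its
range turns over almost completely (94% of current cells lost, slightly more
gained poleward); and the current multi-species hotspots cover ≈2.8 million
km², of which 9.8% fall inside the synthetic MPA network (which covers 10% of
the sea — random placement buys no extra hotspot protection).

The same workflow is scriptable from a shell:

```bash
nicheshift run-all --seed 1 --out runs/demo
nicheshift simulate --seed 1 --out world/       # or stage by stage
nicheshift clean --occurrences world/occurrences_sp01.csv \
    --land world/land.asc --out clean_sp01.csv
```

Every run directory contains a `manifest.json` with the config echo, the root
seed, and SHA-256 checksums of all artifacts; rerunning with the same config
and seed reproduces it bit for bit.

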