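# polydomy

Nest-network analysis for polydomous wood ant colonies.

A single colony of *Formica lugubris* (and other red wood ants) often
occupies several spatially separated nest mounds connected by persistent
trails of workers. Treating the colony as a weighted graph — nests as
nodes, internest trails as edges, trails to aphid-bearing trees as the
nests' foraging activity — lets one ask whether food is redistributed by
a colony-level plan or by purely local exchange between neighbouring
nests. This package provides the full toolkit for that analysis, for
behavioural ecologists working from field maps of nests, trees and
trails, and for anyone who wants a calibrated synthetic testbed for
network-permutation inference.

## The model

Trail activity is measured as the distance needed to count 10 ants,
giving a density *w* (ants·m⁻¹). The strength of the internest trail
between nests *a* and *b* of length *l* is the per-capita flow

    S_ab = w · l / p̄_ab,

where *p̄* is the mean worker population of the two nests. A nest→tree
trail qualifies as a clear foraging trail if *w* > 25 ants·m⁻¹ (more
than 10 ants in 40 cm); its strength is *w·l* divided by the origin
nest's population, and a nest's **amount of foraging** is the sum of its
qualifying foraging-trail strengths. Nests with no qualifying trail are
**nonforaging**, splitting internest trails into F-F, nF-F and nF-nF
categories; the **foraging differential** of a trail is the absolute
difference in amount of foraging between its endpoints.

Populations come from mound volume (half an ellipsoid, π·d₁·d₂·h/6)
through a site calibration regression against mark–release–recapture
counts; canopy cover is the dark-pixel fraction of an 8-bit vertical
photograph.

On top of this sit weighted network metrics (degree, node/trail
betweenness, closeness, Newman's assortativity coefficient *r*) and QAP
permutation inference: node labels are shuffled within each colony while
the trail structure stays fixed, derived quantities are recomputed per
permutation, and p = (1 + #extreme)/(1 + N).

## Worked example

```python
import polydomy as pm

net = pm.example_colony()          # 7 nests, 6 trails, 1 nonforaging nest
pm.compute_all(net)
print(pm.summarize_colony(net))    # (7, 6, 6, 1)

r = pm.degree_correlation(pm.to_graph(net), weighted=True)
print(round(r.r, 3), r.n_edges)    # -0.44 6
```

The summary row reads: 7 nests, 6 internest trails, 6 foraged trees, 1
nonforaging nest. The weighted degree correlation of −0.44 says that in
this tiny colony strongly connected nests attach to weakly connected
ones (the chain ends), not to each other.

A full synthetic study and test battery
(`python examples/03_synthetic_study_qap.py`) generates 10 colonies with
a planted differential–strength coupling of 0.36 on nF-F trails and
prints, among others:

```
differential_vs_strength_nF-F    0.3600   0.5848   95
length_by_trail_type             6.8058   0.0020  189
population_by_foraging_status   11.3887   0.0020  152
```

— the planted coupling is recovered exactly as the observed pooled
correlation, foraging nests are detectably larger, and F-F trails are
detectably longer, each with a within-colony QAP p-value. The
`examples/` directory holds one short script per capability.

A thin CLI wraps the same API: `polydomy generate`, `polydomy analyze`,
`polydomy report`.

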