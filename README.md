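# connectotopo

Graph-theoretic analysis of resting-state functional brain networks, built
for studies that compare network topology between a patient group and
controls — the motivating case being type 2 diabetes patients without
cognitive impairment versus matched healthy controls (12 vs 24 subjects,
90-region AAL parcellation).

The package covers the full analysis chain on parcel time series:

1. **Conditioning** — discard initial volumes, linear detrend, zero-phase
   Butterworth band-pass (0.01–0.08 Hz), nuisance regression.
2. **Network construction** — Pearson correlation between every pair of
   region signals, binarised by *sparsity*: at sparsity S the strongest
   round(S·n(n−1)/2) edges are kept, swept over S = 0.10–0.34 (step 0.01).
3. **Metrics** — per graph: clustering coefficient C_p, characteristic
   path length L_p, global/local efficiency E_glob/E_loc, and the
   small-world indices γ = C_p/⟨C_p^rand⟩, λ = L_p/⟨L_p^rand⟩, σ = γ/λ
   against degree-preserving rewired ensembles; nodal degree, nodal
   efficiency and normalised betweenness. Each metric curve is condensed
   to its trapezoidal area under the curve (AUC) over the sweep.
4. **Inference** — one-tailed randomised-reallocation permutation tests on
   AUCs (95th-percentile critical value, +1-corrected p-values); the
   network-based statistic (NBS: edge-wise two-sample t on Fisher-z
   correlations, primary threshold T, permutation null for the largest
   suprathreshold component, optional region mask); Euclidean-distance
   classification of connections (long-range > 75 mm); and
   confounder-adjusted regression of cognitive scores on network metrics.
5. **Synthetic ground truth** — a first-class generator producing
   two-group band-limited signals over a small-world substrate with a
   connected subnetwork of weakened couplings in the patient group, so
   every stage is testable end-to-end with known answers.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_group_inference_nbs.py` (a 13-edge lesion implanted at
correlation effect 0.4, 12 patients vs 24 controls) prints:

```
E_glob AUC: controls 0.1416 vs patients 0.1416
  one-tailed permutation p = 0.4872 (critical diff 0.0001, reject=False)
NBS component: 13 edges on 9 regions, p = 0.0005, contains 13/13 implanted edges
```

The two lines summarise the method's behaviour at this design: a compact
13-edge lesion is invisible to a global summary metric (global-efficiency
AUCs agree to four decimals), while the network-based statistic restricted
to the affected regions recovers the implanted subnetwork exactly, with a
family-wise-corrected p of 0.0005.

The library is the primary interface; a thin CLI mirrors the stages
(`connectotopo simulate | preprocess | build | stats | nbs |
classify-edges | run`), with `connectotopo run --config cfg.yaml`
executing the whole pipeline and writing a manifest with checksums for
reproducibility.

## Documentation

`docs/methods.md` describes the generative model, every convention and
default (disconnected-graph handling, edge ranking, rounding, the random
ensemble), and a power analysis explaining when the network-based
statistic can and cannot recover a small lesion at this study scale.
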