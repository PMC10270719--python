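# connectoloop

Persistent-homology loop analysis of functional-connectome time courses.

Resting-state fMRI connectivity is usually modelled as a graph of pairwise
correlations, which cannot express *high-order* interaction structure: three
or more brain regions that synchronize in pairs around a closed cycle while
the interior of the cycle stays weakly connected. `connectoloop` detects
exactly those structures. For each subject it:

1. maps regional time courses to a point cloud with the correlation
   distance d(X, Y) = √((1 − r(X, Y)) / 2), where r is the Pearson
   correlation between the two signals (so r = 1 ↦ 0 and r = −1 ↦ 1);
2. builds the Vietoris–Rips filtration on that metric (a k-simplex enters
   at the scale ε at which its vertices are pairwise within ε);
3. computes persistent homology in dimensions 0 and 1 over the two-element
   field GF(2) by boundary-matrix column reduction, keeping for every
   finite H₁ bar a representative cycle: an even-degree edge set through
   the bar's birth edge;
4. selects the most persistent H₁ bar (largest death − birth, called the
   bar's *longitude*) and reports the brain regions on its boundary;

and across a cohort it aggregates the per-subject records into a
loop-length histogram, an enhanced persistence diagram (one point per
subject, annotated with the loop's region count), and a region-occurrence
frequency table.

A synthetic-cohort generator plants circular synchronization structure
(phase-shifted cosine oscillators on a circle) whose σ = 0 persistence is
solvable in closed form, so every stage of the pipeline is verifiable
without fMRI data. It is intended for methods developers and
connectomics researchers who want a tested, deterministic, pure-Python
reference implementation of the loop analysis.

## Worked example

Generate one synthetic subject with a planted 6-region loop among 16
regions and run the per-subject pipeline:

```python
from connectoloop import SynthConfig, generate_subject, subject_pipeline

cfg = SynthConfig(n_regions=16, n_timepoints=255, loop_size=6,
                  noise_sigma=0.2, seed=7)
tc = generate_subject(cfg, subject_seed=0)
feat = subject_pipeline(tc, "sub-000")
print(f"longest H1 bar: birth={feat.bar.birth:.4f} death={feat.bar.death:.4f} "
      f"persistence={feat.bar.longitude:.4f}")
print(f"loop regions ({feat.n_regions}):", ", ".join(feat.regions))
```

prints

```
longest H1 bar: birth=0.5330 death=0.7015 persistence=0.1685
loop regions (6): lh-bankssts, lh-caudalanteriorcingulate, lh-caudalmiddlefrontal, lh-cuneus, lh-entorhinal, lh-fusiform
```

The loop is *born* at ε ≈ 0.53 — the scale at which its weakest pairwise
synchronization enters the complex — and *dies* at ε ≈ 0.70 when triangles
fill the enclosed hole. The persistence 0.17 means the hole survives 17%
of the normalized [0, 1] scale range, and the six reported regions are
exactly the planted oscillators (the first six Desikan–Killiany labels by
default).

The same pipeline runs from the shell on directories of subjects:

```sh
connectoloop simulate --subjects 20 --regions 32 --loop-size 8 --seed 7 --out cohort/
connectoloop run --in cohort/ --out results/
```

`results/` then holds per-subject barcode CSVs, `cycles.json` with each
subject's longest-loop record, `features.csv`, and `summary/` with the
cohort tables (`lengths.csv`, `diagram_points.csv`,
`region_frequency.csv`, `projection.csv`).

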