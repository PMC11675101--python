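# pmnet

Graph-theoretic analysis of parieto-premotor structural connectomes.

`pmnet` turns per-subject probabilistic tractography matrices — directed
ROI×ROI streamline counts between 23 posterior-parietal and 14 premotor
cortical areas per hemisphere — into the standard battery of weighted
network statistics used to characterize fronto-parietal circuitry:
multi-threshold graph admission, shortest-path connectivity ranking, a
two-stage hub taxonomy, and edge-wise hemispheric lateralization tests.
A seeded synthetic-cohort generator with planted modules, hubs and
left/right asymmetries makes every stage testable without imaging data.

## The model

Raw counts are normalized per seed by the *waytotal* (total streamlines
drawn from that seed), then directionally averaged,

P_ij = (c_ij / w_i + c_ji / w_j) / 2,

yielding a weighted-undirected graph per subject.  Group graphs
(edgewise mean by default) are thresholded over t ∈ [0.01, 0.1] in steps
of 0.0025 (37 graphs per hemisphere) and each graph must pass three
goodness criteria to be admitted:

* **connectedness** — a single component spans all nodes;
* **modularity** — maximized Newman Q > 0.3, with
  Q = (1/2W) Σ_ij (w_ij − s_i s_j / 2W) δ(m_i, m_j),
  maximized by spectral bisection with Kernighan–Lin refinement;
* **small-worldness** — S = (C/C_rand)/(L/L_rand) > 1, where C is the
  mean binary clustering coefficient, L the characteristic path length,
  and the null values are means over 100 Maslov–Sneppen
  degree-preserving rewirings.

On the admitted graph of highest density, edge weights are inverted to
lengths (ℓ = 1/w) and all-pairs Dijkstra distances over the
parieto-premotor (bipartite) graph are ranked by 15/25/50/75th
percentile cutoffs.  Nodes are classified in two stages: connector hubs
(participation coefficient y_i = 1 − Σ_m (s_i(m)/s_i)² above the third
quartile at both the lowest and highest admitted threshold), provincial
hubs (within-module degree z-score z_i above Q3 at both endpoints),
then subtyped rich/rich-central/poor-central/poor by strength and
Brandes betweenness relative to the network median; nonhubs below the
first quartile in both are peripheral.  Each of the 322
parietal–premotor connections is finally compared between hemispheres
by a two-sided paired t test across subjects with Benjamini–Hochberg
FDR control (α = 0.05), and between-subject variability is summarized
by the coefficient of variation in quartile clusters A–D.

## Worked example

```bash
pmnet synth --out cohort --seed 7      # 40 subjects × 2 hemispheres × 37 ROIs
cat > config.yaml <<EOF
cohort_dir: cohort
outdir: out
seed: 7
EOF
pmnet run config.yaml
pmnet report out
```

prints

```
pmnet 0.1.0 run summary
  subjects: 40
  thresholds swept: 37
  left: admitted 6 thresholds [0.01, 0.0125, 0.015, 0.0175, 0.02, 0.0225]; analysis graph at 0.01
  right: admitted 6 thresholds [0.01, 0.0125, 0.015, 0.0175, 0.02, 0.0225]; analysis graph at 0.01
  lateralized edges (FDR-significant): 10 / 322
  left hub types: {'nonhub': 25, 'provincial': 8, 'connector': 4}
  right hub types: {'nonhub': 24, 'provincial': 8, 'connector': 5}
```

Six of the 37 thresholded graphs per hemisphere pass all three
admission criteria; the densest (t = 0.01) is used for distances and
stage-2 metrics.  The ten FDR-significant lateralized edges are exactly
the ten asymmetries the synthetic spec plants (δ = 2 on the left), and
the connector/provincial hub lists contain the planted hubs.  Output
CSVs in `out/` mirror the usual reporting layout: an admissibility
table per hemisphere, parietal×premotor distance and percentile-class
matrices, a node-role table with all raw metrics per admitted
threshold, the 322-row edge statistics table, CV/cluster matrices and a
JSON run manifest.

Real data can be analyzed the same way by laying out per-subject
matrix CSVs under `<cohort_dir>/left/` and `<cohort_dir>/right/` with a
`roi_metadata.csv` (columns `name,lobe,subdomain,hemisphere`) and a
`waytotals.csv` (columns `name,waytotal`); set `normalized: true` in
the config if matrices are already waytotal-normalized.

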