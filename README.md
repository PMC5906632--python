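# h33course

Temporal analysis of histone-variant **H3.3** deposition during a
bifurcating cell-fate transition.

When fibroblasts are pushed toward pluripotency (OSKM reprogramming), cells
split into a *successful* trajectory (Thy-1⁻ at days 6/9, SSEA-1⁺ at days
12/16, ending in iPSCs) and an *unsuccessful* one (Thy-1⁺ / SSEA-1⁻).  H3.3
is deposited replication-independently on active chromatin, so the **timing**
of its appearance on a gene is an early readout of fate commitment — often
preceding transcription of the same gene.  `h33course` provides the full
desk analysis for such a sorted ChIP/RNA/ATAC time course:

* **Region annotation** — strand-aware assignment of peaks to promoter
  (3 kb upstream of the TSS), genebody or intergenic space.
* **Quantification** — library-normalized tag counts over genes, FPKM,
  and boolean presence calls at fold-over-input ≥ 2 (with a configurable
  tag-density floor).
* **Onset classification** — the "D-onwards" rule: a gene is a *D-onwards*
  gene when enrichment is absent at day 0 and at every point before *D*, and
  present from *D* through the end of the course.  Genes already enriched at
  day 0 are *constitutive*; gained-then-lost patterns are *unsustained*.
  Expression onset uses FPKM > 1 (existential or sustained reading, both
  exposed).
* **Precedence** — per-gene lead of deposition onset over expression onset,
  in time-point steps.
* **Route-dependent clustering** — Clusters I–IV of differentially
  expressed genes from endpoint log2 fold changes on both routes
  (down-both, down-successful-only, up-both, up-successful-only).
* **Discovery** — top-*N* ranking by sharpest H3.3 loss, Venn intersection
  of gene sets, route-exclusive activator identification (H3.3 onset in the
  D6–D12 window, never enriched on the unsuccessful route, expression rising
  on the successful route only), and hypergeometric marker-set enrichment
  with Benjamini–Hochberg adjustment (score = −log10 p_adj, significant at
  ≥ 2).
* **Synthetic benchmark** — a deterministic generator of the whole
  branching design (gene catalog, ChIP IP/input counts, FPKM,
  accessibility, peaks, coverage) with planted classes, onsets, clusters
  and activators, so every stage is testable without external data.

## Worked example

```python
from h33course.synthetic import SimulationConfig, simulate_bundle
from h33course import quantify, onset, dynamics, discovery

cfg = SimulationConfig(seed=7, n_genes=500, fpkm_log_sd=0.0, count_dispersion=0.0)
b = simulate_bundle(cfg)

ip  = quantify.normalize_library(b.h33_ip_counts, b.library_sizes)
inp = quantify.normalize_library(b.h33_input_counts, b.library_sizes)
presence = quantify.call_enrichment(ip, inp, b.catalog.lengths())

calls = onset.classify_onsets(presence, b.sheet)
print(calls["status"].value_counts().to_dict())
# {'constitutive': 200, 'never': 150, 'onset': 150}
print(calls.loc[calls.status == "onset", "onset_label"].value_counts().to_dict())
# {'D6T-': 44, 'D9T-': 41, 'D12S+': 35, 'D3': 30}

clusters = dynamics.assign_cluster(dynamics.endpoint_de(b.fpkm, b.sheet))
print(clusters.value_counts().to_dict())
# {'unassigned': 225, 'III': 89, 'II': 65, 'IV': 61, 'I': 60}

acts = discovery.identify_activators(calls, b.fpkm, b.sheet)
prec = onset.precedence_table(calls, onset.expression_onsets(b.fpkm, b.sheet))
d = prec[prec.relation != "undefined"]
print(len(acts), (d.relation == "deposition_first").mean())
# 49 0.9
```

At zero noise the pipeline reads back exactly what the generator planted:
150 of 500 genes carry an H3.3 onset, the 49 recovered activators are
precisely the planted ones, and 90% of onset genes acquire H3.3 one
time-point before they start being expressed (the configured
deposition-lead fraction).  Marker-set enrichment of the activators against
the bundled GMT file gives an mESC-set score of 38.8 (overlap 49/100) and 0
for the somatic sets.

## Command line

```bash
h33course simulate -o bundle --seed 7 --n-genes 500
h33course run-all -i bundle -o results --seed 7
```

`run-all` writes annotation tables, presence/normalized matrices, cluster
labels, onset/precedence tables, the top-loss ranking, the activator list,
marker enrichment, profile/trajectory TSVs and a `manifest.json`; every
output carries the config hash, and identical configs produce byte-identical
bundles.  Individual stages (`annotate`, `quantify`, `clusters`, `onset`,
`profiles`, `discover`) compose to the same result.

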