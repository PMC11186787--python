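# neuralsig

Tools for the epigenetically defined **neural signature** of high-grade
glioma: estimating how "neuronal" a tumor's bulk DNA-methylation profile is,
splitting cohorts into low- and high-neural classes, carrying that
classification to new cohorts, and predicting the neural score from the
spatial arrangement of transcripts.

High-grade gliomas integrate into neuronal circuits, and tumors with a
stronger neural character behave differently in the clinic. Because a bulk
tumor methylome is a mixture of its constituent cell types, the neural
character can be read off directly from DNA methylation: the package
deconvolves a bulk beta matrix against a 25-component cell-type reference
atlas containing a single cortical-neuron entry, using non-negative least
squares,

&nbsp;&nbsp;&nbsp;&nbsp; min<sub>w≥0</sub> ‖A·w − b‖₂,&nbsp;&nbsp; ŵ = w / Σ<sub>k</sub> w<sub>k</sub>,

and calls the neuron component's proportion the **neural score**. A cohort
is dichotomized at the median neural score (0.41 in the reference cohort);
score ≥ cutoff means *high-neural*. Around this core the package provides:

- **`neuralsig.synthetic`** — generators for every input modality with known
  ground truth: block-structured reference atlases, Dirichlet-mixed bulk
  cohorts, zero-inflated single-cell expression with planted gene modules,
  and Visium-style spatial samples (hexagonal 100 µm lattice, latent
  per-spot cell composition tied to a sample-level neural score, nucleus
  positions).
- **`neuralsig.deconvolution`** — NNLS deconvolution, median cutoff
  derivation, low/high classification.
- **`neuralsig.dmp`** — differentially methylated positions (per-CpG
  t-tests, Benjamini–Hochberg) and an L2 logistic model that transfers the
  low/high labels to cohorts without methylation-wide reprocessing.
- **`neuralsig.modules`** — the zero-inflation-aware module expression score
  m_exp = (Σᵢ xᵢ / n) · (#{xᵢ ≠ 0} / n) for projecting co-expression gene
  modules onto single cells.
- **`neuralsig.spatial`** — spot adjacency graphs (distance threshold = one
  unit above the smallest nonzero spot distance; interior Visium spots get
  exactly six neighbors), 3-hop subgraph extraction with a 15-node minimum,
  and standardized log1p node features of the most variable genes.
- **`neuralsig.nn`** — a three-layer graph isomorphism network (GIN)
  regressor, x′_v = (1+ε)·x_v + Σ_{u∈N(v)} ReLU(x_u) followed by an MLP,
  batch norm, LeakyReLU(0.2) and dropout 0.5 per layer, a Xavier-initialized
  merge into a latent space, global mean pooling and an MLP head; trained
  with mean-absolute-error loss in batches of 32. Built on an in-package
  numpy reverse-mode autodiff engine with a hand-written Adam optimizer.
- **`neuralsig.composition`** — integer cell counts per spot,
  C_jk = round(d′_jk · N_j / Σ_k d′_jk), and a nucleus-level cell-type map.

## Worked example

```python
import neuralsig as ns

atlas = ns.make_reference_atlas(n_cpgs=250, seed=0)          # 25 components
cohort = ns.make_bulk_cohort(atlas, n_samples=1058, noise_sd=0.005, seed=1)
results = ns.deconvolve(cohort, atlas)
cutoff = ns.derive_cutoff([r.neural_score for r in results])
print(f"cutoff {cutoff:.4f}")
labels = [ns.classify(r.neural_score, cutoff) for r in results]
print(labels.count("low"), "low /", labels.count("high"), "high")
```

prints

```
cutoff 0.4197
529 low / 529 high
```

the derived cutoff sits at the cohort's median neural proportion (the
generator is calibrated so this median falls near the published 0.41), and
the median split sends exactly half of the 1,058 samples to each class.

The numbered scripts under `analysis/` run the full pipeline and narrate
their findings: `01` simulates the atlas and cohorts, `02` deconvolves and
dichotomizes (recovering true proportions to ≈0.001 mean absolute error),
`03` finds ~250 DMPs and transfers the classification at ≈0.99/0.98
train/validation accuracy, `04` scores planted single-cell modules, `05`
builds spot graphs and 3-hop subgraphs, `06` trains the GIN (held-out
R² ≈ 0.996, F1 = 1.0 at the 0.41 cutoff), and `07` apportions nuclei into
integer cell-type counts.

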