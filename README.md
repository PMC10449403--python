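# scenebound

Analysis pipeline for **scene-memory boundary transformations**: do
observers' memories of a photograph's spatial boundaries expand
(*boundary extension*) or shrink (*boundary contraction*), and is the
direction predicted by how much information the scene contains?

The package is aimed at visual-cognition researchers running forced-error
RSVP experiments.  It measures per-image **visual information** (edge
density, CIELAB color entropy, gist-descriptor entropy) and **semantic
information** (median description length, lexical entropy, mean pairwise
word-embedding distance over ~100 free-text descriptions per image),
collapses each triple into a single score via PCA, reduces forced-choice
"closer"/"farther" responses to per-image **boundary-transformation
scores**, estimates a split-half **noise ceiling**, and fits the
regression and **variance-partitioning** models that relate memory errors
to scene depth and information.

## The statistics in brief

For image *i* with *n* observers, the boundary-transformation score is
the mean of ±1-coded forced errors ("closer" = extension = +1,
"farther" = contraction = −1):

    score_i = (n_extension − n_contraction) / n  ∈ [−1, 1]

Information metrics reduce to Shannon entropy H = −Σ pₖ log₂ pₖ over
normalized histograms (color bins, gist filter energies, word types), and
each metric triple is projected onto its first principal component.  The
core model is OLS:

    score_i = β₀ + β_d·depth_i + β_s·semantic_i + β_v·visual_i + ε_i

with a seven-model commonality analysis decomposing the full-model R²
into unique and shared components, and a 10,000-split noise ceiling
bounding the explainable variance.

A seeded synthetic-study generator (`generate_study`) emulates all four
inputs — procedural images, Zipfian description corpora, a toy embedding
table, and binomial observer responses with extension probability
(1 + s)/2 — so the whole chain is testable end to end by parameter
recovery.

## Worked example

```bash
python examples/visual_metrics.py
```

```
    sparse: edge_density=   395 px   color_entropy=1.027 bits   gist_entropy= 9.203 bits
 cluttered: edge_density=  5320 px   color_entropy=3.581 bits   gist_entropy= 9.795 bits
```

A cluttered scene has more Canny edge pixels, spreads its chromaticities
over more A\*/B\* histogram bins, and distributes oriented filter energy
more evenly — all three proxies of visual information rise.

```bash
python examples/full_pipeline.py
```

```
noise ceiling: [0.503, 0.758]
full model adjusted R^2: 0.691
recovered coefficients (truth in parentheses):
           depth: -0.1143 (-0.1300), SE 0.0134
   semantic_info: -0.0462 (-0.0300), SE 0.0135
     visual_info: -0.0008 (-0.0010), SE 0.0140
```

The pipeline regenerates the generative coefficients from raw pixels,
text, and responses: deeper scenes and semantically richer scenes push
scores toward contraction; the full model's R² sits inside the noise
ceiling.  Other examples cover semantic metrics, boundary scores, and
variance partitioning (`examples/*.py`), and a thin CLI mirrors the
stages (`scenebound simulate|visual-features|semantic-features|unify|
score|noise-ceiling|regress|partition|run-all`).

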