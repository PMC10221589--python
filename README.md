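# liverscan

Hierarchical classification of liver ultrasound frames into the 11
standardized scan locations — SL, ST, RSPV, RSLT, LD, RSHV, GBL, EBL,
RIA, RIP and LK — from the outputs of organ and vessel semantic
segmentation models.  The package is aimed at researchers building
probe-guidance systems who have a segmentation backend (a
MaskFormer-style network in production, or the built-in synthetic
generator on a desk) and need the downstream location classifier,
together with the evaluation harness for subject-wise validation.

## The method

Per frame and per backend, the segmentation artifacts are: image
features `G_i = (1 / H_F W_F) Σ_{h,w} F_{i,h,w}` (global average
pooling of the encoder feature map), per-segment query embeddings
`Q ∈ R^{C_Q×N}`, per-query class scores, and the geometric matrix
`V ∈ R^{(N−1)×10}` whose row for class *i* is
`[T_i, L_{i,x}, L_{i,y}, S_i, λ1, λ2, v1, v2]` — detection tag,
centroid, area fraction `|C_i|/(HW)` and the eigenstructure of the
mask's pixel-coordinate covariance (zero rows for undetected classes).

Classification is a two-level hierarchy:

1. **8 regions from organ features alone** (two fully connected layers,
   cross-entropy, AdamW lr 1e-4, early stopping patience 10).  The six
   unambiguous locations are final here; {ST, RSPV, RSHV} and
   {SL, EBL} are group classes resolved at level 2.
2. **ST/RSPV/RSHV** — an initial classifier on liver + vessel features
   partitions training data into clear/ambiguous; a 3-layer triplet
   encoder (`L(a,p,n) = max(|a−p|² − |a−n|² + α, 0)`, α = 1, batch-hard
   mining, 64-d embedding) is trained on clear frames; reference points
   are sampled one per occupied cell of a 10×10 grid over their 2-D
   t-SNE projection; queries are classified by 3-NN voting against the
   references.
   **SL/EBL** — the vessel model's mask logits are rectified
   (`P̂ = max(P, 0)`) and stacked with vessel-masked intensities into a
   three-channel image classified by an image head.

A non-hierarchical ablation (one 11-class MLP on all features) and a
subject-wise C(5,3) = 10-fold comparison harness are included.  Since
the clinical datasets behind this problem are private, the package
ships a synthetic artifact generator with class-dependent organ/vessel
geometry, embedding structure, subject effects and a controllable
within-group ambiguity dial; see `docs/methods.md` for what it does and
does not emulate.

## Worked example

```python
import liverscan as ls
from liverscan.hierarchy import HierarchyConfig, train_hierarchy, predict

specs = ls.default_spec_set()                      # the 11 scan locations
subjects = [f"subj{i}" for i in range(1, 6)]
samples = ls.generate_samples(specs, 20, subjects, seed=1)

train = [s for s in samples if s.subject_id in subjects[:3]]
test = [s for s in samples if s.subject_id in subjects[3:]]

model = train_hierarchy(train, HierarchyConfig(seed=0))
report = ls.score([(s.label, predict(s, model)) for s in test])
print(f"macro-F1 on held-out subjects: {report.macro_f1:.3f}")
print(report.per_class[["label", "precision", "recall", "f1", "support"]].to_string(index=False))
```

prints

```
macro-F1 on held-out subjects: 1.000
label  precision  recall  f1  support
   SL        1.0     1.0 1.0        8
   ST        1.0     1.0 1.0        8
 RSPV        1.0     1.0 1.0        8
 ...
```

Training uses subjects 1–3; the report scores subjects 4–5, whom no
stage has seen.  Under the default *separable* generator conditions the
hierarchy recovers every held-out frame; raising
`ls.default_spec_set(ambiguity_overlap=...)` makes the ST/RSPV/RSHV and
SL/EBL groups progressively confusable, which is where the
reference-point KNN and the image branch earn their keep.

The same pipeline is scriptable from a shell:

```sh
liverscan simulate --out data/ --seed 1
liverscan train    --manifest data/manifest.csv --out model/ --seed 1
liverscan predict  --bundle model/ --manifest data/manifest.csv --out preds.csv
liverscan evaluate --manifest data/manifest.csv --out reports/
```

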