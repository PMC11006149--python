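# convrules

Neuro-symbolic knowledge extraction from CNN image classifiers: turn the
kernels of a convolutional layer into logical literals, approximate the
network with a compact decision-tree rule set, attach anatomical-region
concepts to kernels, let an expert intervene on the kernel vocabulary, and
quantify how much each concept group contributes to the model's accuracy.

The package is aimed at researchers studying interpretability of medical
image classifiers (the running example is pleural-effusion detection on
frontal chest radiographs) and ships with a synthetic phantom generator and a
small built-in NumPy CNN, so the entire workflow runs end-to-end on a laptop
CPU with no external data or deep-learning framework.

## The method

A trained classifier `M` is split at a designated convolutional layer `l`
into `g(·)` (image → one activation map per kernel) and `h(·)` (maps → class
scores), so `M(x) = h(g(x))`.  For image `i` and kernel `k`:

- kernel norm: `a[i,k] = ‖A[i,k]‖₁` — the L1 norm of the activation map;
- threshold: `θ[k] = mean_i a[i,k]` over the training set;
- literal: `b[i,k] = +1` if `a[i,k] > θ[k]` (strictly), else `−1`.

A decision tree over the literals is grown against the CNN's own predictions
(Gini branching, at most three literals per path, reduced-error pruning,
majority-class leaves).  Each root-to-leaf path is a rule such as
`¬ET ∧ ¬QN → Effusion`.  The rule set `M*` is scored by **accuracy** (vs
ground truth) and **fidelity** (fraction of predictions agreeing with the
CNN), plus sensitivity/specificity with the disease class positive.

Kernels receive concepts by geometry: a kernel's activated image region
(upsampled, receptive-field-smoothed, half-peak support around the peak) is
compared with per-image anatomical-region boxes; a *hit* is IOU > 0.5, and a
kernel is assigned the region it hits in more than 70% of the dataset (at
most two highly-hit regions, else *uninterpretable*).  Rule sets restricted
to interpretable kernels, what-if interventions (allow/deny kernel lists),
muting experiments (zeroing kernel maps before `h`) and radiomics texture
correlations (GLCM joint entropy, GLRLM non-uniformities, first-order
MAD/RMS vs kernel norms) complete the picture.

## Worked example

```python
from convrules import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig().with_seed(1), outdir="run1")
print(result.summary())
```

prints (abridged):

```
convrules pipeline summary (seed 1, config 3f386d8eb57165e9)

phantom: 400 train images (64px), signal regions ['CS', 'UM']
CNN: 16 kernels at the feature layer; train acc 1.000, val acc 1.000
thresholds theta: min 0.092, median 16.476, max 98.324
concept thresholds: iou_min 0.5, hit_frac 0.7, max_regions 2, percentile 95.0
kernel concepts: AA=UNINTERPRETABLE, ..., AF=CS, AG=CS, AI=CS, AL=UM, AM=CS, AN=CS, ...

baseline rule set (all kernels):
  train: accuracy 1.000, fidelity 1.000, sensitivity 1.000, specificity 1.000
  validation: accuracy 1.000, fidelity 1.000, sensitivity 1.000, specificity 1.000
interpretable-kernel rule set:
  train: accuracy 1.000, fidelity 1.000, sensitivity 1.000, specificity 1.000
  validation: accuracy 1.000, fidelity 1.000, sensitivity 1.000, specificity 1.000
```

The phantom plants class signal in the cardiac-silhouette (CS) and
upper-mediastinum (UM) regions; the summary shows that several kernels were
assigned exactly those concepts, and that both the full rule set and the one
restricted to interpretable kernels reproduce the CNN almost perfectly.  The
run directory contains the kernel-norm and literal tables (CSV), the concept
map, the rule sets (JSON + Graphviz DOT), evaluation reports, tidy ablation
tables and radiomics correlations.

The same workflow is scriptable stage by stage from the shell:

```bash
convrules generate -o run1 --seed 1
convrules train -o run1
convrules extract -o run1
convrules concepts -o run1
convrules rules -o run1
convrules ablate -o run1
convrules radiomics -o run1
convrules what-if -o run1 --deny 5
```

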