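# pulvigrad

Multimodal connectopic gradient mapping for small subcortical structures,
modelled on the pulvinar complex of the thalamus.

The pulvinar is traditionally subdivided into discrete anatomical nuclei, yet
its cortical connectivity and neurochemistry vary *continuously* across the
nucleus.  Gradient mapping captures this: each pulvinar voxel gets a profile
(functional connectivity to cortical parcels, tract-density counts, or
receptor densities), profiles are compared voxel-to-voxel with cosine
similarity, and diffusion-map embedding of the resulting affinity yields a
few *gradients* — unitless axes along which connectivity or coexpression
changes smoothly.  The package implements the full analysis stack for users
who want to run, test, or stress this kind of pipeline:

- **features** — voxel-by-parcel functional connectomes (Pearson r, top-10%
  row sparsification, Fisher z, group averaging), tract-density matrices,
  z-scored receptor tables, and voxel-wise tSNR/b0-SNR maps;
- **embedding** — cosine affinities and the diffusion operator
  `M = D⁻¹ A/(q^α q^α)` (α = 0.5), with explained variance, scree-elbow
  selection, sign alignment and orthogonal Procrustes alignment;
  exposed as the scikit-learn style `DiffusionMapEmbedding` transformer;
- **projection** — gradient-weighted cortical connectivity maps
  `map(p) = mean_v g(v)·F(v,p)`, network/nucleus summaries, receptor
  correlates, cross-modal gradient correlations;
- **nulls** — variogram-matched, spatial-autocorrelation-preserving
  surrogate maps, SA-corrected permutation p-values (two-sided on |r|), and
  Benjamini-Hochberg FDR;
- **clustering** — `GradientKMeans` (k = 2…30, silhouette model selection)
  and Dice overlap against atlas nuclei;
- **reliability** — split-half stability, test-retest repeatability, and
  SNR-confound association, all with Procrustes-aligned comparison;
- **synth** — generators that plant ground truth (gradient axes, cluster
  structure, spatial autocorrelation with known correlation length) so every
  stage has a recoverable target.

## Worked example

Plant a two-axis pulvinar-like dataset, embed it, and check that the
gradients recover the planted organisation:

```python
import numpy as np
import pulvigrad as pg
from pulvigrad.reliability import EmbedConfig, embed_connectome
from pulvigrad.synth import make_ground_truth_bundle

bundle = make_ground_truth_bundle(n_voxels=600, n_parcels=100, k=2,
                                  snr=10.0, seed=1)
domain = bundle["domain"]
left = domain.mask("left")                      # 300 voxels
w = bundle["connectome"][left]                  # voxel x parcel connectome
truth = bundle["ground_truth"]

g = embed_connectome(np.clip(w, 0, None), EmbedConfig(n_components=5),
                     "structural")
print("explained variance:", np.round(g.explained_variance[:2], 3))
for j in range(2):
    r = np.corrcoef(g.components[:, j], truth.planted_axes[left, j])[0, 1]
    gw = pg.gradient_weighted_map(w, g.components[:, j])
    rc = pg.map_correlation(gw.values,
                            truth.planted_cortical_gradients[:, j])
    print(f"axis {j + 1}: recovery |r|={abs(r):.3f}, "
          f"cortical projection |r|={abs(rc):.3f}")
```

Output:

```
explained variance: [0.726 0.264]
axis 1: recovery |r|=1.000, cortical projection |r|=1.000
axis 2: recovery |r|=1.000, cortical projection |r|=1.000
```

The first two gradients recover the planted spatial axes essentially
perfectly at snr 10, their explained-variance ordering follows the planted
amplitudes, and projecting each gradient back through the connectome
reproduces the cortical gradient that generated it — the synthetic analogue
of the replication-principle result that pulvinar-cortical connectivity
mirrors cortico-cortical organisation.

The same stages are available from the shell:

```bash
pulvigrad simulate --n-voxels 600 --n-parcels 100 --k 2 --seed 1 --out sim/
pulvigrad gradients --features sim/connectome.tsv --modality structural \
    --n-components 5 --out grad/
pulvigrad cluster --gradients grad/gradients.tsv --k-min 2 --k-max 30 \
    --seed 1 --out clus/
pulvigrad run --seed 1 --out full_run/   # complete end-to-end pipeline
```

## Layout

```
src/pulvigrad/     domain, synth, features, embedding, projection,
                   nulls, clustering, reliability, pipeline, io, cli
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model, parameters, numerical choices, limitations
scripts/acceptance.py
```
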