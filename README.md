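# fedmsrw

Federated training for volumetric white-matter-lesion segmentation with
two dynamic re-weighting mechanisms, simulated in a single process.

## The problem

Multi-site lesion-segmentation studies (the motivating case is multiple
sclerosis on FLAIR MRI) often cannot pool raw images across hospitals.
Federated learning trains a shared model by exchanging only parameters:
each site ("client") trains locally, a server averages the local models
and redistributes them. Two kinds of cross-site heterogeneity break the
plain protocol:

* **domain shift** — scanners differ in intensity, contrast and noise;
* **label shift** — sites differ in lesion burden, and a site with few,
  small lesions is poorly served by a uniformly averaged model.

## The method

On top of a normalization-preserving baseline (batch-norm parameters and
running statistics θ^bn stay client-local; only the shared set θ^r is
aggregated), this package implements two re-weightings:

1. **Ability-weighted central aggregation.** Each client reports its
   per-round segmentation ability
   `P_i = (Σ p·y / Σ y) · (1 − L_dice)` — mean predicted probability on
   true-lesion voxels times one minus the soft Dice loss — and the
   server aggregates `θ̂^r = Σ_i P_i θ_i^r / Σ_i P_i`, so weak local
   models do not drag the shared model down.
2. **Lesion-volume loss re-weighting.** Each client tracks its running
   mean lesion-to-brain volume ratio `vr_i`; its soft Dice loss is
   scaled by `(Σ_j vr_j) / (N·vr_i)` so low-burden sites train with
   larger effective steps.

FedAvg, FedProx and FedBN baselines, the single-mechanism ablations and
the entropy-/voxel-count variants are all available as modes of the same
loop. A built-in phantom generator produces multi-client 3-D brain
volumes with controllable intensity shift and lesion burden, so the
whole federation runs on one CPU in about a minute. Real single-channel
NIfTI volumes with binary masks are also supported.

## Worked example

```python
from fedmsrw import (ClientProfile, FederationConfig, NetworkConfig,
                     generate_federation, run_federation)

profiles = [
    ClientProfile(client_id="A", n_cases=4, volume_shape=(24, 24, 24),
                  target_ratio=0.01, intensity_offset=0.0),
    ClientProfile(client_id="B", n_cases=4, volume_shape=(24, 24, 24),
                  target_ratio=0.04, intensity_offset=50.0),
]
data = generate_federation(profiles, rng_seed=0)
config = FederationConfig(mode="fedmsrw", n_rounds=3, iters_per_round=30,
                          lr=1e-2, batch_size=4, patch_size=(16, 16, 16),
                          master_seed=0)
result = run_federation(data, config, NetworkConfig(depth=2, base_channels=8))
for e in result.history:
    print(e["round"], e["loss_weight"], e["aggregation_weights"])
```

prints (abridged):

```
1 {'A': 1.0, 'B': 1.0}    {'A': 0.36, 'B': 0.64}
2 {'A': 2.12, 'B': 0.65}  {'A': 0.36, 'B': 0.64}
3 {'A': 2.13, 'B': 0.65}  {'A': 0.44, 'B': 0.56}
```

(weights rounded to two decimals)

Round 1 trains unweighted; from round 2 the low-burden client A gets a
loss weight > 1 (its lesion-volume ratio is below the federation mean)
and the aggregation weights track the clients' measured abilities,
normalised to sum to 1. `examples/` contains one short script per
capability: phantom generation, the re-weighting primitives, federated
training, tiled inference, cross-validated experiments, and a protocol
comparison.

Evaluation reports, per client, the case-averaged Dice (C-Dice), the
Dice / true-positive rate / false-positive rate computed from voxel
counts pooled over all cases (V-Dice, V-TPR, V-FPR), all in percent;
the reported FPR is FP/(TP+FP).

A thin CLI wraps the same functions:

```bash
fedmsrw experiment --config config.yaml --mode fedmsrw --out-dir runs/msrw
fedmsrw simulate-data --config config.yaml --seed 0 --out-dir data/
```

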