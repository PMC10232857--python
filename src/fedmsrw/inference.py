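"""Patch-tiled full-volume prediction and per-client model assembly.

Training operates on small patches, so a full case is segmented by
tiling it with network-sized patches, predicting each, and averaging the
probabilities where patches overlap.  The default stride is half the
patch size (seam-robust); stride = patch size reproduces exact
non-overlapping tiling.  At evaluation time each client's model is the
shared aggregated parameters combined with that client's private
normalization state, run in evaluation mode (running statistics, not
batch statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .metrics import MetricsReport, evaluate_cases
from .nn import NetworkConfig, ParameterPartition, assemble_client_parameters, build_network
from .phantom import SyntheticCase

__all__ = [
    "TilingPlan",
    "tile_volume",
    "predict_case",
    "evaluate_client",
    "write_mask_nifti",
]


def write_mask_nifti(path, mask: np.ndarray, reference_path=None):
    """Write a predicted binary mask as NIfTI.

    When `reference_path` points to the input NIfTI case, its affine and
    header are reused so the prediction overlays the source image.
    """
    import nibabel as nib

    if reference_path is not None:
        ref = nib.load(reference_path)
        img = nib.Nifti1Image(mask.astype(np.uint8), ref.affine, ref.header)
    else:
        img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4))
    nib.save(img, path)


@dataclass(frozen=True)
class TilingPlan:
    offsets: tuple[tuple[int, int, int], ...]
    patch_size: tuple[int, int, int]
    volume_shape: tuple[int, int, int]


def _axis_offsets(extent: int, patch: int, stride: int) -> list[int]:
    offs = list(range(0, extent - patch + 1, stride))
    if offs[-1] != extent - patch:
        offs.append(extent - patch)  # clamp the last patch to the far edge
    return offs


def tile_volume(volume_shape, patch_size, stride) -> TilingPlan:
    """Offsets covering every voxel with fully-inside patches.

    Offsets advance by `stride` per axis, with a final offset clamped to
    ``extent - patch`` so coverage is complete; duplicates are dropped.
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    patch_size = tuple(int(p) for p in patch_size)
    if isinstance(stride, int):
        stride = (stride,) * 3
    stride = tuple(int(s) for s in stride)
    for ax, (p, s, st) in enumerate(zip(patch_size, volume_shape, stride)):
        if p > s:
            raise ValueError(f"patch {p} exceeds volume extent {s} on axis {ax}")
        if not (1 <= st <= p):
            raise ValueError(f"stride {st} must be in [1, patch={p}] on axis {ax}")
    per_axis = [
        _axis_offsets(s, p, st)
        for s, p, st in zip(volume_shape, patch_size, stride)
    ]
    offsets = tuple(product(*per_axis))
    return TilingPlan(offsets=offsets, patch_size=patch_size, volume_shape=volume_shape)


def predict_case(
    model,
    volume: np.ndarray,
    patch_size=None,
    stride=None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile, predict, and overlap-average one case.

    Returns (probability volume, binary mask at `threshold`).  Volumes
    smaller than the patch on some axis are zero-padded for prediction
    and cropped back.  The model runs in evaluation mode.
    """
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim == 3:
        vol = vol[None]  # channel axis
    if patch_size is None:
        patch_size = vol.shape[1:]
    patch_size = tuple(int(p) for p in patch_size)
    if stride is None:
        stride = tuple(max(1, p // 2) for p in patch_size)

    orig_shape = vol.shape[1:]
    pad = [max(0, p - s) for p, s in zip(patch_size, orig_shape)]
    if any(pad):
        vol = np.pad(vol, [(0, 0)] + [(0, p) for p in pad])
    shape = vol.shape[1:]

    plan = tile_volume(shape, patch_size, stride)
    prob_sum = np.zeros(shape, dtype=np.float64)
    cover = np.zeros(shape, dtype=np.int32)
    for off in plan.offsets:
        sl = tuple(slice(o, o + p) for o, p in zip(off, patch_size))
        patch = vol[(slice(None),) + sl][None]  # (1, C, d, h, w)
        pred = model.forward(patch, training=False)[0, 0]
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError(f"non-finite prediction at offset {off}")
        prob_sum[sl] += pred
        cover[sl] += 1
    assert cover.min() >= 1, "tiling failed to cover the volume"
    prob = prob_sum / cover
    crop = tuple(slice(0, s) for s in orig_shape)
    prob = prob[crop]
    return prob, prob >= threshold


def evaluate_client(
    cases: list[SyntheticCase],
    global_rest: dict[str, np.ndarray],
    client_bn: dict[str, np.ndarray],
    partition: ParameterPartition,
    network_config: NetworkConfig,
    patch_size=None,
    stride=None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Assemble one client's model and score it on its held-out cases."""
    state = assemble_client_parameters(global_rest, client_bn, partition)
    model = build_network(network_config, rng_seed=0)
    model.load_state_dict(state)
    preds, truths = {}, {}
    for case in cases:
        _, mask = predict_case(
            model, case.volume, patch_size=patch_size, stride=stride,
            threshold=threshold,
        )
        preds[case.case_id] = mask
        truths[case.case_id] = case.lesion_mask
    return evaluate_cases(preds, truths)
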