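"""Synthetic multi-client 3-D lesion phantoms.

Each simulated client stands in for one scanner/site in a federated
white-matter-lesion study.  A client is described by a :class:`ClientProfile`
holding the generative knobs that create cross-site domain shift (additive
intensity offset, multiplicative contrast, noise level) and label shift
(the mean lesion-to-brain volume ratio).  Cases are brain-extracted-like
volumes: an axis-aligned ellipsoidal "brain" filled with a smooth
low-frequency tissue field, hyperintense spherical lesions, and zero
background.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ClientProfile",
    "SyntheticCase",
    "generate_case",
    "generate_federation",
    "sample_patch",
    "write_client_cases",
    "read_client_cases",
]

#: lesions are brighter than surrounding tissue by this fraction of the
#: local tissue intensity (hyperintense, FLAIR-like)
LESION_CONTRAST = 0.4

#: mean tissue intensity of the unshifted base field (arbitrary units)
TISSUE_MEAN = 100.0

_PLACEMENT_RETRIES = 200


def _stable_client_key(client_id: str) -> int:
    """Deterministic integer key for a client id (stable across runs)."""
    return zlib.crc32(client_id.encode("utf-8"))


def _sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets of all voxels within `radius` of the origin."""
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dz * dz + dy * dy + dx * dx <= radius * radius
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _mean_sphere_volume(radius_range: tuple[float, float], n_grid: int = 33) -> float:
    """Expected voxel count of a digitised sphere, radius ~ U(min, max).

    Computed on a radius grid because small digitised spheres deviate a lot
    from (4/3)πr³ (a radius-1 sphere has 7 voxels, not 4.2).
    """
    lo, hi = radius_range
    radii = np.linspace(lo, hi, n_grid)
    return float(np.mean([len(_sphere_offsets(r)) for r in radii]))


@dataclass(frozen=True)
class ClientProfile:
    """Generative parameters for one simulated client (scanner/site).

    ``lesion_count_mean`` may be left ``None``; it is then calibrated at
    construction so that the expected lesion-to-brain volume ratio equals
    ``target_ratio``, using the brain volume implied by ``volume_shape`` /
    ``brain_radius_frac`` and the mean digitised-sphere volume over
    ``lesion_radius_range``.
    """

    client_id: str
    n_cases: int
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    brain_radius_frac: float = 0.85
    intensity_offset: float = 0.0
    intensity_scale: float = 1.0
    noise_sigma: float = 2.0
    lesion_radius_range: tuple[float, float] = (1.0, 2.5)
    target_ratio: float = 0.02
    lesion_count_mean: float | None = None
    allow_empty: bool = False

    def __post_init__(self):
        if not self.client_id:
            raise ValueError("client_id must be non-empty")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        shape = tuple(int(s) for s in self.volume_shape)
        object.__setattr__(self, "volume_shape", shape)
        rmin, rmax = self.lesion_radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("lesion_radius_range must satisfy 1 <= min <= max")
        if any(s < 2 * rmax for s in shape):
            raise ValueError(
                f"volume_shape {shape} too small for max lesion radius {rmax}"
            )
        if not (0 < self.brain_radius_frac <= 1):
            raise ValueError("brain_radius_frac must be in (0, 1]")
        if not (0 < self.target_ratio < 0.1):
            raise ValueError("target_ratio must be in (0, 0.1)")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.lesion_count_mean is None:
            object.__setattr__(self, "lesion_count_mean", self._calibrated_count())
        if self.lesion_count_mean <= 0:
            raise ValueError("lesion_count_mean must be > 0")
        if self.lesion_count_mean < 1 and not self.allow_empty:
            raise ValueError(
                f"profile {self.client_id!r}: target_ratio {self.target_ratio} needs "
                f"a mean lesion count of {self.lesion_count_mean:.2f} < 1 for shape "
                f"{shape}; shrink lesion_radius_range or set allow_empty=True"
            )

    # -- geometry ---------------------------------------------------------

    @property
    def _semi_axes(self) -> np.ndarray:
        return self.brain_radius_frac * (np.asarray(self.volume_shape) - 1) / 2.0

    def brain_mask(self) -> np.ndarray:
        shape = self.volume_shape
        center = (np.asarray(shape) - 1) / 2.0
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        d2 = sum(
            ((g - c) / a) ** 2 for g, c, a in zip(grids, center, self._semi_axes)
        )
        return d2 <= 1.0

    def _calibrated_count(self) -> float:
        brain_vox = int(self.brain_mask().sum())
        mean_vol = _mean_sphere_volume(self.lesion_radius_range)
        return self.target_ratio * brain_vox / mean_vol


@dataclass
class SyntheticCase:
    """One subject: intensity volume, binary lesion mask, binary brain mask."""

    case_id: str
    volume: np.ndarray
    lesion_mask: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        if not (self.volume.shape == self.lesion_mask.shape == self.brain_mask.shape):
            raise ValueError("volume and masks must share one shape")


def _base_tissue_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth positive tissue texture: 1 + a few random low-frequency cosines."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    out = np.ones(shape)
    for _ in range(4):
        freq = rng.uniform(0.5, 1.5, size=3) / np.asarray(shape)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.08, 0.2)
        arg = sum(2 * np.pi * f * g for f, g in zip(freq, grids)) + phase
        out = out + amp * np.cos(arg)
    return out


def _stochastic_round(mean: float, rng: np.random.Generator) -> int:
    """Integer draw with the exact requested mean: floor(mean)+Bernoulli(frac).

    Degenerate at integer means, so a profile with mean 1 always produces
    exactly one lesion; a calibrated mean >= 1 never produces zero.
    """
    base = int(np.floor(mean))
    return base + int(rng.random() < (mean - base))


def _place_lesions(
    profile: ClientProfile, brain: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    shape = np.asarray(profile.volume_shape)
    center = (shape - 1) / 2.0
    semi = profile._semi_axes
    n_lesions = _stochastic_round(profile.lesion_count_mean, rng)
    mask = np.zeros(profile.volume_shape, dtype=bool)
    for _ in range(n_lesions):
        radius = rng.uniform(*profile.lesion_radius_range)
        offs = _sphere_offsets(radius)
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            # erode the ellipsoid by the lesion radius so the sphere fits
            shrunk = semi - radius
            if np.any(shrunk <= 0):
                break
            c = rng.uniform(center - shrunk, center + shrunk)
            c = np.round(c).astype(int)
            if np.sum(((c - center) / shrunk) ** 2) > 1.0:
                continue
            vox = c[None, :] + offs
            mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a radius-{radius:.1f} lesion inside the brain "
                f"for profile {profile.client_id!r}"
            )
    if not mask.any() and brain.any():
        # defensive: only reachable when allow_empty permits a zero draw
        if not profile.allow_empty:
            raise RuntimeError(f"profile {profile.client_id!r} produced no lesions")
    return mask


def generate_case(profile: ClientProfile, rng_seed) -> SyntheticCase:
    """Generate one phantom case; a pure function of (profile, seed)."""
    rng = np.random.default_rng(rng_seed)
    brain = profile.brain_mask()
    tissue = TISSUE_MEAN * _base_tissue_field(profile.volume_shape, rng)
    lesions = _place_lesions(profile, brain, rng)
    lesions &= brain
    tissue = np.where(lesions, tissue * (1.0 + LESION_CONTRAST), tissue)
    volume = tissue * profile.intensity_scale + profile.intensity_offset
    if profile.noise_sigma > 0:
        volume = volume + rng.normal(0.0, profile.noise_sigma, size=volume.shape)
    volume = np.where(brain, volume, 0.0)
    seed_tag = rng_seed if isinstance(rng_seed, (int, np.integer)) else "seq"
    return SyntheticCase(
        case_id=f"{profile.client_id}-{seed_tag}",
        volume=volume.astype(np.float32),
        lesion_mask=lesions,
        brain_mask=brain,
    )


def generate_federation(
    profiles: list[ClientProfile], rng_seed: int
) -> dict[str, list[SyntheticCase]]:
    """Generate every client's case list.

    Per-case seeds derive from (master seed, a stable hash of the client id,
    case index), so editing one client's profile or resampling one case never
    perturbs any other client's data.
    """
    if len(profiles) < 2:
        raise ValueError("a federation needs at least 2 clients")
    ids = [p.client_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate client_id in {ids}")
    federation: dict[str, list[SyntheticCase]] = {}
    for profile in profiles:
        key = _stable_client_key(profile.client_id)
        cases = []
        for i in range(profile.n_cases):
            seq = np.random.SeedSequence([rng_seed, key, i])
            case = generate_case(profile, seq)
            case.case_id = f"{profile.client_id}_case{i:03d}"
            cases.append(case)
        federation[profile.client_id] = cases
    return federation


# -- patch sampling -------------------------------------------------------


def _random_orthogonal_transform(rng: np.random.Generator):
    """Random composition of axis flips and 90-degree rotations.

    Restricted to the octahedral group so masks stay binary (no
    interpolation); returns a callable applied identically to image and mask.
    """
    flips = tuple(int(a) for a in np.flatnonzero(rng.random(3) < 0.5))
    rots = [(int(rng.integers(0, 4)), axes) for axes in ((0, 1), (0, 2), (1, 2))]

    def apply(arr: np.ndarray) -> np.ndarray:
        if flips:
            arr = np.flip(arr, axis=flips)
        for k, axes in rots:
            if k:
                arr = np.rot90(arr, k=k, axes=axes)
        return arr.copy()

    return apply


def sample_patch(
    case: SyntheticCase,
    patch_size: tuple[int, int, int],
    augment: bool = False,
    rng_seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly crop a training patch (and its mask) from a case.

    With ``augment`` a random flip/rotation from the 90-degree orthogonal
    group is applied identically to both arrays.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    shape = case.volume.shape
    patch_size = tuple(int(p) for p in patch_size)
    for ax, (p, s) in enumerate(zip(patch_size, shape)):
        if p > s:
            raise ValueError(f"patch size {p} exceeds volume extent {s} on axis {ax}")
    offset = [int(rng.integers(0, s - p + 1)) for p, s in zip(patch_size, shape)]
    sl = tuple(slice(o, o + p) for o, p in zip(offset, patch_size))
    vol = case.volume[sl]
    msk = case.lesion_mask[sl]
    if augment:
        transform = _random_orthogonal_transform(rng)
        vol, msk = transform(vol), transform(msk)
    return np.ascontiguousarray(vol), np.ascontiguousarray(msk)


# -- optional on-disk representation (NIfTI + JSON manifest) ---------------


def write_client_cases(cases: list[SyntheticCase], out_dir) -> Path:
    """Write cases as ``<id>_flair.nii.gz`` / ``<id>_mask.nii.gz`` + manifest."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for case in cases:
        affine = np.eye(4)
        img = nib.Nifti1Image(case.volume.astype(np.float32), affine)
        msk = nib.Nifti1Image(case.lesion_mask.astype(np.uint8), affine)
        nib.save(img, out_dir / f"{case.case_id}_flair.nii.gz")
        nib.save(msk, out_dir / f"{case.case_id}_mask.nii.gz")
        manifest.append(
            {
                "case_id": case.case_id,
                "flair": f"{case.case_id}_flair.nii.gz",
                "mask": f"{case.case_id}_mask.nii.gz",
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def read_client_cases(manifest_path) -> list[SyntheticCase]:
    """Load cases written by :func:`write_client_cases`.

    The brain mask is recovered as the nonzero-intensity support, matching
    how brain-extracted inputs are interpreted throughout the package.
    """
    import nibabel as nib

    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    cases = []
    for e in entries:
        vol = np.asarray(
            nib.load(manifest_path.parent / e["flair"]).dataobj, dtype=np.float32
        )
        msk = np.asarray(nib.load(manifest_path.parent / e["mask"]).dataobj) > 0
        cases.append(
            SyntheticCase(
                case_id=e["case_id"],
                volume=vol,
                lesion_mask=msk,
                brain_mask=vol != 0,
            )
        )
    return cases
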