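"""Synthetic labeled textures with controlled spatial correlation.

The generator produces gray-level textures whose classes differ in spatial
correlation length and/or intensity mixture, so the full feature pipeline
can be exercised and validated end to end.  Three kinds are supported:

- ``smoothed-noise``: seeded white noise blurred with a Gaussian kernel of
  the given correlation scale, affinely mapped onto the intensity range;
- ``binary-mosaic``: blurred noise thresholded at its median, the two sides
  assigned the two intensity levels, plus additive Gaussian noise — the two
  levels each cover exactly half the pixels, so mosaics with different
  correlation scales share the same marginal histogram and differ only in
  spatial structure;
- ``checkerboard``: a deterministic tiling of the levels plus noise.

The default benchmark pairs two binary mosaics with identical intensity
histograms but correlation scales 1 and 6: intensity-only features cannot
separate the classes, spatial-uncertainty features can.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import IntensityImage

__all__ = [
    "TextureSpec",
    "generate_texture",
    "generate_dataset",
    "dataset_from_manifest",
    "default_benchmark_specs",
]

KINDS = ("smoothed-noise", "binary-mosaic", "checkerboard")


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of one texture class; identical spec + seed -> identical image."""

    kind: str
    shape: tuple[int, int]
    correlation_scale: float = 0.0
    intensity_levels: tuple[float, ...] = (0.2, 0.8)
    noise_sd: float = 0.0
    seed: int = 0
    tile: int = 4  # checkerboard tile edge, pixels

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}; one of {KINDS}")
        if self.correlation_scale < 0:
            raise ValueError("correlation_scale must be >= 0")
        if len(self.intensity_levels) < 2:
            raise ValueError("need at least two intensity levels")
        if not all(0.0 <= v <= 1.0 for v in self.intensity_levels):
            raise ValueError("intensity levels must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "intensity_levels", tuple(float(v) for v in self.intensity_levels)
        )

    def replace(self, **changes) -> "TextureSpec":
        fields = asdict(self)
        fields.update(changes)
        return TextureSpec(**fields)


def generate_texture(spec: TextureSpec) -> IntensityImage:
    """Render one texture realization; clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = min(spec.intensity_levels), max(spec.intensity_levels)

    if spec.kind == "checkerboard":
        r, c = np.indices(spec.shape)
        idx = (r // spec.tile + c // spec.tile) % len(spec.intensity_levels)
        base = np.asarray(spec.intensity_levels)[idx]
    else:
        noise = rng.standard_normal(spec.shape)
        blurred = (
            gaussian_filter(noise, spec.correlation_scale)
            if spec.correlation_scale > 0
            else noise
        )
        if spec.kind == "smoothed-noise":
            span = blurred.max() - blurred.min()
            if span == 0:
                base = np.full(spec.shape, 0.5 * (lo + hi))
            else:
                base = lo + (blurred - blurred.min()) / span * (hi - lo)
        else:  # binary-mosaic: median split -> equal-area two-level field
            mask = blurred > np.median(blurred)
            base = np.where(mask, hi, lo)

    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, spec.shape)
    return IntensityImage(np.clip(base, 0.0, 1.0))


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-window seeds derived from the master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def generate_dataset(
    class_specs: dict[str, TextureSpec] | list[TextureSpec],
    windows_per_class: int = 40,
    window_shape: tuple[int, int] = (32, 32),
    seed: int = 0,
):
    """Labeled window collection: independent realizations cropped per window.

    Returns ``(windows, labels, manifest)`` where the manifest records every
    parameter and per-window seed needed to rebuild the identical dataset
    with :func:`dataset_from_manifest`.
    """
    if isinstance(class_specs, dict):
        items = list(class_specs.items())
    else:
        items = [(f"class{q}", spec) for q, spec in enumerate(class_specs)]
    if len(items) < 2:
        raise ValueError("need at least 2 texture classes")
    for _, spec in items:
        if window_shape[0] > spec.shape[0] or window_shape[1] > spec.shape[1]:
            raise ValueError(
                f"window {window_shape} larger than generated image {spec.shape}"
            )

    seeds = _child_seeds(seed, 2 * len(items) * windows_per_class)
    windows: list[IntensityImage] = []
    labels: list[str] = []
    entries = []
    pos = 0
    for label, spec in items:
        for _ in range(windows_per_class):
            realization_seed = seeds[pos]
            crop_seed = seeds[pos + 1]
            pos += 2
            image = generate_texture(spec.replace(seed=realization_seed))
            crop_rng = np.random.default_rng(crop_seed)
            r0 = int(crop_rng.integers(0, spec.shape[0] - window_shape[0] + 1))
            c0 = int(crop_rng.integers(0, spec.shape[1] - window_shape[1] + 1))
            windows.append(image.window((r0, c0), window_shape))
            labels.append(label)
            entry = asdict(spec)
            entry.update(
                label=label, seed=realization_seed, origin=(r0, c0)
            )
            entries.append(entry)

    manifest = {
        "master_seed": seed,
        "windows_per_class": windows_per_class,
        "window_shape": list(window_shape),
        "windows": entries,
    }
    return windows, labels, manifest


def dataset_from_manifest(manifest: dict):
    """Rebuild the exact dataset recorded by :func:`generate_dataset`."""
    window_shape = tuple(manifest["window_shape"])
    windows, labels = [], []
    for entry in manifest["windows"]:
        fields = {
            k: entry[k]
            for k in (
                "kind",
                "shape",
                "correlation_scale",
                "intensity_levels",
                "noise_sd",
                "seed",
                "tile",
            )
        }
        fields["shape"] = tuple(fields["shape"])
        fields["intensity_levels"] = tuple(fields["intensity_levels"])
        image = generate_texture(TextureSpec(**fields))
        windows.append(image.window(tuple(entry["origin"]), window_shape))
        labels.append(entry["label"])
    return windows, labels


def default_benchmark_specs(shape: tuple[int, int] = (32, 32)) -> dict[str, TextureSpec]:
    """Two equal-histogram mosaic classes differing only in correlation scale.

    ``fine`` uses scale 1, ``coarse`` scale 6; both mix gray levels 0.2 and
    0.8 in equal proportion with additive noise of sd 0.05, so the marginal
    intensity distributions match and only the spatial arrangement differs.
    """
    common = dict(
        kind="binary-mosaic",
        shape=shape,
        intensity_levels=(0.2, 0.8),
        noise_sd=0.05,
    )
    return {
        "fine": TextureSpec(correlation_scale=1.0, **common),
        "coarse": TextureSpec(correlation_scale=6.0, **common),
    }
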