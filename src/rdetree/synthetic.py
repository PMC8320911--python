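"""Synthetic labelled collections for exercising the retrieval stack.

Real evaluation corpora for this kind of engine are labelled image
collections (tens of classes, tens of images per class, one dense feature
vector per image).  This module emulates that shape two ways:

* :func:`gaussian_mixture_features` — feature vectors drawn from an
  isotropic Gaussian mixture with a tunable class-separation parameter
  ``s``: class means sit on a sphere of radius ``s * sigma * sqrt(K)``, so
  ``s`` reads as "mean distance from origin in per-axis noise units".
  ``s=6`` gives well-separated classes (an "easy" corpus), ``s=0``
  collapses every class onto the same mean.
* :func:`synthetic_images` — tiny RGB images with a deterministic per-class
  pattern (base colour plus stripe/checker frequency) and per-item pixel
  noise, for exercising feature extractors end to end.

Randomness is split per class via ``numpy`` seed sequences: class ``c``
always draws from the substream ``(seed, c)``, so adding classes never
perturbs earlier classes' draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LabelledFeatureSet", "gaussian_mixture_features", "synthetic_images",
           "write_labels", "write_images"]


@dataclass
class LabelledFeatureSet:
    """A labelled corpus of feature vectors.

    ``features`` is N x K (N = C * M, row-aligned with ``labels``);
    ``class_means`` is C x K; ``params`` echoes the generator settings.
    """

    features: np.ndarray
    labels: np.ndarray
    class_means: np.ndarray
    params: dict

    @property
    def n_items(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def _class_rng(seed: int, c: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c,)))


def gaussian_mixture_features(C: int, M: int, K: int, s: float = 6.0,
                              sigma: float = 1.0, seed: int = 0) -> LabelledFeatureSet:
    """Draw a C-class, M-per-class, K-dimensional Gaussian-mixture corpus.

    Class means are uniform on the sphere of radius ``s * sigma * sqrt(K)``
    about the origin; items are the class mean plus isotropic Gaussian
    noise of standard deviation ``sigma``.  Bit-for-bit reproducible from
    ``seed``.

    Raises
    ------
    ValueError
        On non-positive counts/dimension, negative ``s``, or ``sigma <= 0``.
    """
    if C < 1 or M < 1 or K < 1:
        raise ValueError("C, M, K must all be >= 1")
    if s < 0:
        raise ValueError("separation s must be >= 0")
    if sigma <= 0:
        raise ValueError("noise sigma must be > 0")
    radius = s * sigma * np.sqrt(K)
    means = np.empty((C, K))
    rows = np.empty((C * M, K))
    labels = np.repeat(np.arange(C), M)
    for c in range(C):
        rng = _class_rng(seed, c)
        direction = rng.standard_normal(K)
        norm = np.linalg.norm(direction)
        means[c] = radius * direction / norm if norm > 0 else 0.0
        rows[c * M:(c + 1) * M] = means[c] + sigma * rng.standard_normal((M, K))
    return LabelledFeatureSet(
        features=rows, labels=labels, class_means=means,
        params={"C": C, "M": M, "K": K, "s": s, "sigma": sigma, "seed": seed},
    )


# class patterns cycle through stripes (3 orientations) and checkers
def _class_pattern(c: int, side: int, rng: np.random.Generator) -> np.ndarray:
    base = rng.uniform(40, 215, size=3)
    freq = 2 + (c % 5)
    yy, xx = np.mgrid[0:side, 0:side]
    kind = c % 4
    if kind == 0:
        mask = (xx * freq // side) % 2
    elif kind == 1:
        mask = (yy * freq // side) % 2
    elif kind == 2:
        mask = ((xx + yy) * freq // side) % 2
    else:
        mask = ((xx * freq // side) + (yy * freq // side)) % 2
    img = np.empty((side, side, 3))
    alt = 255.0 - base
    img[mask == 0] = base
    img[mask == 1] = alt
    return img


def synthetic_images(C: int, M: int, side: int = 32,
                     seed: int = 0, noise_sd: float = 8.0):
    """Generate ``C * M`` noisy patterned RGB images plus labels.

    Each class owns a deterministic pattern (base colour + stripe/checker
    orientation and frequency derived from the class id); each item adds
    independent Gaussian pixel noise.  Returns ``(images, labels)`` with
    ``images`` a list of uint8 arrays of shape (side, side, 3).

    Raises
    ------
    ValueError
        If ``side < 16`` or counts are non-positive.
    """
    if side < 16:
        raise ValueError("side must be >= 16")
    if C < 1 or M < 1:
        raise ValueError("C and M must be >= 1")
    images, labels = [], []
    for c in range(C):
        rng = _class_rng(seed, c)
        pattern = _class_pattern(c, side, rng)
        for _ in range(M):
            noisy = pattern + noise_sd * rng.standard_normal(pattern.shape)
            images.append(np.clip(noisy, 0, 255).astype(np.uint8))
            labels.append(c)
    return images, np.asarray(labels)


def write_labels(labels: np.ndarray, path) -> None:
    """Plain-text labels file: one ``item_id<TAB>class_id`` line per item."""
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{int(lab)}\n")


def write_images(images, directory) -> list[Path]:
    """Write images as PNG files ``item_<i>.png`` under ``directory``."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = directory / f"item_{i:05d}.png"
        Image.fromarray(img).save(p)
        paths.append(p)
    return paths
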