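"""Image-to-vector feature extraction.

Extractors satisfy a minimal transformer contract: ``transform`` maps a
list of H x W x 3 images to an (n, dim) float matrix, and ``spec`` declares
name, output dimension and determinism.  Two extractors are provided:

* :class:`ToyGridExtractor` — deterministic per-channel block means over a
  g x g grid (dim = 3 g**2), cheap enough for tests and toy pipelines.
* :class:`DeepBackboneExtractor` — adapter for a pretrained 50-layer
  residual network cut before the classifier (global-pooled, 2048-D).  It
  requires an optional deep-learning runtime; when none is importable it
  raises :class:`BackboneUnavailableError` rather than silently degrading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExtractorSpec",
    "BackboneUnavailableError",
    "ToyGridExtractor",
    "DeepBackboneExtractor",
    "toy_extract",
    "spm_descriptor_length",
]


class BackboneUnavailableError(RuntimeError):
    """The configured deep backbone is not available in this runtime."""


@dataclass(frozen=True)
class ExtractorSpec:
    name: str
    dim: int
    deterministic: bool
    params: dict = field(default_factory=dict)


def _check_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("image is empty")
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    if img.ndim != 3:
        raise ValueError(f"expected H x W x C image, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def toy_extract(image, grid: int = 4) -> np.ndarray:
    """Per-channel block means over a ``grid x grid`` partition of the image.

    Output layout is channel-major: for each channel, the g**2 cell means
    in row-major cell order; dim = 3 * grid**2.  8-bit input is scaled by
    1/255 so values lie in [0, 1].
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    img = _check_image(image)
    H, W, C = img.shape
    rows = np.linspace(0, H, grid + 1).round().astype(int)
    cols = np.linspace(0, W, grid + 1).round().astype(int)
    out = np.empty(C * grid * grid)
    k = 0
    for ch in range(C):
        for i in range(grid):
            for j in range(grid):
                cell = img[rows[i]:rows[i + 1], cols[j]:cols[j + 1], ch]
                out[k] = cell.mean() if cell.size else 0.0
                k += 1
    return out


class ToyGridExtractor(BaseEstimator, TransformerMixin):
    """Deterministic grid-block-mean extractor (dim = 3 * grid**2)."""

    def __init__(self, grid: int = 4):
        self.grid = grid

    @property
    def spec(self) -> ExtractorSpec:
        return ExtractorSpec(name="toy", dim=3 * self.grid ** 2,
                             deterministic=True, params={"grid": self.grid})

    def fit(self, X=None, y=None):
        return self

    def transform(self, images) -> np.ndarray:
        return np.array([toy_extract(img, self.grid) for img in images])


class DeepBackboneExtractor(BaseEstimator, TransformerMixin):
    """Pretrained residual-network feature extractor (optional capability).

    Uses the activations of the layer immediately before the classifier of
    a 50-layer residual network pretrained on ImageNet, global-pooled to a
    2048-D vector per image; inputs are resized (bilinear) to 224 x 224.
    The 50-layer variant is the default because it is the smallest member
    of the family with a 2048-D penultimate layer; 101/152 are accepted.

    The adapter only declares its contract here; constructing it requires
    ``torch`` + ``torchvision`` at run time and otherwise raises
    :class:`BackboneUnavailableError`.
    """

    DIM = 2048
    INPUT_SIDE = 224

    def __init__(self, depth: int = 50, pretrained: bool = True):
        self.depth = depth
        self.pretrained = pretrained

    @property
    def spec(self) -> ExtractorSpec:
        return ExtractorSpec(name=f"resnet{self.depth}", dim=self.DIM,
                             deterministic=True,
                             params={"depth": self.depth,
                                     "input_side": self.INPUT_SIDE,
                                     "pretrained": self.pretrained})

    def _backbone(self):
        if self.depth not in (50, 101, 152):
            raise ValueError("depth must be one of 50, 101, 152")
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as e:
            raise BackboneUnavailableError(
                "the deep extractor needs torch and torchvision; install them "
                "or use the toy extractor"
            ) from e
        import torch
        from torchvision import models
        ctor = getattr(models, f"resnet{self.depth}")
        net = ctor(weights="IMAGENET1K_V1" if self.pretrained else None)
        net.fc = torch.nn.Identity()
        net.eval()
        return net

    def fit(self, X=None, y=None):
        self.net_ = self._backbone()
        return self

    def transform(self, images) -> np.ndarray:
        if not hasattr(self, "net_"):
            self.fit()
        import torch
        from PIL import Image

        batch = []
        for img in images:
            arr = np.asarray(img)
            if arr.shape[:2] != (self.INPUT_SIDE, self.INPUT_SIDE):
                pil = Image.fromarray(arr.astype(np.uint8))
                pil = pil.resize((self.INPUT_SIDE, self.INPUT_SIDE),
                                 Image.BILINEAR)
                arr = np.asarray(pil)
            batch.append(arr.astype(np.float32) / 255.0)
        x = torch.from_numpy(np.stack(batch).transpose(0, 3, 1, 2))
        with torch.no_grad():
            out = self.net_(x)
        return out.numpy().astype(np.float64)


def spm_descriptor_length(levels: int, codebook_size: int) -> int:
    """Length of a concatenated spatial-pyramid bag-of-words descriptor.

    Level ``l`` contributes ``4**l`` sub-region histograms of
    ``codebook_size`` bins each, so the total over levels ``0..levels-1``
    is ``codebook_size * sum(4**l)`` — e.g. three levels with a 2000-word
    codebook give (1 + 4 + 16) * 2000 = 42000 dimensions.
    """
    if levels < 1 or codebook_size < 1:
        raise ValueError("levels and codebook_size must be >= 1")
    return codebook_size * sum(4 ** l for l in range(levels))
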