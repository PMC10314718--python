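"""Ordered collections of same-shape grayscale images with provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def derive_image_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Per-image seed sequence, a stable pure function of (master seed, index).

    Uses numpy's SeedSequence spawn-key mechanism so that every image in an
    ensemble has an independent, reproducible stream and the ensemble as a
    whole is a pure function of the master seed.
    """
    if master_seed is None:
        raise ValueError("a seed is required; all sampling must be reproducible")
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))


@dataclass
class ImageEnsemble:
    """Stack of same-shape 2-D grayscale images.

    Parameters
    ----------
    images : ndarray, shape (n, h, w)
        Pixel data. Nonnegative gray values for simulator output.
    pixel_pitch : float or None
        Physical size of one pixel in meters, if meaningful for the modality.
    provenance : dict
        How the ensemble was produced (model name, config, seed, or a path).
    """

    images: np.ndarray
    pixel_pitch: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError(f"expected (n, h, w) image stack, got shape {self.images.shape}")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("ensemble contains non-finite pixel values")

    def __len__(self) -> int:
        return self.images.shape[0]

    def __iter__(self):
        return iter(self.images)

    def __getitem__(self, i):
        return self.images[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def save(self, path: str | Path, fmt: str = "tiff") -> None:
        """Write the ensemble to ``path``.

        ``fmt='tiff'`` writes one multi-page TIFF stack plus a JSON sidecar
        with pitch and provenance; ``fmt='png'`` writes one 8- or 16-bit PNG
        per image into a directory.
        """
        path = Path(path)
        if fmt == "tiff":
            import tifffile

            path.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(path, self.images, photometric="minisblack")
            meta = {"pixel_pitch": self.pixel_pitch, "provenance": self.provenance}
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
        elif fmt == "png":
            from PIL import Image as PILImage

            path.mkdir(parents=True, exist_ok=True)
            arr = self.images
            if arr.dtype not in (np.uint8, np.uint16):
                raise ValueError("PNG export requires uint8 or uint16 pixel data; quantize first")
            for i, img in enumerate(arr):
                PILImage.fromarray(img).save(path / f"img_{i:06d}.png")
            (path / "meta.json").write_text(
                json.dumps({"pixel_pitch": self.pixel_pitch, "provenance": self.provenance}, indent=1)
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")

    @classmethod
    def load(cls, path: str | Path) -> "ImageEnsemble":
        """Load an ensemble from a TIFF stack or a directory of PNG/TIFF images."""
        path = Path(path)
        if path.is_dir():
            import tifffile
            from PIL import Image as PILImage

            files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
            if not files:
                raise ValueError(f"no PNG/TIFF images found in {path}")
            stacks = []
            for f in files:
                if f.suffix.lower() in {".tif", ".tiff"}:
                    arr = tifffile.imread(f)  # may be a multi-page stack
                else:
                    arr = np.asarray(PILImage.open(f))
                if arr.ndim == 2:
                    arr = arr[None]
                if arr.ndim != 3:
                    raise ValueError(f"{f} is not single-channel grayscale")
                stacks.append(arr)
            images = np.concatenate(stacks)
            meta = {}
            if (path / "meta.json").exists():
                meta = json.loads((path / "meta.json").read_text())
            return cls(images, meta.get("pixel_pitch"), meta.get("provenance", {"path": str(path)}))
        import tifffile

        images = tifffile.imread(path)
        if images.ndim == 2:
            images = images[None]
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(images, meta.get("pixel_pitch"), meta.get("provenance", {"path": str(path)}))
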