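"""Reading, normalising and writing multichannel marker images and sample manifests.

Images are held channels-last (H, W, N) with one plane per protein marker,
the layout used throughout the package.  Multichannel TIFFs are read with
plane order taken as channel order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "donor_id", "image_path", "label")


class ChannelNotFoundError(KeyError):
    """A requested channel name is absent from the image."""


@dataclass
class MultiplexImage:
    """An H x W x N raster of marker intensities with named channels.

    Parameters
    ----------
    pixels
        Array of shape (H, W, N); finite and non-negative before
        normalisation.
    channel_names
        N unique marker identifiers, one per plane.
    sample_id
        Identifier of the sample the image belongs to.
    """

    pixels: np.ndarray
    channel_names: list[str]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be 3-D (H, W, N), got shape {self.pixels.shape}")
        h, w, n = self.pixels.shape
        if n < 1 or h < 16 or w < 16:
            raise ValueError(f"image too small: H={h}, W={w}, N={n} (need H,W>=16, N>=1)")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n} planes"
            )
        if len(set(self.channel_names)) != n:
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def select_channels(self, channels: Sequence[str]) -> "MultiplexImage":
        """Return a view-copy restricted to ``channels`` in the given order."""
        idx = []
        for c in channels:
            if c not in self.channel_names:
                raise ChannelNotFoundError(f"channel {c!r} not in {self.channel_names}")
            idx.append(self.channel_names.index(c))
        return MultiplexImage(self.pixels[:, :, idx].copy(), list(channels), self.sample_id)


@dataclass(frozen=True)
class SampleRecord:
    """One manifest row: a sample, its donor, its image file and outcome class."""

    sample_id: str
    donor_id: str
    image_path: str
    label: int
    raw_label: str = ""


def read_image(path: str | Path, channels: Sequence[str] | None = None) -> MultiplexImage:
    """Read a multichannel TIFF as a :class:`MultiplexImage`.

    TIFF planes are treated as channels in file order.  Channel names are
    taken from the TIFF page names when present, else ``c0..c{N-1}``.
    ``channels`` restricts and reorders the result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    # planes-first in the file -> channels-last in memory
    pixels = np.moveaxis(arr, 0, -1).astype(np.float64)
    names = _tiff_channel_names(path, pixels.shape[2])
    image = MultiplexImage(pixels, names, sample_id=path.stem)
    if channels is not None:
        image = image.select_channels(channels)
    return image


def write_image(image: MultiplexImage, path: str | Path) -> None:
    """Write an image as a planes-first multichannel TIFF with channel metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    planes = np.moveaxis(np.asarray(image.pixels), -1, 0)
    tifffile.imwrite(
        path,
        planes.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "CYX", "channel_names": image.channel_names},
    )


def _tiff_channel_names(path: Path, n: int) -> list[str]:
    try:
        with tifffile.TiffFile(path) as tf:
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta:
                if isinstance(meta, (list, tuple)):
                    meta = meta[0]
                names = meta.get("channel_names")
                if names is not None and len(names) == n:
                    return [str(x) for x in names]
    except Exception:  # noqa: BLE001 - metadata is best-effort
        pass
    return [f"c{i}" for i in range(n)]


def normalize_channels(
    image: MultiplexImage, cofactor: float = 5.0, clip_q: float = 99.0
) -> MultiplexImage:
    """arcsinh-transform, percentile-clip and min-max scale each channel to [0, 1].

    Per channel: ``y = arcsinh(x / cofactor)``, clipped at that channel's
    ``clip_q`` percentile, then divided by the clip value.  An all-zero
    channel stays all-zero.  The transform is monotone within each channel.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    if not 0 < clip_q <= 100:
        raise ValueError(f"clip_q must lie in (0, 100], got {clip_q}")
    x = np.asarray(image.pixels, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("negative intensities: normalise raw (non-negative) images")
    y = np.arcsinh(x / cofactor)
    out = np.zeros_like(y)
    for c in range(y.shape[2]):
        hi = np.percentile(y[:, :, c], clip_q)
        if hi > 0:
            out[:, :, c] = np.clip(y[:, :, c], 0.0, hi) / hi
    return replace(image, pixels=out)


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a comma-delimited sample manifest.

    Required header columns: sample_id, donor_id, image_path, label.  Raw
    labels are re-encoded to contiguous integers 0..K-1 in alphabetical
    order of the raw values; the mapping is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        warnings.warn(f"manifest {path} has no data rows", stacklevel=2)
        return []
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dupes}")
    mapping = {raw: k for k, raw in enumerate(sorted(df["label"].unique()))}
    logger.info("label encoding: %s", mapping)
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            donor_id=row.donor_id,
            image_path=row.image_path,
            label=mapping[row.label],
            raw_label=row.label,
        )
        for row in df.itertuples()
    ]
    for rec in records:
        if not Path(rec.image_path).exists():
            logger.warning("image for sample %s not found at %s", rec.sample_id, rec.image_path)
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records back to a comma-delimited manifest (raw labels if known)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "donor_id": [r.donor_id for r in records],
            "image_path": [r.image_path for r in records],
            "label": [r.raw_label or str(r.label) for r in records],
        }
    ).to_csv(path, index=False)
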