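"""Shared containers and errors for the translocation-assay pipeline.

Coordinate convention throughout the package: row-major, 0-based pixel
indices; images and masks always share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

NUCLEAR_CHANNEL = "nuclear_marker"
GFP_CHANNEL = "gfp"
DAPI_CHANNEL = "dapi"


class ConfigError(ValueError):
    """A configuration, layout or schema problem detected before computation."""


class PipelineError(RuntimeError):
    """A stage failed mid-run; partial outputs are retained."""


@dataclass
class ImageField:
    """One imaged field of view: named 2-D intensity channels plus metadata.

    ``channels`` maps channel name -> 2-D float array (counts). The nuclear
    marker channel (DAPI or a constitutive nuclear label such as mCherry-NF1)
    drives segmentation; the GFP reporter channel is quantified.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float = 325.0
    plate: str = "PLATE"
    well: str = "A01"
    field_index: int = 0
    timepoint: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField requires at least one channel")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name, arr in self.channels.items():
            if np.ndim(arr) != 2:
                raise ValueError(f"channel {name!r} is not a 2-D image")
            if np.min(arr) < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class LabelMask:
    """Integer label image: 0 = background, 1..K = objects.

    ``kind`` is ``"nucleus"`` or ``"ring"``. For a paired set, ring labels are
    a subset of nucleus labels and ring pixels never overlap any nucleus.
    """

    data: np.ndarray
    kind: str = "nucleus"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    @property
    def labels(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def iter_slices(self) -> Iterator[tuple[int, tuple[slice, slice]]]:
        from scipy import ndimage

        objs = ndimage.find_objects(self.data)
        for lab, sl in enumerate(objs, start=1):
            if sl is not None:
                yield lab, sl


def as_labels(mask: "LabelMask | np.ndarray") -> np.ndarray:
    """Return the raw integer label array behind a mask-like input."""
    if isinstance(mask, LabelMask):
        return mask.data
    arr = np.asarray(mask)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label array must be integer-typed")
    return arr
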