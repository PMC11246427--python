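"""Named-channel 2-D raster container used throughout the package.

A :class:`FieldImage` is the in-memory form of one imaged field of view:
a stack of co-registered single-plane channels (nuclei, reporters, ligands,
immunostains) sharing one pixel size.  Intensities are stored as float64
copies of the raw values and are never rescaled on construction — thresholds
and correlation statistics operate in raw camera units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["FieldImage"]


@dataclass
class FieldImage:
    """Multichannel 2-D fluorescence field.

    Parameters
    ----------
    channels
        Mapping of channel name to 2-D array. All channels must share one
        shape. Arrays are converted to float64 without rescaling.
    px_size_um
        Physical pixel size in micrometres per pixel; must be positive.
    """

    channels: dict[str, np.ndarray]
    px_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.px_size_um <= 0:
            raise ValueError(f"px_size_um must be positive, got {self.px_size_um}")
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=np.float64)
            if a.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D (shape {a.shape})")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError(
                    f"channel {name!r} shape {a.shape} differs from {shape}"
                )
            clean[name] = a
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field in micrometres."""
        nrow, ncol = self.shape
        return (ncol * self.px_size_um, nrow * self.px_size_um)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in image (have {self.channel_names})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def add_channel(self, name: str, arr: np.ndarray) -> None:
        a = np.asarray(arr, dtype=np.float64)
        if a.shape != self.shape:
            raise ValueError(f"channel {name!r} shape {a.shape} != {self.shape}")
        self.channels[name] = a

    def to_stack(self) -> np.ndarray:
        """Channels stacked along axis 0, in insertion order."""
        return np.stack([self.channels[n] for n in self.channels], axis=0)

    @classmethod
    def from_stack(
        cls, stack: np.ndarray, names: list[str], px_size_um: float, meta: Mapping | None = None
    ) -> "FieldImage":
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"expected (C, H, W) stack, got shape {stack.shape}")
        if len(names) != stack.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {stack.shape[0]} planes"
            )
        return cls(dict(zip(names, stack)), px_size_um, dict(meta or {}))
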