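"""Shared in-memory containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeLapse:
    """Ordered single-channel image frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; dtype float for intensity images or
        bool for confluence masks.
    pixel_size
        Physical size of one pixel in µm/px.
    frame_interval
        Time between consecutive frames in hours.
    t0
        Acquisition time of the first frame in hours.
    """

    frames: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in hours."""
        return self.t0 + np.arange(self.n_frames) * self.frame_interval

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class RegionMasks:
    """Per-cell partition into the sub-cellular regions used for ratiometry.

    ``peripheral`` may extend up to 2 px beyond ``cell`` (membrane-band mode);
    ``cytoplasm`` is always ``cell`` minus ``peripheral`` minus ``nucleus``.
    """

    cell: np.ndarray
    nucleus: np.ndarray
    peripheral: np.ndarray
    cytoplasm: np.ndarray
    juxtanuclear: np.ndarray
    meta: dict = field(default_factory=dict)

    def region(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def whole(self) -> np.ndarray:
        """Whole-cell reference mask (cell plus any outward band overhang)."""
        return self.cell | self.peripheral

    def validate(self) -> None:
        if (self.peripheral & self.nucleus).any():
            raise ValueError("peripheral and nucleus masks overlap")
        expected = self.cell & ~self.peripheral & ~self.nucleus
        if not np.array_equal(self.cytoplasm, expected):
            raise ValueError("cytoplasm is not cell - peripheral - nucleus")
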