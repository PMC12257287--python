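"""Hardware driver contract and its simulated implementation.

Real instruments differ; jobs therefore talk to a minimal three-call
contract — move the stage, project a frame, capture the current field —
and any object honouring it can execute a plan. This package ships only
the simulated driver: it records every call and accumulates the projected
dose on a virtual substrate, so whole jobs run and are testable with no
microscope attached. Move-then-project is treated as atomic per exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class DriverContract(Protocol):
    """What a job needs from an instrument."""

    def move_stage(self, x_um: float, y_um: float) -> None: ...

    def project_frame(self, frame: np.ndarray, time_ms: float) -> None: ...

    def capture_image(self) -> np.ndarray: ...


@dataclass
class SimulatedDriver:
    """Records stage moves and projections; no hardware involved.

    ``pixel_size_um`` is the projected DMD pixel size used to place frames
    on the virtual substrate; the dose model matches the virtual printer
    (uniform energy over the illuminated field's ON pixels).
    """

    pixel_size_um: float = 0.702
    power_mW: float = 2.96
    moves: list[tuple[float, float]] = field(default_factory=list)
    projections: list[tuple[float, float, float, int]] = field(default_factory=list)

    _x: float = 0.0
    _y: float = 0.0
    _last_frame: np.ndarray | None = None

    def move_stage(self, x_um: float, y_um: float) -> None:
        self._x, self._y = float(x_um), float(y_um)
        self.moves.append((self._x, self._y))

    def project_frame(self, frame: np.ndarray, time_ms: float) -> None:
        frame = np.asarray(frame, dtype=bool)
        self._last_frame = frame
        self.projections.append(
            (self._x, self._y, float(time_ms), int(frame.sum()))
        )

    def capture_image(self) -> np.ndarray:
        """Return an 8-bit rendering of the last projected field.

        Bright where mirrors were ON — a stand-in for the camera view used
        for fiducial alignment on real hardware.
        """
        if self._last_frame is None:
            return np.zeros((1, 1), dtype=np.uint8)
        return (self._last_frame.astype(np.uint8)) * 255

    @property
    def n_calls(self) -> int:
        return len(self.moves) + len(self.projections)
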