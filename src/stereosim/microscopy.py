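"""Virtual microscopy: exhaustive sectioning and systematic frame placement.

Reproduces the physical sampling chain of a design-based stereology study:
the tissue is cut exhaustively into coronal sections of fixed thickness,
every ``period``-th section (after a uniform random start) is retained, and
unbiased counting frames are laid out on a systematic square grid with a
uniform random offset drawn once per animal.

Conventions (chosen so the partition/tiling guarantees are exact):

* section z-intervals are half-open ``[z, z + t)`` and tile the extent;
* frame membership is open on the left/bottom (exclusion) edges and closed
  on the right/top (inclusion) edges, i.e. a frame with lower-left corner
  ``(x0, y0)`` and side ``s`` contains points with ``x0 < x <= x0 + s``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import TissueModel
from .errors import ConfigurationError, ConsistencyError

__all__ = [
    "SamplingGeometry",
    "SectionPlan",
    "Section",
    "FrameGrid",
    "plan_sections",
    "take_sections",
    "place_frames",
    "layout_to_json",
]


@dataclass(frozen=True)
class SamplingGeometry:
    """Physical sampling parameters (µm) of the virtual microscope.

    Defaults are the conventional design: 40 µm coronal sections sampled
    every 12th, 40×40 µm frames on a 500×500 µm grid, and a 20 µm dissector
    inside 2 µm guard zones (tsf = 0.5).
    """

    section_thickness: float = 40.0
    period: int = 12
    frame_side: float = 40.0
    grid_step: float = 500.0
    dissector_height: float = 20.0
    guard_zone: float = 2.0

    def __post_init__(self) -> None:
        if self.section_thickness <= 0 or self.period < 1:
            raise ConfigurationError("invalid sectioning parameters")
        if not 0 < self.frame_side <= self.grid_step:
            raise ConfigurationError("frame_side must lie in (0, grid_step]")
        if self.dissector_height <= 0 or self.guard_zone < 0:
            raise ConfigurationError("invalid dissector window")
        if self.dissector_height + 2 * self.guard_zone > self.section_thickness + 1e-9:
            raise ConfigurationError("dissector window must fit within the section")


@dataclass(frozen=True)
class SectionPlan:
    """Exhaustive coronal sectioning plus a systematic sampling rule."""

    z_extent: float
    thickness: float
    period: int
    random_start: int

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigurationError("section thickness must be positive")
        if self.period < 1:
            raise ConfigurationError("sampling period must be >= 1")
        if not 0 <= self.random_start < self.period:
            raise ConfigurationError("random_start must lie in [0, period)")

    @property
    def n_sections(self) -> int:
        return math.ceil(self.z_extent / self.thickness)

    @property
    def section_z_intervals(self) -> list[tuple[float, float]]:
        t = self.thickness
        return [(i * t, (i + 1) * t) for i in range(self.n_sections)]

    @property
    def sampled_indices(self) -> list[int]:
        return [i for i in range(self.n_sections) if i % self.period == self.random_start]


@dataclass
class Section:
    """One retained section with the neurons whose counting point it contains."""

    index: int
    z0: float
    z1: float
    positions: np.ndarray  # (n, 3), alive neurons only
    volumes: np.ndarray  # (n,)
    extent_xy: tuple[float, float]

    @property
    def n_contained(self) -> int:
        return int(self.positions.shape[0])


def plan_sections(
    extent: Sequence[float],
    thickness: float,
    period: int,
    rng: np.random.Generator,
) -> SectionPlan:
    """Plan exhaustive sectioning of ``extent`` with a random systematic start."""
    if thickness <= 0:
        raise ConfigurationError("section thickness must be positive")
    if period < 1:
        raise ConfigurationError("sampling period must be >= 1")
    start = int(rng.integers(period))
    return SectionPlan(
        z_extent=float(extent[2]), thickness=float(thickness),
        period=int(period), random_start=start,
    )


def take_sections(tissue: TissueModel, plan: SectionPlan) -> list[Section]:
    """Assign each alive neuron to its section; return the sampled sections.

    The counting point is the neuron's position point; half-open z-intervals
    make the assignment a partition.
    """
    pos = tissue.alive_positions()
    vol = tissue.alive_volumes()
    idx = np.floor(pos[:, 2] / plan.thickness).astype(int)
    if pos.shape[0] and (idx.min() < 0 or idx.max() >= plan.n_sections):
        raise ConsistencyError("neuron z outside all section intervals")
    extent_xy = (float(tissue.extent[0]), float(tissue.extent[1]))
    sections = []
    for i in plan.sampled_indices:
        m = idx == i
        sections.append(
            Section(
                index=i,
                z0=i * plan.thickness,
                z1=(i + 1) * plan.thickness,
                positions=pos[m],
                volumes=vol[m],
                extent_xy=extent_xy,
            )
        )
    return sections


@dataclass(frozen=True)
class FrameGrid:
    """Systematic grid of square counting frames.

    One frame sits at the origin corner of every ``grid_step`` × ``grid_step``
    tile; the whole pattern is translated by ``offset``, drawn uniformly once
    per animal.
    """

    frame_side: float
    grid_step: float
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.frame_side <= 0 or self.grid_step <= 0:
            raise ConfigurationError("frame_side and grid_step must be positive")
        if self.frame_side > self.grid_step:
            raise ConfigurationError("frame_side must not exceed grid_step")
        if not (0 <= self.offset[0] < self.grid_step and 0 <= self.offset[1] < self.grid_step):
            raise ConfigurationError("offset must lie in [0, grid_step)^2")

    @classmethod
    def random(
        cls, frame_side: float, grid_step: float, rng: np.random.Generator
    ) -> "FrameGrid":
        off = rng.random(2) * grid_step
        return cls(frame_side=frame_side, grid_step=grid_step,
                   offset=(float(off[0]), float(off[1])))

    @property
    def area_sampling_fraction(self) -> float:
        return (self.frame_side / self.grid_step) ** 2


def place_frames(section: Section, grid: FrameGrid) -> np.ndarray:
    """Frames intersecting the section's x–y extent, as ``(k, 4)`` rectangles.

    Each row is ``(x0, y0, x1, y1)``; membership is ``x0 < x <= x1`` (and
    likewise in y).  Frames clipped by the tissue boundary are retained —
    simulated neurons cannot lie outside the tissue, so no edge bias arises.
    """
    sx, sy = section.extent_xy
    s = grid.grid_step
    side = grid.frame_side
    ox, oy = grid.offset

    def _ks(origin: float, hi: float) -> np.ndarray:
        # tile-corner frames (origin + k*s, origin + k*s + side] intersecting [0, hi)
        kmin = math.floor((-side - origin) / s)
        kmax = math.ceil((hi - origin) / s)
        k = np.arange(kmin, kmax + 1)
        x0 = origin + k * s
        return x0[(x0 < hi) & (x0 + side > 0)]

    xs = _ks(ox, sx)
    ys = _ks(oy, sy)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    x0 = gx.ravel()
    y0 = gy.ravel()
    return np.column_stack([x0, y0, x0 + side, y0 + side])


def layout_to_json(
    plan: SectionPlan, grid: FrameGrid, frames_by_section: dict[int, np.ndarray],
    path: str | Path | None = None,
) -> str:
    """Serialize the sampling layout (for debugging/plotting)."""
    payload = {
        "plan": {
            "z_extent": plan.z_extent,
            "thickness": plan.thickness,
            "period": plan.period,
            "random_start": plan.random_start,
            "sampled_indices": plan.sampled_indices,
        },
        "grid": {
            "frame_side": grid.frame_side,
            "grid_step": grid.grid_step,
            "offset": list(grid.offset),
        },
        "frames": {str(k): np.asarray(v).tolist() for k, v in frames_by_section.items()},
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
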