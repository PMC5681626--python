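"""Space-filling design of experiments over the slab-parameter hypercube.

Simulation settings are triples ``[t, g, s_l]`` (slab thickness, anisotropy
factor, scattering length).  They are laid out with a Sobol sequence so that
every consecutive prefix of the design is itself space-filling, which lets a
single design serve nested training subsets of increasing size plus a
held-out test block.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .simulator import SampleParams

__all__ = [
    "DesignSpace",
    "Design",
    "DesignPartition",
    "generate_design",
    "partition_design",
    "read_design",
    "write_design",
]


@dataclass(frozen=True)
class DesignSpace:
    """Bounding box of the slab parameters.

    Parameters
    ----------
    g_bounds : (low, high)
        Anisotropy factor, dimensionless.
    sl_bounds : (low, high)
        Scattering length in **mm** (the conventional I/O unit; internally
        lengths are carried in µm).
    t_bounds : (low, high)
        Slab thickness in µm.

    Defaults cover the scattering properties of a wide range of soft
    biological tissues (liver, white/grey brain matter, cerebellum,
    brainstem).
    """

    g_bounds: tuple[float, float] = (0.7, 0.93)
    sl_bounds: tuple[float, float] = (0.03, 0.12)
    t_bounds: tuple[float, float] = (200.0, 600.0)

    def __post_init__(self) -> None:
        for name in ("g_bounds", "sl_bounds", "t_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: require lower < upper, got {lo, hi}")

    @property
    def lower(self) -> np.ndarray:
        """Lower corner in (g, sl_mm, t_um) order."""
        return np.array([self.g_bounds[0], self.sl_bounds[0], self.t_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.g_bounds[1], self.sl_bounds[1], self.t_bounds[1]])

    def scale(self, unit_points: np.ndarray) -> np.ndarray:
        """Affinely map points from the unit cube to this box (g, sl_mm, t_um)."""
        unit_points = np.atleast_2d(np.asarray(unit_points, dtype=float))
        return qmc.scale(unit_points, self.lower, self.upper)

    def unscale(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`scale`: map (g, sl_mm, t_um) rows to the unit cube."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return qmc.scale(points, self.lower, self.upper, reverse=True)


@dataclass(frozen=True)
class Design:
    """An ordered Sobol design; consecutive prefixes remain space-filling."""

    points: tuple[SampleParams, ...]
    space: DesignSpace = field(default_factory=DesignSpace)
    sequence_index: int = 0  # offset (skip) into the Sobol sequence

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, i):
        return self.points[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_um": [p.t for p in self.points],
                "g": [p.g for p in self.points],
                "sl_mm": [p.s_l / 1000.0 for p in self.points],
            }
        )

    def to_array(self) -> np.ndarray:
        """(n, 3) array in (g, sl_mm, t_um) column order."""
        return np.column_stack(
            [
                [p.g for p in self.points],
                [p.s_l / 1000.0 for p in self.points],
                [p.t for p in self.points],
            ]
        )


@dataclass(frozen=True)
class DesignPartition:
    """Nested training prefixes plus a disjoint held-out test block."""

    train: tuple[Design, ...]
    test: Design


def generate_design(
    n: int, space: DesignSpace | None = None, skip: int = 0
) -> Design:
    """Draw ``n`` consecutive Sobol points and rescale them to ``space``.

    The unscrambled Sobol sequence (scipy's direction numbers, first point at
    the origin) is used so that runs are exactly reproducible from
    ``(n, skip)`` alone; ``skip`` fast-forwards past the first ``skip``
    points and is recorded on the returned design.
    """
    if n < 1:
        raise ValueError(f"need at least one design point, got n={n}")
    if skip < 0:
        raise ValueError(f"skip must be nonnegative, got {skip}")
    space = space or DesignSpace()
    sampler = qmc.Sobol(d=3, scramble=False)
    if skip:
        sampler.fast_forward(skip)
    unit = sampler.random(n)
    scaled = space.scale(unit)
    points = tuple(
        SampleParams(t=row[2], g=row[0], s_l=row[1] * 1000.0) for row in scaled
    )
    return Design(points=points, space=space, sequence_index=skip)


def partition_design(
    design: Design, train_sizes: Sequence[int], n_test: int
) -> DesignPartition:
    """Split a design into nested training prefixes and a trailing test block.

    The i-th training subset is the first ``train_sizes[i]`` points; the test
    set is the last ``n_test`` points, so train and test are disjoint as long
    as ``max(train_sizes) + n_test <= len(design)``.
    """
    sizes = sorted(int(s) for s in train_sizes)
    if not sizes or sizes[0] < 1:
        raise ValueError("train_sizes must be positive")
    if sizes[-1] + n_test > len(design):
        raise ValueError(
            f"max train size {sizes[-1]} + n_test {n_test} exceeds "
            f"design size {len(design)}"
        )
    train = tuple(
        Design(design.points[:s], design.space, design.sequence_index)
        for s in sizes
    )
    test = Design(
        design.points[len(design) - n_test :],
        design.space,
        design.sequence_index + len(design) - n_test,
    )
    return DesignPartition(train=train, test=test)


def write_design(design: Design, path: str | Path) -> None:
    """Write a design as CSV (columns t_um, g, sl_mm) with a metadata comment."""
    sp = design.space
    header = (
        f"# sobol design, skip={design.sequence_index}, "
        f"g in {sp.g_bounds}, sl_mm in {sp.sl_bounds}, t_um in {sp.t_bounds}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        design.to_frame().to_csv(fh, index=False)


def read_design(path: str | Path) -> Design:
    """Read a design CSV written by :func:`write_design`."""
    text = Path(path).read_text()
    skip = 0
    space = DesignSpace()
    lines = text.splitlines(keepends=True)
    body = []
    for line in lines:
        if line.startswith("#"):
            if "skip=" in line:
                skip = int(line.split("skip=")[1].split(",")[0])
            if "g in" in line:
                g = eval(line.split("g in ")[1].split(", sl_mm")[0])  # noqa: S307
                sl = eval(line.split("sl_mm in ")[1].split(", t_um")[0])  # noqa: S307
                t = eval(line.split("t_um in ")[1].strip())  # noqa: S307
                space = DesignSpace(tuple(g), tuple(sl), tuple(t))
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)))
    points = tuple(
        SampleParams(t=r.t_um, g=r.g, s_l=r.sl_mm * 1000.0)
        for r in df.itertuples()
    )
    return Design(points=points, space=space, sequence_index=skip)
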