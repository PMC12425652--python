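"""Checkerboard spatial cross-validation partitioning.

Checkerboard1 assigns every point to one of two bins by the parity of the
coarse grid block it falls in: blocks are ``aggregation_factor`` raster
cells on a side, anchored at the raster origin, and bin = 1 + ((block_col +
block_row) mod 2).  Training and validation data are therefore separated by
spatial structure rather than at random, limiting the leakage caused by
spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import CovariateStack

__all__ = ["PartitionAssignment", "checkerboard1"]


@dataclass
class PartitionAssignment:
    """Two-bin assignment for occurrences and background points."""

    occurrence_bins: np.ndarray  # int in {1, 2}
    background_bins: np.ndarray
    aggregation_factor: int

    def to_frame(self, occ_xy: np.ndarray, bg_xy: np.ndarray) -> pd.DataFrame:
        """Long-format table: x, y, role, bin."""
        occ = pd.DataFrame({"x": occ_xy[:, 0], "y": occ_xy[:, 1],
                            "role": "occurrence", "bin": self.occurrence_bins})
        bg = pd.DataFrame({"x": bg_xy[:, 0], "y": bg_xy[:, 1],
                           "role": "background", "bin": self.background_bins})
        return pd.concat([occ, bg], ignore_index=True)


def _bins_for(stack: CovariateStack, xy: np.ndarray, f: int) -> np.ndarray:
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    row, col = stack.cell_index(xy[:, 0], xy[:, 1])
    if np.any((row < 0) | (col < 0)):
        bad = int(np.argmax((row < 0) | (col < 0)))
        raise ValueError(f"point ({xy[bad, 0]:g}, {xy[bad, 1]:g}) is off the stack's frame")
    return 1 + ((row // f + col // f) % 2)


def checkerboard1(occ_xy: np.ndarray, bg_xy: np.ndarray, stack: CovariateStack,
                  aggregation_factor: int = 10) -> PartitionAssignment:
    """Assign occurrences and background to the two checkerboard bins.

    Both point sets are partitioned by the same block grid, so a model
    trained on bin 1 occurrences is evaluated against bin 2 occurrences
    *and* bin 2 background.
    """
    if aggregation_factor < 1:
        raise ValueError("aggregation_factor must be >= 1")
    return PartitionAssignment(
        _bins_for(stack, occ_xy, aggregation_factor),
        _bins_for(stack, bg_xy, aggregation_factor),
        aggregation_factor,
    )
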