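"""2-D parameter grids with per-cell stability classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhaseGrid"]


@dataclass
class PhaseGrid:
    """Stability classification over a 2-D parameter grid.

    ``classes[i, j]`` is the class at ``axis1_values[i]``, ``axis2_values[j]``
    (one of ``monostable``, ``monostable_gene1``, ``monostable_gene2``,
    ``bistable``, ``joint_bistable``, ``unknown``); ``n_stable`` counts
    deterministic stable states where applicable; ``frequency`` holds
    stochastic switching frequencies in Hz (NaN where not measured).
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    classes: np.ndarray
    n_stable: np.ndarray | None = None
    frequency: np.ndarray | None = None
    cell_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = (len(self.axis1_values), len(self.axis2_values))
        if self.classes.shape != shape:
            raise ValueError(f"classes shape {self.classes.shape} != {shape}")
        if self.frequency is not None and np.any(self.frequency < 0):
            raise ValueError("switching frequencies must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.axis1_values), len(self.axis2_values))

    def count(self, cls: str) -> int:
        return int(np.sum(self.classes == cls))

    def to_frame(self):
        """Long-format table: one row per grid cell."""
        import pandas as pd
        rows = []
        for i, v1 in enumerate(self.axis1_values):
            for j, v2 in enumerate(self.axis2_values):
                row = {self.axis1_name: v1, self.axis2_name: v2,
                       "class": self.classes[i, j]}
                if self.n_stable is not None:
                    row["n_stable"] = int(self.n_stable[i, j])
                if self.frequency is not None:
                    row["frequency_hz"] = float(self.frequency[i, j])
                rows.append(row)
        return pd.DataFrame(rows)
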