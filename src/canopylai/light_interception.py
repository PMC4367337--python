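"""Ceptometer readings → fraction of light intercepted by the canopy.

One incident PAR reading above the canopy (I_o) and one or more transmitted
readings below it (I) give the dimensionless intercepted fraction

    I_c = 1 − mean(I) / I_o

I_c serves as an instantaneous proxy for the light extinction coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CeptometerSet", "compute_ic", "read_ceptometer_csv"]

_NEG_TOL = 1e-9


@dataclass(frozen=True)
class CeptometerSet:
    """One tree's PAR readings and its intercepted fraction."""

    i_o: float
    i_below: tuple[float, ...]
    i_c: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.i_o <= 0:
            raise ValueError(f"incident PAR must be positive, got {self.i_o}")
        below = tuple(float(v) for v in self.i_below)
        if not below:
            raise ValueError("at least one below-canopy reading is required")
        if any(v < 0 for v in below):
            raise ValueError("below-canopy readings cannot be negative")
        mean_below = float(np.mean(below))
        ic = 1.0 - mean_below / self.i_o
        if ic < -_NEG_TOL:
            raise ValueError(
                f"below-canopy exceeds incident: mean(I)={mean_below} > I_o={self.i_o}"
            )
        ic = min(max(ic, 0.0), 1.0)
        object.__setattr__(self, "i_below", below)
        object.__setattr__(self, "i_c", ic)


def compute_ic(i_o: float, i_below) -> CeptometerSet:
    """Average the below-canopy readings and form I_c = 1 − I/I_o."""
    return CeptometerSet(i_o=float(i_o), i_below=tuple(i_below))


def read_ceptometer_csv(path: str | Path) -> dict[str, CeptometerSet]:
    """Read per-tree ceptometer readings from CSV.

    Expected columns: ``tree_id``, ``i_o``, then one or more below-canopy
    reading columns (any names; five is the usual field protocol but any
    number ≥ 1 is accepted).  Returns one :class:`CeptometerSet` per row,
    keyed by tree id, with I_c computed on load.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "tree_id" not in cols or "i_o" not in cols:
        raise ValueError(
            f"{path}: CSV must have 'tree_id' and 'i_o' columns, got {cols}"
        )
    below_cols = [c for c in cols if c not in ("tree_id", "i_o")]
    if not below_cols:
        raise ValueError(f"{path}: no below-canopy reading columns found")
    out: dict[str, CeptometerSet] = {}
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        try:
            i_o = float(row["i_o"])
            below = [float(row[c]) for c in below_cols if pd.notna(row[c])]
            if not below:
                raise ValueError("no below-canopy readings")
            out[str(row["tree_id"])] = compute_ic(i_o, below)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, row {rownum}: {exc}") from exc
    return out
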