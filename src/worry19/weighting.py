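"""Quota / post-stratification weights on gender and age.

Two modes: ``cell`` (joint gender x age post-stratification: weight =
target share / sample share per cell) and ``raking`` (iterative proportional
fitting on the two margins). Weights are rescaled to a configurable
normalization total, defaulting to the sample size, since published weighted
totals need not equal n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

WEIGHT_DIMS = ("gender", "age_band")
_MARGIN_TOL = 1e-9


@dataclass
class MarginTargets:
    """Population targets: either joint cell shares or per-margin shares.

    ``cells`` maps (gender, age_band) -> share. When absent, cell-mode targets
    are formed as the product of the supplied margins. ``total`` is the
    normalization total for the weight vector (None = sample size).
    """

    margins: dict[str, dict[str, float]] = field(default_factory=dict)
    cells: Optional[dict[tuple[str, str], float]] = None
    total: Optional[float] = None

    def __post_init__(self) -> None:
        for dim, shares in self.margins.items():
            if dim not in WEIGHT_DIMS:
                raise ValueError(f"unknown weighting dimension {dim!r}")
            vals = np.array(list(shares.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative target share in margin {dim!r}")
            if abs(vals.sum() - 1.0) > _MARGIN_TOL:
                raise ValueError(f"margin {dim!r} shares sum to {vals.sum()}, not 1")
        if self.cells is not None:
            vals = np.array(list(self.cells.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError("negative cell target share")
            if abs(vals.sum() - 1.0) > _MARGIN_TOL:
                raise ValueError(f"cell shares sum to {vals.sum()}, not 1")

    def cell_shares(self) -> dict[tuple[str, str], float]:
        if self.cells is not None:
            return dict(self.cells)
        if not all(d in self.margins for d in WEIGHT_DIMS):
            missing = [d for d in WEIGHT_DIMS if d not in self.margins]
            raise ValueError(f"cell mode needs joint cells or both margins; missing {missing}")
        g, a = self.margins["gender"], self.margins["age_band"]
        return {(gv, av): gs * as_ for gv, gs in g.items() for av, as_ in a.items()}

    @classmethod
    def from_yaml(cls, path) -> "MarginTargets":
        payload = yaml.safe_load(open(path))
        cells = None
        if "cells" in payload:
            cells = {(c["gender"], c["age_band"]): float(c["share"]) for c in payload["cells"]}
        return cls(
            margins={k: {lv: float(s) for lv, s in v.items()} for k, v in payload.get("margins", {}).items()},
            cells=cells,
            total=payload.get("total"),
        )


def _check_complete(df: pd.DataFrame) -> None:
    for dim in WEIGHT_DIMS:
        if df[dim].isna().any():
            raise ValueError(f"cannot weight: missing {dim} for some respondents")


def compute_weights(
    df: pd.DataFrame, targets: MarginTargets, mode: str = "cell", max_iter: int = 100
) -> pd.Series:
    """Weight vector indexed like ``df``, matching targets on gender and age.

    Cell mode is exact post-stratification; raking iterates proportional
    fitting on the two margins until the maximum margin error is below 1e-8.
    An empty sample cell with a positive target is a hard error (cell mode).
    """
    _check_complete(df)
    n = len(df)
    if n == 0:
        raise ValueError("cannot weight an empty table")
    total = targets.total if targets.total is not None else float(n)

    if mode == "cell":
        shares = targets.cell_shares()
        key = list(zip(df["gender"], df["age_band"]))
        counts = pd.Series(key).value_counts().to_dict()
        empty = [c for c, s in shares.items() if s > 0 and c not in counts]
        if empty:
            raise ValueError(f"empty sample cells with positive targets: {sorted(empty)}")
        covered = sum(s for c, s in shares.items() if c in counts)
        w = np.array([shares.get(k, 0.0) / (counts[k] / n) for k in key])
        if (w <= 0).any():
            bad = sorted({k for k, wi in zip(key, w) if wi <= 0})
            raise ValueError(f"sample cells with zero target share: {bad}")
        w *= total / w.sum()
        _ = covered
    elif mode == "raking":
        for dim in WEIGHT_DIMS:
            if dim not in targets.margins:
                raise ValueError(f"raking needs margin targets for {dim!r}")
        w = np.ones(n, dtype=float)
        for _ in range(max_iter):
            max_err = 0.0
            for dim in WEIGHT_DIMS:
                shares = targets.margins[dim]
                lv = df[dim].to_numpy()
                for level, share in shares.items():
                    mask = lv == level
                    cur = w[mask].sum() / w.sum()
                    if share > 0 and not mask.any():
                        raise ValueError(f"empty sample level {dim}={level!r} with positive target")
                    if mask.any() and cur > 0:
                        w[mask] *= share / cur
                    max_err = max(max_err, abs(cur - share))
            if max_err < 1e-8:
                break
        w *= total / w.sum()
    else:
        raise ValueError("mode must be 'cell' or 'raking'")
    return pd.Series(w, index=df.index, name="weight")


def margin_error(df: pd.DataFrame, weights: pd.Series, targets: MarginTargets) -> float:
    """Largest absolute deviation of a weighted margin from its target."""
    err = 0.0
    wsum = weights.sum()
    if targets.cells is not None:
        for (g, a), s in targets.cells.items():
            m = (df["gender"] == g) & (df["age_band"] == a)
            err = max(err, abs(weights[m].sum() / wsum - s))
        return err
    for dim, shares in targets.margins.items():
        for level, s in shares.items():
            err = max(err, abs(weights[df[dim] == level].sum() / wsum - s))
    return err


def weighted_counts(df: pd.DataFrame, weights: Optional[pd.Series], by: str) -> pd.DataFrame:
    """Unweighted and weighted n and percentages per level of ``by``."""
    w = weights if weights is not None else pd.Series(1.0, index=df.index)
    groups = df[by].astype("string")
    out = []
    for level in groups.dropna().unique():
        m = (groups == level).fillna(False)
        out.append(
            {
                "group": level,
                "n": int(m.sum()),
                "weighted_n": float(w[m].sum()),
            }
        )
    table = pd.DataFrame(out)
    table["pct"] = 100 * table["n"] / table["n"].sum()
    table["weighted_pct"] = 100 * table["weighted_n"] / table["weighted_n"].sum()
    return table
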