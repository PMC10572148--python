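"""Cost-effectiveness scoring of the costed ladder.

The comprehensive score (C-score) trades diagnostic accuracy against test
cost:

    C-score = w * AUC + (1 - w) * (1 - regularized(cost))

where ``regularized`` is min-max scaling of the candidate costs to [0, 1]
and the weight ``w`` in [0, 1] is the importance assigned to accuracy.  At
w = 0 the cheapest panel always wins; at w = 1 only AUC matters.  Sweeping
w over a grid traces how the recommended panel migrates from the cheapest
rung toward the highest-AUC rung.

Also here: median-split quadrant segmentation of the ladder (high/low AUC x
high/low cost) and flagging of rungs that omit an anchor marker (the
outlier rungs are exactly those without PE.CEA).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .markers import ANCHOR_MARKER, parse_panel, validate_marker

__all__ = [
    "regularize_costs",
    "c_score",
    "sweep_w",
    "quadrant_segmentation",
    "flag_missing_anchor",
    "recommend",
    "round3",
    "DEFAULT_W_GRID",
    "DEFAULT_PERSONAS",
]

#: Representative sweep grid: coarse steps plus the high-accuracy corner.
DEFAULT_W_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0)

#: Persona weights -> human labels for the recommendation report.
DEFAULT_PERSONAS = {0.5: "budget", 0.95: "balanced", 0.99: "accuracy-first"}

QUADRANTS = (
    "high-AUC/low-cost",
    "low-AUC/low-cost",
    "high-AUC/high-cost",
    "low-AUC/high-cost",
)


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (matches printed scores)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def regularize_costs(costs) -> np.ndarray:
    """Min-max scale costs to [0, 1]; order-preserving."""
    costs = np.asarray(costs, dtype=float)
    if costs.size < 2:
        raise ValueError("need at least 2 costs to regularize")
    lo, hi = costs.min(), costs.max()
    if hi == lo:
        raise ValueError("all costs are equal; min-max scaling is degenerate")
    return (costs - lo) / (hi - lo)


def c_score(auc, regularized_cost, w) -> float | np.ndarray:
    """w * AUC + (1 - w) * (1 - regularized cost); all arguments in [0, 1]."""
    auc = np.asarray(auc, dtype=float)
    r = np.asarray(regularized_cost, dtype=float)
    w = float(w)
    for name, v in (("auc", auc), ("regularized_cost", r)):
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{name} out of [0,1]")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w out of [0,1]: {w}")
    out = w * auc + (1.0 - w) * (1.0 - r)
    return float(out) if out.ndim == 0 else out


def _argbest(scores: np.ndarray, costs: np.ndarray, best: str) -> int:
    """Index of the max (or min) score; ties break toward lower cost."""
    target = scores.max() if best == "max" else scores.min()
    tied = np.flatnonzero(np.isclose(scores, target, rtol=0, atol=1e-12))
    return int(tied[np.argmin(costs[tied])])


def sweep_w(ladder: pd.DataFrame, w_grid=DEFAULT_W_GRID) -> pd.DataFrame:
    """Score every ladder rung at every weight of the grid.

    Returns one row per (w, rung) with the regularized cost, the C-score at
    full precision, and argmax/argmin flags (score ties break toward the
    cheaper rung).
    """
    w_grid = list(w_grid)
    if not w_grid:
        raise ValueError("w grid must be non-empty")
    costs = ladder["cost"].to_numpy(dtype=float)
    aucs = ladder["auc"].to_numpy(dtype=float)
    reg = regularize_costs(costs)
    frames = []
    for w in w_grid:
        scores = c_score(aucs, reg, w)
        i_max = _argbest(scores, costs, "max")
        i_min = _argbest(-scores, costs, "max")
        block = pd.DataFrame(
            {
                "w": w,
                "rung": ladder["rank"].to_numpy(),
                "combination": ladder["combination"].to_numpy(),
                "cost": costs,
                "auc": aucs,
                "regularized_cost": reg,
                "c_score": scores,
            }
        )
        block["is_argmax"] = np.arange(len(block)) == i_max
        block["is_argmin"] = np.arange(len(block)) == i_min
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def sweep_extrema(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-w argmax/argmin rungs, one row per weight."""
    rows = []
    for w, block in sweep.groupby("w", sort=True):
        rows.append(
            {
                "w": w,
                "argmax": block.loc[block["is_argmax"], "rung"].iloc[0],
                "argmin": block.loc[block["is_argmin"], "rung"].iloc[0],
            }
        )
    return pd.DataFrame(rows)


def quadrant_segmentation(ladder: pd.DataFrame) -> pd.DataFrame:
    """Median-split quadrant assignment of the ladder rungs.

    "High" means strictly greater than the median (computed over the
    ladder's costs and AUCs; even counts use the mean of the central pair);
    exact ties with a median land on the "low" side and are flagged in the
    ``tie`` column.
    """
    if len(ladder) < 2:
        raise ValueError("need at least 2 rungs to segment")
    med_cost = float(np.median(ladder["cost"].to_numpy(dtype=float)))
    med_auc = float(np.median(ladder["auc"].to_numpy(dtype=float)))
    out = ladder[["rank", "combination", "cost", "auc"]].copy()
    hi_auc = out["auc"] > med_auc
    hi_cost = out["cost"] > med_cost
    out["quadrant"] = np.select(
        [hi_auc & ~hi_cost, ~hi_auc & ~hi_cost, hi_auc & hi_cost],
        [QUADRANTS[0], QUADRANTS[1], QUADRANTS[2]],
        default=QUADRANTS[3],
    )
    out["tie"] = (out["auc"] == med_auc) | (out["cost"] == med_cost)
    out.attrs["median_cost"] = med_cost
    out.attrs["median_auc"] = med_auc
    return out


def flag_missing_anchor(ladder: pd.DataFrame, anchor: str = ANCHOR_MARKER) -> list[str]:
    """Rung ids whose panel does not include the anchor marker."""
    validate_marker(anchor)
    flagged = []
    for _, row in ladder.iterrows():
        if anchor not in parse_panel(row["combination"]):
            flagged.append(row["rank"])
    return flagged


def recommend(
    sweep: pd.DataFrame, personas: dict[float, str] | None = None
) -> pd.DataFrame:
    """Map persona weights to their winning rung.

    Each persona's weight must be a value of the computed sweep grid; the
    report row carries the winning rung's combination, cost, AUC and score.
    """
    if personas is None:
        personas = dict(DEFAULT_PERSONAS)
    grid = set(np.round(sweep["w"].unique(), 12))
    rows = []
    for w, label in sorted(personas.items()):
        if round(w, 12) not in grid:
            raise ValueError(f"persona weight {w} not in the computed sweep grid")
        block = sweep[np.isclose(sweep["w"], w)]
        win = block.loc[block["is_argmax"]].iloc[0]
        rows.append(
            {
                "persona": label,
                "w": w,
                "rung": win["rung"],
                "combination": win["combination"],
                "cost": win["cost"],
                "auc": win["auc"],
                "c_score": win["c_score"],
            }
        )
    return pd.DataFrame(rows)
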