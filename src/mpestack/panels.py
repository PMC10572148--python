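"""Exhaustive panel pricing and the best-AUC-per-cost ladder.

Tumor-marker tests are priced per analyte: one price for CEA and one shared
price for the three carbohydrate antigens (CA19-9, CA125, CA15-3), identical
for pleural-effusion and peripheral-blood specimens.  A panel's cost is the
sum of its members' unit prices, so the 255 non-empty panels collapse onto
exactly 20 distinct cost values; at each distinct cost the panel with the
highest cross-validated AUC forms one rung of the "ladder" (C1 cheapest
through C20 most expensive) that the cost-effectiveness stage scores.

Default unit prices (RMB 56.5 for CEA, RMB 84.0 per CA marker) are
back-solved from the published single-marker rungs and validated against
all twenty published costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .markers import ALL_MARKERS, enumerate_panels, marker_analyte, panel_str, parse_panel

__all__ = [
    "PriceTable",
    "DEFAULT_PRICES",
    "enumerate_panels",
    "panel_cost",
    "distinct_costs",
    "build_ladder",
    "load_table2",
    "LADDER_COLUMNS",
]

LADDER_COLUMNS = ["rank", "combination", "cost", "auc", "sensitivity", "specificity"]


@dataclass(frozen=True)
class PriceTable:
    """Unit test prices in RMB: one for CEA, one shared by the CA markers.

    The same price applies to a pleural-effusion and a peripheral-blood
    test of the same analyte.
    """

    cea: float = 56.5
    ca: float = 84.0

    def __post_init__(self) -> None:
        if self.cea <= 0 or self.ca <= 0:
            raise ValueError("all prices must be positive")

    def price(self, marker: str) -> float:
        analyte = marker_analyte(marker)
        return self.cea if analyte == "CEA" else self.ca


DEFAULT_PRICES = PriceTable()


def panel_cost(panel, prices: PriceTable = DEFAULT_PRICES) -> float:
    """Additive panel cost: the sum of each member marker's unit price."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    return float(sum(prices.price(m) for m in panel))


def distinct_costs(
    panels, prices: PriceTable = DEFAULT_PRICES
) -> list[tuple[float, list[tuple[str, ...]]]]:
    """Group panels by cost: sorted list of (cost, panels at that cost)."""
    panels = list(panels)
    if not panels:
        raise ValueError("panel list must be non-empty")
    groups: dict[float, list] = {}
    for p in panels:
        groups.setdefault(panel_cost(p, prices), []).append(tuple(p))
    return [(c, groups[c]) for c in sorted(groups)]


def build_ladder(
    records: pd.DataFrame,
    prices: PriceTable = DEFAULT_PRICES,
    require_complete: bool = False,
) -> pd.DataFrame:
    """Best-AUC panel per distinct cost, as a C1..Cn ladder table.

    ``records`` carries one row per panel of a single model with columns
    ``panel`` (canonical '+'-joined string), ``auc``, ``sensitivity``,
    ``specificity``.  With ``require_complete=True`` a record for every one
    of the 255 panels is demanded (the full-pipeline setting); otherwise the
    ladder ranks whatever panels are given, e.g. a published 20-rung table.
    AUC ties at one cost break toward fewer markers, then the
    lexicographically smaller panel string.
    """
    if require_complete:
        complete_ladder_check(records)
    required = {"panel", "auc", "sensitivity", "specificity"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")
    if records["panel"].duplicated().any():
        dups = records.loc[records["panel"].duplicated(), "panel"].tolist()
        raise ValueError(f"duplicate panel records: {dups[:5]}")

    recs = records.copy()
    recs["panel"] = recs["panel"].map(lambda s: panel_str(parse_panel(s)))
    recs["cost"] = recs["panel"].map(lambda s: panel_cost(parse_panel(s), prices))
    recs["_size"] = recs["panel"].map(lambda s: len(parse_panel(s)))

    rows = []
    for _, grp in recs.groupby("cost", sort=True):
        grp = grp.sort_values(["auc", "_size", "panel"], ascending=[False, True, True])
        rows.append(grp.iloc[0])
    ladder = pd.DataFrame(rows).reset_index(drop=True)
    ladder.insert(0, "rank", [f"C{i}" for i in range(1, len(ladder) + 1)])
    ladder = ladder.rename(columns={"panel": "combination"})
    return ladder[LADDER_COLUMNS]


def complete_ladder_check(records: pd.DataFrame, prices: PriceTable = DEFAULT_PRICES) -> None:
    """Raise if ``records`` does not cover all 255 panels (names the missing)."""
    have = {panel_str(parse_panel(s)) for s in records["panel"]}
    want = {panel_str(p) for p in enumerate_panels(ALL_MARKERS)}
    missing = sorted(want - have)
    if missing:
        raise ValueError(
            f"records incomplete: missing {len(missing)} panels, e.g. {missing[:3]}"
        )


def load_table2() -> pd.DataFrame:
    """The published stacking-model ladder (C1-C20), shipped as a fixture.

    Columns: rank, combination, cost, auc, sensitivity, specificity.  Used
    by replay mode, which reruns the cost-effectiveness arithmetic on the
    published numbers without touching any model code.
    """
    with resources.files("mpestack.data").joinpath("table2.csv").open("r") as fh:
        ladder = pd.read_csv(fh)
    ladder["combination"] = ladder["combination"].map(lambda s: panel_str(parse_panel(s)))
    return ladder[LADDER_COLUMNS]
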