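"""Index-based clone selection, selection differentials, and Kappa agreement.

Clones are ranked by a weighted selection index over trait values (BLUPs,
GEBVs or GETGVs),

    InS = sum_t w_t * value_t,

with the default weights of the drought-breeding program: 5 for plant
architecture traits, 10 for starch/harvest traits, 15 for dry matter and
root number, 20 for fresh root yield.  Because raw trait scales differ by
orders of magnitude, trait columns are z-scored before weighting by default
(``standardize=False`` restores the literal weighted sum).

Selected sets at a given selection intensity (percentage retained) yield the
base mean X0, selected mean XS and the selection differential
SD% = 100 (XS - X0)/|X0| per trait.  Agreement between two selection
strategies is Cohen's kappa on the 2x2 selected/not-selected table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_INDEX_WEIGHTS", "DEFAULT_INTENSITIES", "selection_index",
           "select_top", "selection_differential", "kappa_agreement",
           "kappa_matrix", "SelectionReport", "build_selection_report"]

DEFAULT_INDEX_WEIGHTS = {
    "Nstem.Plant": 5.0, "Stem.D": 5.0, "Root.Di": 5.0, "Root.Le": 5.0,
    "Plant.Height": 5.0, "StC": 10.0, "HI": 10.0, "StY": 10.0, "ShY": 10.0,
    "DMC": 15.0, "N_Roots": 15.0, "FRY": 20.0,
}

DEFAULT_INTENSITIES = (10.0, 15.0, 20.0, 25.0, 30.0)


def selection_index(values: pd.DataFrame, weights: dict[str, float] | None = None,
                    standardize: bool = True) -> pd.Series:
    """Weighted selection index per clone (rows = clones, columns = traits)."""
    w = weights if weights is not None else DEFAULT_INDEX_WEIGHTS
    if any(v <= 0 for v in w.values()):
        raise ValueError("index weights must be positive")
    missing = [t for t in w if t not in values.columns]
    if missing:
        raise ValueError(f"missing trait column(s) for the index: {missing}")
    idx = pd.Series(0.0, index=values.index)
    for trait, weight in w.items():
        col = values[trait].astype(float)
        if standardize:
            sd = col.std(ddof=1)
            col = (col - col.mean()) / sd if sd > 0 else col * 0.0
        idx = idx + weight * col
    idx.name = "InS"
    return idx


def select_top(index: pd.Series, intensity: float, n: int | None = None) -> list:
    """The top-index clones at the given selection intensity (percent).

    k = round(intensity/100 * n), half rounded up.  Ties broken by clone id
    (stable sort on descending index).
    """
    if not 0 < intensity <= 100:
        raise ValueError("intensity must be in (0, 100]")
    n = n if n is not None else index.size
    k = math.floor(intensity / 100.0 * n + 0.5)
    if k == 0:
        raise ValueError(f"intensity {intensity}% of {n} clones selects nobody")
    ordered = index.sort_index().sort_values(ascending=False, kind="stable")
    return ordered.index[:k].tolist()


def selection_differential(values: pd.DataFrame, selected: list) -> pd.DataFrame:
    """Base mean X0, selected mean XS, and SD% = 100 (XS - X0)/|X0| per trait.

    Where X0 is exactly zero the percentage is undefined; the absolute
    difference is reported instead and flagged.
    """
    unknown = set(selected) - set(values.index)
    if unknown:
        raise ValueError(f"selected clones not in the value table: {sorted(unknown)[:5]}")
    x0 = values.mean(axis=0)
    xs = values.loc[list(selected)].mean(axis=0)
    rows = []
    for trait in values.columns:
        if x0[trait] == 0.0:
            warnings.warn(f"trait '{trait}' has zero base mean; reporting the "
                          "absolute differential", UserWarning)
            rows.append((trait, x0[trait], xs[trait], xs[trait] - x0[trait], True))
        else:
            sd = 100.0 * (xs[trait] - x0[trait]) / abs(x0[trait])
            rows.append((trait, x0[trait], xs[trait], sd, False))
    return pd.DataFrame(rows, columns=["trait", "x0", "xs", "sd_percent",
                                       "absolute_flag"]).set_index("trait")


def kappa_agreement(selected_a, selected_b, n: int) -> float:
    """Cohen's kappa between two selected sets over an n-clone universe.

    kappa = (p_o - p_e) / (1 - p_e) on the 2x2 selected/not-selected table.
    Returns NaN when chance agreement is 1 (both strategies select all
    clones or none).
    """
    sa, sb = set(selected_a), set(selected_b)
    if len(sa) > n or len(sb) > n:
        raise ValueError("selected sets larger than the clone universe")
    a, b = len(sa), len(sb)
    both = len(sa & sb)
    p_o = (both + (n - a - b + both)) / n
    p_e = (a * b + (n - a) * (n - b)) / n ** 2
    if p_e == 1.0:
        warnings.warn("chance agreement is 1; kappa undefined", UserWarning)
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_matrix(selections: dict[str, list], n: int) -> pd.DataFrame:
    """Pairwise kappa between named selected sets."""
    names = list(selections)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            kap = kappa_agreement(selections[a], selections[b], n)
            out.loc[a, b] = out.loc[b, a] = kap
    return out


@dataclass
class SelectionReport:
    """Index values, selected sets and differentials for one prediction basis."""

    basis: str  # blup | gebv | getgv
    index_values: pd.Series
    selected: dict[float, list]             # intensity -> ordered clone list
    differentials: dict[float, pd.DataFrame]  # intensity -> SD table

    def selected_frame(self) -> pd.DataFrame:
        rows = [(self.basis, inten, rank + 1, clone)
                for inten, clones in self.selected.items()
                for rank, clone in enumerate(clones)]
        return pd.DataFrame(rows, columns=["basis", "intensity", "rank", "clone"])

    def summary(self) -> str:
        lines = [f"Selection report — basis '{self.basis}'", "-" * 40]
        for inten, clones in self.selected.items():
            sd = self.differentials[inten]["sd_percent"]
            lines.append(f"  {inten:g}%: {len(clones)} clones selected; "
                         f"mean |SD| {sd.abs().mean():.2f}%")
        return "\n".join(lines)


def build_selection_report(values: pd.DataFrame, basis: str,
                           weights: dict[str, float] | None = None,
                           intensities=DEFAULT_INTENSITIES,
                           standardize: bool = True) -> SelectionReport:
    """Rank clones by the index and evaluate every selection intensity."""
    idx = selection_index(values, weights, standardize=standardize)
    selected, diffs = {}, {}
    for inten in intensities:
        sel = select_top(idx, inten)
        selected[inten] = sel
        diffs[inten] = selection_differential(values, sel)
    return SelectionReport(basis=basis, index_values=idx,
                           selected=selected, differentials=diffs)
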