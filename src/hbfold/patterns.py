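"""Hydrogen-bond pattern statistics.

A frame's bond pattern is the 0/1 string over the maxhb candidate
bonds ('1' = formed). With k of n bonds formed there are C(n, k)
possible arrangements; observed populations of these patterns reveal
e.g. the extra stability of terminal partial helices ('110', '001')
over interior ones ('101').
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .constants import PATTERN_THRESHOLD


@dataclass(frozen=True)
class PatternTable:
    """Populations of observed bond patterns.

    table : DataFrame with columns pattern (0/1 string), population
        (fraction of frames), nhb (count of '1's), sorted by nhb then
        descending population.
    """

    table: pd.DataFrame
    maxhb: int

    def __post_init__(self) -> None:
        tot = self.table["population"].sum()
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"pattern populations sum to {tot}, expected 1")
        counted = self.table["pattern"].str.count("1")
        if not (counted == self.table["nhb"]).all():
            raise ValueError("nhb column must equal the number of '1's")

    def population(self, pattern: str) -> float:
        rows = self.table.loc[self.table["pattern"] == pattern, "population"]
        return float(rows.iloc[0]) if len(rows) else 0.0

    def microstate_populations(self) -> np.ndarray:
        """Class sums: total population per NHB microstate 0..maxhb."""
        p = np.zeros(self.maxhb + 1)
        for _, row in self.table.iterrows():
            p[row["nhb"]] += row["population"]
        return p


def count_patterns(n: int, k: int) -> int:
    """Number of arrangements of k formed bonds among n sites, C(n, k)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return comb(n, k)


def pattern_table(
    weights: np.ndarray, threshold: float = PATTERN_THRESHOLD
) -> PatternTable:
    """Tabulate 0/1 bond patterns of a frames x bonds weight matrix.

    A bond counts as formed when its weight is >= ``threshold``.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.size == 0:
        raise ValueError("weights must be a non-empty frames x bonds matrix")
    formed = (w >= threshold).astype(np.int8)
    # encode each pattern as an integer for fast counting
    powers = 1 << np.arange(w.shape[1])[::-1]
    codes = formed @ powers
    uniq, counts = np.unique(codes, return_counts=True)
    maxhb = w.shape[1]
    rows = []
    for code, cnt in zip(uniq, counts):
        pattern = format(int(code), f"0{maxhb}b")
        rows.append(
            {"pattern": pattern, "population": cnt / len(codes),
             "nhb": pattern.count("1")}
        )
    df = (
        pd.DataFrame(rows)
        .sort_values(["nhb", "population", "pattern"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    return PatternTable(table=df, maxhb=maxhb)


def _is_terminal_run(pattern: str) -> tuple[bool, bool]:
    """Whether the '1's form a single run touching the N- or C-terminus."""
    ones = [i for i, c in enumerate(pattern) if c == "1"]
    if not ones:
        return False, False
    contiguous = ones[-1] - ones[0] + 1 == len(ones)
    n_term = contiguous and ones[0] == 0
    c_term = contiguous and ones[-1] == len(pattern) - 1
    return n_term, c_term


def terminal_helix_report(table: PatternTable) -> pd.DataFrame:
    """Patterns ranked by population within each NHB class.

    Adds flags for N-terminal-contiguous and C-terminal-contiguous
    runs of formed bonds, the configurations of partial terminal
    helices.
    """
    if len(table.table) == 0:
        raise ValueError("empty pattern table")
    df = table.table.copy()
    flags = df["pattern"].map(_is_terminal_run)
    df["n_terminal"] = [f[0] for f in flags]
    df["c_terminal"] = [f[1] for f in flags]
    df["rank_in_class"] = (
        df.groupby("nhb")["population"].rank(method="first", ascending=False)
        .astype(int)
    )
    return df
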