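"""Two-sample binomial proportion z test on altered-step counts.

The test compares the fraction of altered steps between two conditions
(e.g. control vs silenced, or overground vs treadmill). The default
standard error is the *unpooled* form,

    z = (p2 − p1) / sqrt(p1(1−p1)/n1 + p2(1−p2)/n2),

with a two-tailed p-value from the standard normal and no continuity
correction. A pooled-SE variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = ["ProportionComparison", "two_proportion_z", "proportion_report"]


@dataclass(frozen=True)
class ProportionComparison:
    """One two-sample proportion comparison; z sign follows sign(p2 − p1)."""

    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p_value: float
    pooled: bool = False

    @property
    def p1(self) -> float:
        return self.x1 / self.n1

    @property
    def p2(self) -> float:
        return self.x2 / self.n2

    @property
    def pct1(self) -> float:
        return 100.0 * self.p1

    @property
    def pct2(self) -> float:
        return 100.0 * self.p2


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     pooled: bool = False) -> ProportionComparison:
    """Two-sample proportion z statistic with unpooled SE (default).

    Raises :class:`UndefinedStatisticError` when the standard error vanishes
    (both proportions 0, or both 1, under the unpooled form).
    """
    for x, n, side in ((x1, n1, "first"), (x2, n2, "second")):
        if n <= 0:
            raise UndefinedStatisticError(f"{side} sample size must be positive")
        if not 0 <= x <= n:
            raise UndefinedStatisticError(f"{side} count must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    if pooled:
        p = (x1 + x2) / (n1 + n2)
        var = p * (1 - p) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        raise UndefinedStatisticError(
            "zero standard error: both proportions are degenerate (all 0 or all 1)")
    z = (p2 - p1) / np.sqrt(var)
    p_value = 2.0 * stats.norm.sf(abs(z))
    return ProportionComparison(x1, n1, x2, n2, float(z), float(p_value), pooled)


def proportion_report(counts: Iterable[Mapping]) -> pd.DataFrame:
    """Tabulate proportion comparisons from pre-tabulated altered/total counts.

    Each entry needs keys ``pair``, ``contrast``, ``x1``, ``n1``, ``x2``,
    ``n2``; rows whose statistic is undefined are skipped with a note in the
    ``note`` column left empty for valid rows. Percentages are reported to
    two decimals, |z| rounded to two decimals, matching the reporting
    convention of the comparisons this reproduces.
    """
    rows = []
    for entry in counts:
        row = {"pair": entry["pair"], "contrast": entry["contrast"],
               "x1": entry["x1"], "n1": entry["n1"],
               "x2": entry["x2"], "n2": entry["n2"]}
        try:
            cmp_ = two_proportion_z(entry["x1"], entry["n1"], entry["x2"], entry["n2"],
                                    pooled=bool(entry.get("pooled", False)))
        except UndefinedStatisticError as exc:
            row.update(pct1=np.nan, pct2=np.nan, z=np.nan, p=np.nan, note=str(exc))
        else:
            row.update(pct1=round(cmp_.pct1, 2), pct2=round(cmp_.pct2, 2),
                       z=round(abs(cmp_.z), 2), p=cmp_.p_value, note="")
        rows.append(row)
    return pd.DataFrame(rows)
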