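"""Group comparison of per-well readouts: ANOVA, Tukey HSD, letter display.

Plate experiments compare conditions (typically N = 8 replicate wells each)
on the two assay readouts, fibrinolysis time and amount.  Results are
summarised as mean ± SD, tested with one-way fixed-effects ANOVA, followed
by Tukey's HSD on all pairs, and rendered as a compact letter display:
conditions not connected by the same letter differ significantly.

ANOVA and Tukey are delegated to scipy (``f_oneway`` / ``tukey_hsd``, which
applies the Tukey–Kramer adjustment for unequal group sizes); the compact
letter display uses the insert-and-absorb construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, InvalidInputError

__all__ = [
    "ComparisonResult",
    "summarize",
    "anova_tukey",
    "compact_letter_display",
    "compare_conditions",
]


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups to compare")
    out: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise InvalidInputError(f"group {name!r} has n={arr.size}; need n >= 2")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"group {name!r} contains non-finite values")
        out[str(name)] = arr
    return out


@dataclass
class ComparisonResult:
    """ANOVA + Tukey outcome across conditions.

    ``pairwise`` is a symmetric DataFrame of Tukey-adjusted p-values indexed
    by condition; ``letters`` maps condition -> letter string once
    :func:`compact_letter_display` has run.
    """

    groups: dict[str, np.ndarray]
    summary: pd.DataFrame
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    alpha: float = 0.05
    letters: dict[str, str] | None = None

    def significant(self, g1: str, g2: str) -> bool:
        return bool(self.pairwise.loc[g1, g2] < self.alpha)


def summarize(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n - 1 denominator)."""
    data = _validate_groups(groups)
    rows = [
        {"condition": name, "n": int(arr.size),
         "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}
        for name, arr in data.items()
    ]
    return pd.DataFrame(rows)


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA plus all-pairs Tukey HSD.

    Raises :class:`DegenerateVarianceError` when no group carries any
    within-group variance (the studentized range is undefined).
    """
    data = _validate_groups(groups)
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must lie in (0, 1)")
    names = list(data)
    samples = [data[n] for n in names]
    dof_within = sum(s.size - 1 for s in samples)
    ss_within = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
    if ss_within == 0.0 or dof_within == 0:
        raise DegenerateVarianceError("zero within-group variance; ANOVA/Tukey undefined")

    f_stat, p_val = sps.f_oneway(*samples)
    tk = sps.tukey_hsd(*samples)
    pairwise = pd.DataFrame(np.asarray(tk.pvalue), index=names, columns=names)
    return ComparisonResult(
        groups=data,
        summary=summarize(data),
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pairwise,
        alpha=alpha,
    )


def _insert_absorb(names: list[str], significant) -> list[set[str]]:
    """Insert-and-absorb letter construction.

    Start with one column holding every group; for each significant pair
    found in a column, split the column into two copies, one lacking each
    member; finally absorb columns that are subsets of others.
    """
    columns: list[set[str]] = [set(names)]
    changed = True
    while changed:
        changed = False
        for col in list(columns):
            pair = next(
                ((g1, g2) for i, g1 in enumerate(sorted(col))
                 for g2 in sorted(col)[i + 1:] if significant(g1, g2)),
                None,
            )
            if pair is not None:
                columns.remove(col)
                columns.append(col - {pair[0]})
                columns.append(col - {pair[1]})
                changed = True
                break
    # absorb: drop columns contained in another column
    columns = [c for c in columns if c]
    kept: list[set[str]] = []
    for col in sorted(columns, key=len, reverse=True):
        if not any(col <= other for other in kept):
            kept.append(col)
    return kept


def compact_letter_display(result: ComparisonResult) -> dict[str, str]:
    """Assign letters so that two conditions share a letter iff their Tukey
    pair is not significant at ``result.alpha``.

    Groups are ordered canonically by decreasing mean, so the labelling does
    not depend on input order.  The letters are stored on ``result`` and
    returned as a mapping condition -> sorted letter string (e.g. 'ab').
    """
    pw = result.pairwise
    if not pw.index.equals(pw.columns):
        raise InvalidInputError("pairwise p matrix must be square with matching labels")
    if not np.allclose(pw.values, pw.values.T, equal_nan=True):
        raise InvalidInputError("pairwise p matrix must be symmetric")

    means = {name: float(arr.mean()) for name, arr in result.groups.items()}
    names = sorted(result.groups, key=lambda n: (-means[n], n))
    columns = _insert_absorb(names, result.significant)
    # order columns by the best-ranked member so letter 'a' goes to the top group
    columns.sort(key=lambda col: min(names.index(g) for g in col))
    letters: dict[str, list[str]] = {n: [] for n in names}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for g in col:
            letters[g].append(letter)
    out = {n: "".join(sorted(ls)) for n, ls in letters.items()}
    result.letters = out
    return out


def compare_conditions(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> ComparisonResult:
    """ANOVA + Tukey + letters in one call."""
    result = anova_tukey(groups, alpha=alpha)
    compact_letter_display(result)
    return result
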