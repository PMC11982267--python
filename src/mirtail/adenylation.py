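"""Adenylation-level statistic, the count filter, and group comparisons.

The level for a miRNA in a sample is
``adenylated / (adenylated + canonical) * 100`` (percent), computed only for
miRNAs whose adenylated counts pass a strict ``> threshold`` rule.  Group
comparisons use one-way ANOVA with Fisher's LSD post hoc (pairwise t tests on
the pooled within-group mean square, no multiplicity adjustment).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountTable

__all__ = [
    "filter_mirnas",
    "adenylation_level",
    "adenylation_table",
    "one_way_anova",
    "fisher_lsd",
    "compare_adenylation",
    "GroupComparison",
]


def filter_mirnas(
    counts: CountTable, threshold: int = 100, mode: str = "sum"
) -> list[str]:
    """miRNAs whose adenylated counts exceed ``threshold`` (strict ``>``).

    ``mode="sum"`` applies the rule to the total over all samples (default);
    ``mode="every"`` requires every individual sample to exceed it.
    """
    if mode == "sum":
        keep = counts.adenylated.sum(axis=1) > threshold
    elif mode == "every":
        keep = (counts.adenylated > threshold).all(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return list(counts.adenylated.index[keep])


def adenylation_level(adenylated: int, canonical: int) -> float:
    """Percent of reads carrying the extra 3' A: a / (a + c) * 100."""
    if adenylated < 0 or canonical < 0:
        raise ValueError("counts must be non-negative")
    total = adenylated + canonical
    if total == 0:
        raise ValueError("adenylation level undefined for zero total counts")
    return adenylated / total * 100.0


def adenylation_table(
    counts: CountTable,
    threshold: int = 100,
    mode: str = "sum",
    mirna_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample adenylation levels (percent) for filtered miRNAs.

    Samples where a miRNA has zero canonical+adenylated counts get NaN rather
    than a fabricated 0.
    """
    if mirna_ids is None:
        mirna_ids = filter_mirnas(counts, threshold, mode)
    a = counts.adenylated.loc[list(mirna_ids)].astype(float)
    c = counts.canonical.loc[list(mirna_ids)].astype(float)
    total = a + c
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = a / total * 100.0
    levels = levels.where(total > 0)
    levels.index.name = "mirna_id"
    return levels


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("at least two groups required")
    for g in out:
        if len(g) < 2:
            raise ValueError("each group needs at least two observations")
    return out


def _sums_of_squares(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    return float(ssb), float(ssw), df_between, df_within


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Raises on degenerate input (zero between- and within-group variance).
    """
    gs = _as_groups(groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(gs)
    if dfw < 1:
        raise ValueError("not enough residual degrees of freedom")
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("degenerate input: all observations identical")
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), p


def fisher_lsd(
    groups: Sequence[Sequence[float]],
    pairs: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Fisher's LSD pairwise tests over group indices.

    Each pair gets a t statistic on the pooled within-group mean square with
    the ANOVA residual degrees of freedom; p-values are two-sided and, by
    definition of the LSD procedure, unadjusted.
    """
    gs = _as_groups(groups)
    _, ssw, _, dfw = _sums_of_squares(gs)
    if dfw < 1:
        raise ValueError("not enough residual degrees of freedom")
    msw = ssw / dfw
    if pairs is None:
        pairs = list(combinations(range(len(gs)), 2))
    rows = []
    for i, j in pairs:
        diff = gs[i].mean() - gs[j].mean()
        if msw == 0.0:
            t = 0.0 if diff == 0.0 else float("inf") * np.sign(diff)
        else:
            se = np.sqrt(msw * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), dfw))
        rows.append((i, j, float(t), dfw, p))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "t", "df", "p"])


@dataclass
class GroupComparison:
    mirna_id: str
    f_statistic: float
    p_anova: float
    group_means: dict[str, float]
    lsd: pd.DataFrame  # columns group_a, group_b, t, df, p
    significant: bool


def compare_adenylation(
    levels: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    with_fdr: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-miRNA ANOVA + Fisher's LSD across sample groups.

    ``levels`` is the adenylation table (rows = miRNAs, columns = samples,
    NaN = missing); ``design`` maps sample -> group label.  miRNAs where any
    group retains fewer than two non-missing replicates are skipped with a
    logged reason.  Returns (results frame, skipped {mirna: reason}).
    """
    group_names = sorted(set(design.values()))
    if len(group_names) < 2:
        raise ValueError("at least two groups required")
    members = {g: [s for s in levels.columns if design.get(s) == g] for g in group_names}
    for g, ms in members.items():
        if not ms:
            raise ValueError(f"group {g!r} has no samples in the table")

    rows = []
    skipped: dict[str, str] = {}
    pair_labels = list(combinations(range(len(group_names)), 2))
    for mirna in levels.index:
        groups = []
        short = None
        for g in group_names:
            vals = levels.loc[mirna, members[g]].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                short = g
                break
            groups.append(vals)
        if short is not None:
            skipped[mirna] = f"group {short!r} has <2 non-missing replicates"
            continue
        try:
            f, p = one_way_anova(groups)
        except ValueError as exc:
            skipped[mirna] = str(exc)
            continue
        lsd = fisher_lsd(groups, pair_labels)
        row: dict[str, object] = {"mirna_id": mirna, "F": f, "p_anova": p}
        for g, vals in zip(group_names, groups):
            row[f"mean_{g}"] = float(np.mean(vals))
        for (_, rec) in lsd.iterrows():
            a = group_names[int(rec["group_i"])]
            b = group_names[int(rec["group_j"])]
            row[f"p_{a}_vs_{b}"] = rec["p"]
        row["significant"] = bool(p < alpha)
        rows.append(row)

    results = pd.DataFrame(rows)
    if with_fdr and not results.empty:
        results["q_anova"] = stats.false_discovery_control(results["p_anova"])
    return results, skipped


def write_levels(levels: pd.DataFrame, path: str | Path) -> None:
    levels.to_csv(path, sep="\t", float_format="%.4f")


def write_comparisons(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
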