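"""qPCR relative quantification and the down-and-restored rescue screen.

Implements the 2^-ddCt method (target Ct normalized to an internal-control
gene, then to the averaged control-sample dCt), the internal-control-free
2^-dCt variant used for circularization qPCR of adenylated species, and the
screen that selects targets reduced in the disease group whose levels return
to control range when the driver is knocked down.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "FoldTable",
    "delta_delta_ct",
    "rel_quant_delta_ct",
    "screen_restored",
    "export_heatmap_matrix",
    "read_ct_table",
    "read_design",
]


def read_ct_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a wide Ct table (rows = targets, columns = samples)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return frame.astype(float)


def read_design(path: str | Path) -> dict[str, str]:
    """Read a sample -> group design CSV (columns: sample, group)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in frame.columns}
    if "sample" not in cols or "group" not in cols:
        raise ValueError("design file needs 'sample' and 'group' columns")
    return dict(zip(frame[cols["sample"]].astype(str), frame[cols["group"]].astype(str)))


@dataclass
class FoldTable:
    """Per-target, per-sample dCt / ddCt / fold-change values."""

    delta_ct: pd.DataFrame  # rows = targets, columns = samples
    delta_delta_ct: pd.DataFrame
    fold: pd.DataFrame  # 2^-ddCt, > 0 wherever Ct observed
    control_avg_delta_ct: pd.Series  # per-target mean dCt over control samples
    internal_control: str | None
    control_samples: list[str]

    def __post_init__(self) -> None:
        finite = self.fold.to_numpy()[np.isfinite(self.fold.to_numpy())]
        if (finite <= 0).any():
            raise ValueError("fold changes must be positive")


def delta_delta_ct(
    ct: pd.DataFrame,
    internal_control: str,
    control_samples: Sequence[str],
) -> FoldTable:
    """2^-ddCt relative quantification.

    dCt = Ct_target - Ct_internal-control (per sample); the per-target dCt is
    averaged over the control samples; ddCt = dCt - that average;
    fold = 2^-ddCt.  Missing target Ct propagates as NaN; a missing
    internal-control well is an error naming the sample.
    """
    if internal_control not in ct.index:
        raise ValueError(f"internal control {internal_control!r} not in table")
    control_samples = list(control_samples)
    if not control_samples:
        raise ValueError("at least one control sample required")
    missing = [s for s in control_samples if s not in ct.columns]
    if missing:
        raise ValueError(f"control samples not in table: {missing}")
    ref = ct.loc[internal_control]
    bad = [s for s in ct.columns if not np.isfinite(ref[s])]
    if bad:
        raise ValueError(f"missing internal-control Ct in sample(s): {bad}")
    targets = ct.drop(index=internal_control)
    dct = targets.sub(ref, axis=1)
    avg = dct[control_samples].mean(axis=1)
    ddct = dct.sub(avg, axis=0)
    fold = np.power(2.0, -ddct)
    return FoldTable(dct, ddct, fold, avg, internal_control, control_samples)


def rel_quant_delta_ct(
    ct: pd.DataFrame,
    control_samples: Sequence[str],
) -> pd.DataFrame:
    """2^-dCt relative levels with no internal-control normalization.

    dCt = Ct - mean(Ct over control samples) per target; level = 2^-dCt.
    The geometric mean of control-sample levels is 1 per target.
    """
    control_samples = list(control_samples)
    if not control_samples:
        raise ValueError("at least one control sample required")
    missing = [s for s in control_samples if s not in ct.columns]
    if missing:
        raise ValueError(f"control samples not in table: {missing}")
    dct = ct.sub(ct[control_samples].mean(axis=1), axis=0)
    return np.power(2.0, -dct)


def screen_restored(
    folds: FoldTable | pd.DataFrame,
    design: Mapping[str, str],
    down_threshold: float = 0.8,
    restore_low: float = 0.8,
    restore_high: float = 1.25,
    disease_group: str = "disease",
    rescue_group: str = "disease+knockdown",
    summary: str = "mean",
) -> tuple[set[str], pd.DataFrame]:
    """Select targets downregulated in disease and restored on knockdown.

    A target passes when its summarized disease fold is <= ``down_threshold``
    AND its summarized rescue fold lies within ``[restore_low, restore_high]``
    of the control level (fold scale, control = 1).  Group summary is the
    arithmetic mean of per-sample folds (``summary="geometric"`` for the
    geometric mean).  Returns (selected ids, per-target verdict frame).
    """
    fold = folds.fold if isinstance(folds, FoldTable) else folds
    groups: dict[str, list[str]] = {}
    for s in fold.columns:
        if s in design:
            groups.setdefault(design[s], []).append(s)
    for needed in (disease_group, rescue_group):
        if needed not in groups:
            raise ValueError(f"group {needed!r} missing from design")

    def summarize(sub: pd.DataFrame) -> pd.Series:
        if summary == "mean":
            return sub.mean(axis=1)
        if summary == "geometric":
            return np.exp(np.log(sub).mean(axis=1))
        raise ValueError(f"unknown summary {summary!r}")

    disease = summarize(fold[groups[disease_group]])
    rescue = summarize(fold[groups[rescue_group]])
    down = disease <= down_threshold
    restored = (rescue >= restore_low) & (rescue <= restore_high)
    verdict = pd.DataFrame(
        {
            "disease_fold": disease,
            "rescue_fold": rescue,
            "down_in_disease": down,
            "restored_on_knockdown": restored,
            "selected": down & restored,
        }
    )
    verdict.index.name = "target"
    return set(verdict.index[verdict["selected"]]), verdict


def write_screen_verdicts(
    verdict: pd.DataFrame,
    path: str | Path,
    down_threshold: float,
    restore_low: float,
    restore_high: float,
) -> None:
    """Write the verdict table with threshold provenance in the header."""
    with open(path, "w") as out:
        out.write(f"# down_threshold={down_threshold}\n")
        out.write(f"# restore_low={restore_low}\n")
        out.write(f"# restore_high={restore_high}\n")
        verdict.to_csv(out, sep="\t")


def export_heatmap_matrix(
    folds: FoldTable | pd.DataFrame,
    selection: Sequence[str],
    path: str | Path | None = None,
    order: str = "input",
) -> pd.DataFrame:
    """log2 fold matrix (rows = selected targets) for heat-map plotting.

    ``order="cluster"`` reorders rows by hierarchical clustering of the fold
    profiles (average linkage on Euclidean distance); ``"input"`` keeps the
    selection order.
    """
    fold = folds.fold if isinstance(folds, FoldTable) else folds
    selection = list(selection)
    if not selection:
        raise ValueError("selection must be non-empty")
    missing = [t for t in selection if t not in fold.index]
    if missing:
        raise ValueError(f"targets not in fold table: {missing}")
    matrix = np.log2(fold.loc[selection])
    if order == "cluster" and len(selection) > 2:
        link = hierarchy.linkage(pdist(matrix.values), method="average")
        matrix = matrix.iloc[hierarchy.leaves_list(link)]
    elif order not in ("input", "cluster"):
        raise ValueError(f"unknown row order {order!r}")
    if path is not None:
        matrix.to_csv(path)
    return matrix
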