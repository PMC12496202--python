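"""Intersectional subset classification of differential-expression results.

Three comparison tables — male vs. female (MvF), intersex vs. female (IvF)
and male vs. intersex (MvI) — are joined on transcript id and every
transcript upregulated in MvF is assigned to exactly one of four subsets
according to its significance/sign pattern in the other two comparisons:

* ``full_recovery``: up in MvF and IvF, not significant in MvI;
* ``male_independent``: up in MvF and MvI, not significant in IvF;
* ``partial_recovery``: up in all three comparisons;
* ``mvf_only``: up in MvF only, not significant elsewhere.

A comparison counts as "up" iff ``padj < threshold`` and ``log2fc > 0``;
"not significant" means ``padj >= threshold`` regardless of sign. The four
labels partition the MvF-up set; everything else is ``not_male_upregulated``.
``direction="down"`` mirrors the rules with negative fold changes for the
female-side analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_FULL",
    "LABEL_INDEPENDENT",
    "LABEL_PARTIAL",
    "LABEL_MVF_ONLY",
    "LABEL_NOT_UP",
    "LABEL_FEMALE_SIDE",
    "SUBSET_LABELS",
    "OverlapResult",
    "classify_subsets",
    "subset_counts",
    "overlap_de_lists",
]

LABEL_FULL = "full_recovery"
LABEL_INDEPENDENT = "male_independent"
LABEL_PARTIAL = "partial_recovery"
LABEL_MVF_ONLY = "mvf_only"
LABEL_NOT_UP = "not_male_upregulated"
#: planted-truth label for transcripts higher in females (used by simulators)
LABEL_FEMALE_SIDE = "female_upregulated"

SUBSET_LABELS = (LABEL_FULL, LABEL_INDEPENDENT, LABEL_PARTIAL, LABEL_MVF_ONLY)

_REQUIRED_COLUMNS = {"transcript_id", "log2fc", "padj"}


@dataclass(frozen=True)
class OverlapResult:
    """Exact set overlap between two transcript lists."""

    shared: int
    only_a: int
    only_b: int
    shared_fraction_of_union: float


def _validate(table: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if table["transcript_id"].duplicated().any():
        raise ValueError(f"{name} table has duplicate transcript ids")
    padj = table["padj"].to_numpy(dtype=float)
    finite = np.isfinite(padj)
    if np.any((padj[finite] < 0) | (padj[finite] > 1)):
        raise ValueError(f"{name} table has padj outside [0, 1]")
    return table


def classify_subsets(
    mvf: pd.DataFrame,
    ivf: pd.DataFrame,
    mvi: pd.DataFrame,
    fdr_threshold: float = 0.05,
    direction: str = "up",
) -> pd.DataFrame:
    """Assign each transcript to one intersectional subset label.

    Tables are inner-joined on ``transcript_id``; transcripts absent from any
    table are excluded (their count is reported in ``df.attrs["n_dropped"]``).
    Missing ``padj`` values are treated as not significant and counted in
    ``df.attrs["n_missing_padj"]``. Returns a frame with per-comparison
    significance/sign columns and a ``subset_label`` column.
    """
    if not (0.0 < fdr_threshold < 1.0):
        raise ValueError("fdr_threshold must lie in (0, 1)")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    frames = {}
    for name, table in (("mvf", mvf), ("ivf", ivf), ("mvi", mvi)):
        frames[name] = _validate(table, name)[
            ["transcript_id", "log2fc", "padj"]
        ].rename(columns={"log2fc": f"log2fc_{name}", "padj": f"padj_{name}"})

    merged = frames["mvf"].merge(frames["ivf"], on="transcript_id").merge(
        frames["mvi"], on="transcript_id"
    )
    universe_sizes = [len(mvf), len(ivf), len(mvi)]
    n_dropped = max(universe_sizes) - len(merged)

    sign = 1.0 if direction == "up" else -1.0
    n_missing = 0
    flags = {}
    for name in ("mvf", "ivf", "mvi"):
        padj = merged[f"padj_{name}"].to_numpy(dtype=float)
        lfc = merged[f"log2fc_{name}"].to_numpy(dtype=float)
        missing = ~np.isfinite(padj)
        n_missing += int(missing.sum())
        sig = np.where(missing, False, padj < fdr_threshold)
        flags[f"sig_{name}"] = sig
        flags[f"dir_{name}"] = sig & (sign * lfc > 0)

    up_mvf = flags["dir_mvf"]
    sig_ivf, sig_mvi = flags["sig_ivf"], flags["sig_mvi"]
    dir_ivf, dir_mvi = flags["dir_ivf"], flags["dir_mvi"]

    labels = np.full(len(merged), LABEL_NOT_UP, dtype=object)
    labels[up_mvf & dir_ivf & ~sig_mvi] = LABEL_FULL
    labels[up_mvf & dir_mvi & ~sig_ivf] = LABEL_INDEPENDENT
    labels[up_mvf & dir_ivf & dir_mvi] = LABEL_PARTIAL
    labels[up_mvf & ~sig_ivf & ~sig_mvi] = LABEL_MVF_ONLY
    # remaining MvF-up patterns (e.g. significant-but-opposite companions)
    # fall into mvf_only-style residual handling below
    unassigned = up_mvf & (labels == LABEL_NOT_UP)
    labels[unassigned] = LABEL_MVF_ONLY

    out = merged.copy()
    for key, values in flags.items():
        out[key] = values
    out["subset_label"] = labels
    out.attrs["n_dropped"] = int(n_dropped)
    out.attrs["n_missing_padj"] = int(n_missing)
    out.attrs["fdr_threshold"] = fdr_threshold
    out.attrs["direction"] = direction
    return out


def subset_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Per-label transcript counts (all five labels always present)."""
    counts = assignments["subset_label"].value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in (*SUBSET_LABELS, LABEL_NOT_UP)}


def overlap_de_lists(list_a, list_b) -> OverlapResult:
    """Exact intersection/difference counts between two transcript-id sets."""
    a, b = set(list_a), set(list_b)
    shared = len(a & b)
    union = len(a | b)
    return OverlapResult(
        shared=shared,
        only_a=len(a - b),
        only_b=len(b - a),
        shared_fraction_of_union=(shared / union) if union else 0.0,
    )
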