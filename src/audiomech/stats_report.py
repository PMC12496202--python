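"""Statistical decision tree for group comparisons.

Each group is screened with a Shapiro-Wilk normality test at alpha = 0.05.
Independent designs use Welch's t test when every group passes the screen and
a Mann-Whitney rank-sum test otherwise; paired designs use the Wilcoxon
signed-rank test. Raw p-values receive a Bonferroni correction for the
caller-declared family size. An optional rank-based omnibus (Kruskal-Wallis)
annotates, but never suppresses, pairwise results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparisonResult", "OmnibusResult", "compare_groups", "rank_omnibus"]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparisonResult:
    group_names: tuple[str, str]
    design: str  # {"independent", "paired"}
    normality_p: dict
    all_normal: bool
    test_name: str
    statistic: float
    raw_p: float
    corrected_p: float
    n_comparisons: int


@dataclass(frozen=True)
class OmnibusResult:
    test_name: str
    statistic: float
    p_value: float
    n_groups: int


def _as_sample(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError(f"group {name!r} needs at least 3 one-dimensional values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name!r} contains non-finite values")
    return arr


def compare_groups(
    samples: dict,
    design: str = "independent",
    family_size: int = 1,
    test_override: str | None = None,
) -> GroupComparisonResult:
    """Compare two groups following the normality-gated decision tree.

    ``samples`` maps two group names to value lists. ``test_override`` (one of
    ``welch``, ``mannwhitney``, ``wilcoxon``) bypasses the gate when a caller
    must force a specific procedure.
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if len(samples) != 2:
        raise ValueError("compare_groups takes exactly two groups")
    (name_a, raw_a), (name_b, raw_b) = samples.items()
    a = _as_sample(raw_a, name_a)
    b = _as_sample(raw_b, name_b)
    if design == "paired" and a.size != b.size:
        raise ValueError("paired design requires equal group lengths")

    normality = {
        name_a: float(stats.shapiro(a).pvalue),
        name_b: float(stats.shapiro(b).pvalue),
    }
    all_normal = all(p >= NORMALITY_ALPHA for p in normality.values())

    if test_override is not None:
        chosen = test_override
    elif design == "paired":
        chosen = "wilcoxon"
    else:
        chosen = "welch" if all_normal else "mannwhitney"

    if chosen == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "Welch t test"
    elif chosen == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U test"
    elif chosen == "wilcoxon":
        if a.size != b.size:
            raise ValueError("Wilcoxon signed-rank requires paired samples")
        diffs = a - b
        if np.all(diffs == 0):
            # identical paired samples: no evidence of a difference
            return GroupComparisonResult(
                group_names=(name_a, name_b),
                design=design,
                normality_p=normality,
                all_normal=all_normal,
                test_name="Wilcoxon signed-rank test",
                statistic=0.0,
                raw_p=1.0,
                corrected_p=1.0,
                n_comparisons=family_size,
            )
        res = stats.wilcoxon(a, b)
        name = "Wilcoxon signed-rank test"
    else:
        raise ValueError(f"unknown test override {test_override!r}")

    raw_p = float(res.pvalue)
    return GroupComparisonResult(
        group_names=(name_a, name_b),
        design=design,
        normality_p=normality,
        all_normal=all_normal,
        test_name=name,
        statistic=float(res.statistic),
        raw_p=raw_p,
        corrected_p=min(1.0, raw_p * family_size),
        n_comparisons=family_size,
    )


def rank_omnibus(samples: dict) -> OmnibusResult:
    """Kruskal-Wallis omnibus over all groups (annotation only)."""
    if len(samples) < 2:
        raise ValueError("omnibus requires at least two groups")
    groups = [_as_sample(v, k) for k, v in samples.items()]
    res = stats.kruskal(*groups)
    return OmnibusResult(
        test_name="Kruskal-Wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_groups=len(groups),
    )
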