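"""Segmentation validation (Dice) and two-group statistics.

Validation follows the standard protocol for semiautomated segmentation:
the Dice similarity coefficient DSC(A, G) = 2|A n G| / (|A| + |G|) between
the algorithm mask A and a ground-truth mask G, evaluated on representative
calf (decade 3) and thigh (decade 7) slices, with per-group DSC means
compared by a pooled-variance Student's t-test after a Shapiro-Wilk
normality screen.

Composition metrics (which are not normally distributed across subjects)
are compared with the Mann-Whitney U test using midrank tie handling --
exact permutation p-values at small group sizes, a tie-corrected normal
approximation otherwise -- and the rank-based effect size
r = |Z| / sqrt(n1 + n2), bounded in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "dice",
    "mann_whitney",
    "effect_size_r",
    "dsc_report",
    "compare_dsc_groups",
]

# below this per-group size the exact permutation null is enumerated
EXACT_MAX_GROUP = 8
# enumeration guard: number of label arrangements we are willing to visit
EXACT_MAX_ARRANGEMENTS = 500_000


@dataclass
class GroupComparison:
    """Two-group test result with the standardized statistic behind r."""

    statistic: float        # U (Mann-Whitney) or t (Student)
    p_value: float
    z: float                # tie-corrected standardized statistic
    effect_size_r: float    # |Z| / sqrt(n1 + n2)
    n1: int
    n2: int
    test: str               # "mann-whitney" | "t"
    exact: bool = False


def dice(a: np.ndarray, g: np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks on one grid.

    Defined as 1.0 when both masks are empty (both raters agree there is no
    tissue; the case is logged).
    """
    a = np.asarray(a, dtype=bool)
    g = np.asarray(g, dtype=bool)
    if a.shape != g.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {g.shape}")
    denom = int(a.sum()) + int(g.sum())
    if denom == 0:
        logger.info("both masks empty; Dice defined as 1.0")
        return 1.0
    return 2.0 * int((a & g).sum()) / denom


def _u_statistic(ranks: np.ndarray, idx1: tuple[int, ...] | np.ndarray, n1: int, n2: int) -> float:
    r1 = float(ranks[list(idx1)].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(group1, group2, exact: bool | None = None) -> GroupComparison:
    """Mann-Whitney U comparison with midrank ties.

    ``exact=None`` enumerates the permutation null when both groups have
    fewer than 8 values (and the arrangement count is tractable); otherwise
    the two-sided p comes from the tie-corrected normal approximation.  The
    standardized Z is always the normal-approximation value, since the
    effect size r is defined through it.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x1, x2])
    N = n1 + n2
    ranks = sps.rankdata(pooled)
    u = _u_statistic(ranks, np.arange(n1), n1, n2)

    # tie-corrected normal approximation
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts) / (N * (N - 1.0))).sum()) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
    z = 0.0 if var <= 0 else (u - mu) / math.sqrt(var)

    n_arrangements = math.comb(N, n1)
    if exact is None:
        exact = min(n1, n2) < EXACT_MAX_GROUP and n_arrangements <= EXACT_MAX_ARRANGEMENTS
    if exact and n_arrangements > EXACT_MAX_ARRANGEMENTS:
        logger.warning("exact enumeration of %d arrangements infeasible; "
                       "falling back to the normal approximation", n_arrangements)
        exact = False

    if exact:
        u_low, u_high = min(u, n1 * n2 - u), max(u, n1 * n2 - u)
        hits = 0
        eps = 1e-9
        for idx in combinations(range(N), n1):
            u_perm = _u_statistic(ranks, idx, n1, n2)
            if u_perm <= u_low + eps or u_perm >= u_high - eps:
                hits += 1
        p = min(1.0, hits / n_arrangements)
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z))) if var > 0 else 1.0

    r = abs(z) / math.sqrt(N)
    return GroupComparison(statistic=u, p_value=p, z=z, effect_size_r=r,
                           n1=n1, n2=n2, test="mann-whitney", exact=exact)


def effect_size_r(comparison: GroupComparison) -> float:
    """Rank-based effect size ``r = |Z| / sqrt(n1 + n2)``."""
    return abs(comparison.z) / math.sqrt(comparison.n1 + comparison.n2)


# ---------------------------------------------------------------------------
# DSC reporting and group comparison
# ---------------------------------------------------------------------------

def dsc_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-subject DSC rows into the validation report table.

    Each row needs ``subject``, ``group``, ``region`` ("calf"/"thigh"),
    ``tissue`` ("sat"/"muscle") and ``dsc``.
    """
    df = pd.DataFrame(rows, columns=["subject", "group", "region", "tissue", "dsc"])
    if len(df) and not df["dsc"].between(0.0, 1.0).all():
        raise ValueError("DSC values must lie in [0, 1]")
    return df


def compare_dsc_groups(report: pd.DataFrame,
                       groups: tuple[str, str] = ("control-like", "lipedema-like"),
                       ) -> dict[tuple[str, str], GroupComparison]:
    """Per region/tissue two-sided pooled-variance t-test between the groups.

    Each group's DSC values are first screened for normality (Shapiro-Wilk,
    logged when rejected at 0.05); group sizes below 2 raise.
    """
    out: dict[tuple[str, str], GroupComparison] = {}
    for (region, tissue), sub in report.groupby(["region", "tissue"]):
        g1 = sub.loc[sub["group"] == groups[0], "dsc"].to_numpy(float)
        g2 = sub.loc[sub["group"] == groups[1], "dsc"].to_numpy(float)
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(f"{region}/{tissue}: both groups need >= 2 subjects")
        for name, g in zip(groups, (g1, g2)):
            if len(g) >= 3 and np.ptp(g) > 0:
                w = sps.shapiro(g)
                if w.pvalue < 0.05:
                    logger.warning("%s/%s %s: Shapiro-Wilk rejects normality (p=%.3g)",
                                   region, tissue, name, w.pvalue)
        t = sps.ttest_ind(g1, g2, equal_var=True)
        n1, n2 = len(g1), len(g2)
        stat = float(t.statistic) if np.isfinite(t.statistic) else 0.0
        p = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
        out[(region, tissue)] = GroupComparison(
            statistic=stat, p_value=p, z=stat,
            effect_size_r=min(1.0, abs(stat) / math.sqrt(n1 + n2)),
            n1=n1, n2=n2, test="t")
    return out
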