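"""Differential pathway analysis between cell groups.

Protocol: for every pair of groups, compare each pathway's per-cell scores
with an unpaired two-sided Student's t-test (pooled variance; Welch available
behind a flag), adjust p-values across pathways within that pair by
Benjamini-Hochberg, then aggregate per focal group: the reported FDR for a
pathway is the LARGEST FDR across all of the group's pairwise comparisons,
and the pathway is called up (down) in the group only when the median
difference is positive (negative) against every other group and that max FDR
is below the threshold (default 0.01). Direction comes from medians, not
from the sign of t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, DegenerateVarianceError, ValidationError

logger = logging.getLogger(__name__)

STUDENT = "student"
WELCH = "welch"

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass
class PairResult:
    """One pathway compared between one pair of groups (a vs b)."""

    pathway: str
    group_a: str
    group_b: str
    t_stat: float
    p_value: float
    fdr: float
    median_diff: float    # median(a) - median(b)
    n_a: int
    n_b: int

    def flipped(self) -> "PairResult":
        """The same comparison oriented b vs a."""
        return PairResult(self.pathway, self.group_b, self.group_a,
                          -self.t_stat, self.p_value, self.fdr,
                          -self.median_diff, self.n_b, self.n_a)


@dataclass
class PathwayCall:
    """Direction call for one pathway in one focal group."""

    pathway: str
    focal_group: str
    direction: str        # "up" | "down" | "ns"
    max_fdr: float
    pairs: list = field(default_factory=list)  # PairResult, oriented focal vs other


def t_test_pathway(scores_a, scores_b, test: str = STUDENT):
    """Two-sided unpaired t-test between two score vectors.

    Returns (t_stat, p_value, median_diff) with median_diff =
    median(a) - median(b). Zero pooled variance with equal means yields
    (0, 1) by convention; with unequal means it raises, because the
    statistic is unbounded.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs >= 2 cells for a t-test")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("scores must be finite")
    median_diff = float(np.median(a) - np.median(b))
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, median_diff
        raise DegenerateVarianceError(
            "zero variance in both groups with unequal means"
        )
    res = stats.ttest_ind(a, b, equal_var=(test == STUDENT))
    return float(res.statistic), float(res.pvalue), median_diff


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(scores_frame: pd.DataFrame, groups) -> dict:
    """Usable groups -> list of cell columns; groups with <2 scored cells are
    dropped with a warning."""
    cols = set(scores_frame.columns)
    usable = {}
    for label in groups.labels:
        cells = [c for c in groups.cells_in(label) if c in cols]
        if len(cells) < 2:
            logger.warning("group %r has %d scored cell(s) (<2); excluded",
                           label, len(cells))
            continue
        usable[label] = cells
    return usable


def pairwise_analysis(scores, groups, fdr_threshold: float = 0.01,
                      test: str = STUDENT) -> list:
    """All pairwise group comparisons for every pathway, with max-FDR calls.

    ``scores`` is a PathwayScoreMatrix or a pathways x cells DataFrame;
    ``groups`` a GroupAssignment. FDR adjustment is done across pathways
    within each pairwise comparison; the per-(pathway, focal group) call then
    takes the largest FDR over that group's pairs. Returns a list of
    PathwayCall, one per pathway per focal group.
    """
    frame = getattr(scores, "frame", scores)
    if not 0 < fdr_threshold < 1:
        raise AnalysisError("fdr_threshold must be in (0, 1)")
    usable = _group_columns(frame, groups)
    if len(usable) < 2:
        raise AnalysisError(
            f"differential analysis needs >= 2 groups with >= 2 scored cells; "
            f"got {len(usable)}"
        )
    pathways = list(frame.index)

    # per-pair t-tests, BH within the pair's pathway family
    pair_results = {}  # (a, b) -> {pathway: PairResult}
    for ga, gb in combinations(usable, 2):
        sub_a = frame[usable[ga]].to_numpy()
        sub_b = frame[usable[gb]].to_numpy()
        stats_rows = [t_test_pathway(sub_a[i], sub_b[i], test=test)
                      for i in range(len(pathways))]
        fdrs = bh_fdr([r[1] for r in stats_rows])
        pair_results[(ga, gb)] = {
            pw: PairResult(pw, ga, gb, t, p, float(q), md,
                           len(usable[ga]), len(usable[gb]))
            for pw, (t, p, md), q in zip(pathways, stats_rows, fdrs)
        }

    calls = []
    for pw in pathways:
        for focal in usable:
            oriented = []
            for (ga, gb), res in pair_results.items():
                if focal == ga:
                    oriented.append(res[pw])
                elif focal == gb:
                    oriented.append(res[pw].flipped())
            max_fdr = max(r.fdr for r in oriented)
            if max_fdr < fdr_threshold and all(r.median_diff > 0 for r in oriented):
                direction = UP
            elif max_fdr < fdr_threshold and all(r.median_diff < 0 for r in oriented):
                direction = DOWN
            else:
                direction = NS
            calls.append(PathwayCall(pathway=pw, focal_group=focal,
                                     direction=direction, max_fdr=max_fdr,
                                     pairs=oriented))
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    """Flatten PathwayCall objects into a tidy table (one row per call)."""
    rows = []
    for c in calls:
        row = {"pathway": c.pathway, "focal_group": c.focal_group,
               "direction": c.direction, "max_fdr": c.max_fdr}
        for pr in c.pairs:
            tag = f"vs_{pr.group_b}"
            row[f"t_{tag}"] = pr.t_stat
            row[f"p_{tag}"] = pr.p_value
            row[f"fdr_{tag}"] = pr.fdr
            row[f"median_diff_{tag}"] = pr.median_diff
        rows.append(row)
    return pd.DataFrame(rows)
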