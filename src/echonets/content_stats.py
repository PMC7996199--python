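"""Statistical comparison of interaction content across edge types.

Each retweet or comment is the analysis unit; it inherits the homophily
class (like-minded / cross-cutting / unclear) of its author -> target
edge, a lexicon sentiment score, and manual information and civility
codes.  The comparison grid, run separately per mechanism:

  (a) sentiment x edge type          one-way ANOVA
  (b) information x edge type        chi-square
  (c) civility x edge type           chi-square
  (d) sentiment x information        one-way ANOVA
  (e) sentiment x civility           Mann-Whitney U
  (f) civility x information         chi-square

No multiple-testing correction is applied by default; Bonferroni or
Benjamini-Hochberg can be requested.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coding import aggregate_user_attitude
from .data_model import Attitude, CivilityCode, Dataset, InfoCode, Kind, SentimentLexicon
from .echo_metrics import classify_edge
from .sentiment import score_text

__all__ = [
    "TestResult",
    "anova_oneway",
    "chi_square",
    "mann_whitney_u",
    "content_summary",
    "interaction_table",
    "run_comparisons",
]

_EXACT_MAX_COMBINATIONS = 200_000


@dataclass
class TestResult:
    """One hypothesis test with its grouping context."""

    test: str
    grouping: str
    statistic: Optional[float]
    df: Optional[tuple]
    p_value: Optional[float]
    groups: list[dict] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def defined(self) -> bool:
        return self.p_value is not None


def anova_oneway(values_by_group: dict[str, Sequence[float]]) -> TestResult:
    """One-way ANOVA: F with (k-1, N-k) df.

    A group with fewer than 2 observations is an error naming the group;
    zero variance everywhere leaves F undefined (flagged, not 0).
    """
    if len(values_by_group) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n={arr.size} < 2")
        arrays[name] = arr
    groups = [
        {"name": name, "n": int(a.size), "mean": float(a.mean())}
        for name, a in arrays.items()
    ]
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0.0:  # all observations identical
        return TestResult(
            test="anova_oneway",
            grouping=" vs ".join(arrays),
            statistic=None,
            df=(k - 1, n_total - k),
            p_value=None,
            groups=groups,
            note="undefined: zero variance within and between groups",
        )
    f_stat, p = sps.f_oneway(*arrays.values())
    return TestResult(
        test="anova_oneway",
        grouping=" vs ".join(arrays),
        statistic=float(f_stat),
        df=(k - 1, n_total - k),
        p_value=float(p),
        groups=groups,
    )


def chi_square(table, row_labels=None, col_labels=None) -> TestResult:
    """Pearson chi-square of independence on an r x c count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("table has a zero row or column marginal")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    n = arr.sum()
    row_labels = row_labels or [f"row{i}" for i in range(arr.shape[0])]
    groups = [
        {"name": lab, "n": int(arr[i].sum()), "proportions": (arr[i] / arr[i].sum()).tolist()}
        for i, lab in enumerate(row_labels)
    ]
    return TestResult(
        test="chi_square",
        grouping=" vs ".join(str(r) for r in row_labels),
        statistic=float(stat),
        df=(int(dof),),
        p_value=float(p),
        groups=groups,
        note=f"N={int(n)}",
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x, y) pairs with x > y, ties counting 1/2."""
    nx_, ny_ = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    rx = ranks[:nx_].sum()
    return float(rx - nx_ * (nx_ + 1) / 2)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Valid with ties (midranks); the permutation distribution of U is
    symmetric about nx*ny/2, so the two-sided p sums both tails at the
    observed distance from the center.
    """
    nx_, ny_ = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = nx_ * (nx_ + 1) / 2
    center = nx_ * ny_ / 2
    dist = abs(u_obs - center)
    lo, hi = center - dist, center + dist
    total = comb(nx_ + ny_, nx_)
    extreme = 0
    for idx in itertools.combinations(range(nx_ + ny_), nx_):
        u = ranks[list(idx)].sum() - offset
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            extreme += 1
    return min(1.0, extreme / total)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U (U reported for x; x wholly above y gives nx*ny).

    Exact enumeration (tie-safe) when min(n) <= 8 and the assignment count
    is tractable; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    small = min(x.size, y.size) <= 8
    tractable = comb(x.size + y.size, min(x.size, y.size)) <= _EXACT_MAX_COMBINATIONS
    if small and tractable:
        p = _exact_mwu_p(x, y, u)
        method = "exact"
    else:
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "asymptotic"
    groups = [
        {"name": "x", "n": int(x.size), "mean": float(x.mean())},
        {"name": "y", "n": int(y.size), "mean": float(y.mean())},
    ]
    return TestResult(
        test="mann_whitney_u",
        grouping="x vs y",
        statistic=u,
        df=None,
        p_value=p,
        groups=groups,
        note=method,
    )


# ---------------------------------------------------------------------------
# Dataset-level orchestration
# ---------------------------------------------------------------------------


def content_summary(posts) -> dict[str, float]:
    """Proportions of information and civility categories over posts."""
    posts = list(posts)
    n = len(posts)
    if n == 0:
        raise ValueError("no posts to summarize")
    info = defaultdict(int)
    civ = defaultdict(int)
    for p in posts:
        info[p.info_code] += 1
        civ[p.civility_code] += 1
    return {
        "n": n,
        "seeking": info[InfoCode.SEEKING] / n,
        "sharing": info[InfoCode.SHARING] / n,
        "none": info[InfoCode.NONE] / n,
        "civil": civ[CivilityCode.CIVIL] / n,
        "uncivil": civ[CivilityCode.UNCIVIL] / n,
    }


def interaction_table(
    dataset: Dataset,
    mechanism: Kind,
    lexicon: Optional[SentimentLexicon] = None,
    topics: Optional[list[str]] = None,
) -> pd.DataFrame:
    """One row per interaction post with edge type, sentiment and codes.

    Edge type comes from the (author attitude, target attitude) pair in
    the topic's mechanism network; self-interactions are excluded,
    mirroring network construction.
    """
    mechanism = Kind(mechanism)
    lexicon = lexicon or dataset.lexicon
    if lexicon is None:
        raise ValueError("a sentiment lexicon is required")
    if topics is None:
        topics = dataset.topics
    by_id = dataset.by_id
    # per (topic) aggregated attitudes for this mechanism
    rows = []
    for topic in topics:
        posts_by_author = defaultdict(list)
        original_authors = set()
        for p in dataset.posts:
            if p.topic != topic:
                continue
            if p.kind is Kind.ORIGINAL:
                original_authors.add(p.author_id)
            elif p.kind is mechanism:
                posts_by_author[p.author_id].append(p)

        def att_of(user: str) -> Attitude:
            if user in posts_by_author:
                return aggregate_user_attitude(posts_by_author[user]).attitude
            if user in original_authors:
                return Attitude.AGREE
            return Attitude.UNKNOWN

        cache: dict[str, Attitude] = {}
        for p in dataset.posts:
            if p.topic != topic or p.kind is not mechanism:
                continue
            target = by_id[p.parent_post_id].author_id
            if target == p.author_id:
                continue
            for user in (p.author_id, target):
                if user not in cache:
                    cache[user] = att_of(user)
            rows.append(
                {
                    "post_id": p.post_id,
                    "topic": topic,
                    "mechanism": mechanism.value,
                    "edge_type": classify_edge(cache[p.author_id], cache[target]),
                    "sentiment": score_text(p.tokens, lexicon).value,
                    "info": p.info_code.value,
                    "civility": p.civility_code.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["post_id", "topic", "mechanism", "edge_type", "sentiment",
                 "info", "civility"],
    )


def _crosstab(frame: pd.DataFrame, row: str, col: str) -> tuple[np.ndarray, list, list]:
    tab = pd.crosstab(frame[row], frame[col])
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    return tab.to_numpy(), list(tab.index), list(tab.columns)


def run_comparisons(
    dataset: Dataset,
    lexicon: Optional[SentimentLexicon] = None,
    mechanisms: tuple[Kind, ...] = (Kind.RETWEET, Kind.COMMENT),
    topics: Optional[list[str]] = None,
    correction: Optional[str] = None,
) -> list[TestResult]:
    """Run the six-comparison grid per mechanism over pooled topics.

    Comparisons whose grouping degenerates (a single populated group, or a
    group too small for the test) are returned with a note instead of
    failing the whole grid.  ``correction`` in {None, "bonferroni",
    "fdr_bh"} appends adjusted p-values across the defined tests.
    """
    results: list[TestResult] = []
    for mechanism in mechanisms:
        table = interaction_table(dataset, mechanism, lexicon=lexicon, topics=topics)
        mech = Kind(mechanism).value
        if table.empty:
            continue

        def add(result: TestResult, label: str) -> None:
            result.grouping = f"{mech}: {label}"
            results.append(result)

        # (a, d) ANOVA of sentiment over categorical groupings
        for label, col in (("sentiment x edge_type", "edge_type"),
                           ("sentiment x info", "info")):
            groups = {
                name: sub["sentiment"].to_numpy()
                for name, sub in table.groupby(col)
                if len(sub) >= 2
            }
            if len(groups) >= 2:
                add(anova_oneway(groups), label)
            else:
                add(
                    TestResult("anova_oneway", label, None, None, None,
                               note="skipped: fewer than 2 usable groups"),
                    label,
                )
        # (b, c, f) chi-square of category composition
        for label, row, col in (("info x edge_type", "edge_type", "info"),
                                ("civility x edge_type", "edge_type", "civility"),
                                ("civility x info", "info", "civility")):
            arr, rlab, clab = _crosstab(table, row, col)
            if arr.shape[0] >= 2 and arr.shape[1] >= 2:
                add(chi_square(arr, row_labels=rlab, col_labels=clab), label)
            else:
                add(
                    TestResult("chi_square", label, None, None, None,
                               note="skipped: degenerate contingency table"),
                    label,
                )
        # (e) Mann-Whitney of sentiment by civility
        civil = table.loc[table["civility"] == "civil", "sentiment"].to_numpy()
        uncivil = table.loc[table["civility"] == "uncivil", "sentiment"].to_numpy()
        label = "sentiment x civility"
        if civil.size and uncivil.size:
            add(mann_whitney_u(civil, uncivil), label)
        else:
            add(
                TestResult("mann_whitney_u", label, None, None, None,
                           note="skipped: a civility group is empty"),
                label,
            )

    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        defined = [r for r in results if r.defined]
        if defined:
            _, adjusted, _, _ = multipletests(
                [r.p_value for r in defined], method=correction
            )
            for r, p_adj in zip(defined, adjusted):
                r.note = (r.note + f"; p_{correction}={p_adj:.4g}").lstrip("; ")
    return results
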