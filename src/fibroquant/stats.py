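"""Statistical layer: stage labels, Fleiss kappa, paired t-tests, one-way
ANOVA with Tukey HSD post hoc, and stage-wise summaries.

Fibrosis stages follow the NASH CRN semi-quantitative system with the F1
sub-stages kept distinct and totally ordered:
F1a < F1b < F1c < F2 < F3 < F4; a coarse view collapses F1a/b/c to F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats import inter_rater

__all__ = [
    "STAGE_ORDER",
    "COARSE_ORDER",
    "StageLabel",
    "RatingMatrix",
    "GroupSummary",
    "fleiss_kappa",
    "kappa_band",
    "paired_t_test",
    "PairedTTestResult",
    "anova_tukey",
    "AnovaTukeyResult",
    "summarize_by_stage",
    "p_to_stars",
]

STAGE_ORDER: tuple[str, ...] = ("F1a", "F1b", "F1c", "F2", "F3", "F4")
COARSE_ORDER: tuple[str, ...] = ("F1", "F2", "F3", "F4")

_CANONICAL = {s.lower(): s for s in STAGE_ORDER}
# Accept bare numeric forms as they appear in clinical tables: "1a", "3", "4".
_CANONICAL.update({s.lower().lstrip("f"): s for s in STAGE_ORDER})


@dataclass(frozen=True, order=False)
class StageLabel:
    """Ordinal NASH CRN fibrosis stage."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in STAGE_ORDER:
            raise ValueError(
                f"unknown stage {self.value!r}; expected one of {STAGE_ORDER}"
            )

    @classmethod
    def parse(cls, text: str | "StageLabel") -> "StageLabel":
        """Case-insensitive parse; '1a' and 'F1a' are equivalent."""
        if isinstance(text, StageLabel):
            return text
        key = str(text).strip().lower()
        if key not in _CANONICAL:
            raise ValueError(f"cannot parse fibrosis stage {text!r}")
        return cls(_CANONICAL[key])

    @property
    def index(self) -> int:
        return STAGE_ORDER.index(self.value)

    @property
    def coarse(self) -> str:
        return "F1" if self.value.startswith("F1") else self.value

    def __lt__(self, other: "StageLabel") -> bool:
        return self.index < other.index

    def __le__(self, other: "StageLabel") -> bool:
        return self.index <= other.index

    def __gt__(self, other: "StageLabel") -> bool:
        return self.index > other.index

    def __ge__(self, other: "StageLabel") -> bool:
        return self.index >= other.index

    def __str__(self) -> str:
        return self.value


@dataclass
class RatingMatrix:
    """items x raters matrix of ordinal stage labels (no missing ratings)."""

    labels: np.ndarray  # (n_items, n_raters) of str
    category_set: tuple[str, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=object)
        if arr.ndim != 2:
            raise ValueError("labels must be an items x raters matrix")
        if arr.shape[1] < 2:
            raise ValueError("at least 2 raters are required")
        parsed = np.empty_like(arr)
        for idx, val in np.ndenumerate(arr):
            parsed[idx] = StageLabel.parse(val).value
        self.labels = parsed

    @classmethod
    def from_csv(cls, path) -> "RatingMatrix":
        """Rows = biopsies, columns = raters, values in {F1a..F4}."""
        df = pd.read_csv(path, index_col=0)
        return cls(labels=df.to_numpy(dtype=object))

    def to_coarse(self) -> "RatingMatrix":
        coarse = np.vectorize(lambda s: StageLabel.parse(s).coarse)(self.labels)
        return RatingMatrix.__new__(RatingMatrix)._init_raw(coarse, COARSE_ORDER)

    def _init_raw(self, labels, category_set):
        self.labels = labels
        self.category_set = category_set
        return self

    def count_table(self) -> np.ndarray:
        """n_items x n_categories table of rating counts."""
        cats = {c: k for k, c in enumerate(self.category_set)}
        table = np.zeros((self.labels.shape[0], len(cats)), dtype=np.int64)
        for i in range(self.labels.shape[0]):
            for j in range(self.labels.shape[1]):
                table[i, cats[self.labels[i, j]]] += 1
        return table


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    sem: float
    iqr: float
    min: float
    max: float


def fleiss_kappa(ratings: RatingMatrix, coarse: bool = False) -> float:
    """Fleiss' chance-corrected multi-rater agreement kappa.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar) over the matrix's category set.
    Perfect agreement returns exactly 1.0 even when chance agreement is 1
    (all ratings in a single category); a degenerate matrix with Pe = 1 but
    imperfect agreement raises, since kappa is undefined there.
    """
    if coarse:
        ratings = ratings.to_coarse()
    table = ratings.count_table()
    n_raters = ratings.labels.shape[1]
    perfect = bool((table.max(axis=1) == n_raters).all())
    if perfect:
        return 1.0
    p_cat = table.sum(axis=0) / table.sum()
    pe = float((p_cat**2).sum())
    if pe >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: chance agreement is 1 without perfect agreement")
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


_BANDS = (
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
)


def kappa_band(kappa: float) -> str:
    """Map kappa to the conventional Landis-Koch agreement band.

    kappa is rounded to 2 decimals first so the printed inclusive ranges
    (0.01-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80
    substantial, above that almost perfect) tile [-1, 1] completely;
    rounded values <= 0 are labeled "poor/none".
    """
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError("kappa must lie in [-1, 1]")
    k = round(kappa + 1e-12, 2)
    if k <= 0.0:
        return "poor/none"
    if k <= 0.20:
        return "slight"
    for lo, hi, name in _BANDS:
        if lo <= k <= hi:
            return name
    return "almost perfect"


@dataclass
class PairedTTestResult:
    t: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def paired_t_test(pre: Sequence[float], post: Sequence[float]) -> PairedTTestResult:
    """Two-sided dependent-samples (paired) t-test on pre/post values."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    if len(pre) < 2:
        raise ValueError("paired t-test requires n >= 2")
    diffs = post - pre
    if np.ptp(diffs) == 0:
        raise ValueError("paired t-test undefined: all differences identical")
    res = sps.ttest_rel(post, pre)
    return PairedTTestResult(t=float(res.statistic), df=len(pre) - 1, p=float(res.pvalue))


def p_to_stars(p: float) -> str:
    """Significance stars: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, stars


def anova_tukey(
    values: Sequence[float], groups: Iterable[str | StageLabel]
) -> AnovaTukeyResult:
    """One-way ANOVA across groups plus Tukey HSD pairwise adjusted p-values
    (studentized-range correction)."""
    values = np.asarray(values, dtype=float)
    group_keys = [str(g) for g in groups]
    if len(group_keys) != len(values):
        raise ValueError("values and groups must have equal length")
    by_group: dict[str, list[float]] = {}
    for v, g in zip(values, group_keys):
        by_group.setdefault(g, []).append(v)
    names = sorted(by_group)
    if len(names) < 2:
        raise ValueError("at least 2 groups are required")
    samples = [np.asarray(by_group[g]) for g in names]
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    f, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(hsd.pvalue[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(samples[j].mean() - samples[i].mean()),
                    "p_adj": p_adj,
                    "stars": p_to_stars(p_adj),
                }
            )
    n_total = sum(len(s) for s in samples)
    return AnovaTukeyResult(
        f=float(f),
        p=float(p),
        df_between=len(names) - 1,
        df_within=n_total - len(names),
        tukey=pd.DataFrame(rows),
    )


def summarize_by_stage(
    values: Sequence[float],
    groups: Iterable[str | StageLabel],
    coarse: bool = True,
) -> list[GroupSummary]:
    """Per-stage n, mean, sd, SEM, IQR (linear-interpolation quartiles),
    min and max, ordered by stage.  Heterogeneity summaries deliberately
    report both sd and SEM."""
    values = np.asarray(values, dtype=float)
    labels = [StageLabel.parse(g) for g in groups]
    if len(labels) != len(values):
        raise ValueError("values and groups must have equal length")
    keys = [lab.coarse if coarse else lab.value for lab in labels]
    order = COARSE_ORDER if coarse else STAGE_ORDER
    out = []
    for stage in order:
        vals = values[[k == stage for k in keys]]
        if len(vals) == 0:
            continue
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            GroupSummary(
                group=stage,
                n=len(vals),
                mean=float(vals.mean()),
                sd=sd,
                sem=sd / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                iqr=float(q3 - q1),
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    if not out:
        raise ValueError("no groups to summarize")
    return out
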