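"""Group statistics: normality, one-way ANOVA, Tamhane T2, letter display.

The statistical battery operates on vector-level observations (one value
per tracer sphere, either the 3D magnitude or the signed z component), not
per-sample means.  This yields very large within-group degrees of freedom
and is, strictly, pseudo-replication; it is retained deliberately because
ANOVA is robust to the resulting mild violations (Winer's argument) and
because the per-sphere distribution is the object of interest.  Group
variances are wildly unequal between bulk and lined restorations, hence a
heteroscedastic post hoc: Tamhane's T2, i.e. Welch pairwise t statistics
with Welch–Satterthwaite degrees of freedom and a Sidak-type familywise
adjustment (Bonferroni available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSample:
    """One labeled sample of scalar observations (μm)."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise StatsError(f"group {self.label!r}: values must be a finite "
                             "1-D array")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass
class PosthocTable:
    """All pairwise comparisons plus the compact letter display."""

    pairs: pd.DataFrame
    alpha: float
    letters: dict = field(default_factory=dict)


def shapiro_wilk(values, max_n: int = 5000, subsample_seed: int = 20210127):
    """Shapiro–Wilk normality test ``(W, p)``.

    The W statistic loses meaning (and scipy warns) for huge n, so samples
    above ``max_n`` are tested on a fixed-seed subsample of ``max_n``
    values — a deterministic, documented policy for the ~10⁴-sphere fields
    this pipeline produces.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise StatsError("shapiro_wilk needs a 1-D sample with n >= 3")
    if np.ptp(v) == 0:
        raise StatsError("shapiro_wilk is undefined for a constant sample")
    if len(v) > max_n:
        rng = np.random.default_rng(subsample_seed)
        v = rng.choice(v, size=max_n, replace=False)
    w, p = sps.shapiro(v)
    return float(w), float(p)


def one_way_anova(groups: list[GroupSample]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from sums of squares.

    ``F = MS_between / MS_within`` with ``df = (k - 1, N - k)``.  Zero
    within-group variance with unequal means is reported as an infinite F
    with p = 0 and the ``degenerate`` flag set.
    """
    if len(groups) < 2:
        raise StatsError("one_way_anova needs >= 2 groups")
    for g in groups:
        if g.n < 2:
            raise StatsError(f"group {g.label!r} needs n >= 2")
    k = len(groups)
    ns = np.array([g.n for g in groups])
    means = np.array([g.values.mean() for g in groups])
    grand = np.concatenate([g.values for g in groups]).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g.values - m) ** 2)
                          for g, m in zip(groups, means)))
    df_b, df_w = k - 1, int(ns.sum()) - k
    ms_b = ss_between / df_b
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, degenerate=True)
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def _welch_pair(gi: GroupSample, gj: GroupSample):
    vi = gi.values.var(ddof=1) / gi.n
    vj = gj.values.var(ddof=1) / gj.n
    diff = gi.values.mean() - gj.values.mean()
    se2 = vi + vj
    if se2 == 0.0:
        # both groups constant: identical means -> no evidence of difference
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        df = gi.n + gj.n - 2
        p = 1.0 if diff == 0 else 0.0
        return diff, t, float(df), p
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / (vi ** 2 / (gi.n - 1) + vj ** 2 / (gj.n - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return diff, float(t), float(df), p


def tamhane_t2(groups: list[GroupSample], alpha: float = 0.05,
               adjustment: str = "sidak") -> PosthocTable:
    """Tamhane's T2 pairwise comparisons for unequal variances.

    Per pair: Welch t statistic, Welch–Satterthwaite df, two-sided raw p,
    and the Sidak-type familywise adjustment
    ``p_adj = 1 - (1 - p_raw)^m`` over the ``m = k(k-1)/2`` comparisons
    (``adjustment="bonferroni"`` uses ``min(1, m p_raw)`` instead).
    """
    if len(groups) < 2:
        raise StatsError("tamhane_t2 needs >= 2 groups")
    for g in groups:
        if g.n < 2:
            raise StatsError(f"group {g.label!r} needs n >= 2")
    if adjustment not in ("sidak", "bonferroni"):
        raise StatsError(f"unknown adjustment {adjustment!r}")
    k = len(groups)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff, t, df, p_raw = _welch_pair(groups[i], groups[j])
            if adjustment == "sidak":
                p_adj = 1.0 - (1.0 - p_raw) ** m
            else:
                p_adj = min(1.0, m * p_raw)
            p_adj = min(1.0, max(p_adj, p_raw))
            rows.append({
                "group_i": groups[i].label, "group_j": groups[j].label,
                "mean_difference": diff, "welch_t": t, "welch_df": df,
                "raw_p": p_raw, "adjusted_p": p_adj,
                "significant": bool(p_adj < alpha),
            })
    table = PosthocTable(pairs=pd.DataFrame(rows), alpha=alpha)
    table.letters = letters_from_pairs(table,
                                       order=[g.label for g in groups])
    return table


def letters_from_pairs(posthoc: PosthocTable,
                       order: list | None = None) -> dict:
    """Compact letter display by insert-and-absorb.

    Groups share at least one letter iff their pairwise comparison is not
    significant.  Columns (letters) are built by splitting on each
    significant pair and absorbing subset columns; letters are assigned in
    the order the groups appear.
    """
    pairs = posthoc.pairs
    if order is None:
        order = sorted(set(pairs["group_i"]) | set(pairs["group_j"]),
                       key=str)
    columns: list[set] = [set(order)]
    sig = [(r.group_i, r.group_j) for r in pairs.itertuples(index=False)
           if r.significant]
    for a, b in sig:
        new_cols: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if col and not any(col <= kept for kept in columns):
                columns.append(col)
    # stable letter order: by first (then second, ...) member appearance
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: sorted(rank[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict = {g: [] for g in order}
    for idx, col in enumerate(columns):
        letter = alphabet[idx] if idx < 26 else f"l{idx}"
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def analyze_measure(fields_values: dict, alpha: float = 0.05,
                    adjustment: str = "sidak") -> dict:
    """Full battery on ``{label: values}``: normality, ANOVA, post hoc."""
    groups = [GroupSample(label, vals) for label, vals in
              fields_values.items()]
    normality = {}
    for g in groups:
        try:
            w, p = shapiro_wilk(g.values)
            normality[g.label] = {"W": w, "p": p}
        except StatsError as exc:
            normality[g.label] = {"error": str(exc)}
    anova = one_way_anova(groups)
    posthoc = tamhane_t2(groups, alpha=alpha, adjustment=adjustment)
    return {"normality": normality, "anova": anova, "posthoc": posthoc}
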