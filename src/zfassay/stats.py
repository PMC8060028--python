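"""Group-comparison statistics mirroring the assays' decision tree.

The branch is chosen by data: every group must pass Shapiro-Wilk
normality AND the groups jointly pass Brown-Forsythe (median-centered
Levene) variance homogeneity, each at alpha, to take the parametric
branch — one-way ANOVA with pairwise t tests adjusted by step-down
Holm-Sidak.  Otherwise the rank branch runs: a Wilcoxon rank-sum test
for two groups, or Kruskal-Wallis (tie-corrected) followed by Dunn's z
on mean ranks with tie-corrected variance for three or more, adjusted by
Holm step-down (Sidak and unadjusted variants are exposed because the
classical Dunn procedure is sometimes reported raw).

Post-hoc tables are computed unconditionally rather than gated on the
omnibus test, so pairwise familywise error tracks alpha under the null;
the omnibus result is always reported alongside.

Summaries follow the branch: mean +/- SD for parametric data, median
with quartiles for rank data.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatConfig",
    "GateResult",
    "GroupComparison",
    "holm_sidak_adjust",
    "holm_adjust",
    "normality_gate",
    "anova_holm_sidak",
    "rank_dunn",
    "summarize_groups",
    "compare_groups",
]

#: combined-n ceiling below which the two-group rank-sum test is exact
EXACT_RANKSUM_N = 20


@dataclass(frozen=True)
class StatConfig:
    """Significance level, branch forcing, and comparison scheme."""

    alpha: float = 0.05
    branch: str = "auto"  # auto | parametric | rank
    control_label: str | None = None
    comparisons: str = "all"  # all | control (control-vs-each-other-group)
    dunn_adjust: str = "holm"  # holm | sidak | none

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.branch not in ("auto", "parametric", "rank"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.comparisons not in ("all", "control"):
            raise ValueError(f"unknown comparison scheme {self.comparisons!r}")
        if self.comparisons == "control" and self.control_label is None:
            raise ValueError("control comparisons need a control_label")
        if self.dunn_adjust not in ("holm", "sidak", "none"):
            raise ValueError(f"unknown dunn_adjust {self.dunn_adjust!r}")


@dataclass
class GateResult:
    parametric: bool
    per_group: pd.DataFrame  # label, n, shapiro_W, shapiro_p, normal, note
    bf_stat: float
    bf_p: float
    equal_variance: bool


@dataclass
class GroupComparison:
    """Omnibus + pairwise post-hoc results with the branch actually taken."""

    branch: str  # parametric | rank
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, n_a, n_b, statistic, p_raw, p_adj, significant
    summaries: pd.DataFrame
    alpha: float
    gate: GateResult | None = field(default=None, repr=False)

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))

    def to_csv(self, path) -> None:
        self.pairwise.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "branch": self.branch,
            "alpha": self.alpha,
            "omnibus": {
                "test": self.omnibus_test,
                "statistic": self.omnibus_stat,
                "p": self.omnibus_p,
            },
            "pairwise": self.pairwise.to_dict(orient="records"),
            "summaries": self.summaries.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_groups(groups) -> dict[str, np.ndarray]:
    if not isinstance(groups, dict):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    out = {}
    for label, g in groups.items():
        arr = np.asarray(g, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[str(label)] = arr
    return out


def _pairs(labels, cfg: StatConfig | None = None):
    comparisons = cfg.comparisons if cfg else "all"
    control = cfg.control_label if cfg else None
    if comparisons == "control":
        if control not in labels:
            raise ValueError(f"control label {control!r} not among groups")
        return [(control, l) for l in labels if l != control]
    return list(itertools.combinations(labels, 2))


# ---------------------------------------------------------------------------
# p-value adjustment


def holm_sidak_adjust(p_raw) -> np.ndarray:
    """Step-down Sidak adjustment.

    With raw p sorted ascending, adjusted_i = max_{j<=i} 1-(1-p_j)^(m-j+1)
    (1-based j), clipped to 1; values are returned in the input order.
    """
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def holm_adjust(p_raw) -> np.ndarray:
    """Step-down Bonferroni (Holm) adjustment, input order preserved."""
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _adjust(p_raw, method: str) -> np.ndarray:
    if method == "holm":
        return holm_adjust(p_raw)
    if method in ("sidak", "holm-sidak"):
        return holm_sidak_adjust(p_raw)
    if method == "none":
        return np.minimum(np.asarray(p_raw, dtype=float), 1.0)
    raise ValueError(f"unknown adjustment {method!r}")


# ---------------------------------------------------------------------------
# normality / variance gate


def normality_gate(groups, alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk per group plus Brown-Forsythe across groups.

    Parametric iff every group is consistent with normality at ``alpha``
    AND variances are homogeneous at ``alpha``.  A constant group cannot
    be tested and fails the gate with a diagnostic rather than raising.
    """
    groups = _as_groups(groups)
    rows = []
    all_normal = True
    testable = []
    for label, g in groups.items():
        note = ""
        if g.size < 3:
            w, p, normal, note = np.nan, np.nan, False, "n < 3"
        elif np.ptp(g) == 0:
            w, p, normal, note = np.nan, np.nan, False, "constant"
        else:
            w, p = sps.shapiro(g)
            normal = p >= alpha
            testable.append(g)
        all_normal &= bool(normal)
        rows.append(
            {
                "label": label,
                "n": int(g.size),
                "shapiro_W": w,
                "shapiro_p": p,
                "normal": bool(normal),
                "note": note,
            }
        )
    if len(testable) >= 2:
        bf_stat, bf_p = sps.levene(*testable, center="median")
        equal_var = bool(bf_p >= alpha)
    else:
        bf_stat, bf_p, equal_var = np.nan, np.nan, False
    return GateResult(
        parametric=bool(all_normal and equal_var),
        per_group=pd.DataFrame(rows),
        bf_stat=float(bf_stat),
        bf_p=float(bf_p),
        equal_variance=equal_var,
    )


# ---------------------------------------------------------------------------
# parametric branch


def anova_holm_sidak(
    groups, alpha: float = 0.05, cfg: StatConfig | None = None
) -> GroupComparison:
    """One-way ANOVA omnibus with Holm-Sidak-adjusted pairwise t tests."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    f_stat, f_p = sps.f_oneway(*groups.values())
    pairs = _pairs(list(groups), cfg)
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": groups[a].size,
                "n_b": groups[b].size,
                "statistic": float(t),
                "p_raw": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = holm_sidak_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return GroupComparison(
        branch="parametric",
        omnibus_test="one-way ANOVA",
        omnibus_stat=float(f_stat),
        omnibus_p=float(f_p),
        pairwise=table,
        summaries=summarize_groups(groups, "parametric"),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# rank branch


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-group Wilcoxon rank-sum: exact null when small and tie-free."""
    combined = np.concatenate([a, b])
    exact_ok = combined.size <= EXACT_RANKSUM_N and np.unique(combined).size == combined.size
    method = "exact" if exact_ok else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dunn_pairwise(
    groups: dict[str, np.ndarray], pairs
) -> pd.DataFrame:
    """Dunn's post-hoc z statistics on mean ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) over tie groups of the pooled sample; raw p is
    two-sided normal.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[l] for l in labels])
    n = {l: groups[l].size for l in labels}
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for l in labels:
        mean_rank[l] = ranks[start : start + n[l]].mean()
        start += n[l]
    N = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = np.sum(counts**3 - counts)
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_term * (1.0 / n[a] + 1.0 / n[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": n[a],
                "n_b": n[b],
                "statistic": float(z),
                "p_raw": float(min(p, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def rank_dunn(
    groups, alpha: float = 0.05, cfg: StatConfig | None = None
) -> GroupComparison:
    """Rank-based branch: rank-sum (2 groups) or Kruskal-Wallis + Dunn's."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    adjust = cfg.dunn_adjust if cfg else "holm"
    labels = list(groups)
    if len(groups) == 2:
        a, b = labels
        stat, p = _ranksum(groups[a], groups[b])
        table = pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": groups[a].size,
                    "n_b": groups[b].size,
                    "statistic": stat,
                    "p_raw": p,
                }
            ]
        )
        table["p_adj"] = table["p_raw"]
        omnibus_test, o_stat, o_p = "Wilcoxon rank-sum", stat, p
    else:
        o_stat, o_p = sps.kruskal(*groups.values())
        omnibus_test = "Kruskal-Wallis"
        table = dunn_pairwise(groups, _pairs(labels, cfg))
        table["p_adj"] = _adjust(table["p_raw"].to_numpy(), adjust)
    table["significant"] = table["p_adj"] < alpha
    return GroupComparison(
        branch="rank",
        omnibus_test=omnibus_test,
        omnibus_stat=float(o_stat),
        omnibus_p=float(o_p),
        pairwise=table,
        summaries=summarize_groups(groups, "rank"),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------


def summarize_groups(groups, branch: str) -> pd.DataFrame:
    """Distribution-appropriate per-group summaries.

    Parametric: mean, SD (NaN for n = 1), n.  Rank: median, Q1, Q3
    (linear-interpolation quartiles), n.
    """
    groups = _as_groups(groups)
    rows = []
    for label, g in groups.items():
        if branch == "parametric":
            rows.append(
                {
                    "label": label,
                    "n": g.size,
                    "mean": float(g.mean()),
                    "sd": float(g.std(ddof=1)) if g.size > 1 else np.nan,
                }
            )
        elif branch == "rank":
            q1, med, q3 = np.percentile(g, [25, 50, 75], method="linear")
            rows.append(
                {
                    "label": label,
                    "n": g.size,
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                }
            )
        else:
            raise ValueError(f"unknown branch {branch!r}")
    return pd.DataFrame(rows)


def compare_groups(groups, cfg: StatConfig = StatConfig()) -> GroupComparison:
    """Full decision tree: gate (unless forced), dispatch, summarize."""
    groups = _as_groups(groups)
    gate = None
    if cfg.branch == "auto":
        gate = normality_gate(groups, cfg.alpha)
        branch = "parametric" if gate.parametric else "rank"
    else:
        branch = cfg.branch
    if branch == "parametric":
        result = anova_holm_sidak(groups, cfg.alpha, cfg)
    else:
        result = rank_dunn(groups, cfg.alpha, cfg)
    result.gate = gate
    return result
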