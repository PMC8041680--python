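"""Group-level statistics: one-way ANOVA over GROUP, Tukey post hoc with
effect sizes, covariate-adjusted ANCOVA, and a within-group outlier rule.

The ANOVA is the classical between-subjects sum-of-squares decomposition
(one factor, so Type I and Type III coincide even for unbalanced
groups); eta^2 = SS_between / SS_total.  Tukey-Kramer post hoc p-values
use the studentized-range distribution with the omnibus error df, and t
statistics use the pooled MS_error.  Cohen's d defaults to the
``2 t / sqrt(df_error)`` convention used in the study being modeled
(``pooled_pairwise`` is available as an alternative).  Post hoc tests
are reported for all pairs regardless of omnibus significance.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PosthocPair:
    group_a: str
    group_b: str
    diff: float           # mean_a - mean_b
    t: float              # |diff| / SE with pooled MS_error
    p_adjusted: float     # Tukey-Kramer (studentized range)
    cohens_d: float
    df: float


@dataclass
class GroupComparison:
    variable: str
    F: float
    df_between: int
    df_error: int
    p: float
    eta_squared: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    posthoc: list[PosthocPair] = field(default_factory=list)
    outliers_removed: list[str] = field(default_factory=list)


def remove_outliers(values_by_group: Mapping[str, Sequence[float]],
                    ids_by_group: Mapping[str, Sequence[str]] | None = None,
                    k_sd: float = 3.0):
    """Single-pass within-group outlier removal: drop |x - mean| > k_sd * SD.

    Returns (filtered values_by_group, removed ids).  Zero-variance
    groups remove nothing.
    """
    out = {}
    removed: list[str] = []
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        ids = list(ids_by_group[g]) if ids_by_group else \
            [f"{g}_{i}" for i in range(len(vals))]
        sd = np.std(vals, ddof=1) if len(vals) >= 2 else 0.0
        if sd == 0.0:
            keep = np.ones(len(vals), dtype=bool)
        else:
            keep = np.abs(vals - np.mean(vals)) <= k_sd * sd
        out[g] = vals[keep]
        removed.extend(i for i, k in zip(ids, keep) if not k)
    return out, removed


def _clean(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 usable values")
        out[g] = arr
    return out


def oneway_anova(values_by_group: Mapping[str, Sequence[float]],
                 variable: str = "") -> GroupComparison:
    """Classical one-way between-subjects ANOVA with eta^2."""
    groups = _clean(values_by_group)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    all_vals = np.concatenate(list(groups.values()))
    N = len(all_vals)
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ss_total = ((all_vals - grand) ** 2).sum()
    df_b, df_e = k - 1, N - k
    ms_b, ms_e = ss_between / df_b, ss_within / df_e
    F = ms_b / ms_e if ms_e > 0 else math.inf
    p = float(stats.f.sf(F, df_b, df_e)) if math.isfinite(F) else 0.0
    return GroupComparison(
        variable=variable, F=float(F), df_between=df_b, df_error=df_e, p=p,
        eta_squared=float(ss_between / ss_total) if ss_total > 0 else 0.0,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_ns={g: int(len(v)) for g, v in groups.items()},
    )


def oneway_anova_from_summary(ns: Sequence[int], means: Sequence[float],
                              sds: Sequence[float],
                              variable: str = "",
                              labels: Sequence[str] | None = None) -> GroupComparison:
    """One-way ANOVA reconstructed from per-group (n, mean, SD) summaries.

    Algebraically identical to :func:`oneway_anova` on the raw data; lets
    published summary tables be re-analysed.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    labels = list(labels) if labels else [f"g{i + 1}" for i in range(len(ns))]
    k, N = len(ns), ns.sum()
    grand = float(np.sum(ns * means) / N)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df_b, df_e = k - 1, int(N - k)
    F = (ss_between / df_b) / (ss_within / df_e)
    return GroupComparison(
        variable=variable, F=float(F), df_between=df_b, df_error=df_e,
        p=float(stats.f.sf(F, df_b, df_e)),
        eta_squared=ss_between / (ss_between + ss_within),
        group_means=dict(zip(labels, means.tolist())),
        group_ns=dict(zip(labels, ns.astype(int).tolist())),
    )


def _tukey_pairs(groups: dict[str, np.ndarray], ms_e: float, df_e: int,
                 k: int, d_convention: str) -> list[PosthocPair]:
    pairs = []
    for (ga, va), (gb, vb) in itertools.combinations(groups.items(), 2):
        na, nb = len(va), len(vb)
        diff = float(va.mean() - vb.mean())
        se = math.sqrt(ms_e * (1.0 / na + 1.0 / nb))
        t = abs(diff) / se if se > 0 else math.inf
        # Tukey-Kramer: q = |diff| / sqrt(MS_e/2 * (1/na + 1/nb)) = t * sqrt(2)
        q = t * math.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_e)) if math.isfinite(q) else 0.0
        if d_convention == "pooled_pairwise":
            sp = math.sqrt(((na - 1) * va.var(ddof=1) + (nb - 1) * vb.var(ddof=1))
                           / (na + nb - 2))
            d = abs(diff) / sp if sp > 0 else math.inf
        else:  # '2t_over_sqrt_df'
            d = 2.0 * t / math.sqrt(df_e)
        pairs.append(PosthocPair(ga, gb, diff, float(t), min(1.0, p_adj),
                                 float(d), float(df_e)))
    return pairs


def tukey_posthoc(values_by_group: Mapping[str, Sequence[float]],
                  d_convention: str = "2t_over_sqrt_df") -> list[PosthocPair]:
    """All-pairs Tukey-Kramer comparisons with pooled-error t and Cohen's d."""
    if d_convention not in ("2t_over_sqrt_df", "pooled_pairwise"):
        raise ValueError("unknown d_convention")
    groups = _clean(values_by_group)
    k = len(groups)
    N = sum(len(v) for v in groups.values())
    df_e = N - k
    ms_e = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_e
    return _tukey_pairs(groups, ms_e, df_e, k, d_convention)


def tukey_from_summary(ns: Sequence[int], means: Sequence[float],
                       sds: Sequence[float],
                       labels: Sequence[str] | None = None,
                       d_convention: str = "2t_over_sqrt_df") -> list[PosthocPair]:
    """Tukey-Kramer post hoc reconstructed from per-group summaries."""
    labels = list(labels) if labels else [f"g{i + 1}" for i in range(len(ns))]
    k = len(ns)
    N = sum(ns)
    df_e = N - k
    ms_e = sum((n - 1) * s ** 2 for n, s in zip(ns, sds)) / df_e
    pairs = []
    for (ia, ib) in itertools.combinations(range(k), 2):
        na, nb = ns[ia], ns[ib]
        diff = means[ia] - means[ib]
        se = math.sqrt(ms_e * (1.0 / na + 1.0 / nb))
        t = abs(diff) / se
        q = t * math.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_e))
        if d_convention == "pooled_pairwise":
            sp = math.sqrt(((na - 1) * sds[ia] ** 2 + (nb - 1) * sds[ib] ** 2)
                           / (na + nb - 2))
            d = abs(diff) / sp
        else:
            d = 2.0 * t / math.sqrt(df_e)
        pairs.append(PosthocPair(labels[ia], labels[ib], float(diff), float(t),
                                 min(1.0, p_adj), float(d), float(df_e)))
    return pairs


def ancova(values_by_group: Mapping[str, Sequence[float]],
           covariate_by_group: Mapping[str, Sequence[float]],
           variable: str = "") -> GroupComparison:
    """One-way ANCOVA with a single covariate (homogeneous slopes).

    The group effect is the extra sum of squares of the group factor over
    the covariate-only model; participants with a missing covariate are
    dropped (counted per group).  eta^2 here is the partial
    SS_group / (SS_group + SS_residual).
    """
    ys, xs, gs = [], [], []
    dropped = []
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        cov = np.asarray(covariate_by_group[g], dtype=float)
        if len(vals) != len(cov):
            raise ValueError(f"group '{g}': outcome and covariate lengths differ")
        keep = ~(np.isnan(vals) | np.isnan(cov))
        n_drop = int((~keep).sum())
        if n_drop:
            dropped.append(f"{g}:{n_drop}")
        ys.append(vals[keep]); xs.append(cov[keep]); gs += [g] * int(keep.sum())
    y = np.concatenate(ys)
    x = np.concatenate(xs)
    labels = sorted(set(gs))
    N, k = len(y), len(labels)

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones((N, 1))
    xcol = x.reshape(-1, 1)
    G = np.array([[1.0 if g == lab else 0.0 for lab in labels[1:]] for g in gs])
    rss_reduced = rss(np.hstack([ones, xcol]))          # covariate only
    rss_full = rss(np.hstack([ones, xcol, G]))          # covariate + group
    df_b = k - 1
    df_e = N - k - 1
    ss_group = rss_reduced - rss_full
    F = (ss_group / df_b) / (rss_full / df_e)
    groups_arr = {g: y[np.array(gs) == g] for g in labels}
    return GroupComparison(
        variable=variable, F=float(F), df_between=df_b, df_error=df_e,
        p=float(stats.f.sf(F, df_b, df_e)),
        eta_squared=float(ss_group / (ss_group + rss_full)),
        group_means={g: float(v.mean()) for g, v in groups_arr.items()},
        group_ns={g: int(len(v)) for g, v in groups_arr.items()},
        outliers_removed=dropped,
    )


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   variable: str = "",
                   outlier_k_sd: float | None = None,
                   ids_by_group: Mapping[str, Sequence[str]] | None = None,
                   d_convention: str = "2t_over_sqrt_df") -> GroupComparison:
    """ANOVA + Tukey post hoc, with optional per-variable outlier removal."""
    removed: list[str] = []
    vals = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    vals = {g: v[~np.isnan(v)] for g, v in vals.items()}
    if outlier_k_sd is not None:
        vals, removed = remove_outliers(vals, ids_by_group, outlier_k_sd)
    cmp = oneway_anova(vals, variable)
    cmp.posthoc = tukey_posthoc(vals, d_convention)
    cmp.outliers_removed = removed
    return cmp
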