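"""Confounder statistics: one-way ANOVA variance shares (eta squared),
edge-effect rank-sum testing, normality-gated two-group comparisons, and
Benjamini-Hochberg adjustment.

The variance-component analysis runs a *separate* one-way ANOVA per
covariate with viability as the response, reporting each covariate's
eta squared = SS_between / SS_total — the share of total variance the
covariate explains on its own. Shares from separate ANOVAs need not sum
to 100% when covariates are confounded; on orthogonal designs they do (up
to noise). Continuous covariates (dose, time, volume) are treated as
categorical levels exactly as tested, matching a discrete optimization grid.

The edge-effect test is a two-sided Wilcoxon rank-sum (Mann-Whitney U) of
perimeter- versus interior-well signals. Two-group comparisons are gated by
Shapiro-Wilk normality on each sample: a t-test when both samples look
normal (P > 0.05), the rank-sum test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError
from .io import PlateRead
from .wells import WellRole

SIGNIFICANCE = 0.05

_STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def stars(p: float) -> str:
    """Significance stars: ns if p > 0.05; * <=0.05; ** <=0.01; *** <=0.001;
    **** <=0.0001."""
    for cut, sym in _STAR_LEVELS:
        if p <= cut:
            return sym
    return "ns"


@dataclass
class VarianceRow:
    covariate: str
    ss_between: float
    ss_total: float
    eta_sq: float  # fraction in [0, 1]
    p: float

    @property
    def eta_sq_pct(self) -> float:
        return 100.0 * self.eta_sq

    @property
    def neglog10_p(self) -> float:
        return float(-np.log10(self.p)) if self.p > 0 else np.inf


@dataclass
class ComparisonResult:
    method: str  # "t_test" or "wilcoxon"
    p: float
    p_adj: float | None = None
    warning: str | None = None

    @property
    def stars(self) -> str:
        return stars(self.p_adj if self.p_adj is not None else self.p)


def eta_squared(values, groups) -> VarianceRow:
    """One-way ANOVA variance share.

    ss_between = sum_g n_g (ybar_g - ybar)^2, ss_total = sum (y - ybar)^2,
    eta_sq = ss_between / ss_total; p from the one-way F statistic.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise DomainError("values and groups must have equal length")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise InsufficientDataError("eta_squared needs >= 2 groups")
    if len(y) < len(labels) + 1:
        raise InsufficientDataError("eta_squared needs observations beyond group count")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss_between = 0.0
    for lab in labels:
        yg = y[g == lab]
        ss_between += len(yg) * (yg.mean() - grand) ** 2
    if ss_total <= 0:
        return VarianceRow("", 0.0, 0.0, 0.0, 1.0)
    ss_within = ss_total - ss_between
    df_b = len(labels) - 1
    df_w = len(y) - len(labels)
    if ss_within <= 1e-300 * max(1.0, ss_between):
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    return VarianceRow("", float(ss_between), ss_total,
                       float(ss_between / ss_total), p)


def variance_table(dataset: pd.DataFrame, covariates: list[str],
                   response: str = "viability_pct") -> pd.DataFrame:
    """One VarianceRow per covariate (separate one-way ANOVAs), sorted by
    eta squared descending. Constant covariates are skipped with a warning
    column note; the significance threshold for plots is -log10(0.05)."""
    if response not in dataset.columns:
        raise DomainError(f"response column {response!r} not in dataset")
    rows = []
    for cov in covariates:
        if cov not in dataset.columns:
            raise DomainError(f"covariate column {cov!r} not in dataset")
        sub = dataset[[response, cov]].dropna()
        if sub[cov].nunique() < 2:
            continue  # constant covariate carries no variance information
        vr = eta_squared(sub[response].to_numpy(), sub[cov].to_numpy())
        rows.append({
            "covariate": cov, "ss_between": vr.ss_between,
            "ss_total": vr.ss_total, "eta_sq_pct": vr.eta_sq_pct,
            "p": vr.p, "neglog10_p": vr.neglog10_p,
        })
    out = pd.DataFrame(rows, columns=["covariate", "ss_between", "ss_total",
                                      "eta_sq_pct", "p", "neglog10_p"])
    return out.sort_values("eta_sq_pct", ascending=False).reset_index(drop=True)


def _rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value with mid-rank ties; exact
    distribution for small tie-free samples, normal approximation with
    continuity correction otherwise."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all values tied; no evidence of a shift
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def edge_effect_test(plate) -> ComparisonResult:
    """Wilcoxon rank-sum test of perimeter- vs interior-well signals.

    ``plate`` may be a :class:`PlateRead`, a DataFrame with row/col/signal
    columns (one or more pooled plates), or a (perimeter, interior) pair of
    signal arrays. Excluded wells are ignored when roles are present.
    """
    if isinstance(plate, tuple):
        perim, inner = (np.asarray(v, dtype=float) for v in plate)
    else:
        df = plate.wells if isinstance(plate, PlateRead) else plate
        if "role" in df.columns:
            df = df[df["role"] != WellRole.EXCLUDED.value]
        on_edge = df["row"].isin(["A", "H"]) | df["col"].astype(int).isin([1, 12])
        perim = df.loc[on_edge, "signal"].to_numpy(dtype=float)
        inner = df.loc[~on_edge, "signal"].to_numpy(dtype=float)
    if len(perim) < 3 or len(inner) < 3:
        raise InsufficientDataError(
            f"edge-effect test needs >= 3 wells per group "
            f"(got {len(perim)} perimeter, {len(inner)} interior)"
        )
    return ComparisonResult("wilcoxon", _rank_sum(perim, inner))


def adaptive_compare(a, b, normality_alpha: float = 0.05) -> ComparisonResult:
    """Shapiro-Wilk-gated two-group comparison.

    A two-sided t-test when both samples pass normality (P > 0.05); the
    Wilcoxon rank-sum test when either fails. Constant samples, on which
    Shapiro-Wilk is undefined, fall back to the rank-sum test with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("adaptive_compare needs n >= 3 per sample")
    warning = None
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warning = "constant sample: normality test undefined; using rank-sum"
        normal = False
    else:
        normal = (sps.shapiro(a).pvalue > normality_alpha
                  and sps.shapiro(b).pvalue > normality_alpha)
    if normal:
        p = float(sps.ttest_ind(a, b).pvalue)
        return ComparisonResult("t_test", p)
    return ComparisonResult("wilcoxon", _rank_sum(a, b), warning=warning)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved,
    monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise adaptive comparisons with one BH family per table."""
    names = list(samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = adaptive_compare(samples[names[i]], samples[names[j]])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "method": r.method, "p": r.p})
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "method", "p"])
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["stars"] = [stars(q) for q in df["p_adj"]]
    return df
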