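"""Group-comparison statistics, contingency analysis, odds ratios, and the
delta-delta-Ct relative-expression calculation.

Exposes the tests used for per-site metric comparisons: one-way ANOVA with
Tukey post hoc, independent t-test, pairwise Mann-Whitney U, Kruskal-Wallis
or pairwise Kolmogorov-Smirnov with Dunn post hoc, all with optional
Bonferroni correction; Fisher's exact test with Bonferroni; Wald odds-ratio
confidence intervals with Haldane-Anscombe correction for zero cells.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, TableValidationError

METHODS = ("anova_tukey", "ttest", "mannwhitney_pairwise", "kruskal_dunn", "ks_dunn")


def bonferroni(p: float, m: int) -> float:
    """Adjusted p = min(1, p * m); never smaller than the raw p."""
    return float(min(1.0, p * max(m, 1)))


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupCompareReport:
    """Omnibus + pairwise test report with full method metadata."""

    method: str
    correction: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult]
    n_per_group: dict[str, int]
    n_comparisons: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "group_a": r.group_a, "group_b": r.group_b, "statistic": r.statistic,
                "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "method": self.method,
            }
            for r in self.pairwise
        ]


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's post-hoc rank test with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p.
    """
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for g in labels:
        n = len(samples[g])
        mean_ranks[g] = ranks[i : i + n].mean()
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((a, b, float(z), float(p)))
    return out


def group_compare(
    samples: dict[str, "np.ndarray | list[float]"],
    method: str = "kruskal_dunn",
    correction: str = "bonferroni",
) -> GroupCompareReport:
    """Compare per-site scalar measurements across groups.

    ``samples`` maps group label -> measurements. Methods: anova_tukey
    (Tukey HSD pairwise, no extra correction on top), ttest (two groups),
    mannwhitney_pairwise, kruskal_dunn, ks_dunn (pairwise two-sample KS;
    the omnibus slot carries Kruskal-Wallis since no multi-group KS
    exists). Bonferroni multiplies each raw pairwise p by the number of
    comparisons, capped at 1.
    """
    if method not in METHODS:
        raise ConfigError(f"method must be one of {METHODS}, got {method!r}")
    if correction not in ("bonferroni", "none"):
        raise ConfigError("correction must be 'bonferroni' or 'none'")
    groups = {g: np.asarray(v, float) for g, v in samples.items()}
    if len(groups) < 2:
        raise ConfigError("group comparison needs at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ConfigError(f"group {g!r} needs n >= 2, found {len(v)}")
    if method in ("anova_tukey", "ttest"):
        for g, v in groups.items():
            if np.ptp(v) == 0:
                raise ConfigError(
                    f"group {g!r} has zero variance; use a rank-based method "
                    "(mannwhitney_pairwise or kruskal_dunn)"
                )
    labels = list(groups)
    values = [groups[g] for g in labels]
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)

    def adjust(p):
        return bonferroni(p, m) if correction == "bonferroni" else float(p)

    pairwise: list[PairwiseResult] = []
    if method == "anova_tukey":
        stat, p = sps.f_oneway(*values)
        tukey = sps.tukey_hsd(*values)
        for i, j in itertools.combinations(range(len(labels)), 2):
            pairwise.append(
                PairwiseResult(
                    labels[i], labels[j],
                    float(tukey.statistic[i, j]), float(tukey.pvalue[i, j]),
                    float(tukey.pvalue[i, j]),  # Tukey already family-wise
                )
            )
    elif method == "ttest":
        if len(labels) != 2:
            raise ConfigError("ttest requires exactly 2 groups")
        stat, p = sps.ttest_ind(values[0], values[1])
        pairwise.append(PairwiseResult(labels[0], labels[1], float(stat), float(p), adjust(p)))
    elif method == "mannwhitney_pairwise":
        stat, p = sps.kruskal(*values) if len(values) > 2 else (np.nan, np.nan)
        for a, b in pairs:
            s, pr = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            pairwise.append(PairwiseResult(a, b, float(s), float(pr), adjust(pr)))
        if len(values) == 2:
            stat, p = pairwise[0].statistic, pairwise[0].p_raw
    elif method in ("kruskal_dunn", "ks_dunn"):
        stat, p = sps.kruskal(*values)
        if method == "kruskal_dunn":
            for a, b, z, pr in _dunn_pairwise(groups):
                pairwise.append(PairwiseResult(a, b, z, pr, adjust(pr)))
        else:
            for a, b in pairs:
                s, pr = sps.ks_2samp(groups[a], groups[b])
                pairwise.append(PairwiseResult(a, b, float(s), float(pr), adjust(pr)))
    return GroupCompareReport(
        method=method,
        correction=correction,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        n_per_group={g: len(v) for g, v in groups.items()},
        n_comparisons=m,
    )


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise TableValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise TableValidationError("contingency counts must be nonnegative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise TableValidationError("contingency counts must be integers")
        t = np.round(t).astype(int)
    return t


@dataclass
class FisherResult:
    p_raw: float
    p_adjusted: float
    odds_ratio: float
    correction_m: int


def fisher_exact(table, correction_m: int = 1) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table with Bonferroni.

    Two-sided p sums the probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (the conventional definition). Adjusted p = min(1, p * correction_m).
    """
    t = _check_2x2(table)
    res = sps.fisher_exact(t, alternative="two-sided")
    return FisherResult(
        p_raw=float(res.pvalue),
        p_adjusted=bonferroni(res.pvalue, correction_m),
        odds_ratio=float(res.statistic),
        correction_m=int(correction_m),
    )


def fisher_exact_enumeration(table) -> float:
    """Independent oracle: two-sided Fisher p by full enumeration of all
    tables with the observed margins, hypergeometric probabilities from
    exact integer binomials."""
    from math import comb

    t = _check_2x2(table)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    probs = []
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        probs.append(comb(r1, x) * comb(n - r1, c1 - x) / denom)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    # tolerate float round-off when comparing table probabilities
    return float(sum(p for p in probs if p <= p_obs * (1 + 1e-12)))


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool
    ci_level: float = 0.95


def odds_ratio_ci(table, ci_level: float = 0.95) -> OddsRatioResult:
    """OR = ad/bc with a Wald log-scale CI.

    Any zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell, flagged in the result). CI = exp(ln OR +- z * sqrt(1/a +
    1/b + 1/c + 1/d)).
    """
    t = _check_2x2(table).astype(float)
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + ci_level / 2)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(or_ * np.exp(-z * se)),
        ci_high=float(or_ * np.exp(z * se)),
        continuity_corrected=corrected,
        ci_level=float(ci_level),
    )


@dataclass
class CtTable:
    """Per-sample qPCR cycle thresholds for one target gene.

    Columns: sample_id, group, ct_target, ct_housekeeping. Ct values must
    be finite and positive; the reference group must be present.
    """

    data: pd.DataFrame
    reference_group: str

    def __post_init__(self) -> None:
        need = {"sample_id", "group", "ct_target", "ct_housekeeping"}
        missing = need - set(self.data.columns)
        if missing:
            raise TableValidationError(f"Ct table missing columns {sorted(missing)}")
        if self.reference_group not in set(self.data["group"]):
            raise TableValidationError(
                f"reference group {self.reference_group!r} absent from Ct table"
            )
        ct = self.data[["ct_target", "ct_housekeeping"]].to_numpy(float)
        bad = ~np.isfinite(ct) | (ct <= 0)
        if bad.any():
            rows = self.data.index[bad.any(axis=1)].tolist()
            raise TableValidationError(f"non-finite or non-positive Ct at rows {rows}")


def delta_delta_ct(cts: CtTable) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    dCt = Ct_target - Ct_housekeeping per sample; ddCt = dCt minus the
    arithmetic mean dCt of the reference group; fold change = 2^(-ddCt).
    The reference group's geometric-mean fold is 1 by construction.
    """
    df = cts.data.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_housekeeping"]
    ref_mean = df.loc[df["group"] == cts.reference_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - ref_mean
    df["fold_change"] = 2.0 ** (-df["delta_delta_ct"])
    return df[["sample_id", "group", "delta_ct", "delta_delta_ct", "fold_change"]]
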