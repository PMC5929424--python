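"""Manual IHC scoring and the statistical comparison battery.

The composite manual score averages two evaluators, each contributing a
percentage-positivity bin (0-4) plus a staining-intensity grade (0-3):

    final = [(p1 + i1) + (p2 + i2)] / 2,   range 0-7 in half-steps.

Group comparisons use one-way ANOVA with SPSS-style pairwise contrasts
(mean difference I-J, pooled standard error, adjusted p, 95% CI);
agreement between readouts uses Pearson's r and Lin's concordance
correlation coefficient; per-group normality uses Shapiro-Wilk; diagnostic
discrimination uses rank-based AUC with a Youden-optimal operating point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ManualScorePair",
    "percent_to_pscore",
    "intensity_to_iscore",
    "final_manual_score",
    "emulate_manual_score",
    "lin_ccc",
    "pearson_r",
    "oneway_anova_pairwise",
    "shapiro_wilk",
    "diagnostic_metrics",
    "AnovaReport",
    "RocReport",
]

#: Left-open percentage bins: a boundary value falls in the lower bin.
_PSCORE_EDGES = (10.0, 30.0, 50.0, 70.0)

#: Mean-intensity (0-255, dark-to-light) cuts emulating none/mild/
#: moderate/intense grades when deriving a manual-style score from DIA.
_ISCORE_CUTS = (220.0, 160.0, 110.0)


@dataclasses.dataclass(frozen=True)
class ManualScorePair:
    """Two evaluators' percentage (0-4) and intensity (0-3) scores."""

    p1: int
    i1: int
    p2: int
    i2: int

    def __post_init__(self) -> None:
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ValueError(f"{name} must be an integer in 0..4, got {v!r}")
        for name in ("i1", "i2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 3):
                raise ValueError(f"{name} must be an integer in 0..3, got {v!r}")


def percent_to_pscore(percent: float) -> int:
    """Bin percent positivity onto the 0-4 ordinal scale.

    0: <=10%, 1: >10-30%, 2: >30-50%, 3: >50-70%, 4: >70%.  Exact boundary
    values fall into the lower bin.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return int(sum(percent > e for e in _PSCORE_EDGES))


def intensity_to_iscore(mean_intensity: float) -> int:
    """Grade DAB mean intensity (0-255, dark = strong) as 0..3."""
    if not 0.0 <= mean_intensity <= 255.0:
        raise ValueError(f"mean_intensity must be in [0, 255], got {mean_intensity}")
    return int(sum(mean_intensity <= c for c in _ISCORE_CUTS))


def final_manual_score(pair: ManualScorePair) -> float:
    """Two-evaluator composite score: [(p1 + i1) + (p2 + i2)] / 2."""
    return ((pair.p1 + pair.i1) + (pair.p2 + pair.i2)) / 2.0


def emulate_manual_score(percent: float, mean_intensity: float) -> float:
    """Manual-style 0-7 score derived from DIA readouts.

    Both virtual evaluators see the same DIA numbers, so this is simply
    pscore + iscore; used to stage concordance experiments on synthetic
    cohorts where no human scores exist.
    """
    p = percent_to_pscore(percent)
    i = intensity_to_iscore(mean_intensity)
    return float(final_manual_score(ManualScorePair(p1=p, i1=i, p2=p, i2=i)))


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    return float(sps.pearsonr(x, y).statistic)


def lin_ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    rc = 2 cov(x,y) / (var(x) + var(y) + (mean x - mean y)^2), with
    n-denominator (biased) moments.  The confidence interval transforms rc
    through atanh and uses Lin's asymptotic variance of the transformed
    estimate.  Penalises location/scale shift as well as decorrelation, so
    |rc| <= |r| always.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError(
            "concordance undefined: both inputs are constant with equal means"
        )
    rc = 2.0 * sxy / denom
    if sx2 == 0.0 or sy2 == 0.0 or abs(rc) >= 1.0 - 1e-15:
        # degenerate or perfect agreement: no sampling variability to model
        return float(rc), (float(rc), float(rc))
    r = sxy / np.sqrt(sx2 * sy2)
    u2 = (mx - my) ** 2 / np.sqrt(sx2 * sy2)
    rc2 = rc**2
    if r == 0.0:
        se_z = 1.0 / np.sqrt(n - 2)
    else:
        var_z = (
            (1 - r**2) * rc2 / ((1 - rc2) * r**2)
            + 2 * rc**3 * (1 - rc) * u2 / (r * (1 - rc2) ** 2)
            - rc2**2 * u2**2 / (2 * r**2 * (1 - rc2) ** 2)
        ) / (n - 2)
        se_z = np.sqrt(max(var_z, 0.0))
    z = np.arctanh(rc)
    zc = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zc * se_z), np.tanh(z + zc * se_z)
    return float(rc), (float(lo), float(hi))


@dataclasses.dataclass(frozen=True)
class AnovaReport:
    """Overall F test plus SPSS-style pairwise contrasts."""

    parameter: str
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_i, group_j, mean_difference, std_error, p_adj, ci_low, ci_high
    adjustment: str


def oneway_anova_pairwise(
    table: pd.DataFrame,
    parameter: str,
    reference_group: str,
    group_col: str = "group",
    adjustment: str = "tukey",
    alpha: float = 0.05,
) -> AnovaReport:
    """One-way ANOVA with reference-vs-each pairwise comparisons.

    Pairwise rows report the mean difference I-J (I = reference), the
    pooled-variance standard error sqrt(MSE (1/ni + 1/nj)), an adjusted p
    and a 95% CI.  ``adjustment`` is ``"tukey"`` (Tukey-Kramer via the
    studentized range), ``"bonferroni"`` or ``"lsd"`` (unadjusted t).
    """
    if adjustment not in ("tukey", "bonferroni", "lsd"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = list(dict.fromkeys(table[group_col]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = {g: table.loc[table[group_col] == g, parameter].to_numpy(float) for g in groups}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n={v.size} < 2")
    f_stat, p_val = sps.f_oneway(*samples.values())

    k = len(groups)
    n_total = sum(v.size for v in samples.values())
    df_error = n_total - k
    grand_sse = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    mse = grand_sse / df_error

    rows = []
    others = [g for g in groups if g != reference_group]
    ref = samples[reference_group]
    for g in others:
        other = samples[g]
        diff = ref.mean() - other.mean()
        se = np.sqrt(mse * (1 / ref.size + 1 / other.size))
        if adjustment == "tukey":
            q = abs(diff) / np.sqrt(mse / 2 * (1 / ref.size + 1 / other.size))
            p_adj = float(sps.studentized_range.sf(q, k, df_error))
            q_crit = sps.studentized_range.ppf(1 - alpha, k, df_error)
            half = q_crit * np.sqrt(mse / 2 * (1 / ref.size + 1 / other.size))
        else:
            t = abs(diff) / se
            p_raw = 2 * sps.t.sf(t, df_error)
            m = k * (k - 1) / 2
            p_adj = float(min(p_raw * m, 1.0)) if adjustment == "bonferroni" else float(p_raw)
            a_eff = alpha / m if adjustment == "bonferroni" else alpha
            half = sps.t.ppf(1 - a_eff / 2, df_error) * se
        rows.append(
            {
                "group_i": reference_group,
                "group_j": g,
                "mean_difference": float(diff),
                "std_error": float(se),
                "p_adj": p_adj,
                "ci_low": float(diff - half),
                "ci_high": float(diff + half),
            }
        )
    return AnovaReport(
        parameter=parameter,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows),
        adjustment=adjustment,
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (delegates to the vetted SciPy routine)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(v) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class RocReport:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    proportion_misclassified: float


def diagnostic_metrics(
    scores,
    labels,
    threshold_rule: str = "youden",
) -> RocReport:
    """Rank-based AUC plus confusion-matrix metrics at the Youden point.

    ``labels`` are binary with 1 = disease-positive; higher scores are
    treated as more disease-like.  The AUC is the Mann-Whitney statistic
    with ties averaged.  The operating threshold maximises Youden's
    J = sensitivity + specificity - 1 over candidate thresholds (the
    observed score values), predicting positive when score >= threshold;
    ties in J resolve to the lower threshold.
    """
    if threshold_rule != "youden":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = sps.rankdata(s)  # average ranks on ties
    auc = (ranks[lab == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    best = None
    for thr in np.unique(s):  # ascending => lower threshold wins J ties
        pred = s >= thr
        tp = int(np.sum(pred & (lab == 1)))
        tn = int(np.sum(~pred & (lab == 0)))
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, tp, tn)
    _, thr, tp, tn = best
    fp, fn = n_neg - tn, n_pos - tp
    sens, spec = tp / n_pos, tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return RocReport(
        auc=float(auc),
        threshold=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        ppv=float(ppv),
        npv=float(npv),
        proportion_misclassified=float((fp + fn) / (n_pos + n_neg)),
    )
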