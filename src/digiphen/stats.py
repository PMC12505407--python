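"""Statistical pathway: questionnaire scoring, IQR outlier fences, Pearson
correlations, baseline group tests, 2x3 mixed-design ANOVA with Scheffe
post hoc and change-score Cohen's d, and noncentral-F power / sample-size
calculation for repeated-measures designs.

Conventions fixed here so results are reproducible: quartiles use linear
interpolation of order statistics; sphericity is assumed (integer
uncorrected dfs); DASS-21 subscales are raw 0-21 sums of their 7 items.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .synthetic import DASS_SUBSCALES

log = logging.getLogger(__name__)

ALPHA = 0.05

# ---------------------------------------------------------------------------
# Questionnaire scoring
# ---------------------------------------------------------------------------

#: instrument -> (item count, min response, max response)
_INSTRUMENT_SPECS = {
    "dass": (21, 0, 3),
    "self_efficacy": (22, 1, 5),
    "time_management": (30, 1, 5),
    "mauq": (21, 1, 7),
}

#: MAUQ subfactors: ease of use & satisfaction, information arrangement,
#: usefulness (item counts 8 / 6 / 7).
_MAUQ_SUBFACTORS = {
    "ease_of_use": range(0, 8),
    "arrangement": range(8, 14),
    "usefulness": range(14, 21),
}


def score_questionnaire(responses: Sequence[float], instrument: str) -> Dict[str, float]:
    """Score one participant-wave's item responses.

    DASS gives three raw 7-item subscale sums (0-21 each); self-efficacy
    and time-management give total sums; MAUQ gives the item mean plus
    subfactor means.
    """
    if instrument not in _INSTRUMENT_SPECS:
        raise ValidationError(f"unknown instrument {instrument!r}")
    n_items, lo, hi = _INSTRUMENT_SPECS[instrument]
    r = np.asarray(responses, dtype=float)
    if r.size != n_items:
        raise ValidationError(f"{instrument} expects {n_items} items, got {r.size}")
    if np.any(r < lo) or np.any(r > hi) or np.any(~np.isfinite(r)):
        raise ValidationError(f"{instrument} responses must lie in [{lo}, {hi}]")
    if instrument == "dass":
        return {
            f"dass_{sub}": float(r[list(idx)].sum()) for sub, idx in DASS_SUBSCALES.items()
        }
    if instrument == "mauq":
        out = {"mauq": float(r.mean())}
        out.update({k: float(r[list(v)].mean()) for k, v in _MAUQ_SUBFACTORS.items()})
        return out
    return {instrument: float(r.sum())}


def score_waves(items: pd.DataFrame) -> pd.DataFrame:
    """Score every (participant, wave) from the long item table.

    Returns one row per participant-wave with columns for each scored
    instrument present.
    """
    rows = []
    for (pid, group, wave, inst), g in items.groupby(
        ["participant_id", "group", "wave", "instrument"]
    ):
        vals = g.sort_values("item")["response"].to_numpy()
        scores = score_questionnaire(vals, inst)
        for name, val in scores.items():
            rows.append(
                {"participant_id": pid, "group": group, "wave": wave, "score": val, "outcome": name}
            )
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["participant_id", "group", "wave"], columns="outcome", values="score"
    ).reset_index()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# IQR outlier fences
# ---------------------------------------------------------------------------


def iqr_mask(values, multiplier: float = 1.5) -> np.ndarray:
    """Boolean mask of values inside the Tukey fences.

    Keeps x with Q1 - 1.5*IQR <= x <= Q3 + 1.5*IQR, quartiles by linear
    interpolation of order statistics. With fewer than 4 finite values the
    data pass through unfiltered (with a warning). NaNs are masked out.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 finite values: IQR filter passes data through")
        return finite
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    mask = finite & (v >= lo) & (v <= hi)
    n_out = int(finite.sum() - mask.sum())
    if n_out:
        log.info("IQR filter excluded %d of %d values (fences %.4g..%.4g)",
                 n_out, int(finite.sum()), lo, hi)
    return mask


def iqr_filter(values, multiplier: float = 1.5) -> np.ndarray:
    """Values kept by the Tukey-fence rule (excluded values are logged,
    never imputed)."""
    v = np.asarray(values, dtype=float)
    return v[iqr_mask(v, multiplier)]


# ---------------------------------------------------------------------------
# Correlations and simple group tests
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    feature: str = ""
    construct: str = ""

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.r)


def pearson_corr(x, y, *, feature: str = "", construct: str = "") -> CorrelationResult:
    """Product-moment correlation with two-sided p from the t transform
    (n-2 df). Zero variance in either variable gives the undefined
    sentinel (r = p = NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, feature, construct)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, feature, construct)


def independent_t(a, b) -> Tuple[float, int, float]:
    """Pooled-variance two-sample t test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


def mann_whitney_u(a, b) -> Tuple[float, float]:
    """Mann-Whitney U (reported as min(U1, U2)) with normal-approximation
    p including tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(res.pvalue)


# ---------------------------------------------------------------------------
# Mixed (split-plot) 2x3 ANOVA
# ---------------------------------------------------------------------------

WAVE_ORDER = ("baseline", "mid", "post")


def split_plot_ss(data: pd.DataFrame, dv: str = "score") -> Dict[str, float]:
    """Sum-of-squares partition for a group x time split-plot design.

    ``data`` is long with columns participant_id, group, wave, ``dv`` and
    complete waves per participant. Returns SS and df for the group, time,
    interaction, subject-within-group, and within-error strata.
    """
    y = data[dv].to_numpy(dtype=float)
    grand = y.mean()
    m = data["wave"].nunique()
    subj = data.groupby("participant_id")[dv].mean()
    n_subj = len(subj)
    groups = data.groupby("participant_id")["group"].first()
    group_sizes = groups.value_counts()
    g = len(group_sizes)

    ss_total = float(((y - grand) ** 2).sum())
    ss_subject = float(m * ((subj - grand) ** 2).sum())
    group_means = data.groupby("group")[dv].mean()
    ss_group = float(m * sum(group_sizes[gr] * (group_means[gr] - grand) ** 2 for gr in group_means.index))
    ss_subj_within = ss_subject - ss_group
    time_means = data.groupby("wave", observed=True)[dv].mean()
    ss_time = float(n_subj * ((time_means - grand) ** 2).sum())
    cell = data.groupby(["group", "wave"], observed=True)[dv].mean()
    ss_cells = float(
        sum(
            group_sizes[gr] * (cell[(gr, w)] - grand) ** 2
            for gr, w in cell.index
        )
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_subject - ss_time - ss_inter
    return {
        "ss_total": ss_total,
        "ss_group": ss_group,
        "ss_subj_within": ss_subj_within,
        "ss_time": ss_time,
        "ss_interaction": ss_inter,
        "ss_error_within": ss_error,
        "df_group": g - 1,
        "df_subj_within": n_subj - g,
        "df_time": m - 1,
        "df_interaction": (g - 1) * (m - 1),
        "df_error_within": (n_subj - g) * (m - 1),
    }


def scheffe_pairwise(
    means: Dict[str, float],
    ns: Dict[str, int],
    ms_error: float,
    df_error: int,
    k: int,
) -> pd.DataFrame:
    """Scheffe pairwise contrasts among ``k`` level means.

    A contrast is significant when its F exceeds (k-1) times the omnibus
    critical value, which guarantees no rejection unless the omnibus F is
    itself significant.
    """
    levels = list(means)
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            diff = means[a] - means[b]
            if ms_error <= 0:
                fc, p = 0.0, 1.0
            else:
                fc = diff**2 / (ms_error * (1.0 / ns[a] + 1.0 / ns[b]))
                p = float(sps.f.sf(fc / (k - 1), k - 1, df_error))
            rows.append(
                {"level_a": a, "level_b": b, "diff": diff, "F": fc, "p": p,
                 "significant": p < ALPHA}
            )
    return pd.DataFrame(rows)


def cohens_d_change(waves: pd.DataFrame, outcome: str) -> float:
    """Cohen's d on baseline-to-post change scores between groups:
    (mean change_intervention - mean change_control) / pooled change SD."""
    wide = waves.pivot_table(index=["participant_id", "group"], columns="wave", values=outcome)
    wide = wide.dropna(subset=["baseline", "post"]).reset_index()
    change = wide["post"] - wide["baseline"]
    ci = change[wide["group"] == "intervention"]
    cc = change[wide["group"] == "control"]
    n1, n2 = len(ci), len(cc)
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled = np.sqrt(((n1 - 1) * ci.var(ddof=1) + (n2 - 1) * cc.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return float((ci.mean() - cc.mean()) / pooled)


@dataclass
class AnovaResult:
    outcome: str
    table: pd.DataFrame  # effect, F, df1, df2, p
    posthoc: pd.DataFrame
    effect_size_d: float
    excluded_participants: Tuple[str, ...] = ()


def mixed_anova_2x3(waves: pd.DataFrame, outcome: str) -> AnovaResult:
    """2x3 mixed ANOVA (group between, wave within) for one outcome.

    Participants missing any wave are listwise-deleted (and logged).
    Sphericity is assumed, giving integer uncorrected dfs. Scheffe post
    hoc runs on each significant effect; Cohen's d is computed on
    baseline-to-post change scores.
    """
    data = waves[["participant_id", "group", "wave", outcome]].rename(columns={outcome: "score"})
    counts = data.dropna(subset=["score"]).groupby("participant_id")["wave"].nunique()
    complete = counts[counts == len(WAVE_ORDER)].index
    excluded = tuple(sorted(set(data["participant_id"]) - set(complete)))
    if excluded:
        log.warning("mixed ANOVA %s: excluding participants with missing waves: %s",
                    outcome, excluded)
    data = data[data["participant_id"].isin(complete)].dropna(subset=["score"])
    data["wave"] = pd.Categorical(data["wave"], categories=list(WAVE_ORDER), ordered=True)

    ss = split_plot_ss(data)
    if ss["ss_total"] < 1e-12:
        table = pd.DataFrame(
            [
                {"effect": "group", "F": 0.0, "df1": ss["df_group"], "df2": ss["df_subj_within"], "p": 1.0},
                {"effect": "time", "F": 0.0, "df1": ss["df_time"], "df2": ss["df_error_within"], "p": 1.0},
                {"effect": "time x group", "F": 0.0, "df1": ss["df_interaction"], "df2": ss["df_error_within"], "p": 1.0},
            ]
        )
        return AnovaResult(outcome, table, pd.DataFrame(), 0.0, excluded)

    aov = pg.mixed_anova(
        data=data, dv="score", within="wave", subject="participant_id", between="group"
    )
    aov = aov.set_index("Source")
    table = pd.DataFrame(
        [
            {
                "effect": "group",
                "F": float(aov.loc["group", "F"]),
                "df1": int(aov.loc["group", "DF1"]),
                "df2": int(aov.loc["group", "DF2"]),
                "p": float(aov.loc["group", "p_unc"]),
            },
            {
                "effect": "time",
                "F": float(aov.loc["wave", "F"]),
                "df1": int(aov.loc["wave", "DF1"]),
                "df2": int(aov.loc["wave", "DF2"]),
                "p": float(aov.loc["wave", "p_unc"]),
            },
            {
                "effect": "time x group",
                "F": float(aov.loc["Interaction", "F"]),
                "df1": int(aov.loc["Interaction", "DF1"]),
                "df2": int(aov.loc["Interaction", "DF2"]),
                "p": float(aov.loc["Interaction", "p_unc"]),
            },
        ]
    )

    posthoc_frames = []
    sig = table.set_index("effect")["p"] < ALPHA
    if sig.get("time", False):
        means = data.groupby("wave", observed=True)["score"].mean().to_dict()
        ns = data.groupby("wave", observed=True)["score"].size().to_dict()
        ph = scheffe_pairwise(
            means, ns, ss["ss_error_within"] / max(ss["df_error_within"], 1),
            ss["df_error_within"], k=len(WAVE_ORDER),
        )
        ph.insert(0, "effect", "time")
        posthoc_frames.append(ph)
    if sig.get("group", False):
        means = data.groupby("group")["score"].mean().to_dict()
        ns = data.groupby("group")["score"].size().to_dict()
        ph = scheffe_pairwise(
            means, ns, ss["ss_subj_within"] / max(ss["df_subj_within"], 1),
            ss["df_subj_within"], k=2,
        )
        ph.insert(0, "effect", "group")
        posthoc_frames.append(ph)
    posthoc = pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame()

    d = cohens_d_change(waves, outcome)
    return AnovaResult(outcome, table, posthoc, d, excluded)


# ---------------------------------------------------------------------------
# Power / sample size for the 2x3 repeated-measures design
# ---------------------------------------------------------------------------


def rm_anova_power(
    n_per_group: int,
    effect_size_f: float,
    *,
    alpha: float = 0.05,
    groups: int = 2,
    measures: int = 3,
    rho: float = 0.5,
    effect: str = "within",
) -> float:
    """Power of the mixed-design ANOVA for a given Cohen's f.

    ``effect`` selects the family: 'between' (group main effect), 'within'
    (time), or 'interaction'. The noncentrality uses the standard
    repeated-measures adjustment: between effects gain 1/(1+(m-1)rho),
    within/interaction effects gain 1/(1-rho).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if not 0 <= rho < 1:
        raise ValidationError("rho must be in [0, 1)")
    if effect_size_f < 0:
        raise ValidationError("effect size must be >= 0")
    n_total = n_per_group * groups
    if effect == "between":
        df1 = groups - 1
        df2 = n_total - groups
        lam = effect_size_f**2 * n_total * measures / (1 + (measures - 1) * rho)
    elif effect == "within":
        df1 = measures - 1
        df2 = (n_total - groups) * (measures - 1)
        lam = effect_size_f**2 * n_total * measures / (1 - rho)
    elif effect == "interaction":
        df1 = (groups - 1) * (measures - 1)
        df2 = (n_total - groups) * (measures - 1)
        lam = effect_size_f**2 * n_total * measures / (1 - rho)
    else:
        raise ValidationError(f"unknown effect family {effect!r}")
    if df2 < 1:
        return 0.0
    fcrit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def rm_power_sample_size(
    effect_size_f: float,
    *,
    alpha: float = 0.05,
    power: float = 0.80,
    groups: int = 2,
    measures: int = 3,
    rho: float = 0.5,
    effect: str = "within",
    n_max: int = 10_000,
) -> int:
    """Smallest per-group n whose noncentral-F power reaches the target."""
    if effect_size_f <= 0:
        raise ValidationError("effect size must be > 0 for a finite sample size")
    for n in range(2, n_max + 1):
        if rm_anova_power(
            n, effect_size_f, alpha=alpha, groups=groups, measures=measures,
            rho=rho, effect=effect,
        ) >= power:
            return n
    raise ValidationError(f"target power unattainable with n <= {n_max} per group")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default in
    the correlation grid)."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
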