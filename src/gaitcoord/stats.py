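"""Group-level statistics: outlier exclusion, ANOVA/ANCOVA, permutation SPM.

The factorial models pool participant x speed observations (no random
participant effect), matching the degrees-of-freedom pattern of the
original analysis; the repeated-measures caveat is documented.  The 1-D
statistical parametric mapping uses a label-permutation max-|t|
distribution for the family-wise critical threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SUMMARY_COLUMNS",
    "AnovaResult",
    "AnovaReport",
    "SpmResult",
    "iqr_exclude",
    "two_way_anova",
    "two_way_ancova",
    "spm_ttest2",
]

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "participant",
    "group",
    "speed",
    "marp_deg",
    "dp_deg",
    "hip_excursion_deg",
    "knee_excursion_deg",
    "walking_speed_mps",
    "n_cycles",
]


@dataclass
class AnovaResult:
    """One effect's F test with partial eta-squared effect size."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta2: float


@dataclass
class AnovaReport:
    """Effect table plus Bonferroni-adjusted pairwise post hocs."""

    response: str
    effects: list[AnovaResult]
    posthoc: pd.DataFrame
    alpha: float = 0.05

    def effect(self, name: str) -> AnovaResult:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    @property
    def interaction_significant(self) -> bool:
        return self.effect("group:speed").p < self.alpha


@dataclass
class SpmResult:
    """Pointwise group t-trace with permutation critical threshold.

    ``clusters`` lists (start, end) node indices (inclusive, 0-100% gait
    cycle) of maximal runs where |t| exceeds t*.
    """

    t: np.ndarray
    t_star: float
    clusters: list[tuple[int, int]]
    n_perm: int
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for a, b in self.clusters:
            if not np.all(np.abs(self.t[a : b + 1]) > self.t_star):
                raise ValueError("cluster contains sub-threshold nodes")


# ---------------------------------------------------------------------------
# Outlier exclusion
# ---------------------------------------------------------------------------

def iqr_exclude(
    summaries: pd.DataFrame,
    metrics: tuple[str, ...] = ("marp_deg", "dp_deg"),
    reference_speed: str = "preferred",
    k: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove participants outside the Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR).

    Fences are computed per group and per metric on the ``reference_speed``
    condition (linear-interpolation quartiles); a participant outside any
    fence (strict inequality) is dropped from *all* conditions.  Returns
    the retained summaries and an exclusion log.
    """
    ref = summaries[summaries["speed"] == reference_speed]
    excluded: list[dict] = []
    for group, gdf in ref.groupby("group"):
        if len(gdf) < 4:
            raise ValueError(f"group {group}: need >= 4 participants for fences, got {len(gdf)}")
        for metric in metrics:
            v = gdf[metric].to_numpy(dtype=float)
            q1, q3 = np.percentile(v, [25, 75])
            lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
            bad = gdf[(gdf[metric] < lo) | (gdf[metric] > hi)]
            for _, row in bad.iterrows():
                excluded.append(
                    {
                        "participant": row["participant"],
                        "group": group,
                        "metric": metric,
                        "value": row[metric],
                        "fence_lo": lo,
                        "fence_hi": hi,
                    }
                )
    exclusion_log = pd.DataFrame(
        excluded, columns=["participant", "group", "metric", "value", "fence_lo", "fence_hi"]
    )
    dropped = set(exclusion_log["participant"])
    retained = summaries[~summaries["participant"].isin(dropped)].reset_index(drop=True)
    if retained.empty:
        raise ValueError("IQR exclusion removed every participant")
    if dropped:
        log.info("IQR exclusion removed %d participant(s): %s", len(dropped), sorted(dropped))
    return retained, exclusion_log


# ---------------------------------------------------------------------------
# Factorial models
# ---------------------------------------------------------------------------

def _check_cells(df: pd.DataFrame) -> None:
    for group in df["group"].unique():
        for speed in df["speed"].unique():
            if ((df["group"] == group) & (df["speed"] == speed)).sum() == 0:
                raise ValueError(f"empty design cell: group={group}, speed={speed}")


def _effects_from_table(table: pd.DataFrame, rename: dict[str, str]) -> list[AnovaResult]:
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_den = int(table.loc["Residual", "df"])
    out = []
    for raw, name in rename.items():
        ss = float(table.loc[raw, "sum_sq"])
        out.append(
            AnovaResult(
                effect=name,
                F=float(table.loc[raw, "F"]),
                df_num=int(table.loc[raw, "df"]),
                df_den=df_den,
                p=float(table.loc[raw, "PR(>F)"]),
                partial_eta2=ss / (ss + ss_resid),
            )
        )
    return out


def _bonferroni_posthoc(df: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    """Pairwise independent-sample t tests across a factor's levels, pooled
    over the other factor, with Bonferroni-multiplied p-values."""
    levels = sorted(df[factor].unique())
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        va = df.loc[df[factor] == a, response]
        vb = df.loc[df[factor] == b, response]
        t, p = sps.ttest_ind(va, vb)
        rows.append(
            {
                "factor": factor,
                "level_a": a,
                "level_b": b,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "t": float(t),
                "p_bonferroni": min(float(p) * len(pairs), 1.0),
            }
        )
    return pd.DataFrame(rows)


def two_way_anova(summaries: pd.DataFrame, response: str, alpha: float = 0.05) -> AnovaReport:
    """Two-factor (group x speed) ANOVA on pooled observations.

    Type-II sums of squares; Bonferroni-adjusted pairwise post hocs are
    appended for each significant main effect.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    _check_cells(summaries)
    model = ols(f"{response} ~ C(group) * C(speed)", data=summaries).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = _effects_from_table(
        table,
        {"C(group)": "group", "C(speed)": "speed", "C(group):C(speed)": "group:speed"},
    )
    posthocs = []
    for eff, factor in (("group", "group"), ("speed", "speed")):
        res = next(e for e in effects if e.effect == eff)
        if res.p < alpha and summaries[factor].nunique() > 1:
            posthocs.append(_bonferroni_posthoc(summaries, response, factor))
    posthoc = (
        pd.concat(posthocs, ignore_index=True)
        if posthocs
        else pd.DataFrame(
            columns=["factor", "level_a", "level_b", "mean_a", "mean_b", "t", "p_bonferroni"]
        )
    )
    return AnovaReport(response, effects, posthoc, alpha)


def two_way_ancova(
    summaries: pd.DataFrame,
    response: str,
    covariate: str = "walking_speed_mps",
    alpha: float = 0.05,
) -> AnovaReport:
    """Two-factor ANCOVA: response ~ group * speed + covariate.

    The group x speed interaction is evaluated first; pairwise simple-effect
    post hocs are produced only when it is significant, mirroring the
    gated analysis strategy.  The covariate must vary within every cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    _check_cells(summaries)
    for (group, speed), cell in summaries.groupby(["group", "speed"]):
        if cell[covariate].std(ddof=0) == 0:
            raise ValueError(
                f"covariate {covariate} has zero variance in cell group={group}, speed={speed}"
            )
    model = ols(f"{response} ~ C(group) * C(speed) + {covariate}", data=summaries).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = _effects_from_table(
        table,
        {
            "C(group)": "group",
            "C(speed)": "speed",
            covariate: "covariate",
            "C(group):C(speed)": "group:speed",
        },
    )
    interaction = next(e for e in effects if e.effect == "group:speed")
    if interaction.p < alpha:
        posthoc = _bonferroni_posthoc(summaries, response, "speed")
    else:
        posthoc = pd.DataFrame(
            columns=["factor", "level_a", "level_b", "mean_a", "mean_b", "t", "p_bonferroni"]
        )
    return AnovaReport(response, effects, posthoc, alpha)


# ---------------------------------------------------------------------------
# 1-D statistical parametric mapping by permutation
# ---------------------------------------------------------------------------

_VAR_EPS = 1e-24  # pooled-variance floor for the zero-variance node rule


def _pointwise_t(x: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t at every node; is_a is a boolean mask."""
    a, b = x[is_a], x[~is_a]
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.maximum(sp2, _VAR_EPS) * (1.0 / na + 1.0 / nb))
    return (a.mean(axis=0) - b.mean(axis=0)) / denom


def spm_ttest2(
    waveforms_a: np.ndarray,
    waveforms_b: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> SpmResult:
    """Permutation SPM two-sample t-test over 101-node waveforms.

    A pooled-variance t statistic is computed at each node; the critical
    threshold t* is an order statistic of the max-|t| distribution over
    ``n_perm`` random label permutations plus the observed labelling (so
    the family-wise error is controlled at ``alpha`` exactly under
    exchangeability).  Supra-threshold clusters are maximal runs of nodes
    with |t| > t*.  Deterministic for a fixed ``rng``.
    """
    a = np.atleast_2d(np.asarray(waveforms_a, dtype=float))
    b = np.atleast_2d(np.asarray(waveforms_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("waveform node counts differ between groups")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 waveforms per group")
    if n_perm < 100:
        log.warning("n_perm=%d is low; the critical threshold will be coarse", n_perm)
    rng = rng if rng is not None else np.random.default_rng()

    x = np.vstack([a, b])
    x2 = x * x
    n, n_nodes = x.shape
    na, nb = a.shape[0], b.shape[0]

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:na] = True
    t_obs = _pointwise_t(x, obs_mask)

    # permutation max-|t| distribution, vectorised via group-A selection matrices
    sel = np.zeros((n_perm, n))
    for i in range(n_perm):
        sel[i, rng.permutation(n)[:na]] = 1.0
    tot, tot2 = x.sum(axis=0), x2.sum(axis=0)
    sum_a, sum2_a = sel @ x, sel @ x2
    mean_a = sum_a / na
    mean_b = (tot - sum_a) / nb
    var_a = (sum2_a - na * mean_a**2) / (na - 1)
    var_b = (tot2 - sum2_a - nb * mean_b**2) / (nb - 1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (n - 2)
    t_perm = (mean_a - mean_b) / np.sqrt(np.maximum(sp2, _VAR_EPS) * (1.0 / na + 1.0 / nb))
    maxima = np.concatenate([np.abs(t_perm).max(axis=1), [np.abs(t_obs).max()]])

    order = np.sort(maxima)
    idx = int(np.ceil((1.0 - alpha) * len(order))) - 1
    t_star = float(order[min(max(idx, 0), len(order) - 1)])

    supra = np.abs(t_obs) > t_star
    clusters: list[tuple[int, int]] = []
    i = 0
    while i < n_nodes:
        if supra[i]:
            j = i
            while j + 1 < n_nodes and supra[j + 1]:
                j += 1
            clusters.append((i, j))
            i = j + 1
        else:
            i += 1
    return SpmResult(t_obs, t_star, clusters, n_perm, alpha)
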