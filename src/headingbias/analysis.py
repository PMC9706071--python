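"""Statistical pipeline for heading-perception response tables.

Stages, in the order a study runs them:

1. **Center bias** — per participant and condition, OLS of perceived on
   actual heading (PH = s·AH + intercept); a one-sample t-test asks
   whether the participant slopes are smaller than 1.
2. **Distribution effects** — repeated-measures (or mixed) ANOVA of the
   per-participant cell means over distribution × heading, with a
   Greenhouse–Geisser correction for within factors with more than two
   levels; a contrast helper compares two conditions on their shared
   headings, the signature a central tendency would leave.
3. **Serial dependence** — per participant, the residual heading error
   (RHE) from that participant's own center-bias fit is regressed, at
   group level, on the relative heading RH = AH_prev − AH_cur; a
   negative slope s′ means responses are repelled from the previous
   heading. The CI is a participant-level nonparametric bootstrap.
4. **Bias decomposition** — how much of the mean perceived-heading
   difference between two distributions is attributable to serial
   dependence: per condition, the mean over realized trials of
   s′·RH, differenced across conditions and expressed as a percentage
   of the total bias difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "LinearFit",
    "SlopeTest",
    "AnovaEffect",
    "AnovaResult",
    "SerialDependenceResult",
    "DecompositionResult",
    "MeanBias",
    "fit_center_bias",
    "test_slopes_vs_one",
    "rm_anova",
    "central_tendency_contrast",
    "serial_dependence",
    "decompose_bias",
    "mean_ph_bias",
]

ALPHA = 0.05  # two-sided throughout


# ---------------------------------------------------------------- center bias


@dataclass
class LinearFit:
    """One participant-by-condition OLS fit of PH on AH."""

    participant_id: str
    condition: str
    slope: float
    intercept: float
    slope_se: float
    residuals: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SlopeTest:
    """One-sample t-test of participant slopes against 1."""

    n: int
    mean_slope: float
    se: float
    t: float
    p: float
    cohens_d: float

    @property
    def df(self) -> int:
        return self.n - 1


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Slope, intercept, slope SE and residuals of y = a + b·x."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    dof = n - 2
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else np.nan
    return slope, intercept, se, resid


def fit_center_bias(table: pd.DataFrame) -> list[LinearFit]:
    """Per-(participant, condition) OLS fit of ``ph_deg`` on ``ah_deg``."""
    fits = []
    for (pid, cond), block in table.groupby(["participant", "condition"], sort=True):
        x = block["ah_deg"].to_numpy(dtype=float)
        y = block["ph_deg"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(
                f"block (participant={pid!r}, condition={cond!r}) has a single "
                "heading level; the center-bias slope is undefined"
            )
        slope, intercept, se, resid = _ols(x, y)
        fits.append(LinearFit(str(pid), str(cond), slope, intercept, se, resid))
    return fits


def test_slopes_vs_one(fits: Sequence[LinearFit]) -> SlopeTest:
    """Two-sided one-sample t-test of the participant slopes against 1.

    Cohen's d is |mean − 1| divided by the between-participant SD.
    """
    slopes = np.array([f.slope for f in fits], dtype=float)
    n = slopes.size
    if n < 2:
        raise ValueError("need slopes from at least 2 participants")
    sd = slopes.std(ddof=1)
    se = sd / np.sqrt(n)
    mean = float(slopes.mean())
    if sd == 0:  # degenerate: all slopes identical
        t = 0.0 if mean == 1.0 else np.inf * np.sign(mean - 1.0)
        p = 1.0 if mean == 1.0 else 0.0
        d = 0.0
    else:
        res = stats.ttest_1samp(slopes, popmean=1.0)
        t, p = float(res.statistic), float(res.pvalue)
        d = abs(mean - 1.0) / sd
    return SlopeTest(
        n=n, mean_slope=mean, se=float(se), t=t, p=p, cohens_d=float(d)
    )


test_slopes_vs_one.__test__ = False  # not a pytest test, despite the name


# --------------------------------------------------------------------- ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float
    gg_epsilon: Optional[float] = None


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _cell_means(
    table: pd.DataFrame,
    within_factors: Sequence[str],
    dv: str,
    between: Optional[str] = None,
) -> pd.DataFrame:
    group_cols = ["participant", *([between] if between else []), *within_factors]
    cells = table.groupby(group_cols, as_index=False)[dv].mean()
    # balance: every participant must have every within-level combination
    levels = [sorted(table[f].unique()) for f in within_factors]
    full = pd.MultiIndex.from_product(
        [sorted(table["participant"].unique()), *levels],
        names=["participant", *within_factors],
    )
    have = pd.MultiIndex.from_frame(cells[["participant", *within_factors]])
    missing = full.difference(have)
    if len(missing) > 0:
        raise ValueError(
            f"missing cells (participant, {', '.join(within_factors)}): "
            f"{sorted(missing.tolist())[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    if between is not None:
        n_groups = cells.groupby("participant")[between].nunique()
        bad = n_groups[n_groups != 1]
        if len(bad):
            raise ValueError(
                f"participants in multiple {between!r} groups: {list(bad.index)[:10]}"
            )
    return cells


def rm_anova(
    table: pd.DataFrame,
    within: Sequence[str] | str,
    between: Optional[str] = None,
    dv: str = "ph_deg",
) -> AnovaResult:
    """Repeated-measures (or mixed) ANOVA on per-participant cell means.

    Within factors with more than two levels get Greenhouse–Geisser
    corrected p-values and degrees of freedom; the epsilon is reported.
    Effect size is partial eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    if between is None:
        cells = _cell_means(table, within, dv)
        with np.errstate(divide="ignore", invalid="ignore"):
            aov = pg.rm_anova(
                data=cells,
                dv=dv,
                within=within if len(within) > 1 else within[0],
                subject="participant",
                correction=True,
                detailed=True,
            )
        effects = []
        if "ddof1" in aov.columns:  # two-way within layout
            for _, row in aov.iterrows():
                F = float(row["F"])
                ss = float(row["SS"])
                df1, df2 = float(row["ddof1"]), float(row["ddof2"])
                if np.isfinite(F) and F > 0:
                    # SS_error recovered from F (MS_err = MS_eff / F)
                    np2 = ss / (ss + ss * df2 / (F * df1))
                else:
                    np2 = 1.0 if np.isinf(F) else 0.0
                effects.append(
                    _finalize_effect(
                        str(row["Source"]).replace(" * ", ":"),
                        F, df1, df2,
                        float(row["p_unc"]), float(row["p_GG_corr"]),
                        float(row["eps"]), np2,
                    )
                )
        else:  # one-way within layout: effect row + error row
            err = aov[aov["Source"] == "Error"].iloc[0]
            row = aov[aov["Source"] != "Error"].iloc[0]
            denom = float(row["SS"]) + float(err["SS"])
            np2 = float(row["SS"]) / denom if denom > 0 else 0.0
            effects = [
                _finalize_effect(
                    str(row["Source"]),
                    float(row["F"]), float(row["DF"]), float(err["DF"]),
                    float(row["p_unc"]),
                    float(row.get("p_GG_corr", np.nan)),
                    float(row.get("eps", np.nan)), np2,
                )
            ]
        return AnovaResult(tuple(effects))

    if len(within) != 1:
        raise ValueError("mixed design supports exactly one within factor")
    cells = _cell_means(table, within, dv, between=between)
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.mixed_anova(
            data=cells,
            dv=dv,
            within=within[0],
            subject="participant",
            between=between,
            correction=True,
        )
    effects = []
    for _, row in aov.iterrows():
        name = str(row["Source"])
        if name == "Interaction":
            name = f"{between}:{within[0]}"
        effects.append(
            _finalize_effect(
                name,
                float(row["F"]), float(row["DF1"]), float(row["DF2"]),
                float(row["p_unc"]), float(row.get("p_GG_corr", np.nan)),
                float(row.get("eps", np.nan)), float(row["np2"]),
            )
        )
    return AnovaResult(tuple(effects))


def _finalize_effect(
    name: str,
    F: float,
    df1: float,
    df2: float,
    p_unc: float,
    p_gg: float,
    eps: float,
    np2: float,
) -> AnovaEffect:
    """Assemble an effect row, handling degenerate zero-variance cases."""
    if np.isnan(F):  # 0/0: no effect variance and no error variance
        return AnovaEffect(name, 0.0, df1, df2, 1.0, 0.0, None)
    if np.isinf(F):  # perfect effect: zero error variance
        return AnovaEffect(name, F, df1, df2, 0.0, 1.0, None)
    use_gg = df1 > 1 and np.isfinite(eps) and np.isfinite(p_gg)
    return AnovaEffect(
        name=name,
        F=F,
        df1=df1 * (eps if use_gg else 1.0),
        df2=df2 * (eps if use_gg else 1.0),
        p=p_gg if use_gg else p_unc,
        eta_sq=np2,
        gg_epsilon=eps if use_gg else None,
    )


def central_tendency_contrast(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    shared_headings: Sequence[float],
) -> tuple[pd.Series, AnovaResult]:
    """Compare two conditions on their shared headings.

    Returns the per-heading difference in mean PH (b − a, participant
    means averaged) and the distribution main-effect ANOVA restricted to
    the shared headings: within-subject if the two tables share their
    participants, mixed (distribution as a between factor) otherwise.
    A central tendency toward a right-shifted distribution mean would
    show up as positive differences at headings below that mean.
    """
    shared = sorted(float(h) for h in shared_headings)
    if not shared:
        raise ValueError("shared_headings must be non-empty")
    parts = []
    for label, tab in (("a", table_a), ("b", table_b)):
        sub = tab[tab["ah_deg"].isin(shared)].copy()
        missing = set(shared) - set(sub["ah_deg"].unique())
        if missing:
            raise ValueError(f"table {label} lacks shared headings {sorted(missing)}")
        sub["distribution"] = label
        parts.append(sub)
    combined = pd.concat(parts, ignore_index=True)

    pm = combined.groupby(["distribution", "participant", "ah_deg"], as_index=False)[
        "ph_deg"
    ].mean()
    means = pm.groupby(["distribution", "ah_deg"])["ph_deg"].mean().unstack(0)
    diffs = (means["b"] - means["a"]).rename("ph_diff_deg")

    same_cohort = set(table_a["participant"]) == set(table_b["participant"])
    if same_cohort:
        aov = rm_anova(combined, within=["distribution", "ah_deg"])
    else:
        combined["participant"] = (
            combined["distribution"] + ":" + combined["participant"].astype(str)
        )
        aov = rm_anova(combined, within="ah_deg", between="distribution")
    return diffs, aov


# ---------------------------------------------------------- serial dependence


@dataclass
class SerialDependenceResult:
    """Group-level serial-dependence fit for one condition."""

    condition: str
    rh: np.ndarray = field(repr=False)  # pooled relative headings, deg
    rhe: np.ndarray = field(repr=False)  # pooled residual heading errors, deg
    sd_slope: float = np.nan  # s′
    ci95: tuple[float, float] = (np.nan, np.nan)
    participant_moments: np.ndarray = field(default=None, repr=False)


def _pooled_slope(moments: np.ndarray) -> float:
    """Pooled OLS slope from per-participant moment rows [n, Sx, Sy, Sxx, Sxy]."""
    n, sx, sy, sxx, sxy = moments.sum(axis=0)
    return (sxy - sx * sy / n) / (sxx - sx**2 / n)


def serial_dependence(
    table: pd.DataFrame,
    condition: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> SerialDependenceResult:
    """Serial-dependence slope s′ for one condition.

    Per participant the residual heading error RHE is taken from that
    participant's own PH-on-AH fit; RH is the previous trial's actual
    heading minus the current one (the block's first trial, having no
    predecessor, is excluded). s′ is the pooled group-level OLS slope of
    RHE on RH. The 95% CI is s′ ± t(0.975, n−1) times the SE from a
    participant-level nonparametric bootstrap; with ~20 participants
    this construction holds its nominal error rate, where the raw
    percentile interval is noticeably anticonservative.
    """
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(
            f"condition {condition!r} absent from table; available: "
            f"{sorted(table['condition'].unique())}"
        )
    rh_all, rhe_all, rows = [], [], []
    for pid, block in sub.groupby("participant", sort=True):
        block = block.sort_values("trial")
        ah = block["ah_deg"].to_numpy(dtype=float)
        ph = block["ph_deg"].to_numpy(dtype=float)
        if ah.size < 2:
            raise ValueError(f"participant {pid!r} block has < 2 trials")
        _, _, _, resid = _ols(ah, ph)
        rh = ah[:-1] - ah[1:]
        rhe = resid[1:]
        rh_all.append(rh)
        rhe_all.append(rhe)
        rows.append(
            [
                rh.size,
                rh.sum(),
                rhe.sum(),
                np.sum(rh**2),
                np.sum(rh * rhe),
            ]
        )
    moments = np.asarray(rows, dtype=float)
    slope = float(_pooled_slope(moments))

    rng = np.random.default_rng(seed)
    n_part = moments.shape[0]
    idx = rng.integers(0, n_part, size=(n_boot, n_part))
    boot_m = moments[idx].sum(axis=1)  # (n_boot, 5)
    n, sx, sy, sxx, sxy = boot_m.T
    boot_slopes = (sxy - sx * sy / n) / (sxx - sx**2 / n)
    half = stats.t.ppf(0.975, n_part - 1) * boot_slopes.std(ddof=1)
    return SerialDependenceResult(
        condition=condition,
        rh=np.concatenate(rh_all),
        rhe=np.concatenate(rhe_all),
        sd_slope=slope,
        ci95=(float(slope - half), float(slope + half)),
        participant_moments=moments,
    )


# --------------------------------------------------------- bias decomposition


@dataclass(frozen=True)
class DecompositionResult:
    """Share of a between-distribution bias explained by serial dependence."""

    sd_induced_bias_per_condition: Mapping[str, float]
    sd_induced_difference: float
    total_bias_difference: float
    fraction_pct: float


def decompose_bias(
    sd_results: Mapping[str, SerialDependenceResult],
    tables: Optional[Mapping[str, pd.DataFrame]],
    total_bias_difference: float,
    conditions: Optional[tuple[str, str]] = None,
) -> DecompositionResult:
    """Serial-dependence share of the bias difference between two conditions.

    Per condition the serial-dependence-induced bias is the mean over
    realized trials of s′·RH on that condition's schedules. The induced
    difference is second condition minus first (pass ``conditions`` as
    (reference, shifted)); the fraction is that difference as a
    percentage of ``total_bias_difference``.
    """
    if conditions is None:
        conditions = tuple(sd_results)
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    if total_bias_difference == 0:
        raise ValueError(
            "total_bias_difference is 0; the serial-dependence fraction is undefined"
        )
    induced = {
        c: float(sd_results[c].sd_slope * np.mean(sd_results[c].rh))
        for c in conditions
    }
    diff = induced[conditions[1]] - induced[conditions[0]]
    return DecompositionResult(
        sd_induced_bias_per_condition=induced,
        sd_induced_difference=diff,
        total_bias_difference=float(total_bias_difference),
        fraction_pct=100.0 * diff / float(total_bias_difference),
    )


@dataclass(frozen=True)
class MeanBias:
    """Grand-mean perceived-heading bias with bootstrap CI."""

    condition: str
    value: float
    ci95: tuple[float, float]
    n: int


def mean_ph_bias(
    table: pd.DataFrame,
    condition: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MeanBias:
    """Grand mean PH for a condition, with a participant-level
    percentile-bootstrap 95% CI.

    Per participant, PH is first averaged within each heading and then
    across headings (unweighted), so that a nonuniform trial allocation
    does not drag the mean toward its dense headings; participant means
    are then averaged. For a symmetric design this is the mean heading
    bias, and a constant response shift is recovered as-is.
    """
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(
            f"condition {condition!r} absent from table; available: "
            f"{sorted(table['condition'].unique())}"
        )
    pmeans = (
        sub.groupby(["participant", "ah_deg"])["ph_deg"]
        .mean()
        .groupby("participant")
        .mean()
        .to_numpy()
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pmeans.size, size=(n_boot, pmeans.size))
    lo, hi = np.percentile(pmeans[idx].mean(axis=1), [2.5, 97.5])
    return MeanBias(
        condition=condition,
        value=float(pmeans.mean()),
        ci95=(float(lo), float(hi)),
        n=pmeans.size,
    )
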