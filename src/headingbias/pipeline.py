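"""End-to-end orchestration: simulate a cohort, run every analysis, report.

A run emulates one of the three study designs (or a custom one):

* ``exp1`` — symmetric wide uniform (±3..±33°, 600 trials) vs.
  right-shifted narrow uniform (3..33°, 300 trials), same cohort.
* ``exp2`` — symmetric narrow (±15°) vs. left-shifted narrow (−33..−3°).
* ``exp3`` — symmetric uniform vs. right-heavied nonuniform (both 600
  trials); the nonuniform block carries, by default, a leftward response
  shift and a repulsive serial-dependence coefficient, the pattern the
  analyses are designed to detect and decompose.

Outputs: ``data.csv`` (the simulated response table), ``results.json``
(every statistic), per-figure CSVs plus PNG figures (PH vs AH per
condition; RHE vs RH with the fitted line), and ``manifest.json``
recording config, seeds and library versions. Figures are artifacts;
every number behind a figure is also in a CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis as an
from .design import make_distribution
from .synthetic import COLUMNS, ObserverParams, simulate_cohort

__all__ = ["RunConfig", "EXPERIMENTS", "run_pipeline", "validate_table"]

log = logging.getLogger("headingbias")

#: block presets per experiment, in (reference, shifted) order
EXPERIMENTS: dict[str, tuple[str, str]] = {
    "exp1": ("symmetric_wide_uniform", "right_shifted_narrow_uniform"),
    "exp2": ("symmetric_narrow_uniform", "left_shifted_narrow_uniform"),
    "exp3": ("symmetric_uniform_exp3", "right_heavied_nonuniform"),
}

#: study-condition observer defaults: center-bias slope ~0.8 (the value
#: typical of heading-report experiments), 3° response noise, modest
#: between-participant slope spread; the exp3 nonuniform block adds a
#: −2° shift and a repulsive serial-dependence coefficient of −0.01.
DEFAULT_OBSERVER = ObserverParams(slope_s=0.8, noise_sigma=3.0)
DEFAULT_SLOPE_SD = 0.15
EXP3_NONUNIFORM_OBSERVER = ObserverParams(
    slope_s=0.8, noise_sigma=3.0, shift_delta=-2.0, sd_coef=-0.01
)


def default_observer_params(experiment: str) -> "ObserverParams | dict[str, ObserverParams]":
    """Per-condition observer defaults for a named experiment."""
    if experiment == "exp3":
        ref, shifted = EXPERIMENTS["exp3"]
        return {ref: DEFAULT_OBSERVER, shifted: EXP3_NONUNIFORM_OBSERVER}
    return DEFAULT_OBSERVER


@dataclass
class RunConfig:
    """Configuration of one simulate-and-analyze run."""

    experiment: str = "exp1"
    seed: int = 0
    n_participants: int = 20
    observer: "ObserverParams | dict[str, ObserverParams] | None" = None
    slope_sd: float = DEFAULT_SLOPE_SD
    n_boot: int = 10_000
    output_dir: Path = Path("headingbias_run")
    presets: Optional[tuple[str, str]] = None  # required for experiment="custom"

    def conditions(self) -> tuple[str, str]:
        if self.experiment == "custom":
            if not self.presets or len(self.presets) != 2:
                raise ValueError("custom experiment requires exactly two presets")
            return tuple(self.presets)
        try:
            return EXPERIMENTS[self.experiment]
        except KeyError:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid: "
                f"{', '.join(EXPERIMENTS)} or 'custom'"
            ) from None

    def observer_params(self):
        if self.observer is not None:
            return self.observer
        return default_observer_params(self.experiment)


def _params_dict(p) -> dict:
    if isinstance(p, ObserverParams):
        return dataclasses.asdict(p)
    return {k: dataclasses.asdict(v) for k, v in p.items()}


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulate → analyze → report pipeline.

    Returns the results dictionary that is also written to
    ``results.json``. Any stage failure raises with the stage name;
    artifacts written before the failure are kept.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cond_ref, cond_shift = config.conditions()
    stage = "simulate"
    try:
        table = simulate_cohort(
            [cond_ref, cond_shift],
            config.n_participants,
            config.observer_params(),
            seed=config.seed,
            slope_sd=config.slope_sd,
        )
        table.to_csv(out / "data.csv", index=False)
        log.info("simulate: %d rows, seed=%d", len(table), config.seed)

        results: dict = {"experiment": config.experiment, "conditions": [cond_ref, cond_shift]}

        stage = "center_bias"
        fits = an.fit_center_bias(table)
        results["center_bias"] = {}
        for cond in (cond_ref, cond_shift):
            test = an.test_slopes_vs_one([f for f in fits if f.condition == cond])
            results["center_bias"][cond] = {
                "mean_slope": test.mean_slope,
                "se": test.se,
                "t": test.t,
                "df": test.df,
                "p": test.p,
                "cohens_d": test.cohens_d,
            }
            log.info("center_bias[%s]: slope=%.3f t=%.2f", cond, test.mean_slope, test.t)

        stage = "distribution_anova"
        ref_h = set(make_distribution(cond_ref).headings)
        shift_h = set(make_distribution(cond_shift).headings)
        shared = sorted(ref_h & shift_h)
        diffs, aov = an.central_tendency_contrast(
            table[table["condition"] == cond_ref],
            table[table["condition"] == cond_shift],
            shared,
        )
        results["distribution_anova"] = {
            "shared_headings": shared,
            "per_heading_ph_difference": diffs.to_dict(),
            "effects": [dataclasses.asdict(e) for e in aov.effects],
        }

        stage = "serial_dependence"
        sd = {}
        results["serial_dependence"] = {}
        for cond in (cond_ref, cond_shift):
            r = an.serial_dependence(
                table, cond, n_boot=config.n_boot, seed=config.seed + 1
            )
            sd[cond] = r
            results["serial_dependence"][cond] = {
                "sd_slope": r.sd_slope,
                "ci95": list(r.ci95),
                "n_trials": int(r.rh.size),
            }
            log.info("serial_dependence[%s]: s'=%.4f", cond, r.sd_slope)

        stage = "bias_decomposition"
        biases = {
            cond: an.mean_ph_bias(
                table, cond, n_boot=config.n_boot, seed=config.seed + 2
            )
            for cond in (cond_ref, cond_shift)
        }
        results["mean_ph_bias"] = {
            c: {"value": b.value, "ci95": list(b.ci95)} for c, b in biases.items()
        }
        total = biases[cond_shift].value - biases[cond_ref].value
        if total != 0:
            dec = an.decompose_bias(sd, None, total, conditions=(cond_ref, cond_shift))
            results["decomposition"] = {
                "sd_induced_bias_per_condition": dict(dec.sd_induced_bias_per_condition),
                "sd_induced_difference": dec.sd_induced_difference,
                "total_bias_difference": dec.total_bias_difference,
                "fraction_pct": dec.fraction_pct,
            }

        stage = "figures"
        _write_figures(table, sd, out)

        stage = "report"
        results = _jsonable(results)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
            fh.write("\n")
        manifest = {
            "config": {
                "experiment": config.experiment,
                "seed": config.seed,
                "n_participants": config.n_participants,
                "slope_sd": config.slope_sd,
                "n_boot": config.n_boot,
                "presets": list(config.conditions()),
                "observer": _params_dict(config.observer_params()),
            },
            "versions": _versions(),
            "rows": int(len(table)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2)
            fh.write("\n")
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _versions() -> dict:
    import matplotlib
    import pingouin
    import scipy

    from . import __version__

    return {
        "headingbias": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "pingouin": pingouin.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _write_figures(table: pd.DataFrame, sd: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # PH vs AH: participant means per heading, then mean ± SE across cohort
    pm = table.groupby(["condition", "participant", "ah_deg"], as_index=False)[
        "ph_deg"
    ].mean()
    summ = (
        pm.groupby(["condition", "ah_deg"])["ph_deg"]
        .agg(mean_ph="mean", se_ph=lambda s: s.std(ddof=1) / np.sqrt(s.size))
        .reset_index()
    )
    summ.to_csv(out / "ph_vs_ah.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in summ.groupby("condition"):
        ax.errorbar(
            grp["ah_deg"], grp["mean_ph"], yerr=grp["se_ph"], marker="o", label=cond
        )
    lim = summ["ah_deg"].abs().max() * 1.1
    ax.plot([-lim, lim], [-lim, lim], ls="--", c="gray", lw=0.8)
    ax.axhline(0, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("actual heading (deg)")
    ax.set_ylabel("perceived heading (deg)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "ph_vs_ah.png", dpi=150)
    plt.close(fig)

    # RHE vs RH, binned means with the group-level fitted line
    rows = []
    fig, axes = plt.subplots(1, len(sd), figsize=(5 * len(sd), 4), squeeze=False)
    for ax, (cond, r) in zip(axes[0], sd.items()):
        bins = np.unique(r.rh)
        if bins.size > 25:
            bins = np.linspace(r.rh.min(), r.rh.max(), 25)
            which = np.digitize(r.rh, bins)
        else:
            which = np.searchsorted(bins, r.rh)
        for b in np.unique(which):
            m = which == b
            rows.append(
                {
                    "condition": cond,
                    "rh_deg": float(r.rh[m].mean()),
                    "mean_rhe_deg": float(r.rhe[m].mean()),
                    "n": int(m.sum()),
                }
            )
        sub = [row for row in rows if row["condition"] == cond]
        ax.plot(
            [row["rh_deg"] for row in sub],
            [row["mean_rhe_deg"] for row in sub],
            "o",
            ms=4,
        )
        xx = np.array([r.rh.min(), r.rh.max()])
        ax.plot(xx, r.sd_slope * (xx - r.rh.mean()) + r.rhe.mean(), "r-")
        ax.axhline(0, ls="--", c="gray", lw=0.8)
        ax.set_title(f"{cond}\ns' = {r.sd_slope:.4f}")
        ax.set_xlabel("relative heading (deg)")
        ax.set_ylabel("residual heading error (deg)")
    pd.DataFrame(rows).to_csv(out / "rhe_vs_rh.csv", index=False)
    fig.tight_layout()
    fig.savefig(out / "rhe_vs_rh.png", dpi=150)
    plt.close(fig)


def validate_table(path) -> tuple[Optional[pd.DataFrame], list[str]]:
    """Schema-check a response-table CSV.

    Returns ``(table, violations)``: the parsed table (None if
    unreadable or missing columns) and a complete list of violations.
    """
    violations: list[str] = []
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        return None, [f"unreadable CSV: {exc}"]
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        return None, [f"missing column: {c}" for c in missing]
    for col in ("ah_deg", "ph_deg"):
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if bad.any():
            violations.append(
                f"non-numeric values in {col}: rows {table.index[bad].tolist()[:5]}"
            )
    dup = table.duplicated(subset=["participant", "condition", "trial"], keep=False)
    if dup.any():
        keys = (
            table.loc[dup, ["participant", "condition", "trial"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        violations.append(f"duplicated (participant, condition, trial) keys: {sorted(keys)[:10]}")
    else:
        for (pid, cond), block in table.groupby(["participant", "condition"]):
            t = np.sort(block["trial"].to_numpy())
            if not np.array_equal(t, np.arange(1, len(t) + 1)):
                violations.append(
                    f"trial indices not consecutive from 1 in block ({pid!r}, {cond!r})"
                )
    return (table if not violations else None), violations
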