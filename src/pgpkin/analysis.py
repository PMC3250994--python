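"""Subject-level SUV quantification, group statistics, and the cohort pipeline.

This layer turns fitted rate constants and raw curves into the study-level
outputs: standardized uptake values (SUV = A/(ID/BW), g/mL), brain-to-blood
ratios, one-way ANOVA with Bonferroni-corrected pairwise comparisons across
the WT-saline / WT-cyclo / KO groups, the direct+indirect input-function
validation, and :func:`run_pipeline`, which reproduces the whole analysis
on a synthetic cohort (simulate -> extract -> correct -> fit full and 2-min
windows -> SUV -> statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reference
from .curves import FrameSchedule
from .input_function import (
    auc_percent_difference,
    build_input_function,
    correct_dispersion,
    k1k2_error_percent,
)
from .kinetics import CompartmentModel, FitOptions, KineticFitResults
from .synthetic import (
    BolusInputParams,
    SubjectRecord,
    default_bolus,
    make_cohort,
    simulate_subject,
)

__all__ = [
    "SuvCurve",
    "RatioCurve",
    "GroupComparison",
    "PipelineConfig",
    "CohortReport",
    "suv",
    "brain_to_blood_ratio",
    "group_stats",
    "validate_input_function",
    "run_pipeline",
]


@dataclass(frozen=True)
class SuvCurve:
    """Standardized uptake values per frame (g/mL) for one region."""

    schedule: FrameSchedule
    values: np.ndarray
    region: str = "brain"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.schedule),):
            raise ValueError("SUV values must match the schedule length")
        if np.any(v < 0):
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", v)

    def time_weighted_mean(self) -> float:
        d = self.schedule.durations_s
        return float(np.sum(self.values * d) / np.sum(d))


@dataclass(frozen=True)
class RatioCurve:
    """Pointwise brain/blood SUV ratio; zero-blood frames are flagged missing."""

    schedule: FrameSchedule
    values: np.ndarray  # NaN where missing
    missing: np.ndarray  # boolean

    def time_weighted_mean(self) -> float:
        ok = ~self.missing
        d = self.schedule.durations_s[ok]
        return float(np.sum(self.values[ok] * d) / np.sum(d))


def suv(tac, injected_dose_kBq: float, body_weight_g: float, region: str = "brain") -> SuvCurve:
    """SUV = A/(ID/BW): activity concentration normalised to dose per gram.

    With A in kBq/cc, ID in kBq and BW in g the result carries g/mL.
    """
    if injected_dose_kBq <= 0 or body_weight_g <= 0:
        raise ValueError("injected dose and body weight must be positive")
    return SuvCurve(
        schedule=tac.schedule,
        values=tac.values / (injected_dose_kBq / body_weight_g),
        region=region,
    )


def brain_to_blood_ratio(brain: SuvCurve, lv: SuvCurve) -> RatioCurve:
    """Pointwise SUV_brain / SUV_blood; ID and BW cancel algebraically."""
    if len(brain.schedule) != len(lv.schedule) or not np.allclose(
        brain.schedule.start_s, lv.schedule.start_s
    ):
        raise ValueError("brain and blood curves must share an identical framing")
    missing = lv.values == 0.0
    values = np.full(len(brain.schedule), np.nan)
    np.divide(brain.values, lv.values, out=values, where=~missing)
    return RatioCurve(schedule=brain.schedule, values=values, missing=missing)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with pooled-variance Bonferroni pairwise t-tests.

    The pairwise tests reuse the ANOVA error term MS_within with its
    pooled degrees of freedom (SPSS-style post hoc), and raw p-values are
    multiplied by the number of pairs (capped at 1).
    """

    outcome: str
    group_stats: dict[str, tuple[float, float, int]]  # name -> (mean, sd, n)
    f_statistic: float
    p_omnibus: float
    pairwise: dict[tuple[str, str], dict]
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, d in self.pairwise.items() if d["p_adjusted"] < self.alpha]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "groups": {
                name: {"mean": m, "sd": s, "n": n}
                for name, (m, s, n) in self.group_stats.items()
            },
            "F": self.f_statistic,
            "p_omnibus": self.p_omnibus,
            "p_omnibus_rounded": round(self.p_omnibus, 3),
            "pairwise": {
                f"{a} vs {b}": {**d, "p_adjusted_rounded": round(d["p_adjusted"], 3)}
                for (a, b), d in self.pairwise.items()
            },
            "alpha": self.alpha,
        }

    def summary(self) -> str:
        lines = [f"{self.outcome}: one-way ANOVA F = {self.f_statistic:.3f}, "
                 f"p = {self.p_omnibus:.3f}"]
        for name, (m, s, n) in self.group_stats.items():
            lines.append(f"  {name:<10} {m:8.3f} +/- {s:.3f}  (n={n})")
        for (a, b), d in self.pairwise.items():
            star = " *" if d["p_adjusted"] < self.alpha else ""
            lines.append(
                f"  {a} vs {b}: t = {d['t']:.3f}, raw p = {d['p_raw']:.4f}, "
                f"Bonferroni p = {d['p_adjusted']:.3f}{star}"
            )
        return "\n".join(lines)


def group_stats(
    values_by_group: Mapping[str, Sequence[float]],
    outcome: str = "outcome",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA plus Bonferroni post hoc tests across groups.

    Pairwise two-sided t statistics use the pooled within-group mean
    square with N - k degrees of freedom; adjusted p = min(1, raw x
    number of pairs).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2, has {arr.size}")
    n_total = sum(a.size for a in arrays.values())
    k = len(names)
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance everywhere: F is undefined")
    ms_within = ss_within / df_w
    f_stat = (ss_between / df_b) / ms_within
    p_omni = float(sps.f.sf(f_stat, df_b, df_w))

    pairs = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    pairwise = {}
    for a, b in pairs:
        xa, xb = arrays[a], arrays[b]
        se = np.sqrt(ms_within * (1.0 / xa.size + 1.0 / xb.size))
        t = (xa.mean() - xb.mean()) / se
        p_raw = float(2.0 * sps.t.sf(abs(t), df_w))
        pairwise[(a, b)] = {
            "t": float(t),
            "df": df_w,
            "p_raw": p_raw,
            "p_adjusted": min(1.0, p_raw * len(pairs)),
        }
    stats_by_group = {
        g: (float(a.mean()), float(a.std(ddof=1)), int(a.size)) for g, a in arrays.items()
    }
    return GroupComparison(
        outcome=outcome,
        group_stats=stats_by_group,
        f_statistic=float(f_stat),
        p_omnibus=p_omni,
        pairwise=pairwise,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# input-function validation (direct + indirect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputFunctionValidation:
    """Direct (AUC) and indirect (K1/k2) agreement between the two routes."""

    auc_percent_difference: float
    k1k2_error_percent: float
    fit_image: KineticFitResults
    fit_counter: KineticFitResults
    compared_on: str = "whole-blood (dispersion-corrected counter vs image ROI)"

    def to_dict(self) -> dict:
        return {
            "auc_percent_difference": self.auc_percent_difference,
            "k1k2_error_percent": self.k1k2_error_percent,
            "k1k2_image": self.fit_image.k1_k2,
            "k1k2_counter": self.fit_counter.k1_k2,
            "compared_on": self.compared_on,
        }


def validate_input_function(
    subject: SubjectRecord,
    tau_disp_s: float = reference.TAU_DISP_S,
    plasma_ratio: float = reference.PLASMA_WB_RATIO,
    model: str = "1tc",
    options: FitOptions | None = None,
    apply_dispersion_correction: bool = True,
) -> InputFunctionValidation:
    """Compare image-derived and blood-counter input functions on one subject.

    Direct: percent AUC difference between the left-ventricle TAC and the
    (optionally dispersion-corrected) counter trace, at the whole-blood
    level.  Indirect: the brain curve is fitted once with each input and
    the percent error of the resulting K1/k2 ratios is reported.
    """
    if subject.lv_tac is None or subject.counter_tac is None or subject.brain_tac is None:
        raise ValueError("subject must carry LV, counter and brain curves")
    tau = tau_disp_s if apply_dispersion_correction else 0.0
    counter_wb = (
        correct_dispersion(subject.counter_tac, tau) if tau > 0 else subject.counter_tac
    )
    auc_diff = auc_percent_difference(subject.lv_tac, counter_wb)

    kwargs = dict(plasma_ratio=plasma_ratio, parent_fraction=subject.parent_fraction)
    input_image = build_input_function(subject.lv_tac, tau_disp_s=None, **kwargs)
    input_counter = build_input_function(
        subject.counter_tac, tau_disp_s=tau if tau > 0 else None, **kwargs
    )
    fit_image = CompartmentModel(
        subject.brain_tac, input_image, input_image, model=model, options=options
    ).fit()
    fit_counter = CompartmentModel(
        subject.brain_tac, input_counter, input_counter, model=model, options=options
    ).fit()
    return InputFunctionValidation(
        auc_percent_difference=auc_diff,
        k1k2_error_percent=k1k2_error_percent(fit_image, fit_counter),
        fit_image=fit_image,
        fit_counter=fit_counter,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the synthetic-cohort analysis run."""

    n_per_group: int = 3
    groups: tuple[str, ...] = reference.GROUPS
    spread: float = 0.15
    noise_scale: float = 0.0
    seed: int = 0
    tau_disp_s: float = reference.TAU_DISP_S
    plasma_ratio: float = reference.PLASMA_WB_RATIO
    models: tuple[str, ...] = ("1tc", "2tc")
    window_s: float = 120.0  # the short-window refit, alongside the full fit
    multistart: int = 5
    weighting: str = "frame-duration"
    outcomes: tuple[str, ...] = ("K1", "k2", "K1_k2")
    bolus: BolusInputParams = field(default_factory=default_bolus)

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "PipelineConfig":
        flat: dict = {}
        for section in ("cohort", "corrections", "fitting", "stats", "output"):
            flat.update(cfg.get(section, {}) if isinstance(cfg.get(section), Mapping) else {})
        flat.update({k: v for k, v in cfg.items() if not isinstance(v, Mapping)})
        kwargs = {}
        for name in (
            "n_per_group", "spread", "noise_scale", "seed", "tau_disp_s",
            "plasma_ratio", "window_s", "multistart", "weighting",
        ):
            if name in flat:
                kwargs[name] = flat[name]
        for name in ("groups", "models", "outcomes"):
            if name in flat:
                kwargs[name] = tuple(flat[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class CohortReport:
    """Results of one pipeline run: per-subject table, statistics, log."""

    results: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    subjects: list[SubjectRecord]
    config: PipelineConfig
    log: list[str]

    def save(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "results": directory / "results.csv",
            "stats": directory / "stats.json",
            "log": directory / "run_log.txt",
        }
        self.results.to_csv(paths["results"], index=False)
        paths["stats"].write_text(
            json.dumps({k: v.to_dict() for k, v in self.comparisons.items()}, indent=2)
        )
        paths["log"].write_text("\n".join(self.log) + "\n")
        return paths

    def summary(self) -> str:
        lines = ["Cohort report", self.results.to_string(index=False), ""]
        for comp in self.comparisons.values():
            lines.append(comp.summary())
            lines.append("")
        return "\n".join(lines)

    def plot(self, outcome: str = "K1_k2", window: str = "full", ax=None):
        """Per-subject outcome values by group (strip plot with group means)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        col = {"K1": "K1_ml_cc_min", "k2": "k2_per_min"}.get(outcome, outcome)
        sub = self.results[self.results["window"] == window]
        for i, group in enumerate(self.config.groups):
            vals = sub.loc[sub["group"] == group, col]
            ax.plot([i] * len(vals), vals, "o", alpha=0.7)
            ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k")
        ax.set_xticks(range(len(self.config.groups)), self.config.groups)
        ax.set_ylabel(outcome)
        ax.set_title(f"{outcome} ({window} window)")
        return ax


def _fit_subject(rec: SubjectRecord, cfg: PipelineConfig) -> None:
    opts = FitOptions(weighting=cfg.weighting, multistart=cfg.multistart, seed=rec.seed)
    input_fn = build_input_function(
        rec.lv_tac,
        tau_disp_s=None,  # image route: no catheter, no dispersion
        plasma_ratio=cfg.plasma_ratio,
        parent_fraction=rec.parent_fraction,
    )
    wb = build_input_function(rec.lv_tac, plasma_ratio=1.0)  # whole blood, fine grid
    for model in cfg.models:
        rec.fits[(model, "full")] = CompartmentModel(
            rec.brain_tac, input_fn, wb, model=model, options=opts
        ).fit()
    rec.fits[("1tc", "window")] = CompartmentModel(
        rec.brain_tac, input_fn, wb, model="1tc", t_max_s=cfg.window_s, options=opts
    ).fit()


def _outcome_value(fit: KineticFitResults, outcome: str) -> float:
    if outcome == "K1_k2":
        return fit.k1_k2
    if outcome in ("K1", "k2", "k3", "k4", "vB"):
        return getattr(fit.params, outcome)
    raise KeyError(f"unknown outcome {outcome!r}")


def run_pipeline(config: PipelineConfig | Mapping | None = None, out_dir=None) -> CohortReport:
    """Simulate a cohort and run the full quantification chain on it.

    Stages per subject: curve simulation, input-function construction
    from the left-ventricle TAC, one- and two-tissue fits over the full
    30 min, a one-tissue refit on the first 2 min, and SUV / brain-to-
    blood summaries.  Group statistics (ANOVA + Bonferroni) run per
    outcome and per window.  Identical config and seed give identical
    reports.
    """
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig.from_mapping(config)

    log = [
        f"pgpkin pipeline: n_per_group={cfg.n_per_group} groups={list(cfg.groups)}",
        f"seed={cfg.seed} spread={cfg.spread} noise_scale={cfg.noise_scale}",
        f"tau_disp_s={cfg.tau_disp_s} plasma_ratio={cfg.plasma_ratio}",
        f"models={list(cfg.models)} window_s={cfg.window_s} "
        f"multistart={cfg.multistart} weighting={cfg.weighting}",
    ]
    cohort = make_cohort(cfg.n_per_group, seed=cfg.seed, spread=cfg.spread, groups=cfg.groups)
    rows = []
    for rec in cohort:
        stage = "simulate"
        try:
            simulate_subject(
                rec,
                bolus=cfg.bolus,
                tau_disp_s=cfg.tau_disp_s,
                plasma_ratio=cfg.plasma_ratio,
                noise_scale=cfg.noise_scale,
            )
            stage = "fit"
            _fit_subject(rec, cfg)
            stage = "suv"
            suv_brain = suv(rec.brain_tac, rec.injected_dose_kBq, rec.body_weight_g, "brain")
            suv_lv = suv(rec.lv_tac, rec.injected_dose_kBq, rec.body_weight_g, "LV")
            ratio = brain_to_blood_ratio(suv_brain, suv_lv)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed for subject {rec.id}") from exc
        log.append(f"subject {rec.id}: seed={rec.seed} fits={sorted(k[0] for k in rec.fits)}")
        for key, label in ((("1tc", "full"), "full"), (("1tc", "window"), "2min")):
            fit = rec.fits[key]
            rows.append(
                {
                    "subject": rec.id,
                    "group": rec.group,
                    "window": label,
                    "K1_ml_cc_min": fit.params.K1,
                    "k2_per_min": fit.params.k2,
                    "K1_k2": fit.k1_k2,
                    "vB": fit.params.vB,
                    "AIC_1tc": fit.aic,
                    "AIC_2tc": rec.fits[("2tc", "full")].aic
                    if (label == "full" and ("2tc", "full") in rec.fits)
                    else np.nan,
                    "suv_brain": suv_brain.time_weighted_mean(),
                    "suv_lv": suv_lv.time_weighted_mean(),
                    "brain_to_blood": ratio.time_weighted_mean(),
                }
            )
    results = pd.DataFrame(rows)

    comparisons: dict[str, GroupComparison] = {}
    for window in ("full", "2min"):
        sub = results[results["window"] == window]
        for outcome in cfg.outcomes:
            col = {"K1": "K1_ml_cc_min", "k2": "k2_per_min", "K1_k2": "K1_k2"}.get(
                outcome, outcome
            )
            values = {g: sub.loc[sub["group"] == g, col].to_numpy() for g in cfg.groups}
            name = f"{outcome}[{window}]"
            try:
                comparisons[name] = group_stats(values, outcome=name)
            except ValueError as exc:  # e.g. zero variance in a noiseless run
                log.append(f"stats skipped for {name}: {exc}")

    report = CohortReport(
        results=results, comparisons=comparisons, subjects=cohort, config=cfg, log=log
    )
    if out_dir is not None:
        paths = report.save(out_dir)
        log.append(f"wrote {', '.join(str(p) for p in paths.values())}")
    return report
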