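"""End-to-end pipeline: derive -> propensity -> trim -> match -> estimate -> report.

Fully deterministic given (inputs, config, master seed); the run log records
row counts at every attrition step.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimation as est
from .config import PipelineConfig
from .derive import AnalysisTable, build_analysis_table
from .growth import GrowthReference
from .matching import ReplicateSet, assign_strata, balance_report, decile_bins, replicate_matching
from .propensity import PropensityFit, exclude_extreme, fit_propensity
from .registry import DEFAULT_REGISTRY
from .synthetic import read_days, read_infants

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "estimate_outcomes", "naive_estimates", "render_tables"]


@dataclass
class OutcomeEffect:
    """Replication-averaged results for one outcome (all relevant scales)."""

    outcome: str
    kind: str  # binary | continuous
    primary: est.EffectEstimate  # risk difference or mean difference
    oddsratio: est.EffectEstimate | None = None
    group_fed: float = float("nan")  # mean rate / mean over replicates
    group_unfed: float = float("nan")
    group_fed_ci: tuple[float, float] = (float("nan"), float("nan"))
    group_unfed_ci: tuple[float, float] = (float("nan"), float("nan"))
    n_fed: float = float("nan")  # mean analysed group sizes over replicates
    n_unfed: float = float("nan")
    notes: str = ""


@dataclass
class PipelineResult:
    config: PipelineConfig
    analysis: AnalysisTable
    fit: PropensityFit
    filtered: pd.DataFrame
    replicate_set: ReplicateSet
    balance: pd.DataFrame
    effects: list[OutcomeEffect]
    attrition: dict[str, int]
    milk_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def report_dict(self) -> dict:
        effects = {}
        for e in self.effects:
            row = {
                "kind": e.kind,
                "scale": e.primary.scale,
                "estimate": e.primary.point,
                "se": e.primary.se,
                "ci": list(e.primary.ci),
                "p": e.primary.p,
                "bonferroni_significant": e.primary.bonferroni_significant,
                "within_variance": e.primary.within_variance,
                "between_variance": e.primary.between_variance,
                "group_fed": e.group_fed,
                "group_unfed": e.group_unfed,
                "n_fed": e.n_fed,
                "n_unfed": e.n_unfed,
                "notes": e.notes,
            }
            if e.oddsratio is not None:
                row["odds_ratio"] = e.oddsratio.display_point
                row["odds_ratio_ci"] = list(e.oddsratio.display_ci)
            effects[e.outcome] = row
        return {
            "config": self.config.to_dict(),
            "variance_rule": "Wbar + (1 + 1/R) * B",
            "attrition": self.attrition,
            "replicate_seeds": self.replicate_set.seeds,
            "n_pairs": int(len(self.replicate_set.replicates[0])),
            "propensity": self.fit.summary_dict(),
            "balance_max_abs_after": float(self.balance["after_mean"].abs().max()),
            "effects": effects,
        }

    def report_json(self) -> str:
        return json.dumps(self.report_dict(), indent=2, sort_keys=True, allow_nan=True)


def _group_summary(points: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(points.mean())
    if len(points) > 1:
        halfwidth = est.Z975 * float(points.std(ddof=1)) * math.sqrt(1 + 1 / len(points))
    else:
        halfwidth = float("nan")
    return m, (m - halfwidth, m + halfwidth)


def estimate_outcomes(
    df: pd.DataFrame,
    replicate_set: ReplicateSet,
    outcomes: list[str],
    config: PipelineConfig | None = None,
    bonferroni_m: int | None = None,
) -> list[OutcomeEffect]:
    """Per-outcome replicate contrasts combined across replicates."""
    config = config or PipelineConfig()
    m = bonferroni_m if bonferroni_m is not None else config.bonferroni_m
    indexed = df.set_index("infant_id")
    results: list[OutcomeEffect] = []
    for outcome in outcomes:
        col = f"out__{outcome}"
        vals = indexed[col]
        kind = config.outcome_scale(outcome)
        rd_points, rd_vars, or_points, or_vars = [], [], [], []
        g1, g0, n1, n0 = [], [], [], []
        or_failed = False
        primary_failed = ""
        for rep in replicate_set.replicates:
            fed = vals.loc[rep["fed_id"]].dropna()
            unfed = vals.loc[rep["unfed_id"]].dropna()
            if kind == "binary":
                t = est.TwoByTwo(
                    int((fed == 1).sum()), int((fed != 1).sum()),
                    int((unfed == 1).sum()), int((unfed != 1).sum()),
                )
                rd = est.risk_difference(t)
                rd_points.append(rd.difference)
                rd_vars.append(rd.se**2)
                g1.append(rd.p_fed)
                g0.append(rd.p_unfed)
                try:
                    o = est.odds_ratio(t)
                    or_points.append(o.log_or)
                    or_vars.append(o.se_log**2)
                except ValueError:
                    or_failed = True
            else:
                try:
                    md = est.mean_difference(fed, unfed)
                except ValueError as exc:
                    primary_failed = str(exc)
                    continue
                rd_points.append(md.difference)
                rd_vars.append(md.se**2)
                g1.append(md.mean_fed)
                g0.append(md.mean_unfed)
            n1.append(len(fed))
            n0.append(len(unfed))
        scale = "risk_difference" if kind == "binary" else "mean_difference"
        if not rd_points:
            logger.warning("outcome %s not estimable: %s", outcome, primary_failed)
            results.append(
                OutcomeEffect(outcome=outcome, kind=kind,
                              primary=est.EffectEstimate(outcome=outcome, scale=scale),
                              notes=f"not estimable: {primary_failed}")
            )
            continue
        primary = est.combine_replicates(rd_points, rd_vars, outcome=outcome, scale=scale)
        orr = None
        notes = ""
        if kind == "binary":
            if or_failed or not or_points:
                notes = "odds ratio undefined in at least one replicate (zero margin)"
            else:
                orr = est.combine_replicates(or_points, or_vars, outcome=outcome, scale="odds_ratio")
        fed_mean, fed_ci = _group_summary(np.asarray(g1))
        unfed_mean, unfed_ci = _group_summary(np.asarray(g0))
        results.append(
            OutcomeEffect(
                outcome=outcome,
                kind=kind,
                primary=primary,
                oddsratio=orr,
                group_fed=fed_mean,
                group_unfed=unfed_mean,
                group_fed_ci=fed_ci,
                group_unfed_ci=unfed_ci,
                n_fed=float(np.mean(n1)),
                n_unfed=float(np.mean(n0)),
                notes=notes,
            )
        )
    flags = est.bonferroni([r.primary.p for r in results], m=m)
    for r, f in zip(results, flags):
        r.primary.bonferroni_significant = bool(f)
    return results


def naive_estimates(df: pd.DataFrame, outcome: str, kind: str) -> est.EffectEstimate:
    """Unmatched fed-vs-unfed contrast on the whole table (R = 1 combination)."""
    col = f"out__{outcome}" if f"out__{outcome}" in df.columns else outcome
    fed = df.loc[df["exposure"] == "FED", col].dropna()
    unfed = df.loc[df["exposure"] == "UNFED", col].dropna()
    if kind == "binary":
        t = est.TwoByTwo(int((fed == 1).sum()), int((fed != 1).sum()),
                         int((unfed == 1).sum()), int((unfed != 1).sum()))
        rd = est.risk_difference(t)
        return est.combine_replicates([rd.difference], [rd.se**2], outcome=outcome, scale="risk_difference")
    md = est.mean_difference(fed, unfed)
    return est.combine_replicates([md.difference], [md.se**2], outcome=outcome, scale="mean_difference")


def _milk_table(days: pd.DataFrame, exposure: pd.Series) -> pd.DataFrame:
    """Milk-type frequencies on enterally fed cooling days, by type."""
    fed_days = days[(days["cooled"] == 1) & (days["enteral_fed"] == 1)]
    counts = fed_days["milk_type"].value_counts()
    counts = counts[counts.index != "none"]
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "milk_type": counts.index,
            "fed_day_count": counts.to_numpy(),
            "proportion": (counts / total if total else counts).to_numpy(),
        }
    )


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and its context."""


def _run_stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_pipeline(
    config: PipelineConfig,
    infants: pd.DataFrame | None = None,
    days: pd.DataFrame | None = None,
    growth_ref: GrowthReference | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full matched analysis; optionally write all outputs."""
    if infants is None:
        if config.infants_csv is None or config.infant_days_csv is None:
            raise ValueError("either pass tables in memory or set input paths in the config")
        infants = _run_stage("read", read_infants, config.infants_csv)
        days = _run_stage("read", read_days, config.infant_days_csv)
    assert days is not None

    registry = DEFAULT_REGISTRY
    if config.covariates is not None:
        registry = tuple(c for c in DEFAULT_REGISTRY if c.name in set(config.covariates))

    analysis = _run_stage(
        "derive",
        build_analysis_table,
        infants,
        days,
        registry=registry,
        growth_ref=growth_ref,
        exposure_policy=config.exposure_policy,
        add_pn_day1_covariate=config.add_pn_day1_covariate,
        restrict_years_from=config.restrict_years_from,
    )
    logger.info("eligible analysis rows: %d (excluded %d)", analysis.n, len(analysis.exclusions))

    fit = _run_stage("propensity", fit_propensity, analysis)
    filtered, trim_excl = _run_stage(
        "trim", exclude_extreme, analysis, fit, caps=config.trim_caps, common_support=config.trim_common_support
    )
    logger.info("retained after extreme-propensity exclusion: %d", len(filtered))

    strata = assign_strata(filtered, drop_missing_ph=(config.ph_banding == "strict12"))
    in_strata = strata.notna()
    filtered2 = filtered[in_strata].reset_index(drop=True)
    strata = strata[in_strata.to_numpy()].reset_index(drop=True)
    bins = pd.Series(np.zeros(len(filtered2), dtype=int), index=filtered2.index)
    for _, idx in strata.groupby(strata).groups.items():
        bins.loc[idx] = decile_bins(filtered2.loc[idx, "score"].to_numpy())

    replicate_set = _run_stage(
        "match", replicate_matching, filtered2, strata, bins, R=config.R, master_seed=config.master_seed
    )
    n_pairs = len(replicate_set.replicates[0])
    logger.info("matched pairs per replicate: %d (R=%d)", n_pairs, config.R)

    balance = _run_stage(
        "balance", balance_report, filtered2, analysis.covariate_columns, analysis.column_kinds, replicate_set
    )
    effects = _run_stage("estimate", estimate_outcomes, filtered2, replicate_set, list(config.outcomes), config)

    total = len(infants)
    eligible_n = analysis.n
    trimmed = len(trim_excl)
    dropped_stratum = int((~in_strata).sum())
    retained = len(filtered2)
    attrition = {
        "total_rows": total,
        "ineligible_or_excluded": total - eligible_n,
        "eligible": eligible_n,
        "trimmed_extreme_propensity": trimmed,
        "outside_strata": dropped_stratum,
        "retained": retained,
        "matched": 2 * n_pairs,
        "unmatched": retained - 2 * n_pairs,
    }
    assert attrition["eligible"] == (
        attrition["matched"] + attrition["unmatched"] + attrition["trimmed_extreme_propensity"] + attrition["outside_strata"]
    )

    analysis.exclusions.extend(trim_excl)
    result = PipelineResult(
        config=config,
        analysis=analysis,
        fit=fit,
        filtered=filtered2,
        replicate_set=replicate_set,
        balance=balance,
        effects=effects,
        attrition=attrition,
        milk_table=_milk_table(days, analysis.df.set_index("infant_id")["exposure"]),
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.analysis.df.to_csv(out / "analysis_table.csv", index=False)
    with open(out / "exclusions.jsonl", "w") as fh:
        for e in result.analysis.exclusions:
            fh.write(json.dumps(e, sort_keys=True) + "\n")
    prop = pd.DataFrame(
        {
            "infant_id": result.fit.score.index,
            "score": result.fit.score.to_numpy(),
            "linear_predictor": result.fit.linear_predictor.to_numpy(),
            "included": result.fit.score.index.isin(result.filtered["infant_id"]).astype(int),
        }
    )
    prop.to_csv(out / "propensity.csv", index=False)
    (out / "propensity_model.json").write_text(json.dumps(result.fit.summary_dict(), indent=2, sort_keys=True))
    for r, rep in enumerate(result.replicate_set.replicates):
        rep.to_csv(out / f"matched_pairs_r{r + 1}.csv", index=False)
    result.balance.to_csv(out / "balance.csv", index=False)
    effects_rows = []
    for e in result.effects:
        row = {
            "outcome": e.outcome,
            "scale": e.primary.scale,
            "point": e.primary.point,
            "se": e.primary.se,
            "ci_low": e.primary.ci[0],
            "ci_high": e.primary.ci[1],
            "p": e.primary.p,
            "bonferroni": e.primary.bonferroni_significant,
            "R": len(e.primary.replicate_points),
            "within_variance": e.primary.within_variance,
            "between_variance": e.primary.between_variance,
            "odds_ratio": e.oddsratio.display_point if e.oddsratio else None,
            "or_ci_low": e.oddsratio.display_ci[0] if e.oddsratio else None,
            "or_ci_high": e.oddsratio.display_ci[1] if e.oddsratio else None,
        }
        effects_rows.append(row)
    pd.DataFrame(effects_rows).to_csv(out / "effects.csv", index=False)
    (out / "report.json").write_text(result.report_json())
    (out / "report.txt").write_text(render_tables(result))


def _fmt(x, digits=3):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "NA"
    return f"{x:.{digits}f}"


def _mask(count: float, mask_small: bool) -> str:
    c = int(round(count))
    return "<5" if (mask_small and 0 < c < 5) else str(c)


def render_tables(result: PipelineResult) -> str:
    """Human-readable report: balance table, outcome counts, effect estimates."""
    cfg = result.config
    mask_small = cfg.mask_small_counts
    lines: list[str] = []
    att = result.attrition
    lines.append("== Participant flow ==")
    for k, v in att.items():
        lines.append(f"  {k}: {v}")
    lines.append("")

    df = result.filtered
    fed = df["exposure"] == "FED"
    n_pairs = len(result.replicate_set.replicates[0])
    lines.append("== Table 1 analogue: covariate balance (unmatched vs matched) ==")
    lines.append(f"{'variable':42s} {'before_SMD':>10s} {'after_SMD':>10s} {'after_sd':>9s}")
    for row in result.balance.itertuples():
        lines.append(
            f"{row.variable:42s} {_fmt(row.before):>10s} {_fmt(row.after_mean):>10s} {_fmt(row.after_sd):>9s}"
        )
    lines.append("")

    lines.append(f"== Table 2 analogue: outcomes by group (matched, {n_pairs} pairs, mean over R={cfg.R}) ==")
    lines.append(f"{'outcome':38s} {'unfed':>12s} {'fed':>12s}")
    for e in result.effects:
        if e.kind == "binary":
            cu = _mask(e.group_unfed * e.n_unfed, mask_small)
            cf = _mask(e.group_fed * e.n_fed, mask_small)
            lines.append(
                f"{e.outcome:38s} {cu + ' (' + _fmt(100 * e.group_unfed, 1) + '%)':>12s}"
                f" {cf + ' (' + _fmt(100 * e.group_fed, 1) + '%)':>12s}"
            )
        else:
            lines.append(f"{e.outcome:38s} {_fmt(e.group_unfed, 1):>12s} {_fmt(e.group_fed, 1):>12s}")
    lines.append("")

    lines.append("== Table 3 analogue: replication-averaged effects (fed minus unfed) ==")
    header = (
        f"{'outcome':38s} {'difference':>11s} {'95% CI':>19s} {'OR':>6s} {'OR 95% CI':>15s} {'p':>9s}  sig"
    )
    lines.append(header)
    for e in result.effects:
        p = e.primary
        ci = f"({_fmt(p.ci[0])},{_fmt(p.ci[1])})"
        if e.oddsratio is not None:
            orr = _fmt(e.oddsratio.display_point, 2)
            orci = f"({_fmt(e.oddsratio.display_ci[0], 2)},{_fmt(e.oddsratio.display_ci[1], 2)})"
        else:
            orr, orci = "NA", "NA"
        sig = "*" if p.bonferroni_significant else ""
        lines.append(
            f"{e.outcome:38s} {_fmt(p.point):>11s} {ci:>19s} {orr:>6s} {orci:>15s} {_fmt(p.p, 5):>9s}  {sig}"
        )
    lines.append("")

    if len(result.milk_table):
        lines.append("== Milk types on enterally fed cooling days ==")
        for row in result.milk_table.itertuples():
            lines.append(f"  {row.milk_type:10s} {row.fed_day_count:6d}  ({100 * row.proportion:.1f}%)")
        lines.append("")
    return "\n".join(lines) + "\n"
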