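"""End-to-end orchestration for one exposure-outcome pair or a batch.

For each exposure the pipeline selects instruments, harmonizes them
against the outcome, and branches on the surviving instrument count:

* 1 instrument — Wald ratio only;
* 2 instruments — IVW with Cochran's Q (weighted median and Egger are
  undefined below three instruments);
* 3 or more — the full suite: random-effects IVW (primary), weighted
  median, MR-Egger slope and intercept test, radial MR with a
  post-outlier IVW re-estimate, and leave-one-out.

Report rows carry a significance tier under a Bonferroni-corrected
threshold ``0.05 / bonferroni_m`` for the configured family of tests:
``bonferroni_significant`` (p below the corrected threshold),
``nominal`` (p < 0.05 only) or ``null``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

from mrpipe import estimators as est
from mrpipe.harmonize import HarmonizeConfig, harmonize
from mrpipe.instruments import (
    LDMatrix,
    SelectionConfig,
    drop_listed,
    drop_outcome_associated,
    filter_significant,
    filter_strong,
    ld_clump,
)
from mrpipe.sumstats import HarmonizedInstrument, SumstatsTable

logger = logging.getLogger(__name__)

_METHOD_ORDER = {
    "ivw_re": 0,
    "ivw_fe": 1,
    "weighted_median": 2,
    "egger_slope": 3,
    "ivw_radial": 4,
    "wald_ratio": 5,
}


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure: its table, LD matrix and selection thresholds."""

    label: str
    table: SumstatsTable
    ld: LDMatrix
    selection: SelectionConfig = field(default_factory=SelectionConfig)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed for a deterministic batch analysis."""

    exposures: tuple[ExposureSpec, ...]
    outcome: SumstatsTable
    outcome_label: str = "outcome"
    harmonize: HarmonizeConfig = field(default_factory=HarmonizeConfig)
    n_boot: int = 1000
    seed: int = 0
    outlier_alpha: float = 0.05
    exclusion_ids: frozenset[str] = frozenset()
    bonferroni_m: int = 6

    def __post_init__(self) -> None:
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")


@dataclass(frozen=True)
class MRReportRow:
    """One (exposure, method) line of the forest-table report."""

    exposure: str
    outcome: str
    method: str
    n_snp: int
    beta: float
    se: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    pvalue: float
    tier: str
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_pvalue: float | None = None
    note: str = ""


def significance_tier(pvalue: float, bonferroni_m: int) -> str:
    """Mutually exclusive tiers under the 0.05 / m corrected threshold."""
    if pvalue < 0.05 / bonferroni_m:
        return "bonferroni_significant"
    if pvalue < 0.05:
        return "nominal"
    return "null"


def select_instruments(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LDMatrix,
    selection: SelectionConfig,
    outcome_screen: bool = True,
) -> SumstatsTable:
    """Run the full instrument-selection chain for one exposure.

    ``outcome_screen=False`` skips the outcome-overlap exclusion;
    estimator-calibration simulations turn it off because with a real
    causal effect (or simulated pleiotropy) the screen removes exactly
    the instruments whose properties are being measured.
    """
    table = filter_significant(exposure, selection.p_threshold)
    table = ld_clump(table, ld, selection.clump_r2, selection.clump_window_kb)
    table = filter_strong(table, selection.f_min)
    if outcome_screen:
        table = drop_outcome_associated(table, outcome, selection.outcome_p_exclude)
    return table


def _row_from_estimate(
    e: est.MREstimate,
    exposure: str,
    outcome: str,
    bonferroni_m: int,
    het: est.HeterogeneityResult | None = None,
    egger_res: est.EggerResult | None = None,
    note: str = "",
) -> MRReportRow:
    return MRReportRow(
        exposure=exposure,
        outcome=outcome,
        method=e.method,
        n_snp=e.n_snp,
        beta=e.beta,
        se=e.se,
        odds_ratio=e.odds_ratio,
        or_ci_low=e.or_ci_low,
        or_ci_high=e.or_ci_high,
        pvalue=e.pvalue,
        tier=significance_tier(e.pvalue, bonferroni_m),
        q=None if het is None else het.Q,
        q_df=None if het is None else het.df,
        q_pvalue=None if het is None else het.pvalue,
        egger_intercept=None if egger_res is None else egger_res.intercept,
        egger_intercept_pvalue=(
            None if egger_res is None else egger_res.intercept_pvalue
        ),
        note=note,
    )


def estimate_all(
    harmonized: Sequence[HarmonizedInstrument],
    exposure_label: str,
    outcome_label: str,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    bonferroni_m: int = 6,
) -> tuple[list[MRReportRow], list[tuple[str, est.MREstimate]]]:
    """Apply the estimator suite appropriate for the instrument count.

    Returns the report rows and the leave-one-out series (empty below
    three instruments).
    """
    n = len(harmonized)
    rows: list[MRReportRow] = []
    loo: list[tuple[str, est.MREstimate]] = []
    if n == 0:
        raise ValueError("no harmonized instruments")
    if n == 1:
        e = est.wald_ratio(harmonized[0])
        rows.append(_row_from_estimate(e, exposure_label, outcome_label, bonferroni_m))
        return rows, loo
    ivw_est, het = est.ivw(harmonized, model="random")
    if n == 2:
        rows.append(
            _row_from_estimate(
                ivw_est, exposure_label, outcome_label, bonferroni_m, het=het
            )
        )
        return rows, loo

    egger_res = est.egger(harmonized)
    wm = est.weighted_median(harmonized, n_boot=n_boot, seed=seed)
    radial = est.radial_ivw(harmonized, outlier_alpha=outlier_alpha)
    post_est, post_het = est.remove_outliers_and_reestimate(harmonized, radial)
    loo = est.leave_one_out(harmonized)

    rows.append(
        _row_from_estimate(
            ivw_est, exposure_label, outcome_label, bonferroni_m,
            het=het, egger_res=egger_res,
        )
    )
    rows.append(_row_from_estimate(wm, exposure_label, outcome_label, bonferroni_m))
    rows.append(
        _row_from_estimate(
            egger_res.slope, exposure_label, outcome_label, bonferroni_m,
            egger_res=egger_res,
        )
    )
    rows.append(
        _row_from_estimate(
            dataclasses.replace(post_est, method="ivw_radial"),
            exposure_label, outcome_label, bonferroni_m, het=post_het,
            note=f"removed {len(radial.outlier_ids)} radial outlier(s)",
        )
    )
    return rows, loo


def run_mr(cfg: AnalysisConfig) -> list[MRReportRow]:
    """Run the full analysis for every exposure in the batch.

    An exposure with zero surviving instruments is reported as a
    ``no_valid_instruments`` row (method ``none``) and the run
    continues. Deterministic given ``cfg``.
    """
    rows: list[MRReportRow] = []
    for spec in cfg.exposures:
        selected = select_instruments(spec.table, cfg.outcome, spec.ld, spec.selection)
        if cfg.exclusion_ids:
            selected = drop_listed(selected, cfg.exclusion_ids, "confounder list")
        harmonized, report = harmonize(selected, cfg.outcome, cfg.harmonize)
        if not harmonized:
            logger.warning("%s: no valid instruments survive selection", spec.label)
            rows.append(
                MRReportRow(
                    exposure=spec.label,
                    outcome=cfg.outcome_label,
                    method="none",
                    n_snp=0,
                    beta=float("nan"),
                    se=float("nan"),
                    odds_ratio=float("nan"),
                    or_ci_low=float("nan"),
                    or_ci_high=float("nan"),
                    pvalue=float("nan"),
                    tier="null",
                    note="no_valid_instruments",
                )
            )
            continue
        exp_rows, _ = estimate_all(
            harmonized,
            spec.label,
            cfg.outcome_label,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            outlier_alpha=cfg.outlier_alpha,
            bonferroni_m=cfg.bonferroni_m,
        )
        rows.extend(exp_rows)
    return rows


def rerun_without_confounder_snps(
    cfg: AnalysisConfig, exclusion_ids: Sequence[str] | set[str]
) -> list[MRReportRow]:
    """Repeat the IVW analysis after pruning a confounder-associated list.

    Returns random-effects IVW rows (or the degraded method the
    instrument count dictates) labelled ``confounder-pruned``.
    """
    pruned_cfg = dataclasses.replace(cfg, exclusion_ids=frozenset(exclusion_ids))
    rows = run_mr(pruned_cfg)
    keep = {"ivw_re", "ivw_fe", "wald_ratio", "none"}
    out = []
    for r in rows:
        if r.method in keep:
            note = (r.note + "; " if r.note else "") + "confounder-pruned"
            out.append(dataclasses.replace(r, note=note))
    return out


def _round_half_even(value: float, decimals: int) -> str:
    return f"{round(value, decimals):.{decimals}f}"


def render_forest_table(
    rows: Sequence[MRReportRow],
    or_decimals: int = 2,
    p_decimals: int = 4,
) -> str:
    """Render report rows as a tab-separated forest table (text stand-in
    for the conventional forest plot).

    Rows are canonically sorted by (exposure, method, outcome);
    odds ratios and CI bounds are rounded half-even to ``or_decimals``
    and p-values to ``p_decimals``.
    """
    if not rows:
        raise ValueError("no rows to render")
    ordered = sorted(
        rows, key=lambda r: (r.exposure, _METHOD_ORDER.get(r.method, 99), r.outcome)
    )
    header = [
        "exposure", "outcome", "method", "n_snp", "or_95ci", "pvalue",
        "q", "q_pvalue", "egger_intercept_p", "tier", "note",
    ]
    lines = ["\t".join(header)]
    for r in ordered:
        if r.method == "none":
            or_ci, p = "NA", "NA"
        else:
            or_ci = (
                f"{_round_half_even(r.odds_ratio, or_decimals)} "
                f"({_round_half_even(r.or_ci_low, or_decimals)}-"
                f"{_round_half_even(r.or_ci_high, or_decimals)})"
            )
            p = _round_half_even(r.pvalue, p_decimals)
        lines.append(
            "\t".join(
                [
                    r.exposure,
                    r.outcome,
                    r.method,
                    str(r.n_snp),
                    or_ci,
                    p,
                    "NA" if r.q is None else f"{r.q:.4g}",
                    "NA" if r.q_pvalue is None else _round_half_even(r.q_pvalue, p_decimals),
                    "NA"
                    if r.egger_intercept_pvalue is None
                    else _round_half_even(r.egger_intercept_pvalue, p_decimals),
                    r.tier,
                    r.note,
                ]
            )
        )
    return "\n".join(lines) + "\n"
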