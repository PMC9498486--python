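"""End-to-end applied workflow: crude cis-MR, confounder MR, TSCMR, report.

The orchestration mirrors a drug-target analysis: select cis
instruments for the exposure, harmonize against the outcome GWAS, pool
crude Wald ratios; estimate each confounder's causal effect on the
outcome by genome-wide MR (choosing the weighted median over IVW when
Cochran's Q signals pleiotropy); subtract each confounder pathway from
the variant-outcome associations; re-pool; and report the percentage
deflation of the adjusted versus the crude estimate alongside
instrument-strength and heterogeneity diagnostics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from ._errors import ConfigError, InputError
from . import summary_data as sd
from .adjustment import PathwaySpec, bootstrap_se, sequential_adjust
from .mr_estimators import (
    IVW, WEIGHTED_MEDIAN, MREstimate, RatioInput, cochran_q, estimate_all,
    f_statistic,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the applied TSCMR workflow.

    Paths point at delimited GWAS summary-statistic files (pre-clumped;
    see the YAML schema in ``docs/config.schema.json``).  ``instruments``
    may fix the cis instrument list explicitly; otherwise instruments
    are selected at ``p_threshold``.
    """

    exposure_path: str
    outcome_path: str
    confounder_paths: tuple[str, ...]
    out_dir: str | None = None
    instruments: tuple[str, ...] | None = None
    p_threshold: float = 5e-8
    confounder_p_threshold: float = 5e-8
    q_pvalue_threshold: float = 0.05
    palindrome_eaf_window: float = 0.08
    n_boot: int = 10_000
    estimator_n_boot: int = 1000
    seed: int = 0
    first_order: bool = False
    bandwidth_factor: float = 1.0
    exposure_column_map: Mapping[str, str] | None = None
    outcome_column_map: Mapping[str, str] | None = None
    confounder_column_maps: tuple[Mapping[str, str] | None, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.confounder_paths) == 0:
            raise ConfigError("at least one confounder GWAS is required")
        if not (0.0 < self.q_pvalue_threshold < 1.0):
            raise ConfigError("q_pvalue_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        for key in ("confounder_paths", "instruments", "confounder_column_maps"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class PipelineReport:
    """In-memory results of one pipeline run."""

    crude_estimates: list[MREstimate]
    adjusted_estimates: list[MREstimate]
    primary_crude: MREstimate
    primary_adjusted: MREstimate
    percent_difference: float
    confounder_mr: dict[str, dict]
    per_snp: pd.DataFrame
    adjusted_table: pd.DataFrame
    snp_accounting: pd.DataFrame
    q_crude: tuple[float, int, float] | None
    q_adjusted: tuple[float, int, float] | None


def percent_difference(crude: float, adjusted: float) -> float:
    """Percentage deflation of the adjusted estimate relative to the crude.

    Defined as 100 * (crude - adjusted) / crude; undefined (NaN) when
    the crude estimate is exactly zero.
    """
    if crude == 0:
        return float("nan")
    return 100.0 * (crude - adjusted) / crude


def _choose_primary(
    estimates: Sequence[MREstimate], q_p: float | None, threshold: float
) -> MREstimate:
    """IVW (or single-SNP Wald) unless Q indicates pleiotropy, then weighted median."""
    by_method = {e.method: e for e in estimates}
    if (
        q_p is not None
        and q_p < threshold
        and WEIGHTED_MEDIAN in by_method
    ):
        return by_method[WEIGHTED_MEDIAN]
    return by_method.get(IVW, estimates[0])


def _ratio_inputs(records: Sequence[sd.HarmonizedRecord]) -> list[RatioInput]:
    return [
        RatioInput(
            b_gx=r.base.beta, se_gx=r.base.se,
            b_gy=r.other.beta, se_gy=r.other.se,
            snp_id=r.snp_id,
        )
        for r in records
        if r.usable
    ]


def _confounder_mr(
    confounder: list[sd.SummaryAssociation],
    outcome: list[sd.SummaryAssociation],
    cfg: PipelineConfig,
    label: str,
) -> dict:
    """Genome-wide MR of one confounder on the outcome; Q-driven primary."""
    instruments = sd.filter_instruments(confounder, cfg.confounder_p_threshold)
    if not instruments:
        raise InputError(f"{label}: no genome-wide significant instruments")
    harmonized = sd.harmonize(instruments, outcome, cfg.palindrome_eaf_window)
    ratios = _ratio_inputs(harmonized)
    if not ratios:
        raise InputError(f"{label}: no usable instruments after harmonization")
    estimates = estimate_all(
        ratios, n_boot=cfg.estimator_n_boot, seed=cfg.seed,
        bandwidth_factor=cfg.bandwidth_factor,
    )
    q = cochran_q(ratios) if len(ratios) >= 2 else None
    primary = _choose_primary(estimates, q[2] if q else None, cfg.q_pvalue_threshold)
    logger.info(
        "%s: %d instruments, Q p=%s, primary estimator=%s (beta=%.4f, se=%.4f)",
        label, len(ratios), f"{q[2]:.3g}" if q else "NA",
        primary.method, primary.beta, primary.se,
    )
    return {
        "label": label, "estimates": estimates, "q": q, "primary": primary,
        "n_instruments": len(ratios),
    }


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full TSCMR workflow; optionally write a report bundle."""
    exposure = sd.read_summary_stats(cfg.exposure_path, cfg.exposure_column_map)
    outcome = sd.read_summary_stats(cfg.outcome_path, cfg.outcome_column_map)
    conf_maps = cfg.confounder_column_maps or (None,) * len(cfg.confounder_paths)
    confounders = [
        sd.read_summary_stats(path, cmap)
        for path, cmap in zip(cfg.confounder_paths, conf_maps)
    ]
    labels = [Path(p).stem for p in cfg.confounder_paths]

    # --- cis instruments for the exposure -------------------------------
    if cfg.instruments is not None:
        wanted = set(cfg.instruments)
        cis = [a for a in exposure if a.snp_id in wanted]
        missing = wanted - {a.snp_id for a in cis}
        if missing:
            raise InputError(
                f"instrument(s) absent from exposure GWAS: {', '.join(sorted(missing))}"
            )
    else:
        cis = sd.filter_instruments(exposure, cfg.p_threshold)
    if not cis:
        raise InputError("no cis instruments selected")

    accounting: dict[str, str] = {a.snp_id: "used" for a in cis}

    # --- harmonize exposure vs outcome; crude MR ------------------------
    harmonized = sd.harmonize(cis, outcome, cfg.palindrome_eaf_window)
    present = {h.snp_id for h in harmonized}
    for a in cis:
        if a.snp_id not in present:
            accounting[a.snp_id] = "dropped: absent from outcome GWAS"
    for h in harmonized:
        if not h.usable:
            accounting[h.snp_id] = f"dropped: {h.action}"
        else:
            logger.info("harmonized %s: %s", h.snp_id, h.action)
    usable = [h for h in harmonized if h.usable]
    if not usable:
        raise InputError("all cis instruments dropped during harmonization")
    ratios_crude = _ratio_inputs(usable)
    crude_estimates = estimate_all(
        ratios_crude, n_boot=cfg.estimator_n_boot, seed=cfg.seed,
        bandwidth_factor=cfg.bandwidth_factor,
    )
    q_crude = cochran_q(ratios_crude) if len(ratios_crude) >= 2 else None

    # --- confounder -> outcome MR per pathway ---------------------------
    confounder_mr = {
        label: _confounder_mr(conf, outcome, cfg, label)
        for label, conf in zip(labels, confounders)
    }

    # --- per-SNP confounder associations, aligned to exposure alleles ---
    conf_tables: list[tuple[str, dict[str, sd.PhenotypeStats]]] = []
    for label, conf in zip(labels, confounders):
        aligned = sd.harmonize(
            [a for a in cis], conf, cfg.palindrome_eaf_window
        )
        table = {h.snp_id: h.other for h in aligned if h.usable}
        conf_tables.append((label, table))

    # --- TSCMR adjustment ------------------------------------------------
    rows = []
    adjusted_ratios: list[RatioInput] = []
    for h, r in zip(usable, ratios_crude):
        pathways = []
        missing_from = None
        for label, table in conf_tables:
            stats_ = table.get(h.snp_id)
            if stats_ is None:
                missing_from = label
                break
            mr = confounder_mr[label]["primary"]
            pathways.append(
                PathwaySpec(
                    b_gc=stats_.beta, se_gc=stats_.se,
                    b_co=mr.beta, se_co=mr.se, label=label,
                )
            )
        if missing_from is not None:
            accounting[h.snp_id] = f"excluded: absent from confounder GWAS {missing_from}"
            logger.warning("%s excluded: missing from confounder %s", h.snp_id, missing_from)
            continue
        res = bootstrap_se(
            r.b_gy, r.se_gy, pathways, n_boot=cfg.n_boot, seed=cfg.seed,
            first_order=cfg.first_order,
        ) if cfg.n_boot else sequential_adjust(
            r.b_gy, r.se_gy, pathways, first_order=cfg.first_order
        )
        rows.append({
            "snp_id": h.snp_id,
            "beta_exposure": r.b_gx, "se_exposure": r.se_gx,
            "beta_outcome": r.b_gy, "se_outcome": r.se_gy,
            "beta_adj": res.b_adj, "se_pe": res.se_pe, "se_bs": res.se_bs,
            "subtracted_path": sum(res.subtracted),
            "f_statistic": f_statistic(r.b_gx, r.se_gx),
        })
        adjusted_ratios.append(
            RatioInput(b_gx=r.b_gx, se_gx=r.se_gx, b_gy=res.b_adj,
                       se_gy=res.se_pe, snp_id=h.snp_id)
        )
    if not adjusted_ratios:
        raise InputError("all instruments excluded during adjustment")
    per_snp = pd.DataFrame(rows)

    adjusted_estimates = estimate_all(
        adjusted_ratios, n_boot=cfg.estimator_n_boot, seed=cfg.seed,
        bandwidth_factor=cfg.bandwidth_factor,
    )
    q_adjusted = cochran_q(adjusted_ratios) if len(adjusted_ratios) >= 2 else None

    primary_crude = _choose_primary(
        crude_estimates, q_crude[2] if q_crude else None, cfg.q_pvalue_threshold
    )
    primary_adjusted = _choose_primary(
        adjusted_estimates, q_adjusted[2] if q_adjusted else None, cfg.q_pvalue_threshold
    )
    pct = percent_difference(primary_crude.beta, primary_adjusted.beta)

    report = PipelineReport(
        crude_estimates=crude_estimates,
        adjusted_estimates=adjusted_estimates,
        primary_crude=primary_crude,
        primary_adjusted=primary_adjusted,
        percent_difference=pct,
        confounder_mr=confounder_mr,
        per_snp=per_snp,
        adjusted_table=per_snp[["snp_id", "beta_adj", "se_pe", "se_bs", "subtracted_path"]],
        snp_accounting=pd.DataFrame(
            [{"snp_id": k, "status": v} for k, v in accounting.items()]
        ),
        q_crude=q_crude,
        q_adjusted=q_adjusted,
    )
    if cfg.out_dir is not None:
        _write_bundle(cfg, report, harmonized)
    return report


def _estimates_frame(estimates: Sequence[MREstimate],
                     q: tuple[float, int, float] | None) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "method": e.method, "beta": e.beta, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "n_snps": e.n_snps,
            "Q": q[0] if q else None, "Q_p": q[2] if q else None,
            "intercept": e.intercept, "intercept_se": e.intercept_se,
        })
    return pd.DataFrame(rows)


def _write_bundle(cfg: PipelineConfig, report: PipelineReport,
                  harmonized: Sequence[sd.HarmonizedRecord]) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sd.write_harmonized(harmonized, out / "harmonized_exposure_outcome.tsv")
    report.per_snp.to_csv(out / "per_snp.tsv", sep="\t", index=False)
    report.adjusted_table.to_csv(out / "adjusted_outcome.tsv", sep="\t", index=False)
    report.snp_accounting.to_csv(out / "snp_accounting.tsv", sep="\t", index=False)
    _estimates_frame(report.crude_estimates, report.q_crude).to_csv(
        out / "crude_estimates.tsv", sep="\t", index=False)
    _estimates_frame(report.adjusted_estimates, report.q_adjusted).to_csv(
        out / "adjusted_estimates.tsv", sep="\t", index=False)
    for label, res in report.confounder_mr.items():
        _estimates_frame(res["estimates"], res["q"]).to_csv(
            out / f"confounder_mr_{label}.tsv", sep="\t", index=False)
    summary = {
        "primary_crude": {"method": report.primary_crude.method,
                          "beta": report.primary_crude.beta,
                          "se": report.primary_crude.se,
                          "ci_low": report.primary_crude.ci_low,
                          "ci_high": report.primary_crude.ci_high},
        "primary_adjusted": {"method": report.primary_adjusted.method,
                             "beta": report.primary_adjusted.beta,
                             "se": report.primary_adjusted.se,
                             "ci_low": report.primary_adjusted.ci_low,
                             "ci_high": report.primary_adjusted.ci_high},
        "percent_difference": report.percent_difference,
        "percent_difference_rounded": None
        if math.isnan(report.percent_difference)
        else round(report.percent_difference),
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        pc, pa = report.primary_crude, report.primary_adjusted
        fh.write("Two-step cis-MR report\n")
        fh.write("======================\n\n")
        fh.write(f"Crude estimate    ({pc.method}): "
                 f"{pc.beta:.4f} (95% CI {pc.ci_low:.4f} to {pc.ci_high:.4f})\n")
        fh.write(f"Adjusted estimate ({pa.method}): "
                 f"{pa.beta:.4f} (95% CI {pa.ci_low:.4f} to {pa.ci_high:.4f})\n")
        if not math.isnan(report.percent_difference):
            fh.write(f"Deflation of adjusted vs crude: "
                     f"{round(report.percent_difference)}%\n")
        else:
            fh.write("Deflation of adjusted vs crude: NA (crude estimate is zero)\n")
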