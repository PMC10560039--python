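"""Config-driven orchestration of the full screening and mediation analysis.

``run_screen`` reproduces a three-phase design over many exposures: each
exposure is analysed against every outcome cohort (instrument selection,
harmonization, all applicable estimators, sensitivity diagnostics), the
per-cohort IVW estimates are combined by fixed-effect meta-analysis, and a
findings table flags exposures with IVW p <= alpha per cohort and in the
meta-analysis.  ``run_mediation`` runs two-step mediation MR for each
configured mediator and ranks them by mediation proportion.

Every random draw is seeded and every output is written with fixed
formatting, so identical configuration and seeds reproduce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .estimators import SCREEN_METHODS, estimate_all
from .instruments import harmonize, mean_f, select_instruments, set_variance_explained
from .io import read_gwas, read_ld, write_table
from .mediation import mediate, rank_mediators
from .meta import meta_fixed
from .sensitivity import cochran_q, leave_one_out, mr_presso, plot_data

_EST_COLUMNS = [
    "exposure", "outcome", "cohort", "method", "nsnp",
    "beta", "se", "ci_low", "ci_high", "pval",
]


@dataclass
class RunConfig:
    """Run configuration; loadable from YAML or JSON via :meth:`from_file`."""

    exposures: list[dict] = field(default_factory=list)
    outcomes: list[dict] = field(default_factory=list)
    ld_path: str | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    clump_kb: float = 5000.0
    methods: list[str] = field(default_factory=lambda: list(SCREEN_METHODS))
    seed: int = 0
    n_boot: int = 1000
    presso_n_sim: int = 1000
    significance_alpha: float = 0.05
    palindromic_policy: str = "keep_if_eaf_informative"
    multiple_testing: str | None = None  # None (raw p), "bonferroni" or "fdr_bh"
    mediation: dict | None = None
    outdir: str = "mr_output"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        # YAML 1.1 reads scientific notation like 5e-08 as a string
        for name in ("p_threshold", "r2_threshold", "clump_kb", "significance_alpha"):
            if name in data:
                data[name] = float(data[name])
        for name in ("seed", "n_boot", "presso_n_sim"):
            if name in data:
                data[name] = int(data[name])
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.significance_alpha < 1:
            raise ConfigError(f"significance_alpha: must lie in (0, 1), got {self.significance_alpha!r}")
        if not self.exposures:
            raise ConfigError("exposures: at least one exposure is required")
        if not self.outcomes:
            raise ConfigError("outcomes: at least one outcome cohort is required")
        for item in list(self.exposures) + list(self.outcomes):
            p = item.get("path")
            if p is None or not Path(p).exists():
                raise ConfigError(f"path: missing summary-statistics file {p!r}")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            raise ConfigError(f"ld_path: missing LD table {self.ld_path!r}")
        if self.multiple_testing not in (None, "bonferroni", "fdr_bh"):
            raise ConfigError(f"multiple_testing: unknown method {self.multiple_testing!r}")


def _load(item: dict) -> pd.DataFrame:
    return read_gwas(
        item["path"],
        column_map=item.get("column_map"),
        odds_ratio_col=item.get("odds_ratio_col"),
    )


def _adjust(pvals: pd.Series, how: str | None) -> pd.Series:
    if how is None:
        return pvals
    if how == "bonferroni":
        return np.minimum(pvals * len(pvals), 1.0)
    # Benjamini-Hochberg
    p = pvals.to_numpy()
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return pd.Series(out, index=pvals.index)


def _estimate_rows(exposure, cohort, outcome_name, ests):
    rows = []
    for method, est in sorted(ests.items()):
        if est is None:
            rows.append([exposure, outcome_name, cohort, method, None] + [None] * 5)
        else:
            rows.append(
                [exposure, outcome_name, cohort, method, est.n_snp,
                 est.beta, est.se, est.ci_low, est.ci_high, est.pval]
            )
    return rows


def run_screen(config: RunConfig) -> dict:
    """Run the multi-exposure, multi-cohort screen and write its reports.

    Writes ``estimates.tsv``, ``sensitivity.tsv``, ``meta.tsv``,
    ``findings.tsv``, ``snp_log.tsv``, per-pair plot-data TSVs under
    ``plots/`` and a ``manifest.json`` into ``config.outdir``.  A failing
    exposure is logged and skipped, never aborting the screen.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "plots").mkdir(exist_ok=True)
    ld = read_ld(config.ld_path) if config.ld_path else None

    est_rows, sens_rows, meta_rows, find_rows, log_rows = [], [], [], [], []
    failures = {}
    outcome_tables = [(o["name"], _load(o)) for o in config.outcomes]

    for ex in config.exposures:
        name = ex["name"]
        try:
            exp_df = _load(ex)
            snps, sel_log = select_instruments(
                exp_df, ld, config.p_threshold, config.r2_threshold, config.clump_kb,
                return_log=True,
            )
            for s, status, reason in sel_log:
                log_rows.append([name, "selection", s, status, reason])
            cohort_ivw = []
            finding = {"exposure": name}
            for cohort, out_df in outcome_tables:
                iset = harmonize(
                    exp_df, out_df, snps, config.palindromic_policy,
                    exposure_name=name, outcome_name=cohort,
                    thresholds=(config.p_threshold, config.r2_threshold, config.clump_kb),
                )
                for s, status, reason in iset.selection_log:
                    log_rows.append([name, f"harmonize:{cohort}", s, status, reason])
                if len(iset) == 0:
                    raise ValueError(f"no instruments left after harmonization against {cohort}")
                ests = estimate_all(
                    iset, config.methods, n_boot=config.n_boot, seed=config.seed
                )
                est_rows += _estimate_rows(name, cohort, cohort, ests)
                primary = ests.get("ivw") or ests.get("wald_ratio")
                cohort_ivw.append((cohort, primary.beta, primary.se))
                finding[f"pval_{cohort}"] = primary.pval
                finding[f"beta_{cohort}"] = primary.beta

                fstat = mean_f(iset, warn=False)
                r2set = set_variance_explained(iset)
                srow = {
                    "exposure": name, "cohort": cohort, "nsnp": len(iset),
                    "mean_F": fstat, "r2_sum": r2set,
                    "weak_instruments": fstat < 10,
                }
                if len(iset) >= 2:
                    q = cochran_q(iset, "ivw")
                    srow.update(Q_ivw=q.Q, Q_ivw_df=q.df, Q_ivw_pval=q.pval)
                if len(iset) >= 3:
                    qe = cochran_q(iset, "egger")
                    srow.update(Q_egger=qe.Q, Q_egger_df=qe.df, Q_egger_pval=qe.pval)
                    eg = ests.get("egger")
                    if eg is not None:
                        srow.update(
                            egger_intercept=eg.extra["egger_intercept"],
                            egger_intercept_pval=eg.extra["egger_intercept_pval"],
                            pleiotropy_detected=eg.extra["egger_intercept_pval"] < 0.05,
                        )
                    loo = leave_one_out(iset)
                    srow["loo_influential"] = ";".join(loo.influential)
                if len(iset) >= 4:
                    pr = mr_presso(
                        iset, n_sim=config.presso_n_sim, seed=config.seed
                    )
                    srow.update(
                        presso_global_pval=pr.global_pval,
                        presso_outliers=";".join(s for s, _ in pr.outlier_snps),
                        presso_corrected_beta=pr.estimate_corrected.beta,
                        presso_distortion_pval=pr.distortion_pval,
                    )
                sens_rows.append(srow)

                tables = plot_data(iset, [e for e in ests.values() if e is not None])
                for kind, tbl in tables.items():
                    write_table(tbl, outdir / "plots" / f"{name}__{cohort}__{kind}.tsv")

            m = meta_fixed(cohort_ivw)
            meta_rows.append(
                {
                    "exposure": name, "beta_meta": m.beta_meta, "se_meta": m.se_meta,
                    "ci_low": m.ci_low, "ci_high": m.ci_high, "pval": m.pval,
                    "cohorts": ";".join(lbl for lbl, _, _ in m.inputs),
                    "Q_cohorts": m.heterogeneity.Q if m.heterogeneity else None,
                    "Q_cohorts_pval": m.heterogeneity.pval if m.heterogeneity else None,
                }
            )
            finding["pval_meta"] = m.pval
            finding["beta_meta"] = m.beta_meta
            find_rows.append(finding)
        except Exception as exc:  # noqa: BLE001 - a failing exposure must not abort the screen
            failures[name] = f"{type(exc).__name__}: {exc}"
            log_rows.append([name, "screen", "*", "failed", str(exc)])

    findings = pd.DataFrame(find_rows)
    if len(findings):
        alpha = config.significance_alpha
        for col in [c for c in findings.columns if c.startswith("pval_")]:
            flag = "significant_" + col.removeprefix("pval_")
            findings[flag] = _adjust(findings[col], config.multiple_testing) <= alpha

    estimates = pd.DataFrame(est_rows, columns=_EST_COLUMNS)
    sensitivity = pd.DataFrame(sens_rows)
    meta = pd.DataFrame(meta_rows)
    snp_log = pd.DataFrame(log_rows, columns=["exposure", "stage", "snp_id", "status", "reason"])

    write_table(estimates, outdir / "estimates.tsv")
    write_table(sensitivity, outdir / "sensitivity.tsv")
    write_table(meta, outdir / "meta.tsv")
    write_table(findings, outdir / "findings.tsv")
    write_table(snp_log, outdir / "snp_log.tsv")
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "failures": failures,
        "n_exposures_run": int(len(findings)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return {
        "estimates": estimates,
        "sensitivity": sensitivity,
        "meta": meta,
        "findings": findings,
        "snp_log": snp_log,
        "failures": failures,
    }


def run_mediation(config: RunConfig) -> pd.DataFrame:
    """Two-step mediation MR for every configured mediator; writes the
    ranked table to ``mediation.tsv``."""
    if not config.mediation:
        raise ConfigError("mediation: block missing from configuration")
    block = config.mediation
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = read_ld(config.ld_path) if config.ld_path else None
    exposure = _load(block["exposure"])
    outcome = _load(block["outcome"])
    mediators = block.get("mediators", [])
    if not mediators:
        import warnings

        warnings.warn("mediation block lists no mediators; empty report", stacklevel=2)
        empty = pd.DataFrame(columns=["mediator", "proportion_pct"])
        write_table(empty, outdir / "mediation.tsv")
        return empty

    results, errors = [], {}
    for med in mediators:
        try:
            med_df = _load(med)
            results.append(
                mediate(
                    exposure, med_df, outcome, ld,
                    p_threshold=config.p_threshold,
                    r2_threshold=config.r2_threshold,
                    clump_kb=config.clump_kb,
                    palindromic_policy=config.palindromic_policy,
                    ci_method=block.get("ci_method", "delta"),
                    n_boot=config.n_boot,
                    seed=config.seed,
                    mediator_name=med["name"],
                    exposure_name=block["exposure"].get("name", "exposure"),
                    outcome_name=block["outcome"].get("name", "outcome"),
                )
            )
        except Exception as exc:  # noqa: BLE001
            errors[med["name"]] = f"{type(exc).__name__}: {exc}"
    if results:
        table = rank_mediators(results)
    else:
        table = pd.DataFrame(columns=["mediator", "proportion_pct"])
    if errors:
        not_est = pd.DataFrame(
            {"mediator": list(errors), "error": list(errors.values())}
        )
        write_table(not_est, outdir / "mediation_not_estimable.tsv")
    write_table(table, outdir / "mediation.tsv")
    return table
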