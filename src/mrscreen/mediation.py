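"""Two-step mediation Mendelian randomization with mediation proportions.

For a putative mediator M on the path exposure -> M -> outcome:

* step 1 (``beta1``): univariable IVW of the mediator on the exposure's
  instruments — the causal effect of the exposure on the mediator;
* step 2 (``beta2``): multivariable IVW of the outcome on (mediator,
  exposure) over the union of both traits' instruments — the mediator's
  effect on the outcome conditional on the exposure;
* the total effect: univariable IVW of the outcome on the exposure's
  instruments.

The indirect effect is ``beta1 * beta2`` and the mediation proportion is
``indirect / total``, reported as a percentage truncated to [0, 100] (the
untruncated value is retained).  Its confidence interval comes from the
delta method with zero covariance across the three fits (they use
non-overlapping outcome data), or from a parametric bootstrap when
requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import Z95, ivw, mvmr_ivw, wald_ratio
from .instruments import harmonize, select_instruments


@dataclass
class MediationResult:
    mediator_name: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    proportion: float | None  # untruncated fraction of the total effect
    proportion_pct: float | None  # truncated to [0, 100]
    ci_low_pct: float | None
    ci_high_pct: float | None
    sign_consistent: bool = True
    extra: dict = field(default_factory=dict)


def proportion_mediated(
    beta1: float,
    beta2: float,
    total: float,
    var1: float = 0.0,
    var2: float = 0.0,
    var_total: float = 0.0,
):
    """Mediation proportion (as a fraction) and its delta-method variance.

    ``p = beta1 * beta2 / total``; the variance propagates the three
    independent uncertainties:
    ``var(p) = (b2/T)^2 v1 + (b1/T)^2 v2 + (b1 b2 / T^2)^2 vT``.
    """
    if total == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    p = beta1 * beta2 / total
    var = (
        (beta2 / total) ** 2 * var1
        + (beta1 / total) ** 2 * var2
        + (beta1 * beta2 / total**2) ** 2 * var_total
    )
    return p, var


def _truncate_pct(x: float) -> float:
    return float(min(max(x, 0.0), 100.0))


def mediate(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    ld=None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    clump_kb: float = 5000.0,
    palindromic_policy: str = "keep_if_eaf_informative",
    ci_method: str = "delta",
    n_boot: int = 1000,
    seed: int = 0,
    total_floor: float = 1e-6,
    mediator_name: str = "mediator",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> MediationResult:
    """Two-step mediation MR for one mediator.

    ``ci_method`` selects how the proportion's 95% CI is obtained:
    ``"delta"`` (default) or ``"bootstrap"`` (parametric, seeded).  When
    the absolute total effect is below ``total_floor`` the proportion is
    reported as undefined rather than an unstable ratio.
    """
    if ci_method not in ("delta", "bootstrap"):
        raise ValueError(f"ci_method must be 'delta' or 'bootstrap', got {ci_method!r}")
    kw = dict(p_threshold=p_threshold, r2_threshold=r2_threshold, clump_kb=clump_kb)

    exp_snps = select_instruments(exposure, ld, **kw)
    med_index = set(mediator["snp_id"])

    # total effect: exposure -> outcome
    set_total = harmonize(
        exposure, outcome, exp_snps, palindromic_policy,
        exposure_name=exposure_name, outcome_name=outcome_name,
    )
    est_total = ivw(set_total) if len(set_total) >= 2 else wald_ratio(set_total.instruments[0])

    # step 1: exposure -> mediator
    step1_snps = [s for s in exp_snps if s in med_index]
    set1 = harmonize(
        exposure, mediator, step1_snps, palindromic_policy,
        exposure_name=exposure_name, outcome_name=mediator_name,
    )
    est1 = ivw(set1) if len(set1) >= 2 else wald_ratio(set1.instruments[0])

    # step 2: outcome on (mediator, exposure), conditional coefficient of the mediator
    med_snps = select_instruments(mediator, ld, **kw)
    exp_index = set(exposure["snp_id"])
    union = sorted(set(exp_snps) | set(med_snps))
    union = [s for s in union if s in med_index and s in exp_index]
    set2 = harmonize(
        mediator, outcome, union, palindromic_policy, exposure2=exposure,
        exposure_name=mediator_name, outcome_name=outcome_name,
    )
    X = np.column_stack([set2.beta_exp, set2.beta_exp2])
    mv = mvmr_ivw(set2.beta_out, set2.se_out, X, exposure_names=[mediator_name, exposure_name])
    est2 = mv[0]

    beta1, beta2, total = est1.beta, est2.beta, est_total.beta
    indirect = beta1 * beta2
    extra = {
        "ci_method": ci_method,
        "n_snp_step1": est1.n_snp,
        "n_snp_step2": est2.n_snp,
        "n_snp_total": est_total.n_snp,
        "exposure_conditional_beta": mv[1].beta,
    }
    if abs(total) < total_floor:
        return MediationResult(
            mediator_name=mediator_name,
            beta1=beta1, se1=est1.se, beta2=beta2, se2=est2.se,
            total=total, se_total=est_total.se, indirect=indirect,
            proportion=None, proportion_pct=None, ci_low_pct=None, ci_high_pct=None,
            sign_consistent=True,
            extra={**extra, "note": f"|total| < {total_floor}; proportion undefined"},
        )

    p, var = proportion_mediated(beta1, beta2, total, est1.se**2, est2.se**2, est_total.se**2)
    if ci_method == "delta":
        se_p = float(np.sqrt(var))
        lo, hi = p - Z95 * se_p, p + Z95 * se_p
        extra["proportion_se_pct"] = se_p * 100.0
    else:
        rng = np.random.default_rng(seed)
        b1s = rng.normal(beta1, est1.se, n_boot)
        b2s = rng.normal(beta2, est2.se, n_boot)
        ts = rng.normal(total, est_total.se, n_boot)
        props = b1s * b2s / ts
        lo, hi = np.percentile(props, [2.5, 97.5])
        extra["n_boot"] = n_boot
        extra["seed"] = seed
    extra["ci_low_pct_untruncated"] = lo * 100.0
    extra["ci_high_pct_untruncated"] = hi * 100.0
    return MediationResult(
        mediator_name=mediator_name,
        beta1=beta1, se1=est1.se, beta2=beta2, se2=est2.se,
        total=total, se_total=est_total.se, indirect=indirect,
        proportion=p,
        proportion_pct=_truncate_pct(p * 100.0),
        ci_low_pct=_truncate_pct(lo * 100.0),
        ci_high_pct=_truncate_pct(hi * 100.0),
        sign_consistent=bool(np.sign(indirect) == np.sign(total)),
        extra=extra,
    )


def rank_mediators(results: list[MediationResult]) -> pd.DataFrame:
    """Ranked mediation report: descending point-estimate proportion, ties
    broken lexicographically by mediator name; undefined proportions sort
    last."""
    if not results:
        raise ValueError("no mediation results to rank")
    def key(r: MediationResult):
        defined = r.proportion is not None
        return (not defined, -(r.proportion_pct if defined else 0.0), r.mediator_name)
    ordered = sorted(results, key=key)
    return pd.DataFrame(
        {
            "mediator": [r.mediator_name for r in ordered],
            "beta1": [r.beta1 for r in ordered],
            "beta2": [r.beta2 for r in ordered],
            "total": [r.total for r in ordered],
            "indirect": [r.indirect for r in ordered],
            "proportion_pct": [r.proportion_pct for r in ordered],
            "ci_low_pct": [r.ci_low_pct for r in ordered],
            "ci_high_pct": [r.ci_high_pct for r in ordered],
            "sign_consistent": [r.sign_consistent for r in ordered],
        }
    )
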