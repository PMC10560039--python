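"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Covers Cochran's Q about the IVW or Egger fit, the MR-Egger intercept test
for directional pleiotropy, a simulation-based residual-sum-of-squares
outlier framework (global test, per-SNP outlier test with Bonferroni
correction, and a distortion test), leave-one-out influence analysis, and
the scatter / funnel tables behind the standard MR diagnostic plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, _egger_arrays, _finish, _ivw_arrays, egger, ivw, wald_ratios
from .instruments import InstrumentSet


@dataclass
class HeterogeneityStat:
    """Cochran's Q with its degrees of freedom and upper-tail chi-square p."""

    Q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """Output of the residual-sum-of-squares outlier framework."""

    global_rss_observed: float
    global_pval: float
    outlier_snps: list[tuple[str, float]]
    estimate_raw: MrEstimate
    estimate_corrected: MrEstimate
    distortion_pval: float | None
    n_sim: int
    seed: int


@dataclass
class LooSeries:
    """Leave-one-out IVW estimates with influence flags."""

    full: MrEstimate
    entries: list[tuple[str, MrEstimate]] = field(default_factory=list)
    #: snp_ids whose omission flips the sign of the estimate or moves it by
    #: more than one full-set standard error
    influential: list[str] = field(default_factory=list)


def cochran_q(iset: InstrumentSet, about: str = "ivw") -> HeterogeneityStat:
    """Heterogeneity of the per-SNP ratios about the pooled fit.

    ``about="ivw"``: Q = sum of ``w_j (b_j - beta_ivw)^2`` over the Wald
    ratios with ``w_j = 1/se(b_j)^2``, df = L - 1.  ``about="egger"``: the
    weighted residual sum of squares of the Egger fit, df = L - 2.
    """
    L = len(iset)
    if about == "ivw":
        if L < 2:
            raise ValueError("Q about IVW needs at least 2 instruments")
        b, sb = wald_ratios(iset)
        w = 1.0 / sb**2
        bhat = np.sum(w * b) / np.sum(w)
        q = float(np.sum(w * (b - bhat) ** 2))
        df = L - 1
    elif about == "egger":
        if L < 3:
            raise ValueError("Q about Egger needs at least 3 instruments")
        fit = _egger_arrays(iset.beta_exp, iset.beta_out, iset.se_out)
        q, df = fit["Q"], fit["df"]
    else:
        raise ValueError(f"about must be 'ivw' or 'egger', got {about!r}")
    return HeterogeneityStat(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(iset: InstrumentSet) -> tuple[float, float, float]:
    """MR-Egger intercept, its standard error, and a t-test p-value.

    A small p-value (conventionally < 0.05) indicates directional
    horizontal pleiotropy.
    """
    est = egger(iset)
    return (
        est.extra["egger_intercept"],
        est.extra["egger_intercept_se"],
        est.extra["egger_intercept_pval"],
    )


def _loo_slopes(x, y, w):
    """Leave-one-out zero-intercept WLS slopes, vectorized over the left-out SNP."""
    swxy = np.sum(w * x * y)
    swxx = np.sum(w * x * x)
    return (swxy - w * x * y) / (swxx - w * x * x)


def mr_presso(
    iset: InstrumentSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult | None:
    """Simulation-based pleiotropy-outlier detection and correction.

    Global test: the observed weighted residual sum of squares, each SNP's
    residual taken about the leave-one-out IVW slope, is compared with its
    null distribution built from ``n_sim`` parametric redraws
    ``beta_out_j* ~ Normal(slope_loo_j * beta_exp_j, se_out_j)``.  Empirical
    p-values use the add-one estimator, so the floor is ``1/(n_sim+1)``.

    Outlier test: each SNP's observed residual against its simulated
    distribution, Bonferroni-corrected across the L instruments; flagged
    outliers are removed and the IVW estimate recomputed.  Distortion test:
    the raw-vs-corrected difference compared with differences obtained by
    removing random subsets of the same size.

    Returns ``None`` (with a warning) below 4 instruments, mirroring how a
    screening pipeline skips inapplicable diagnostics rather than aborting.
    """
    L = len(iset)
    if L < 4:
        warnings.warn("outlier test needs at least 4 instruments; skipped", stacklevel=2)
        return None
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    x, y, so = iset.beta_exp, iset.beta_out, iset.se_out
    w = 1.0 / so**2
    slope_loo = _loo_slopes(x, y, w)
    resid = w * (y - slope_loo * x) ** 2
    rss_obs = float(resid.sum())

    rng = np.random.default_rng(seed)
    ystar = slope_loo * x + rng.standard_normal((n_sim, L)) * so
    swxy_s = ystar @ (w * x)
    swxx = np.sum(w * x * x)
    slope_s = (swxy_s[:, None] - (w * x) * ystar) / (swxx - w * x * x)
    resid_s = w * (ystar - slope_s * x) ** 2
    rss_s = resid_s.sum(axis=1)
    global_pval = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))

    p_out = (1 + np.sum(resid_s >= resid, axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(p_out * L, 1.0)
    out_mask = p_bonf < outlier_alpha
    outlier_snps = [
        (s, float(p)) for s, p, m in zip(iset.snp_ids, p_bonf, out_mask) if m
    ]

    raw = ivw(iset)
    n_out = int(out_mask.sum())
    if n_out and L - n_out >= 2:
        keep = [i for i, m in enumerate(out_mask) if not m]
        corrected = ivw(iset.subset(keep))
    else:
        if n_out:
            warnings.warn("too few non-outliers to re-estimate; corrected = raw", stacklevel=2)
        corrected = raw

    distortion_pval = None
    if n_out and L - n_out >= 2:
        obs_diff = abs(raw.beta - corrected.beta)
        diffs = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(L, size=n_out, replace=False)
            keep = np.setdiff1d(np.arange(L), drop)
            b_s, _, _ = _ivw_arrays(x[keep], y[keep], so[keep])
            diffs[s] = abs(raw.beta - b_s)
        distortion_pval = float((1 + np.sum(diffs >= obs_diff)) / (n_sim + 1))

    return PressoResult(
        global_rss_observed=rss_obs,
        global_pval=global_pval,
        outlier_snps=outlier_snps,
        estimate_raw=raw,
        estimate_corrected=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(iset: InstrumentSet, effects_model: str = "multiplicative_random") -> LooSeries:
    """IVW re-estimated with each instrument left out in turn."""
    L = len(iset)
    if L < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    full = ivw(iset, effects_model=effects_model)
    x, y, so = iset.beta_exp, iset.beta_out, iset.se_out
    entries = []
    influential = []
    for j in range(L):
        keep = np.arange(L) != j
        beta, se, q = _ivw_arrays(x[keep], y[keep], so[keep], effects_model)
        est = _finish("ivw", beta, se, L - 1, extra={"Q": q, "left_out": iset.snp_ids[j]})
        entries.append((iset.snp_ids[j], est))
        sign_change = np.sign(beta) != np.sign(full.beta) and full.beta != 0
        if sign_change or abs(beta - full.beta) > full.se:
            influential.append(iset.snp_ids[j])
    return LooSeries(full=full, entries=entries, influential=influential)


def plot_data(iset: InstrumentSet, results: list[MrEstimate] | None = None) -> dict[str, pd.DataFrame]:
    """Tables behind the scatter and funnel diagnostic plots.

    ``scatter``: per-SNP exposure and outcome effects with error bars;
    ``lines``: one fitted line per supplied estimate (Egger keeps its
    intercept, all other methods pass through the origin); ``funnel``:
    per-SNP ratio against its precision, with the IVW estimate as the
    vertical reference when available.
    """
    results = list(results or [])
    scatter = pd.DataFrame(
        {
            "snp_id": iset.snp_ids,
            "beta_exp": iset.beta_exp,
            "se_exp": iset.se_exp,
            "beta_out": iset.beta_out,
            "se_out": iset.se_out,
        }
    )
    lines = pd.DataFrame(
        {
            "method": [r.method for r in results],
            "slope": [r.beta for r in results],
            "intercept": [r.extra.get("egger_intercept", 0.0) for r in results],
        }
    )
    b, sb = wald_ratios(iset)
    ivw_beta = next((r.beta for r in results if r.method == "ivw"), float("nan"))
    funnel = pd.DataFrame(
        {
            "snp_id": iset.snp_ids,
            "ratio": b,
            "precision": 1.0 / sb,
            "ivw_beta": np.full(len(b), ivw_beta),
        }
    )
    return {"scatter": scatter, "lines": lines, "funnel": funnel}


def render_plots(iset: InstrumentSet, results, path_prefix) -> None:
    """Optional rendering convenience (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = plot_data(iset, results)
    sc, lines, fun = tables["scatter"], tables["lines"], tables["funnel"]
    fig, ax = plt.subplots()
    ax.errorbar(sc.beta_exp, sc.beta_out, xerr=sc.se_exp, yerr=sc.se_out, fmt="o", ms=3, lw=0.8)
    xs = np.linspace(min(0, sc.beta_exp.min()), sc.beta_exp.max(), 50)
    for row in lines.itertuples(index=False):
        ax.plot(xs, row.intercept + row.slope * xs, label=row.method)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    if len(lines):
        ax.legend(fontsize=7)
    fig.savefig(f"{path_prefix}_scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(fun.ratio, fun.precision, "o", ms=3)
    if np.isfinite(fun.ivw_beta.iloc[0]):
        ax.axvline(fun.ivw_beta.iloc[0], color="k", lw=0.8)
    ax.set_xlabel("per-SNP causal ratio")
    ax.set_ylabel("precision (1/se)")
    fig.savefig(f"{path_prefix}_funnel.png", dpi=120)
    plt.close(fig)
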