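"""Causal estimators for two-sample Mendelian randomization.

Implements the Wald ratio, inverse-variance-weighted (IVW) combination
with fixed or multiplicative random effects, MR-Egger regression, the
weighted median, kernel-based simple and weighted mode estimators, and
multivariable IVW for conditional effects of several exposures.

Conventions
-----------
* "Random-effect IVW" is the multiplicative random-effects model: the
  fixed-effect standard error is scaled by ``sqrt(max(Q / (L - 1), 1))``
  where Q is Cochran's statistic — the dominant convention in two-sample
  MR software.
* Wald-ratio standard errors use the first-order delta approximation
  ``se_out / |beta_exp|`` (which makes IVW coincide exactly with
  weighted-least-squares through the origin); a second-order option is
  available where per-ratio uncertainty is consumed directly.
* MR-Egger is fit after orienting every instrument so its exposure effect
  is positive; slope and intercept p-values use a t distribution with
  L - 2 degrees of freedom.
* Weighted-median and mode standard errors come from a seeded parametric
  bootstrap over the per-SNP ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import SingularDesignError, UndefinedRatioError
from .instruments import HarmonizedInstrument, InstrumentSet

Z95 = float(stats.norm.ppf(0.975))

#: minimum instrument count per method
MIN_SNPS = {
    "wald_ratio": 1,
    "ivw": 2,
    "egger": 3,
    "weighted_median": 3,
    "simple_mode": 3,
    "weighted_mode": 3,
}

SCREEN_METHODS = ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]


@dataclass
class MrEstimate:
    """One method's causal estimate with normal- or t-theory uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)


def _finish(method, beta, se, n_snp, df=None, extra=None) -> MrEstimate:
    beta, se = float(beta), float(se)
    if df is not None:
        crit = float(stats.t.ppf(0.975, df))
        pval = 2.0 * float(stats.t.sf(abs(beta / se), df)) if se > 0 else 0.0
    else:
        crit = Z95
        pval = 2.0 * float(stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MrEstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - crit * se,
        ci_high=beta + crit * se,
        pval=min(pval, 1.0),
        n_snp=int(n_snp),
        extra=dict(extra or {}),
    )


def wald_ratios(iset: InstrumentSet, second_order: bool = False):
    """Per-SNP causal ratios and their delta-method standard errors."""
    x, y = iset.beta_exp, iset.beta_out
    if np.any(x == 0):
        bad = [s for s, b in zip(iset.snp_ids, x) if b == 0]
        raise UndefinedRatioError(f"zero exposure beta for {bad}; Wald ratio undefined")
    b = y / x
    se = iset.se_out / np.abs(x)
    if second_order:
        se = np.sqrt(iset.se_out**2 / x**2 + y**2 * iset.se_exp**2 / x**4)
    return b, se


def wald_ratio(inst: HarmonizedInstrument) -> MrEstimate:
    """Single-instrument causal estimate ``beta_out / beta_exp``."""
    if inst.beta_exp == 0:
        raise UndefinedRatioError(f"{inst.snp_id}: zero exposure beta; Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return _finish("wald_ratio", beta, se, 1)


def _ivw_arrays(x, y, se_out, effects_model="multiplicative_random"):
    """Core IVW fit on arrays; returns (beta, se, Q)."""
    w = 1.0 / se_out**2
    sxx = np.sum(w * x * x)
    beta = np.sum(w * x * y) / sxx
    var_fixed = 1.0 / sxx
    q = float(np.sum(w * (y - beta * x) ** 2))
    if effects_model == "multiplicative_random":
        scale2 = max(q / (len(x) - 1), 1.0) if len(x) > 1 else 1.0
        se = np.sqrt(var_fixed * scale2)
    elif effects_model == "fixed":
        se = np.sqrt(var_fixed)
    else:
        raise ValueError(f"unknown effects_model {effects_model!r}")
    return float(beta), float(se), q


def ivw(iset: InstrumentSet, effects_model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted combination of the per-SNP Wald ratios.

    Equivalent to a zero-intercept regression of outcome betas on exposure
    betas weighted by ``1 / se_out^2``.
    """
    L = len(iset)
    if L < 2:
        raise ValueError("IVW needs at least 2 instruments; use wald_ratio for a single SNP")
    beta, se, q = _ivw_arrays(iset.beta_exp, iset.beta_out, iset.se_out, effects_model)
    return _finish("ivw", beta, se, L, extra={"Q": q, "effects_model": effects_model})


def _egger_arrays(x, y, se_out):
    """Oriented two-parameter WLS; returns dict of slope/intercept fit."""
    sgn = np.where(x >= 0, 1.0, -1.0)
    xa, ya = np.abs(x), sgn * y
    if np.ptp(xa) == 0:
        raise SingularDesignError("all exposure betas identical; Egger slope not identified")
    w = 1.0 / se_out**2
    sw, swx, swxx = np.sum(w), np.sum(w * xa), np.sum(w * xa * xa)
    swy, swxy = np.sum(w * ya), np.sum(w * xa * ya)
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    L = len(x)
    q = float(np.sum(w * (ya - intercept - slope * xa) ** 2))
    scale2 = max(q / (L - 2), 1.0)
    var_slope = sw / det * scale2
    var_int = swxx / det * scale2
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "se_slope": float(np.sqrt(var_slope)),
        "se_intercept": float(np.sqrt(var_int)),
        "Q": q,
        "df": L - 2,
    }


def egger(iset: InstrumentSet) -> MrEstimate:
    """MR-Egger regression: slope is the causal estimate, intercept the
    average directional pleiotropy.

    Instruments are oriented so all exposure betas are positive before the
    weighted fit (weights ``1 / se_out^2``); standard errors carry the
    multiplicative scaling ``sqrt(max(Q / (L - 2), 1))`` and p-values use a
    t distribution with L - 2 degrees of freedom.
    """
    L = len(iset)
    if L < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    fit = _egger_arrays(iset.beta_exp, iset.beta_out, iset.se_out)
    df = fit["df"]
    ip = 2.0 * float(stats.t.sf(abs(fit["intercept"] / fit["se_intercept"]), df))
    return _finish(
        "egger",
        fit["slope"],
        fit["se_slope"],
        L,
        df=df,
        extra={
            "egger_intercept": fit["intercept"],
            "egger_intercept_se": fit["se_intercept"],
            "egger_intercept_pval": min(ip, 1.0),
            "Q": fit["Q"],
        },
    )


def _weighted_median_1d(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    bs, ws = b[order], w[order]
    wn = ws / ws.sum()
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(bs[0])
    if 0.5 >= s[-1]:
        return float(bs[-1])
    j = int(np.searchsorted(s, 0.5))
    return float(bs[j - 1] + (bs[j] - bs[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))


def _weighted_median_rows(B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of B (n_rows x L) with shared weights."""
    order = np.argsort(B, axis=1, kind="stable")
    Bs = np.take_along_axis(B, order, axis=1)
    Ws = w[order]
    Wn = Ws / Ws.sum(axis=1, keepdims=True)
    S = np.cumsum(Wn, axis=1) - Wn / 2.0
    out = np.empty(B.shape[0])
    for i in range(B.shape[0]):
        s, bs = S[i], Bs[i]
        if 0.5 <= s[0]:
            out[i] = bs[0]
        elif 0.5 >= s[-1]:
            out[i] = bs[-1]
        else:
            j = int(np.searchsorted(s, 0.5))
            out[i] = bs[j - 1] + (bs[j] - bs[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1])
    return out


def weighted_median(iset: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted-median estimator over the per-SNP ratios.

    The estimate interpolates the inverse-variance-weighted empirical CDF
    of the ordered ratios at cumulative weight 1/2; the standard error is
    the SD of the estimate over a seeded parametric bootstrap that redraws
    each ratio from ``Normal(b_j, se_j)``.
    """
    L = len(iset)
    if L < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    b, sb = wald_ratios(iset)
    w = 1.0 / sb**2
    est = _weighted_median_1d(b, w)
    rng = np.random.default_rng(seed)
    B = b + rng.standard_normal((n_boot, L)) * sb
    se = float(np.std(_weighted_median_rows(B, w), ddof=1))
    return _finish("weighted_median", est, se, L, extra={"n_boot": n_boot, "seed": seed})


def _mode_bandwidth(b: np.ndarray, factor: float) -> float:
    sd = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    mad = float(np.median(np.abs(b - np.median(b)))) / 0.6745
    spread = [s for s in (sd, mad) if s > 0]
    if not spread:
        return 0.0
    return factor * 1.06 * min(spread) * len(b) ** (-1.0 / 5.0)


def _kde_mode(b: np.ndarray, w: np.ndarray, h: float, gridsize: int = 4096) -> float:
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, gridsize)
    dens = w @ np.exp(-0.5 * ((grid[None, :] - b[:, None]) / h) ** 2)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    iset: InstrumentSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Mode-based estimate: the maximum of a Gaussian kernel density over
    the per-SNP ratios (inverse-variance weights for the weighted mode,
    uniform for the simple mode).

    The bandwidth is ``bandwidth_factor * 1.06 * min(SD, MAD/0.6745) *
    L^(-1/5)`` over the ratio set; if all ratios coincide, that common
    value is returned.  Standard errors come from a seeded parametric
    bootstrap with the bandwidth held at its observed value.
    """
    L = len(iset)
    if L < 3:
        raise ValueError("mode estimators need at least 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    b, sb = wald_ratios(iset)
    w = 1.0 / sb**2 if weighted else np.full(L, 1.0 / L)
    w = w / w.sum()
    h = _mode_bandwidth(b, bandwidth_factor)
    method = "weighted_mode" if weighted else "simple_mode"
    rng = np.random.default_rng(seed)
    B = b + rng.standard_normal((n_boot, L)) * sb
    if h == 0.0:
        est = float(b[0])
        reps = np.array([_kde_mode(B[i], w, hb) if (hb := _mode_bandwidth(B[i], bandwidth_factor)) > 0 else B[i, 0] for i in range(n_boot)])
    else:
        est = _kde_mode(b, w, h)
        reps = np.array([_kde_mode(B[i], w, h, gridsize=1024) for i in range(n_boot)])
    se = float(np.std(reps, ddof=1))
    return _finish(
        method, est, se, L, extra={"bandwidth": h, "n_boot": n_boot, "seed": seed}
    )


def mvmr_ivw(
    outcome_betas,
    outcome_ses,
    exposure_beta_matrix,
    exposure_names=None,
) -> list[MrEstimate]:
    """Multivariable IVW: conditional causal estimate for each exposure.

    Zero-intercept regression of outcome betas on the L x k matrix of
    exposure betas, weighted by ``1 / se_out^2``, with multiplicative
    random-effects scaling ``sqrt(max(Q / (L - k), 1))``.

    Exposures whose beta column is exactly zero carry no information and
    are excluded from the fit (their estimate is returned as NaN); genuine
    collinearity among informative columns raises
    :class:`~mrscreen.errors.SingularDesignError`.
    """
    y = np.asarray(outcome_betas, dtype=float)
    so = np.asarray(outcome_ses, dtype=float)
    X = np.asarray(exposure_beta_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    L, k = X.shape
    if exposure_names is None:
        exposure_names = [f"exposure_{i + 1}" for i in range(k)]
    if L < k + 2:
        raise ValueError(f"multivariable IVW needs at least {k + 2} SNPs for {k} exposures, got {L}")

    zero_cols = np.all(X == 0, axis=0)
    active = ~zero_cols
    Xa = X[:, active]
    ka = Xa.shape[1]
    results: list[MrEstimate | None] = [None] * k
    if ka:
        if np.linalg.matrix_rank(Xa) < ka:
            names = [n for n, a in zip(exposure_names, active) if a]
            corr = np.corrcoef(Xa, rowvar=False)
            pairs = [
                f"{names[i]}~{names[j]}"
                for i in range(ka)
                for j in range(i + 1, ka)
                if abs(corr[i, j]) > 0.999
            ]
            raise SingularDesignError(
                "exposure beta matrix is rank deficient"
                + (f"; collinear columns: {', '.join(pairs)}" if pairs else "")
            )
        w = 1.0 / so**2
        A = Xa.T @ (w[:, None] * Xa)
        bhat = np.linalg.solve(A, Xa.T @ (w * y))
        cov = np.linalg.inv(A)
        q = float(np.sum(w * (y - Xa @ bhat) ** 2))
        scale2 = max(q / (L - ka), 1.0) if L > ka else 1.0
        j = 0
        for i in range(k):
            if not active[i]:
                continue
            se = float(np.sqrt(cov[j, j] * scale2))
            results[i] = _finish(
                "mvmr_ivw", bhat[j], se, L, extra={"exposure": exposure_names[i], "Q": q}
            )
            j += 1
    for i in range(k):
        if results[i] is None:
            results[i] = MrEstimate(
                method="mvmr_ivw",
                beta=float("nan"),
                se=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                pval=float("nan"),
                n_snp=L,
                extra={"exposure": exposure_names[i], "note": "all-zero beta column; not identified"},
            )
    return results


def estimate_all(
    iset: InstrumentSet,
    methods=None,
    n_boot: int = 1000,
    seed: int = 0,
    effects_model: str = "multiplicative_random",
    bandwidth_factor: float = 1.0,
) -> dict[str, MrEstimate | None]:
    """Run every applicable estimator; methods below their minimum SNP count
    are reported as ``None`` (not-applicable).

    A single-instrument set falls back to the Wald ratio under the key
    ``"wald_ratio"``.
    """
    L = len(iset)
    methods = list(methods) if methods is not None else list(SCREEN_METHODS)
    out: dict[str, MrEstimate | None] = {}
    if L == 1 and "ivw" in methods:
        out["wald_ratio"] = wald_ratio(iset.instruments[0])
    for m in methods:
        if L < MIN_SNPS.get(m, 2):
            out[m] = None
            continue
        if m == "ivw":
            out[m] = ivw(iset, effects_model=effects_model)
        elif m == "egger":
            out[m] = egger(iset)
        elif m == "weighted_median":
            out[m] = weighted_median(iset, n_boot=n_boot, seed=seed)
        elif m == "simple_mode":
            out[m] = mode_estimate(
                iset, weighted=False, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
            )
        elif m == "weighted_mode":
            out[m] = mode_estimate(
                iset, weighted=True, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
            )
        else:
            raise ValueError(f"unknown method {m!r}")
    return out
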