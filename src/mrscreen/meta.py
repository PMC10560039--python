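"""Fixed-effect inverse-variance meta-analysis across cohorts.

Combines per-cohort IVW causal estimates (e.g. a discovery and a
replication biobank) into a single estimate, and reports cross-cohort
Cochran's Q as a consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import Z95, MrEstimate
from .sensitivity import HeterogeneityStat


@dataclass
class MetaEstimate:
    beta_meta: float
    se_meta: float
    ci_low: float
    ci_high: float
    pval: float
    inputs: list[tuple[str, float, float]]
    heterogeneity: HeterogeneityStat | None


def meta_fixed(estimates) -> MetaEstimate:
    """Fixed-effect meta-analysis of ``(label, beta, se)`` inputs.

    ``beta_meta = sum(b_i / se_i^2) / sum(1 / se_i^2)`` and
    ``se_meta = 1 / sqrt(sum(1 / se_i^2))``.  Inputs may also be bare
    ``(beta, se)`` pairs or :class:`~mrscreen.estimators.MrEstimate`
    objects.
    """
    inputs: list[tuple[str, float, float]] = []
    for i, est in enumerate(estimates):
        if isinstance(est, MrEstimate):
            inputs.append((f"input_{i + 1}", est.beta, est.se))
        elif len(est) == 3:
            inputs.append((str(est[0]), float(est[1]), float(est[2])))
        else:
            inputs.append((f"input_{i + 1}", float(est[0]), float(est[1])))
    if not inputs:
        raise ValueError("meta_fixed needs at least one estimate")
    b = np.array([v[1] for v in inputs])
    se = np.array([v[2] for v in inputs])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    pval = min(2.0 * float(stats.norm.sf(abs(beta / se_meta))), 1.0)
    het = None
    if len(inputs) >= 2:
        q = float(np.sum(w * (b - beta) ** 2))
        df = len(inputs) - 1
        het = HeterogeneityStat(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))
    return MetaEstimate(
        beta_meta=beta,
        se_meta=se_meta,
        ci_low=beta - Z95 * se_meta,
        ci_high=beta + Z95 * se_meta,
        pval=pval,
        inputs=inputs,
        heterogeneity=het,
    )
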