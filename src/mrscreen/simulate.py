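"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of biobank-scale GWAS
summary data used in two-sample Mendelian randomization: a set of true
instrument SNPs with normally distributed effects on the exposure, LD
blocks of correlated tag and null SNPs, outcome effects produced under a
configurable causal effect with optional balanced or directional
pleiotropy, an optional mediator chain for two-step mediation MR, and one
or two outcome cohorts with independent sampling noise.

Effect scales
-------------
All effects are per-allele on a standardized-trait (or log-odds) scale.
Standard errors follow standard GWAS sampling theory for a standardized
continuous trait, ``se = 1 / sqrt(2 * eaf * (1 - eaf) * n)``; binary
outcomes are approximated on the log-odds scale with the same formula.

Instrument effects default to ``Normal(0, 0.03)`` which at the default
exposure sample size of 300,000 gives a median per-SNP F statistic of
roughly 50 — the middle of the range seen for strong polygenic instruments
in biobank GWAS.

Directional pleiotropy is defined in the *exposure-increasing* orientation:
the per-SNP direct effect has the configured nonzero mean after aligning
every instrument so that its exposure effect is positive.  This is the
standard construction under which the InSIDE assumption holds and the
inverse-variance-weighted estimator is biased while MR-Egger is not.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import LD_COLUMNS, SSF_COLUMNS

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]

_PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass(frozen=True)
class MediatorSpec:
    """Generating coefficients for a single mediator chain.

    ``beta_exp_med`` is the causal effect of the exposure on the mediator
    (the first-step coefficient), ``beta_med_out`` the effect of the
    mediator on the outcome conditional on the exposure (the second-step
    coefficient), and ``beta_direct`` the direct exposure-to-outcome effect
    not through the mediator.  The generating total effect is
    ``beta_direct + beta_exp_med * beta_med_out`` and the generating
    mediation proportion is the indirect share of that total.

    The mediator receives its own independent instruments (``n_instruments``
    SNPs with direct mediator effects) so that multivariable MR of the
    outcome on (mediator, exposure) is identified.
    """

    beta_exp_med: float
    beta_med_out: float
    beta_direct: float
    n_instruments: int = 100
    n_gwas: int = 300_000


@dataclass
class SimConfig:
    """Configuration of one synthetic two-sample GWAS experiment.

    Parameters
    ----------
    n_instruments : int
        True instrument SNPs for the exposure.
    n_null_snps : int
        SNPs with no effect on any trait.
    ld_block_size : int
        SNPs per LD block.  Instrument SNPs head their own blocks and are
        accompanied by ``ld_block_size - 1`` tag SNPs whose marginal
        effects are attenuated by sqrt(r2); null SNPs fill blocks of the
        same size.
    within_block_r2 : float
        Pairwise LD r2 inside a block (exchangeable structure).
    causal_effect : float
        True effect of the exposure on the outcome (ignored when
        ``mediator_spec`` is given; the chain coefficients then define the
        total effect).
    pleiotropy_mode : {"none", "balanced", "directional"}
        Per-SNP direct (pleiotropic) effects on the outcome: exactly zero,
        zero-mean normal, or normal with nonzero mean in the
        exposure-increasing orientation.
    pleiotropy_sd, pleiotropy_mean : float
        Scale and (directional) location of per-SNP direct effects.
    mediator_spec : MediatorSpec, optional
        Adds a mediator GWAS and mediator-specific instruments.
    n_exposure, n_outcome : int (or tuple for per-cohort outcome sizes)
        GWAS sample sizes.
    n_cohorts : int
        1 or 2 outcome cohorts; cohorts share true effects but draw
        independent sampling noise.
    gamma_sd : float
        SD of true instrument effects on the exposure.
    palindromic_rate : float
        Fraction of SNPs assigned A/T or C/G alleles, to exercise
        harmonization policies.
    allele_swap_rate : float
        Fraction of outcome/mediator records stored with effect and other
        allele swapped (and beta negated), to exercise harmonization.
    seed : int
        RNG seed for the generating truth (and for noise unless
        ``noise_seed`` is given).
    noise_seed : int, optional
        Separate seed for sampling noise, letting callers redraw noise
        around a fixed truth.
    """

    n_instruments: int = 100
    n_null_snps: int = 200
    ld_block_size: int = 4
    within_block_r2: float = 0.3
    causal_effect: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.002
    pleiotropy_mean: float = 0.0
    mediator_spec: MediatorSpec | None = None
    n_exposure: int = 300_000
    n_outcome: int | tuple = 300_000
    n_cohorts: int = 1
    gamma_sd: float = 0.03
    palindromic_rate: float = 0.10
    allele_swap_rate: float = 0.20
    seed: int = 0
    noise_seed: int | None = None

    def outcome_sizes(self) -> list[int]:
        if isinstance(self.n_outcome, (tuple, list)):
            sizes = [int(v) for v in self.n_outcome]
            if len(sizes) != self.n_cohorts:
                raise ConfigError(
                    f"n_outcome: got {len(sizes)} sizes for {self.n_cohorts} cohorts"
                )
            return sizes
        return [int(self.n_outcome)] * self.n_cohorts

    def validate(self) -> None:
        def _count(name, value, minimum=0):
            if not isinstance(value, (int, np.integer)) or value < minimum:
                raise ConfigError(f"{name}: must be an integer >= {minimum}, got {value!r}")

        _count("n_instruments", self.n_instruments)
        _count("n_null_snps", self.n_null_snps)
        _count("ld_block_size", self.ld_block_size, minimum=1)
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ConfigError(f"within_block_r2: must lie in [0, 1], got {self.within_block_r2!r}")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ConfigError(
                f"pleiotropy_mode: must be one of {_PLEIOTROPY_MODES}, got {self.pleiotropy_mode!r}"
            )
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0.0:
            raise ConfigError("pleiotropy_mean: must be 0 when pleiotropy_mode='balanced'")
        if self.pleiotropy_sd < 0:
            raise ConfigError(f"pleiotropy_sd: must be >= 0, got {self.pleiotropy_sd!r}")
        if self.n_exposure < 2:
            raise ConfigError(f"n_exposure: sample size must be >= 2, got {self.n_exposure!r}")
        for i, n in enumerate(self.outcome_sizes()):
            if n < 2:
                raise ConfigError(f"n_outcome: cohort {i} sample size must be >= 2, got {n!r}")
        if self.n_cohorts not in (1, 2):
            raise ConfigError(f"n_cohorts: must be 1 or 2, got {self.n_cohorts!r}")
        if self.gamma_sd <= 0:
            raise ConfigError(f"gamma_sd: must be > 0, got {self.gamma_sd!r}")
        for name in ("palindromic_rate", "allele_swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1], got {v!r}")
        med = self.mediator_spec
        if med is not None:
            if med.n_instruments < 0:
                raise ConfigError("mediator_spec.n_instruments: must be >= 0")
            if med.n_gwas < 2:
                raise ConfigError("mediator_spec.n_gwas: sample size must be >= 2")


@dataclass
class SimTruth:
    """Generating ground truth of one simulated dataset."""

    causal_effect: float
    per_snp_gamma: np.ndarray
    per_snp_alpha: np.ndarray
    true_mediation_proportion: float | None
    seed: int
    instrument_ids: list[str] = field(default_factory=list)
    mediator_instrument_ids: list[str] = field(default_factory=list)
    #: true marginal effect on the outcome for every SNP in table order
    per_snp_outcome_effect: np.ndarray | None = None


@dataclass
class SimResult:
    exposure: pd.DataFrame
    outcomes: list[pd.DataFrame]
    mediator: pd.DataFrame | None
    truth: SimTruth
    ld: pd.DataFrame


def _assoc_table(snp_id, chrom, pos, ea, oa, eaf, true_beta, n, rng, swap_rate):
    """One marginal GWAS table: truth + sampling noise, optional allele swaps."""
    m = len(snp_id)
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    beta = true_beta + rng.standard_normal(m) * se
    swap = rng.random(m) < swap_rate
    ea_out = np.where(swap, oa, ea)
    oa_out = np.where(swap, ea, oa)
    eaf_out = np.where(swap, 1.0 - eaf, eaf)
    beta_out = np.where(swap, -beta, beta)
    z = np.abs(beta / se)
    pval = np.clip(2.0 * stats.norm.sf(z), np.nextafter(0.0, 1.0), 1.0)
    return pd.DataFrame(
        {
            "snp_id": snp_id,
            "chr": chrom,
            "pos": pos,
            "effect_allele": ea_out,
            "other_allele": oa_out,
            "eaf": eaf_out,
            "beta": beta_out,
            "se": se,
            "pval": pval,
            "n": np.full(m, int(n)),
        },
        columns=SSF_COLUMNS,
    )


def simulate_summary_stats(config: SimConfig) -> SimResult:
    """Generate exposure, outcome (and optional mediator) summary statistics.

    Returns a :class:`SimResult` holding one exposure table, one outcome
    table per cohort, an optional mediator table, the generating
    :class:`SimTruth`, and a pairwise within-block LD table.  Identical
    ``(config, seed)`` reproduce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    nseed = config.noise_seed if config.noise_seed is not None else config.seed
    noise_rng = np.random.default_rng([int(nseed), 1])

    med = config.mediator_spec
    bs = config.ld_block_size
    n_exp_inst = config.n_instruments
    n_med_inst = med.n_instruments if med is not None else 0
    r_tag = math.sqrt(config.within_block_r2)

    # Block layout: one block per instrument (exposure then mediator), then
    # null SNPs packed into blocks of the same size.
    sizes = [bs] * (n_exp_inst + n_med_inst)
    roles = ["exp"] * n_exp_inst + ["med"] * n_med_inst
    remaining = config.n_null_snps
    while remaining > 0:
        take = min(bs, remaining)
        sizes.append(take)
        roles.append("null")
        remaining -= take
    n_blocks = len(sizes)
    total = int(sum(sizes))

    block_of = np.repeat(np.arange(n_blocks), sizes)
    within = np.concatenate([np.arange(s) for s in sizes]) if n_blocks else np.array([], int)
    is_head = within == 0

    # --- generating truth -------------------------------------------------
    gamma_head = np.zeros(n_blocks)
    delta_head = np.zeros(n_blocks)
    alpha_head = np.zeros(n_blocks)
    exp_blocks = np.array([ro == "exp" for ro in roles])
    med_blocks = np.array([ro == "med" for ro in roles])
    gamma_head[exp_blocks] = rng.normal(0.0, config.gamma_sd, n_exp_inst)
    if n_med_inst:
        delta_head[med_blocks] = rng.normal(0.0, config.gamma_sd, n_med_inst)
    if config.pleiotropy_mode == "balanced":
        alpha_head[exp_blocks] = rng.normal(0.0, config.pleiotropy_sd, n_exp_inst)
    elif config.pleiotropy_mode == "directional":
        oriented = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n_exp_inst)
        sign = np.where(gamma_head[exp_blocks] >= 0, 1.0, -1.0)
        alpha_head[exp_blocks] = sign * oriented

    attn = np.where(is_head, 1.0, r_tag)
    g = attn * gamma_head[block_of]  # SNP -> exposure
    d = attn * delta_head[block_of]  # SNP -> mediator (direct)
    a = attn * alpha_head[block_of]  # SNP -> outcome (direct, pleiotropic)

    if med is not None:
        m_true = med.beta_exp_med * g + d
        o_true = med.beta_direct * g + med.beta_med_out * m_true + a
        total_effect = med.beta_direct + med.beta_exp_med * med.beta_med_out
        indirect = med.beta_exp_med * med.beta_med_out
        prop = indirect / total_effect if total_effect != 0 else None
    else:
        m_true = None
        o_true = config.causal_effect * g + a
        total_effect = config.causal_effect
        prop = None

    # --- SNP metadata -----------------------------------------------------
    eaf = rng.uniform(0.05, 0.95, total)
    pal = rng.random(total) < config.palindromic_rate
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), total)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), total)
    pal_pairs = np.array(_PALINDROMIC_PAIRS)
    non_pairs = np.array(_NONPALINDROMIC_PAIRS)
    ea = np.where(pal, pal_pairs[pal_idx, 0], non_pairs[non_idx, 0])
    oa = np.where(pal, pal_pairs[pal_idx, 1], non_pairs[non_idx, 1])

    block_ids = np.arange(n_blocks)
    chrom_of_block = (block_ids % 22) + 1
    start_of_block = 1_000_000 + (block_ids // 22) * 20_000_000
    chrom = chrom_of_block[block_of].astype(str)
    pos = start_of_block[block_of] + within * 1000
    snp_id = np.array([f"rs{1000000 + i}" for i in range(total)])

    # --- observed tables --------------------------------------------------
    exposure = _assoc_table(snp_id, chrom, pos, ea, oa, eaf, g, config.n_exposure, noise_rng, 0.0)
    outcomes = [
        _assoc_table(snp_id, chrom, pos, ea, oa, eaf, o_true, n_c, noise_rng, config.allele_swap_rate)
        for n_c in config.outcome_sizes()
    ]
    mediator = None
    if med is not None:
        mediator = _assoc_table(
            snp_id, chrom, pos, ea, oa, eaf, m_true, med.n_gwas, noise_rng, config.allele_swap_rate
        )

    # --- LD table: all within-block pairs --------------------------------
    pa, pb = [], []
    offset = 0
    for s in sizes:
        for i, j in itertools.combinations(range(s), 2):
            pa.append(offset + i)
            pb.append(offset + j)
        offset += s
    ld = pd.DataFrame(
        {
            "snp_a": snp_id[pa] if pa else np.array([], dtype=str),
            "snp_b": snp_id[pb] if pb else np.array([], dtype=str),
            "r2": np.full(len(pa), config.within_block_r2),
        },
        columns=LD_COLUMNS,
    )

    head_mask_exp = is_head & exp_blocks[block_of]
    head_mask_med = is_head & med_blocks[block_of]
    truth = SimTruth(
        causal_effect=total_effect,
        per_snp_gamma=gamma_head[exp_blocks].copy(),
        per_snp_alpha=alpha_head[exp_blocks].copy(),
        true_mediation_proportion=prop,
        seed=config.seed,
        instrument_ids=list(snp_id[head_mask_exp]),
        mediator_instrument_ids=list(snp_id[head_mask_med]),
        per_snp_outcome_effect=o_true.copy(),
    )
    return SimResult(exposure=exposure, outcomes=outcomes, mediator=mediator, truth=truth, ld=ld)
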