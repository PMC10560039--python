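import numpy as np
import pytest

from mrscreen.instruments import HarmonizedInstrument, InstrumentSet
from mrscreen.simulate import SimConfig, simulate_summary_stats


def build_iset(beta_exp, se_exp, beta_out, se_out, eaf=None, snp_ids=None, beta_exp2=None, se_exp2=None):
    """Construct an InstrumentSet directly from effect arrays."""
    L = len(beta_exp)
    eaf = eaf if eaf is not None else [0.3] * L
    snp_ids = snp_ids if snp_ids is not None else [f"rs{i}" for i in range(L)]
    inst = []
    for i in range(L):
        kwargs = {}
        if beta_exp2 is not None:
            kwargs = {"beta_exp2": float(beta_exp2[i]), "se_exp2": float(se_exp2[i])}
        inst.append(
            HarmonizedInstrument(
                snp_id=snp_ids[i],
                beta_exp=float(beta_exp[i]),
                se_exp=float(se_exp[i]),
                beta_out=float(beta_out[i]),
                se_out=float(se_out[i]),
                eaf=float(eaf[i]),
                **kwargs,
            )
        )
    return InstrumentSet(inst)


@pytest.fixture
def make_iset():
    return build_iset


def clean_sim_iset(n_instruments, causal_effect, seed, n=300_000, pleiotropy_mode="none",
                   pleiotropy_sd=0.002, pleiotropy_mean=0.0, gamma_sd=0.03):
    """Simulate instruments only (no LD, no allele swaps) and pair exposure
    with outcome on their shared orientation."""
    cfg = SimConfig(
        n_instruments=n_instruments,
        n_null_snps=0,
        ld_block_size=1,
        causal_effect=causal_effect,
        pleiotropy_mode=pleiotropy_mode,
        pleiotropy_sd=pleiotropy_sd,
        pleiotropy_mean=pleiotropy_mean,
        n_exposure=n,
        n_outcome=n,
        palindromic_rate=0.0,
        allele_swap_rate=0.0,
        gamma_sd=gamma_sd,
        seed=seed,
    )
    res = simulate_summary_stats(cfg)
    return InstrumentSet.from_frames(res.exposure, res.outcomes[0]), res.truth


@pytest.fixture
def sim_iset():
    return clean_sim_iset


def random_iset(rng, L=20):
    """A random, well-conditioned instrument set for oracle comparisons."""
    beta_exp = rng.normal(0.05, 0.03, L)
    beta_exp[np.abs(beta_exp) < 1e-3] = 0.01
    se_exp = rng.uniform(0.002, 0.01, L)
    beta_out = rng.normal(0.0, 0.02, L)
    se_out = rng.uniform(0.002, 0.01, L)
    return build_iset(beta_exp, se_exp, beta_out, se_out)
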