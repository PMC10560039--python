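"""Instrument selection, allele harmonization and instrument diagnostics.

Instruments are selected from exposure summary statistics at a genome-wide
significance threshold (default p < 5e-8) and pruned for linkage
disequilibrium by greedy clumping (default r2 < 0.01 within a 5,000 kb
window).  Exposure and outcome effects are then aligned onto a common
effect allele, with a configurable policy for strand-ambiguous
(palindromic, A/T or C/G) variants.  Per-instrument strength is summarized
by the F statistic ``beta^2 / se^2`` and the explained variance
``2 * eaf * (1 - eaf) * beta^2`` on the standardized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .errors import HarmonizationWarning, WeakInstrumentWarning
from .io import ld_lookup

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROMIC_POLICIES = ("drop", "keep_if_eaf_informative", "keep_all")

#: effect-allele-frequency band within which a palindromic SNP's strand
#: cannot be inferred from frequency
AMBIGUOUS_EAF_BAND = (0.42, 0.58)


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


@dataclass
class HarmonizedInstrument:
    """One instrument with exposure and outcome effects on a shared effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float
    beta_exp2: float | None = None
    se_exp2: float | None = None
    flipped: bool = False
    palindromic_kept: bool = False
    proxy: bool = False

    def __post_init__(self):
        if self.se_exp <= 0:
            raise ValueError(f"{self.snp_id}: se_exp must be > 0")
        if self.se_out <= 0:
            raise ValueError(f"{self.snp_id}: se_out must be > 0")


@dataclass
class InstrumentSet:
    """An ordered collection of harmonized instruments with its selection log."""

    instruments: list[HarmonizedInstrument]
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)
    thresholds: tuple | None = None

    def __len__(self) -> int:
        return len(self.instruments)

    @cached_property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    @cached_property
    def beta_exp(self) -> np.ndarray:
        return np.array([i.beta_exp for i in self.instruments], dtype=float)

    @cached_property
    def se_exp(self) -> np.ndarray:
        return np.array([i.se_exp for i in self.instruments], dtype=float)

    @cached_property
    def beta_out(self) -> np.ndarray:
        return np.array([i.beta_out for i in self.instruments], dtype=float)

    @cached_property
    def se_out(self) -> np.ndarray:
        return np.array([i.se_out for i in self.instruments], dtype=float)

    @cached_property
    def beta_exp2(self) -> np.ndarray | None:
        vals = [i.beta_exp2 for i in self.instruments]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    @cached_property
    def se_exp2(self) -> np.ndarray | None:
        vals = [i.se_exp2 for i in self.instruments]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    @cached_property
    def eaf(self) -> np.ndarray:
        return np.array([i.eaf for i in self.instruments], dtype=float)

    def subset(self, keep) -> "InstrumentSet":
        """A new set restricted to indices or snp_ids in ``keep``."""
        if all(isinstance(k, str) for k in keep):
            chosen = [i for i in self.instruments if i.snp_id in set(keep)]
        else:
            chosen = [self.instruments[k] for k in keep]
        return InstrumentSet(
            chosen, self.exposure_name, self.outcome_name, list(self.selection_log), self.thresholds
        )

    @classmethod
    def from_frames(
        cls,
        exposure: pd.DataFrame,
        outcome: pd.DataFrame,
        snps=None,
        exposure2: pd.DataFrame | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "InstrumentSet":
        """Fast construction from tables already on a common allele orientation.

        No allele reconciliation is performed; use :func:`harmonize` for
        tables whose orientation may differ.
        """
        e = exposure.set_index("snp_id")
        o = outcome.set_index("snp_id")
        e2 = exposure2.set_index("snp_id") if exposure2 is not None else None
        ids = list(snps) if snps is not None else [s for s in e.index if s in o.index]
        inst = []
        for s in ids:
            kwargs = {}
            if e2 is not None:
                kwargs = {"beta_exp2": float(e2.at[s, "beta"]), "se_exp2": float(e2.at[s, "se"])}
            inst.append(
                HarmonizedInstrument(
                    snp_id=s,
                    beta_exp=float(e.at[s, "beta"]),
                    se_exp=float(e.at[s, "se"]),
                    beta_out=float(o.at[s, "beta"]),
                    se_out=float(o.at[s, "se"]),
                    eaf=float(e.at[s, "eaf"]),
                    **kwargs,
                )
            )
        return cls(inst, exposure_name, outcome_name)


def select_instruments(
    exposure: pd.DataFrame,
    ld=None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    clump_kb: float = 5000.0,
    return_log: bool = False,
):
    """Greedy LD clumping of genome-wide-significant SNPs.

    Significant SNPs (``pval < p_threshold``) are ranked by ascending
    p-value (ties broken lexicographically by snp_id).  The most
    significant remaining SNP is kept and every remaining SNP on the same
    chromosome within ``clump_kb`` kilobases with LD ``r2 >= r2_threshold``
    against it is discarded.  Pairs absent from the LD table are treated as
    r2 = 0 (unlinked) and noted in the log.

    Returns the kept snp_ids in priority order; with ``return_log=True``
    also a per-SNP disposition list of ``(snp_id, status, reason)``.
    """
    if len(exposure) == 0:
        raise ValueError("exposure table is empty")
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must lie in (0, 1], got {p_threshold!r}")
    if not 0 <= r2_threshold <= 1:
        raise ValueError(f"r2_threshold must lie in [0, 1], got {r2_threshold!r}")
    if clump_kb < 0:
        raise ValueError(f"clump_kb must be >= 0, got {clump_kb!r}")

    lut = ld_lookup(ld)
    log: list[tuple[str, str, str]] = []
    sig = exposure.loc[exposure["pval"] < p_threshold]
    for s in exposure.loc[exposure["pval"] >= p_threshold, "snp_id"]:
        log.append((s, "dropped", "above_p_threshold"))
    sig = sig.sort_values(["pval", "snp_id"], kind="mergesort")

    kept: list[tuple[str, str, int]] = []  # (snp_id, chr, pos)
    window_bp = clump_kb * 1000.0
    missing_pairs = 0
    for row in sig.itertuples(index=False):
        conflict = None
        for ks, kc, kp in kept:
            if str(row.chr) != kc or abs(int(row.pos) - kp) > window_bp:
                continue
            pair = (row.snp_id, ks)
            if pair not in lut:
                missing_pairs += 1
            if lut.get(pair, 0.0) >= r2_threshold:
                conflict = ks
                break
        if conflict is None:
            kept.append((row.snp_id, str(row.chr), int(row.pos)))
            log.append((row.snp_id, "kept", ""))
        else:
            log.append((row.snp_id, "dropped", f"clumped_with:{conflict}"))
    if missing_pairs:
        log.append(("*", "note", f"{missing_pairs} within-window pairs absent from LD table; treated as r2=0"))
    ids = [k[0] for k in kept]
    return (ids, log) if return_log else ids


def _row_map(df: pd.DataFrame) -> dict:
    cols = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se"]
    return {
        r.snp_id: r
        for r in df[cols].itertuples(index=False)
    }


def _align_to(ref_ea: str, ref_oa: str, rec) -> tuple[float, float, float, int] | None:
    """Align a record onto (ref_ea, ref_oa); returns (beta, se, eaf, n_flips) or None."""
    ea, oa = str(rec.effect_allele).upper(), str(rec.other_allele).upper()
    pal = _is_palindromic(ref_ea, ref_oa)
    if (ea, oa) == (ref_ea, ref_oa):
        return float(rec.beta), float(rec.se), float(rec.eaf), 0
    if (ea, oa) == (ref_oa, ref_ea):
        return -float(rec.beta), float(rec.se), 1.0 - float(rec.eaf), 1
    if not pal:
        cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
        if (cea, coa) == (ref_ea, ref_oa):
            return float(rec.beta), float(rec.se), float(rec.eaf), 0
        if (cea, coa) == (ref_oa, ref_ea):
            return -float(rec.beta), float(rec.se), 1.0 - float(rec.eaf), 1
    return None


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    snps,
    palindromic_policy: str = "keep_if_eaf_informative",
    exposure2: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    thresholds: tuple | None = None,
) -> InstrumentSet:
    """Align outcome (and optional second-exposure) effects onto the exposure's
    effect allele for the given SNPs.

    Records whose alleles match the exposure orientation are copied; records
    with swapped alleles have their beta negated and eaf reflected, exactly
    once, and are flagged ``flipped``.  Non-palindromic records are also
    reconciled across strands.  Palindromic SNPs are handled per policy:

    - ``drop``: always removed;
    - ``keep_if_eaf_informative`` (default): removed when either study's
      aligned eaf falls in the ambiguity band (0.42, 0.58); otherwise kept,
      with the outcome re-oriented when the two frequencies disagree about
      the minor allele;
    - ``keep_all``: kept, trusting allele labels as printed.

    SNPs missing from the outcome, or with irreconcilable allele pairs, are
    dropped and logged — never silently kept.  There is no proxy lookup.
    """
    if palindromic_policy not in PALINDROMIC_POLICIES:
        raise ValueError(
            f"palindromic_policy must be one of {PALINDROMIC_POLICIES}, got {palindromic_policy!r}"
        )
    exp_map = _row_map(exposure)
    out_map = _row_map(outcome)
    exp2_map = _row_map(exposure2) if exposure2 is not None else None

    lo, hi = AMBIGUOUS_EAF_BAND
    instruments: list[HarmonizedInstrument] = []
    log: list[tuple[str, str, str]] = []
    for snp in snps:
        e = exp_map.get(snp)
        if e is None:
            raise ValueError(f"{snp}: not present in the exposure table")
        o = out_map.get(snp)
        if o is None:
            log.append((snp, "dropped", "absent_from_outcome"))
            continue
        ea, oa = str(e.effect_allele).upper(), str(e.other_allele).upper()
        aligned = _align_to(ea, oa, o)
        if aligned is None:
            log.append((snp, "dropped", "incompatible_alleles"))
            continue
        beta_out, se_out, eaf_out, flips = aligned
        pal_kept = False
        if _is_palindromic(ea, oa):
            if palindromic_policy == "drop":
                log.append((snp, "dropped", "palindromic"))
                continue
            pal_kept = True
            if palindromic_policy == "keep_if_eaf_informative":
                eaf_e = float(e.eaf)
                if lo < eaf_e < hi or lo < eaf_out < hi:
                    log.append((snp, "dropped", "palindromic_ambiguous_eaf"))
                    continue
                if (eaf_e - 0.5) * (eaf_out - 0.5) < 0:
                    # frequencies disagree: outcome record is on the other strand
                    beta_out, eaf_out, flips = -beta_out, 1.0 - eaf_out, flips + 1
        kwargs = {}
        if exp2_map is not None:
            e2 = exp2_map.get(snp)
            if e2 is None:
                log.append((snp, "dropped", "absent_from_second_exposure"))
                continue
            a2 = _align_to(ea, oa, e2)
            if a2 is None:
                log.append((snp, "dropped", "incompatible_alleles_second_exposure"))
                continue
            kwargs = {"beta_exp2": a2[0], "se_exp2": a2[1]}
        instruments.append(
            HarmonizedInstrument(
                snp_id=snp,
                beta_exp=float(e.beta),
                se_exp=float(e.se),
                beta_out=beta_out,
                se_out=se_out,
                eaf=float(e.eaf),
                flipped=(flips % 2 == 1),
                palindromic_kept=pal_kept,
                **kwargs,
            )
        )
        log.append((snp, "kept", ""))
    dropped = sum(1 for _, s, _ in log if s == "dropped")
    if dropped:
        warnings.warn(
            f"{dropped} of {len(list(snps))} SNPs dropped during harmonization",
            HarmonizationWarning,
            stacklevel=2,
        )
    return InstrumentSet(instruments, exposure_name, outcome_name, log, thresholds)


def f_statistic(beta_exp: float, se_exp: float) -> float:
    """Per-instrument strength, ``F = beta^2 / se^2``."""
    if se_exp <= 0:
        raise ValueError("se_exp must be > 0")
    return (beta_exp / se_exp) ** 2


def mean_f(iset: InstrumentSet, warn: bool = True) -> float:
    """Set-level instrument strength (mean per-SNP F); warns below F = 10."""
    if len(iset) == 0:
        raise ValueError("empty instrument set")
    f = np.mean((iset.beta_exp / iset.se_exp) ** 2)
    if warn and f < 10:
        warnings.warn(
            f"mean instrument F = {f:.2f} < 10; weak-instrument bias likely",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    return float(f)


def variance_explained(beta_exp: float, eaf: float) -> float:
    """Variance in a standardized trait explained by one SNP: 2*eaf*(1-eaf)*beta^2."""
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must lie in (0, 1), got {eaf!r}")
    return 2.0 * eaf * (1.0 - eaf) * beta_exp**2

def set_variance_explained(iset: InstrumentSet) -> float:
    """Total explained variance over the set, clipped to [0, 1]."""
    eaf = iset.eaf
    ok = np.isfinite(eaf) & (eaf > 0) & (eaf < 1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} instruments without a usable eaf excluded from R^2",
            HarmonizationWarning,
            stacklevel=2,
        )
    r2 = float(np.sum(2.0 * eaf[ok] * (1.0 - eaf[ok]) * iset.beta_exp[ok] ** 2))
    if r2 > 1.0:
        warnings.warn("set-level R^2 exceeded 1; clipped", stacklevel=2)
        r2 = 1.0
    return r2
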