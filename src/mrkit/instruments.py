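"""Instrument selection and strength diagnostics.

A genetic variant is a usable instrument for the exposure when it is
robustly associated with the exposure (genome-wide significance), explains
more of the exposure's variance than of the outcome's (a Steiger-style
directionality filter), and is strong enough that weak-instrument bias is
negligible (F-statistic well above 10).

The variance explained by one variant is approximated from summary data as

    R² = 2 · MAF · (1 − MAF) · β²

and its strength as

    F = R² · (N − 1) / (1 − R²).

For a whole instrument set of K variants, a Cragg–Donald-style aggregate is
used:

    F_overall = ((N − K − 1) / K) · R²_tot / (1 − R²_tot),

with R²_tot the sum of per-instrument R² (instruments assumed independent,
i.e. LD-pruned upstream).  Per-SNP minimum and mean F are reported alongside
so the aggregate can be triangulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: Conventional weak-instrument threshold.
DEFAULT_F_THRESHOLD = 10.0
#: Conventional genome-wide significance threshold.
DEFAULT_GWAS_THRESHOLD = 5e-8

_BELOW_ONE = math.nextafter(1.0, 0.0)


def proportion_variance_explained(maf: float, beta: float) -> float:
    """Approximate variance explained by one variant: 2·maf·(1−maf)·β².

    ``beta`` is ln(OR) for a binary trait or a standardised linear
    coefficient for a quantitative one; ``maf`` must lie in (0, 0.5].
    Pathological inputs whose formula value reaches 1 are clamped just
    below 1 with a warning.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    r2 = 2.0 * maf * (1.0 - maf) * beta * beta
    if r2 >= 1.0:
        warnings.warn(
            f"variance explained 2*maf*(1-maf)*beta^2 = {r2:.3g} >= 1 "
            "(pathological input); clamping below 1",
            stacklevel=2,
        )
        r2 = _BELOW_ONE
    return r2


def per_snp_f(r2: float, n: float) -> float:
    """Per-variant F approximation R²·(N−1)/(1−R²)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    return r2 * (n - 1.0) / (1.0 - r2)


def overall_f(r2_values: Iterable[float], n: float) -> float:
    """Aggregate instrument strength over K variants.

    ((N − K − 1)/K) · R²_tot/(1 − R²_tot) with R²_tot = Σ R², capped just
    below 1.  Requires N > K + 1.
    """
    r2_list = [float(r) for r in r2_values]
    if not r2_list:
        raise ValueError("overall_f requires at least one instrument")
    for r in r2_list:
        if not 0.0 <= r < 1.0:
            raise ValueError(f"r2 must be in [0, 1), got {r}")
    k = len(r2_list)
    if n <= k + 1:
        raise ValueError(f"sample size {n} must exceed K + 1 = {k + 1}")
    r2_tot = min(sum(r2_list), _BELOW_ONE)
    return ((n - k - 1.0) / k) * r2_tot / (1.0 - r2_tot)


def steiger_filter(instruments: Sequence) -> tuple[list, list]:
    """Partition instruments by the directionality rule: keep a variant only
    when it explains strictly more variance in the exposure than in the
    outcome (ties rejected)."""
    kept, rejected = [], []
    for inst in instruments:
        (kept if inst.pve_exposure > inst.pve_outcome else rejected).append(inst)
    return kept, rejected


def significance_filter(
    records: Sequence, threshold: float = DEFAULT_GWAS_THRESHOLD
) -> tuple[list, list]:
    """Partition by exposure association strength: keep p < threshold
    (strict; p equal to the threshold is rejected).

    Accepts either raw summary records (``pvalue``) or harmonised
    instruments (``pvalue_exposure``).
    """
    kept, rejected = [], []
    for rec in records:
        p = rec.pvalue if hasattr(rec, "pvalue") else rec.pvalue_exposure
        (kept if p < threshold else rejected).append(rec)
    return kept, rejected


@dataclass
class InstrumentDiagnostics:
    """Per-variant selection diagnostics: variance explained on both sides,
    F, and the three selection flags."""

    variant_id: str
    r2_exposure: float
    r2_outcome: float
    f_stat: float
    passes_steiger: bool
    passes_significance: bool
    weak_flag: bool


def diagnose(
    instruments: Sequence,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    gwas_threshold: float = DEFAULT_GWAS_THRESHOLD,
) -> list[InstrumentDiagnostics]:
    """Diagnostics for every harmonised instrument (no filtering applied;
    the weak flag marks F below threshold but never excludes)."""
    out = []
    for inst in instruments:
        out.append(
            InstrumentDiagnostics(
                variant_id=inst.variant_id,
                r2_exposure=inst.pve_exposure,
                r2_outcome=inst.pve_outcome,
                f_stat=inst.f_stat,
                passes_steiger=inst.pve_exposure > inst.pve_outcome,
                passes_significance=inst.pvalue_exposure < gwas_threshold,
                weak_flag=inst.f_stat < f_threshold,
            )
        )
    return out


def diagnostics_frame(diagnostics: Sequence[InstrumentDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": d.variant_id,
                "r2_exposure": d.r2_exposure,
                "r2_outcome": d.r2_outcome,
                "f_stat": d.f_stat,
                "passes_steiger": d.passes_steiger,
                "passes_significance": d.passes_significance,
                "weak_flag": d.weak_flag,
            }
            for d in diagnostics
        ],
        columns=[
            "variant_id",
            "r2_exposure",
            "r2_outcome",
            "f_stat",
            "passes_steiger",
            "passes_significance",
            "weak_flag",
        ],
    )


@dataclass
class InstrumentSet:
    """The selected instruments for one exposure-outcome analysis, with
    selection bookkeeping.  ``n_selected + n_rejected_significance +
    n_rejected_steiger`` equals the harmonised input size."""

    exposure_label: str
    outcome_label: str
    instruments: list
    overall_f: float
    n_selected: int
    n_rejected_steiger: int
    n_rejected_significance: int
    f_min: float
    f_mean: float

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)


def build_instrument_set(
    harmonized: Sequence,
    exposure_label: str,
    outcome_label: str,
    gwas_threshold: float = DEFAULT_GWAS_THRESHOLD,
    apply_steiger: bool = True,
) -> InstrumentSet:
    """Apply significance then directionality filtering and aggregate
    strength diagnostics into an :class:`InstrumentSet`."""
    harmonized = list(harmonized)
    sig_kept, sig_rejected = significance_filter(harmonized, gwas_threshold)
    if apply_steiger:
        selected, steiger_rejected = steiger_filter(sig_kept)
    else:
        selected, steiger_rejected = list(sig_kept), []

    if selected:
        n_exp = max(inst.n_exposure for inst in selected)
        k = len(selected)
        if n_exp > k + 1:
            f_overall = overall_f([i.pve_exposure for i in selected], n_exp)
        else:
            f_overall = float("nan")
        f_min = min(i.f_stat for i in selected)
        f_mean = sum(i.f_stat for i in selected) / k
    else:
        f_overall = f_min = f_mean = float("nan")

    return InstrumentSet(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        instruments=selected,
        overall_f=f_overall,
        n_selected=len(selected),
        n_rejected_steiger=len(steiger_rejected),
        n_rejected_significance=len(sig_rejected),
        f_min=f_min,
        f_mean=f_mean,
    )


def thin_by_distance(
    records: Sequence,
    positions: dict[str, tuple[str, int]],
    min_bp: int = 10_000,
) -> list:
    """Optional greedy positional thinning (off by default in the pipeline).

    ``positions`` maps variant_id to (chromosome, 1-based position).
    Variants are visited in position order per chromosome and kept when at
    least ``min_bp`` from the previously kept variant.  Records without a
    position are kept unconditionally.
    """
    with_pos = [r for r in records if r.variant_id in positions]
    without_pos = [r for r in records if r.variant_id not in positions]
    kept = list(without_pos)
    with_pos.sort(key=lambda r: positions[r.variant_id])
    last: dict[str, int] = {}
    for rec in with_pos:
        chrom, pos = positions[rec.variant_id]
        if chrom not in last or pos - last[chrom] >= min_bp:
            kept.append(rec)
            last[chrom] = pos
    order = {r.variant_id: i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[r.variant_id])
    return kept
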