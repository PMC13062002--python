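"""GWAS summary-statistic I/O and allele harmonisation.

Two-sample Mendelian randomisation works entirely from per-variant
association summaries: for every SNP, an effect size (log-odds ratio for a
binary trait, standardised regression coefficient for a quantitative one),
its standard error, the effect-allele frequency, a p-value and the study
sample size.  Before any causal estimate can be formed, the exposure and
outcome tables must be *harmonised* so that both effect estimates refer to
the same effect allele at every variant.  This module provides:

* :class:`SummaryStatRecord` — a validated row of a summary-statistic table;
* :func:`read_summary_stats` / :func:`write_summary_stats` — tab-delimited
  I/O with configurable column names and per-row validation;
* :func:`harmonize` — allele alignment between an exposure and an outcome
  table, including strand-flip resolution and palindromic-SNP policies,
  producing :class:`HarmonizedInstrument` objects that already carry the
  variance-explained and F-statistic diagnostics used downstream.

Variants are matched by identifier only; genomic coordinates, when present
in the input, are not interpreted (a 1-based convention is assumed for any
carried-through metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import pandas as pd

from . import instruments as _inst

logger = logging.getLogger(__name__)

#: Canonical column order of the summary-statistic dialect.
CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROMIC_POLICIES = ("drop_ambiguous", "drop_all", "infer_by_frequency")


class ConfigError(ValueError):
    """A configuration problem (bad column map, unknown policy, ...)."""


class InputError(ValueError):
    """An input table that cannot be used (empty after validation, ...)."""


class HarmonizationError(ValueError):
    """Exposure and outcome tables share no usable variants."""


def complement_allele(allele: str) -> str:
    """Reverse-complement of a (possibly multi-base) allele string."""
    return "".join(_COMPLEMENT[b] for b in reversed(allele))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for single-base A/T or G/C pairs, whose strand is unresolvable
    from allele labels alone."""
    return (
        len(effect_allele) == 1
        and len(other_allele) == 1
        and _COMPLEMENT.get(effect_allele) == other_allele
    )


@dataclass
class SummaryStatRecord:
    """One variant's association summary with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: ln(OR) for a
    binary trait, a standardised linear coefficient for a quantitative one.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        self.variant_id = str(self.variant_id)
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    def validation_error(self) -> str | None:
        """Reason this record is unusable, or None if it is valid."""
        if not self.effect_allele or not self.other_allele:
            return "empty-allele"
        for a in (self.effect_allele, self.other_allele):
            if any(b not in _COMPLEMENT for b in a):
                return "non-ACGT-allele"
        if self.effect_allele == self.other_allele:
            return "identical-alleles"
        if not (0.0 <= self.eaf <= 1.0):
            return "eaf-out-of-range"
        if not self.se > 0.0:
            return "non-positive-se"
        if self.beta != self.beta:  # NaN
            return "missing-beta"
        if not (0.0 < self.pvalue <= 1.0):
            return "pvalue-out-of-range"
        if self.n < 1:
            return "non-positive-n"
        return None

    def allele_flipped(self) -> "SummaryStatRecord":
        """The same association expressed relative to the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class SummaryStats:
    """An ordered, validated collection of records for one trait."""

    label: str
    records: list[SummaryStatRecord]
    #: (row index in the source file, variant_id, reason) per rejected row.
    rejections: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


RecordsLike = Union[SummaryStats, Sequence[SummaryStatRecord]]


def _as_stats(obj: RecordsLike, default_label: str) -> SummaryStats:
    if isinstance(obj, SummaryStats):
        return obj
    return SummaryStats(default_label, list(obj))


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "trait",
) -> SummaryStats:
    """Read a tab-delimited summary-statistic table.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    column_map:
        Optional mapping from canonical names (``variant_id``, ``eaf``, ...)
        to the column names actually present in the file.  Canonical names
        not listed are looked up verbatim.
    trait_label:
        Human-readable trait name used in logs and error messages.

    Invalid rows (non-positive SE, frequency outside [0, 1], unparseable
    numbers, ...) are rejected individually, counted and logged; an input
    whose every row is rejected raises :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistic file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)

    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for canon in CANONICAL_COLUMNS:
        source = column_map.get(canon, canon)
        if source in df.columns:
            resolved[canon] = source
        else:
            missing.append(f"{canon} (looked for '{source}')")
    if missing:
        raise ConfigError(
            f"{trait_label}: missing mapped column(s) in {path.name}: "
            + "; ".join(missing)
        )

    records: list[SummaryStatRecord] = []
    rejections: list[tuple[int, str, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = {canon: getattr(row, src) for canon, src in resolved.items()}
        vid = str(raw["variant_id"])
        try:
            rec = SummaryStatRecord(
                variant_id=vid,
                effect_allele=raw["effect_allele"],
                other_allele=raw["other_allele"],
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pvalue=float(raw["pvalue"]),
                n=int(float(raw["n"])),
            )
        except (TypeError, ValueError):
            rejections.append((i, vid, "unparseable-numeric-field"))
            continue
        reason = rec.validation_error()
        if reason is not None:
            rejections.append((i, vid, reason))
        else:
            records.append(rec)

    for i, vid, reason in rejections:
        logger.warning("%s: rejected row %d (%s): %s", trait_label, i, vid, reason)
    if not records:
        raise InputError(
            f"{trait_label}: no valid rows in {path} "
            f"({len(rejections)} rejected)"
        )
    return SummaryStats(trait_label, records, rejections)


def write_summary_stats(records: RecordsLike, path: str | Path) -> Path:
    """Write records as a canonical-header TSV at full float precision.

    An empty collection yields a header-only file.  Round-trips exactly
    through :func:`read_summary_stats` (floats are written with ``repr``
    precision).
    """
    stats = _as_stats(records, "trait")
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": repr(float(r.eaf)),
                "beta": repr(float(r.beta)),
                "se": repr(float(r.se)),
                "pvalue": repr(float(r.pvalue)),
                "n": r.n,
            }
            for r in stats
        ],
        columns=list(CANONICAL_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on the same effect allele,
    plus the strength diagnostics used by instrument selection.

    ``pve_*`` is the approximate proportion of trait variance explained,
    2·MAF·(1−MAF)·β²; ``f_stat`` the per-SNP F approximation
    R²·(N−1)/(1−R²) on the exposure side.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    eaf_outcome: float
    maf: float
    n_exposure: int
    n_outcome: int
    pvalue_exposure: float
    pvalue_outcome: float
    pve_exposure: float
    pve_outcome: float
    f_stat: float


@dataclass
class LogEntry:
    variant_id: str
    action: str  # kept | dropped | skipped
    reason: str


@dataclass
class HarmonizationResult:
    """Aligned instruments plus a complete per-variant audit trail.

    Every variant present in both inputs is accounted for:
    ``len(instruments) + len(dropped()) == n_overlap``.
    """

    exposure_label: str
    outcome_label: str
    instruments: list[HarmonizedInstrument]
    log: list[LogEntry]
    n_overlap: int

    def dropped(self) -> list[LogEntry]:
        return [e for e in self.log if e.action == "dropped"]

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def write_log(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            [(e.variant_id, e.action, e.reason) for e in self.log],
            columns=["variant_id", "action", "reason"],
        ).to_csv(path, sep="\t", index=False)
        return path


def _dedupe(stats: SummaryStats, log: list[LogEntry]) -> dict[str, SummaryStatRecord]:
    """First-occurrence index by variant_id; duplicates logged."""
    index: dict[str, SummaryStatRecord] = {}
    for rec in stats:
        if rec.variant_id in index:
            log.append(LogEntry(rec.variant_id, "skipped", f"duplicate-in-{stats.label}"))
        else:
            index[rec.variant_id] = rec
    return index


def _within_window(eaf: float, window: float) -> bool:
    # inclusive boundary, robust to float representation (0.42 vs 0.5-0.08)
    return abs(eaf - 0.5) <= window + 1e-12


def harmonize(
    exposure: RecordsLike,
    outcome: RecordsLike,
    palindromic_policy: str = "drop_ambiguous",
    frequency_window: float = 0.08,
) -> HarmonizationResult:
    """Align outcome effects to the exposure's effect alleles.

    For every variant found in both tables (matched by ``variant_id``, first
    occurrence wins) the outcome record is brought onto the exposure's
    effect allele:

    * identical allele pairs are kept as-is;
    * swapped pairs have the outcome beta negated and eaf replaced by 1−eaf;
    * opposite-strand pairs (complement alleles) are complemented first and
      logged as strand flips;
    * palindromic single-base pairs (A/T, G/C) cannot be strand-resolved
      from labels and are handled per ``palindromic_policy``:

      ``drop_all``
          every palindromic variant is dropped;
      ``drop_ambiguous`` (default)
          dropped when either table's eaf lies within ``frequency_window``
          of 0.5 (default ±0.08, i.e. eaf in [0.42, 0.58]); otherwise
          aligned so the minor-allele side agrees between the tables;
      ``infer_by_frequency``
          always aligned by minor-allele side (eaf exactly 0.5 is still
          undecidable and dropped).

    Irreconcilable allele pairs are dropped with reason ``allele-mismatch``.
    Every kept or dropped variant appears in the result's log.

    Raises
    ------
    HarmonizationError
        if the two tables share no variants at all.
    """
    if palindromic_policy not in PALINDROMIC_POLICIES:
        raise ConfigError(
            f"unknown palindromic_policy {palindromic_policy!r}; "
            f"expected one of {PALINDROMIC_POLICIES}"
        )
    exp = _as_stats(exposure, "exposure")
    out = _as_stats(outcome, "outcome")
    if len(exp) == 0 or len(out) == 0:
        raise InputError("harmonize requires non-empty exposure and outcome collections")

    log: list[LogEntry] = []
    exp_index = _dedupe(exp, log)
    out_index = _dedupe(out, log)

    overlap = [vid for vid in exp_index if vid in out_index]
    if not overlap:
        raise HarmonizationError(
            f"no overlapping variants between exposure '{exp.label}' "
            f"and outcome '{out.label}'"
        )
    for vid in exp_index:
        if vid not in out_index:
            log.append(LogEntry(vid, "skipped", "not-in-outcome"))

    instruments: list[HarmonizedInstrument] = []
    for vid in overlap:
        e = exp_index[vid]
        o = out_index[vid]
        aligned, entry = _align_outcome(e, o, palindromic_policy, frequency_window)
        log.append(entry)
        if aligned is None:
            continue
        if e.maf <= 0.0:
            # a monomorphic exposure record explains no variance and has an
            # undefined PVE; it cannot serve as an instrument
            log[-1] = LogEntry(vid, "dropped", "monomorphic")
            continue
        pve_exp = _inst.proportion_variance_explained(e.maf, e.beta)
        pve_out = _inst.proportion_variance_explained(e.maf, aligned.beta)
        instruments.append(
            HarmonizedInstrument(
                variant_id=vid,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                beta_exposure=e.beta,
                se_exposure=e.se,
                beta_outcome=aligned.beta,
                se_outcome=aligned.se,
                eaf_exposure=e.eaf,
                eaf_outcome=aligned.eaf,
                maf=e.maf,
                n_exposure=e.n,
                n_outcome=aligned.n,
                pvalue_exposure=e.pvalue,
                pvalue_outcome=aligned.pvalue,
                pve_exposure=pve_exp,
                pve_outcome=pve_out,
                f_stat=_inst.per_snp_f(pve_exp, e.n),
            )
        )

    result = HarmonizationResult(
        exposure_label=exp.label,
        outcome_label=out.label,
        instruments=instruments,
        log=log,
        n_overlap=len(overlap),
    )
    logger.info(
        "harmonize(%s, %s): %d overlap, %d kept, %d dropped",
        exp.label, out.label, result.n_overlap, len(instruments),
        len(result.dropped()),
    )
    return result


def _align_outcome(
    e: SummaryStatRecord,
    o: SummaryStatRecord,
    policy: str,
    window: float,
) -> tuple[SummaryStatRecord | None, LogEntry]:
    """Return the outcome record expressed on the exposure's effect allele,
    or None with a dropped log entry."""
    vid = e.variant_id
    ea, oa = e.effect_allele, e.other_allele

    if is_palindromic(ea, oa):
        if {o.effect_allele, o.other_allele} != {ea, oa}:
            return None, LogEntry(vid, "dropped", "allele-mismatch")
        if policy == "drop_all":
            return None, LogEntry(vid, "dropped", "palindromic")
        ambiguous_window = _within_window(e.eaf, window) or _within_window(o.eaf, window)
        if policy == "drop_ambiguous" and ambiguous_window:
            return None, LogEntry(vid, "dropped", "palindromic-ambiguous")
        if e.eaf == 0.5 or o.eaf == 0.5:
            return None, LogEntry(vid, "dropped", "palindromic-ambiguous")
        # label orientation is meaningless for a palindrome; align so the
        # minor-allele side agrees between the two studies
        cand = o if o.effect_allele == ea else o.allele_flipped()
        if (e.eaf < 0.5) != (cand.eaf < 0.5):
            cand = cand.allele_flipped()
        return cand, LogEntry(vid, "kept", "frequency-aligned")

    if (o.effect_allele, o.other_allele) == (ea, oa):
        return o, LogEntry(vid, "kept", "exact")
    if (o.effect_allele, o.other_allele) == (oa, ea):
        return o.allele_flipped(), LogEntry(vid, "kept", "flipped")

    # opposite strand: compare after reverse-complementing the outcome pair
    try:
        cea, coa = complement_allele(o.effect_allele), complement_allele(o.other_allele)
    except KeyError:
        return None, LogEntry(vid, "dropped", "allele-mismatch")
    if (cea, coa) == (ea, oa):
        return o, LogEntry(vid, "kept", "strand-flipped")
    if (cea, coa) == (oa, ea):
        return o.allele_flipped(), LogEntry(vid, "kept", "strand-flipped+flipped")
    return None, LogEntry(vid, "dropped", "allele-mismatch")
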