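"""Replication-phase statistics: confirmation, clonal expansion, agreement.

Putative variants surviving screening are re-measured by deep amplicon
sequencing of a second blood sample.  Confirmation combines two
determinants: the one-sided Fisher exact p-value on the 2x2 read-count
table (the test behind VarScan2's somatic p-value) below a Bonferroni-
corrected threshold, and the direction of effect (target AAF above the
reference AAF).  For replication samples drawn at a later time point, the
change in AAF per year yields a clonal expansion rate; agreement between
screening- and replication-phase AAFs is summarised by the squared
Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Sequence

import numpy as np
from scipy import stats

from .callsets import CallsetError, VariantKey

__all__ = [
    "ReplicationRecord",
    "ExpansionEstimate",
    "fisher_exact_one_sided",
    "confirm_variant",
    "confirm_from_summary",
    "estimate_expansion_rate",
    "aaf_agreement",
    "BONFERRONI_THRESHOLD",
]

#: the printed screening-study confirmation threshold (Bonferroni-corrected)
BONFERRONI_THRESHOLD = 5.88e-4


@dataclass(frozen=True)
class ReplicationRecord:
    """Amplicon read counts for one putative variant plus its verdict."""

    key: VariantKey
    patient_id: str
    cell_type: str
    alt_target: int
    ref_target: int
    alt_reference: int
    ref_reference: int
    p_value: float | None = None
    confirmed: bool | None = None
    timepoint: str = "same"  # "same" | "later"
    delta_years: float = 0.0

    def __post_init__(self) -> None:
        for c in (self.alt_target, self.ref_target, self.alt_reference, self.ref_reference):
            if c < 0:
                raise CallsetError(f"{self.key}: negative read count")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise CallsetError(f"{self.key}: p-value {self.p_value} outside [0,1]")
        if self.timepoint not in ("same", "later"):
            raise CallsetError(f"{self.key}: timepoint must be 'same' or 'later'")
        if self.delta_years < 0:
            raise CallsetError(f"{self.key}: delta_years must be >= 0")

    @property
    def aaf_target(self) -> float:
        n = self.alt_target + self.ref_target
        return self.alt_target / n if n else 0.0

    @property
    def aaf_reference(self) -> float:
        n = self.alt_reference + self.ref_reference
        return self.alt_reference / n if n else 0.0


@dataclass(frozen=True)
class ExpansionEstimate:
    """Clonal expansion summarised over longitudinal variant pairs.

    Rates are in percentage points of AAF per year.  The summary is the
    median (robust over a handful of variants); the mean is reported for
    reference, and ``p_vs_zero`` comes from the Wilcoxon signed-rank test
    of the per-variant rates against zero.
    """

    per_variant_rates: tuple[float, ...]
    summary_rate: float
    mean_rate: float
    p_vs_zero: float


def fisher_exact_one_sided(
    alt_t: int, ref_t: int, alt_r: int, ref_r: int
) -> float:
    """One-sided Fisher exact p-value that the target is enriched for ALT.

    Conditions on the margins of the 2x2 table
    ``[[alt_t, ref_t], [alt_r, ref_r]]`` and returns the exact
    hypergeometric upper-tail probability of observing at least ``alt_t``
    alternate reads in the target sample.  This is the test underlying
    VarScan2's somatic p-value.
    """
    for c in (alt_t, ref_t, alt_r, ref_r):
        if c < 0:
            raise CallsetError("read counts must be non-negative")
    n_target = alt_t + ref_t
    n_total = n_target + alt_r + ref_r
    k_alt = alt_t + alt_r
    if n_target == 0 or n_total - n_target == 0:
        raise CallsetError("both samples need at least one read")
    # P(X >= alt_t), X ~ Hypergeom(N=n_total, K=k_alt, n=n_target)
    return float(stats.hypergeom.sf(alt_t - 1, n_total, k_alt, n_target))


def confirm_variant(
    rec: ReplicationRecord,
    alpha: float = 0.05,
    m: int | None = None,
    threshold: float | None = None,
) -> ReplicationRecord:
    """Attach the confirmation verdict to a replication record.

    ``threshold`` overrides the Bonferroni-corrected level ``alpha / m``
    (use it when reproducing a printed threshold rather than deriving one
    from the family size).  The p-value is computed from the read counts
    unless already present.  Confirmation requires both the p-value below
    the threshold and the direction of effect (target AAF > reference AAF).
    """
    if threshold is None:
        if m is None or m < 1:
            raise CallsetError("confirm_variant needs m >= 1 or an explicit threshold")
        threshold = alpha / m
    p = rec.p_value
    if p is None:
        p = fisher_exact_one_sided(
            rec.alt_target, rec.ref_target, rec.alt_reference, rec.ref_reference
        )
    confirmed = (p < threshold) and (rec.aaf_target > rec.aaf_reference)
    return replace(rec, p_value=p, confirmed=confirmed)


def confirm_from_summary(
    p_value: float,
    aaf_target: float,
    aaf_reference: float = 0.0,
    threshold: float = BONFERRONI_THRESHOLD,
) -> bool:
    """Confirmation rule on pre-computed summaries (p-value and AAFs)."""
    return (p_value < threshold) and (aaf_target > aaf_reference)


def estimate_expansion_rate(
    pairs: Sequence[tuple[float, float, float]],
) -> ExpansionEstimate:
    """Estimate the clonal expansion rate from (aaf_t1, aaf_t2, years) pairs.

    AAFs are fractions in [0,1]; per-variant rates are reported in
    percentage points of AAF per year.  An all-zero rate vector yields
    p = 1 (the signed-rank test is undefined without non-zero differences).
    """
    if not pairs:
        raise CallsetError("no longitudinal pairs supplied")
    rates = []
    for a1, a2, dt in pairs:
        if dt <= 0:
            raise CallsetError(f"delta_years must be > 0, got {dt}")
        rates.append(100.0 * (a2 - a1) / dt)
    nonzero = [r for r in rates if r != 0.0]
    if nonzero:
        _, p = stats.wilcoxon(rates)
    else:
        p = 1.0
    return ExpansionEstimate(
        per_variant_rates=tuple(rates),
        summary_rate=float(median(rates)),
        mean_rate=float(np.mean(rates)),
        p_vs_zero=float(p),
    )


def aaf_agreement(
    pairs: Sequence[tuple[float, float]],
) -> dict[str, float]:
    """Screening-vs-replication AAF agreement.

    Returns the squared Spearman rank correlation with its p-value (the
    primary summary; AAFs are far from normal), the signed rho, and the
    Pearson r-squared for reference.
    """
    if len(pairs) < 3:
        raise CallsetError("need at least 3 AAF pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CallsetError("correlation undefined for a constant AAF vector")
    rho, p_s = stats.spearmanr(x, y)
    r, p_p = stats.pearsonr(x, y)
    return {
        "rho": float(rho),
        "rho_squared": float(rho**2),
        "p_spearman": float(p_s),
        "pearson_r_squared": float(r**2),
        "p_pearson": float(p_p),
    }
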