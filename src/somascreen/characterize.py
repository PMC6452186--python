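"""Characterization of confirmed somatic variants.

Summaries over the confirmed variant set: per-patient and per-cell-type
tallies, the somatic-versus-matched-germline comparison (novelty in
population databases, COSMIC overlap, deleteriousness via CADD against the
gene-specific MSC cutoff, conservation via GERP++), synonymous/
non-synonymous co-occurrence and the single-base substitution spectrum.

Test selection follows the study's conventions: Fisher's exact test for
categorical contrasts; for continuous variables a Shapiro-Wilk normality
gate followed by Kruskal-Wallis (non-normal, the usual case for scores and
frequencies) or Welch's t-test (both groups normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callsets import CallsetError, VariantKey

__all__ = [
    "VariantProfile",
    "summarize_cohort",
    "compare_groups",
    "synonymous_cooccurrence",
    "mutation_spectrum",
    "substitution_class",
    "SUBSTITUTION_CLASSES",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: pyrimidine-referenced single-base substitution classes
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def substitution_class(ref: str, alt: str) -> str:
    """Strand-folded substitution class (purine refs are complemented)."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise CallsetError(f"not a single-base substitution: {ref}>{alt}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class VariantProfile:
    """One confirmed variant with the attributes used for characterization.

    AAFs are fractions; ``kaviar_af`` of 0 with ``novel`` True means the
    allele has never been seen in the Kaviar germline compendium.
    ``cpg_context`` is None when the dinucleotide context is unknown.
    """

    key: VariantKey
    patient_id: str
    cell_type: str
    effect: str  # "synonymous" | "non-synonymous"
    aaf_screen: float
    aaf_repl: float
    kaviar_af: float = 0.0
    novel: bool = True
    cadd: float = 0.0
    msc: float = 0.0
    gerp: float = 0.0
    cosmic: bool = False
    cpg_context: bool | None = None
    gene: str = ""

    def __post_init__(self) -> None:
        if self.effect not in ("synonymous", "non-synonymous"):
            raise CallsetError(f"{self.key}: effect must be (non-)synonymous")

    @property
    def substitution_class(self) -> str:
        return substitution_class(self.key.ref, self.key.alt)


def summarize_cohort(
    profiles: Iterable[VariantProfile],
    cohort_patients: Sequence[str] | None = None,
) -> dict:
    """Per-cell-type and per-patient tallies over confirmed variants.

    ``cohort_patients`` supplies the full cohort (including patients with
    zero variants) so the affected fraction has the right denominator.
    """
    profiles = list(profiles)
    per_cell: dict[str, int] = {}
    per_patient: dict[str, int] = {}
    for p in profiles:
        per_cell[p.cell_type] = per_cell.get(p.cell_type, 0) + 1
        per_patient[p.patient_id] = per_patient.get(p.patient_id, 0) + 1
    if cohort_patients is None:
        cohort_patients = sorted(per_patient)
    n_cohort = len(cohort_patients)
    affected = [pt for pt in cohort_patients if per_patient.get(pt, 0) > 0]
    counts = [per_patient[pt] for pt in affected]
    return {
        "n_variants": len(profiles),
        "per_cell_type": per_cell,
        "per_patient": {pt: per_patient.get(pt, 0) for pt in cohort_patients},
        "n_patients": n_cohort,
        "n_affected_patients": len(affected),
        "affected_fraction": len(affected) / n_cohort if n_cohort else 0.0,
        "min_variants_per_affected": min(counts) if counts else 0,
        "max_variants_per_affected": max(counts) if counts else 0,
    }


def _continuous_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Shapiro-Wilk gate, then Kruskal-Wallis or Welch's t."""
    if len(x) < 2 or len(y) < 2:
        raise CallsetError("continuous comparison needs >= 2 values per group")
    normal = (
        stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha
    )
    if normal:
        res = stats.ttest_ind(x, y, equal_var=False)
        return "welch_t", float(res.pvalue)
    if np.array_equal(np.sort(x), np.sort(y)):
        return "kruskal_wallis", 1.0  # identical samples: no evidence at all
    res = stats.kruskal(x, y)
    return "kruskal_wallis", float(res.pvalue)


def compare_groups(
    somatic: Sequence[VariantProfile],
    germline: Sequence[VariantProfile],
    gerp_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Somatic-versus-germline characteristics table.

    One row per metric: counts (with group percentages) for the
    categorical metrics — novel in Kaviar, present in COSMIC, CADD above
    the gene's MSC, GERP above ``gerp_cutoff`` — and medians (with ranges)
    for Kaviar frequency, CADD and GERP.  Categorical p-values are
    two-sided Fisher exact on the 2x2 count table.
    """
    if not somatic or not germline:
        raise CallsetError("both groups must be non-empty")
    n_s, n_g = len(somatic), len(germline)

    def _cat_row(metric: str, pred) -> dict:
        a = sum(1 for p in somatic if pred(p))
        c = sum(1 for p in germline if pred(p))
        _, pval = stats.fisher_exact([[a, n_s - a], [c, n_g - c]])
        return {
            "metric": metric,
            "kind": "categorical",
            "somatic": a,
            "somatic_pct": 100.0 * a / n_s,
            "germline": c,
            "germline_pct": 100.0 * c / n_g,
            "test": "fisher_exact",
            "p": float(pval),
        }

    def _cont_row(metric: str, attr) -> dict:
        x = np.array([attr(p) for p in somatic], dtype=float)
        y = np.array([attr(p) for p in germline], dtype=float)
        test, pval = _continuous_test(x, y)
        return {
            "metric": metric,
            "kind": "continuous",
            "somatic": float(np.median(x)),
            "somatic_range": (float(x.min()), float(x.max())),
            "germline": float(np.median(y)),
            "germline_range": (float(y.min()), float(y.max())),
            "test": test,
            "p": pval,
        }

    rows = [
        _cat_row("novel", lambda p: p.novel),
        _cont_row("population_frequency_median", lambda p: p.kaviar_af),
        _cat_row("cosmic_present", lambda p: p.cosmic),
        _cat_row("cadd_above_msc", lambda p: p.cadd > p.msc),
        _cont_row("cadd_median", lambda p: p.cadd),
        _cat_row(f"gerp_above_{gerp_cutoff:g}", lambda p: p.gerp > gerp_cutoff),
        _cont_row("gerp_median", lambda p: p.gerp),
    ]
    return pd.DataFrame(rows)


def synonymous_cooccurrence(
    profiles: Iterable[VariantProfile],
    cohort_patients: Sequence[str],
) -> tuple[np.ndarray, float]:
    """Patient-level co-occurrence of synonymous and non-synonymous variants.

    Builds the 2x2 presence/absence table (has non-synonymous x has
    synonymous) over *all* cohort patients, including those without any
    variant, and returns it with the two-sided Fisher exact p-value.
    """
    has_syn: set[str] = set()
    has_nonsyn: set[str] = set()
    for p in profiles:
        (has_syn if p.effect == "synonymous" else has_nonsyn).add(p.patient_id)
    table = np.zeros((2, 2), dtype=int)
    for pt in cohort_patients:
        i = 0 if pt in has_nonsyn else 1
        j = 0 if pt in has_syn else 1
        table[i, j] += 1
    _, p = stats.fisher_exact(table)
    return table, float(p)


def mutation_spectrum(profiles: Iterable[VariantProfile]) -> dict:
    """Strand-folded substitution spectrum and CpG fraction within C>T.

    CpG tallies use only profiles whose dinucleotide context is known.
    """
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    ct_known = ct_cpg = 0
    for p in profiles:
        cls = p.substitution_class  # raises on non-SNV
        counts[cls] += 1
        if cls == "C>T" and p.cpg_context is not None:
            ct_known += 1
            ct_cpg += int(p.cpg_context)
    return {
        "counts": counts,
        "modal_class": max(counts, key=lambda c: (counts[c], c)),
        "ct_with_known_context": ct_known,
        "ct_at_cpg": ct_cpg,
        "cpg_fraction_of_ct": (ct_cpg / ct_known) if ct_known else float("nan"),
    }


def variant_count_correlation(
    counts: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of per-patient variant count with a covariate
    (age, disease duration)."""
    if len(counts) != len(covariate) or len(counts) < 3:
        raise CallsetError("need >= 3 aligned (count, covariate) pairs")
    r, p = stats.pearsonr(np.asarray(counts, float), np.asarray(covariate, float))
    return float(r), float(p)
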