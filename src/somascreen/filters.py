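"""Two-caller consensus and technical filtering of candidate somatic SNVs.

Candidates must be called by both MuTect2 and VarScan2 at the same site
(caller agreement strongly enriches for true positives at low allele
fractions).  The merged candidates then pass through five technical rules:

i.   coverage >= 300x in both the target and the reference sample;
ii.  alternate allele fraction (AAF) >= 0.5% in the target and < 0.5%
     in the reference sample;
iii. observed at most twice in the same cell type and at most once in the
     other cell type across the cohort (recurrent sites are artifacts or
     germline leakage);
iv.  alternate allele detected on both strands;
v.   PASS under MuTect2's built-in filters, or failing only the
     clustered-events / homologous-mapping-event filters (which may be
     overruled: they penalise nearby events and remove true positives).

Every rule is always evaluated so a failing candidate carries the complete
list of violated rules as reason codes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .callsets import CandidateCall, CallsetError, VariantKey

__all__ = [
    "FilterThresholds",
    "ConsensusCandidate",
    "FilterDecision",
    "RecurrenceIndex",
    "intersect_callsets",
    "mutect_filter_policy",
    "build_recurrence_index",
    "technical_filter",
    "DEFAULT_OVERRULED_FILTERS",
]

#: MuTect2 filters related to adjacent/nearby events; overruling them
#: recovers true positives lost to clustered real mutations.
DEFAULT_OVERRULED_FILTERS = frozenset(
    {"clustered_events", "homologous_mapping_event"}
)


def _canon_filter(name: str) -> str:
    """Case- and separator-insensitive MuTect2 filter-name form."""
    return name.strip().lower().replace("-", "_").replace(" ", "_")


@dataclass(frozen=True)
class FilterThresholds:
    """Technical filter cut-offs (defaults are the screening-design values).

    ``min_target_aaf`` is inclusive (>=); ``max_reference_aaf`` is an
    exclusive upper bound (<).  ``min_reads_per_strand`` parameterises the
    both-strands rule.  For larger designs, scale the recurrence caps via
    configuration rather than a second hard-coded profile.
    """

    min_coverage: int = 300
    min_target_aaf: float = 0.005
    max_reference_aaf: float = 0.005
    max_same_celltype_recurrence: int = 2
    max_other_celltype_recurrence: int = 1
    min_reads_per_strand: int = 1
    overruled_mutect_filters: frozenset[str] = DEFAULT_OVERRULED_FILTERS

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise CallsetError("min_coverage must be >= 1")
        for name in ("min_target_aaf", "max_reference_aaf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CallsetError(f"{name} must be in [0,1], got {v}")
        object.__setattr__(
            self,
            "overruled_mutect_filters",
            frozenset(_canon_filter(f) for f in self.overruled_mutect_filters),
        )


@dataclass(frozen=True)
class ConsensusCandidate:
    """A site called by both callers in one patient/target/reference pair.

    AAFs are computed from the VarScan2 read counts (alt / (alt + ref)),
    whose detailed output the filter thresholds are defined on; the
    MuTect2 evidence is retained alongside.
    """

    key: VariantKey
    patient_id: str
    target_cell: str
    reference_cell: str
    mutect: CandidateCall
    varscan: CandidateCall

    def __post_init__(self) -> None:
        if self.mutect.key != self.key or self.varscan.key != self.key:
            raise CallsetError(f"caller evidence keys disagree at {self.key}")
        if self.mutect.caller != "mutect2" or self.varscan.caller != "varscan2":
            raise CallsetError(f"{self.key}: caller roles swapped")

    @property
    def aaf_target(self) -> float:
        return self.varscan.aaf_target

    @property
    def aaf_reference(self) -> float:
        return self.varscan.aaf_reference


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise CallsetError("passed must be equivalent to an empty reason list")


class RecurrenceIndex:
    """Counts of distinct samples carrying each (site, cell type) candidate.

    A sample is one patient/target-cell combination; the same variant seen
    as a candidate in many samples of a cell type is characteristic of a
    recurrent artifact (or germline leakage through the pair design).
    """

    def __init__(self, counts: Mapping[tuple[VariantKey, str], int]):
        self._counts = dict(counts)

    def count(self, key: VariantKey, cell_type: str) -> int:
        return self._counts.get((key, cell_type), 0)

    def cell_types(self, key: VariantKey) -> list[str]:
        return [ct for (k, ct) in self._counts if k == key]

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return len(self._counts)


def intersect_callsets(
    mutect_calls: Iterable[CandidateCall],
    varscan_calls: Iterable[CandidateCall],
) -> tuple[list[ConsensusCandidate], dict[str, int]]:
    """Merge the two callers' candidate lists on site identity.

    Returns the consensus candidates sorted by (chrom, pos, ref, alt)
    together with a tally of how many keys were exclusive to each caller
    (the funnel statistics of the pipeline's first stage).
    """
    mutect_by_key: dict[VariantKey, CandidateCall] = {}
    for call in mutect_calls:
        if call.key in mutect_by_key:
            raise CallsetError(f"duplicate mutect2 candidate for {call.key}")
        mutect_by_key[call.key] = call
    varscan_by_key: dict[VariantKey, CandidateCall] = {}
    for call in varscan_calls:
        if call.key in varscan_by_key:
            raise CallsetError(f"duplicate varscan2 candidate for {call.key}")
        varscan_by_key[call.key] = call

    shared = sorted(
        set(mutect_by_key) & set(varscan_by_key),
        key=lambda k: (k.chrom, k.pos, k.ref, k.alt),
    )
    merged = []
    for key in shared:
        vs = varscan_by_key[key]
        merged.append(
            ConsensusCandidate(
                key=key,
                patient_id=vs.patient_id,
                target_cell=vs.target_cell,
                reference_cell=vs.reference_cell,
                mutect=mutect_by_key[key],
                varscan=vs,
            )
        )
    tally = {
        "both": len(shared),
        "mutect2_only": len(mutect_by_key) - len(shared),
        "varscan2_only": len(varscan_by_key) - len(shared),
    }
    return merged, tally


def mutect_filter_policy(
    call: CandidateCall, overruled: frozenset[str] = DEFAULT_OVERRULED_FILTERS
) -> bool:
    """True iff the call is PASS or fails only overruled filters."""
    if call.caller != "mutect2":
        raise CallsetError("mutect_filter_policy requires a mutect2 call")
    overruled = frozenset(_canon_filter(f) for f in overruled)
    failed = {_canon_filter(f) for f in (call.mutect_filters or frozenset())}
    return failed <= overruled


def build_recurrence_index(
    candidates: Iterable[ConsensusCandidate],
) -> RecurrenceIndex:
    """Tally distinct (patient, target cell) observations per site/cell type."""
    seen: set[tuple[VariantKey, str, str]] = set()
    counts: Counter[tuple[VariantKey, str]] = Counter()
    for cand in candidates:
        stamp = (cand.key, cand.target_cell, cand.patient_id)
        if stamp in seen:
            continue
        seen.add(stamp)
        counts[(cand.key, cand.target_cell)] += 1
    return RecurrenceIndex(counts)


def technical_filter(
    candidate: ConsensusCandidate,
    index: RecurrenceIndex,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterDecision:
    """Apply all five technical rules; collect every violated rule.

    Rules are evaluated without short-circuiting so that a candidate's
    reason list fully explains its failure (the attrition tables depend on
    this).  Reason order is fixed: coverage, AAF, recurrence, strand,
    MuTect2 policy, non-SNV flag.
    """
    reasons: list[str] = []
    vs = candidate.varscan
    if vs.depth_target < thresholds.min_coverage:
        reasons.append("low_coverage_target")
    if vs.depth_reference < thresholds.min_coverage:
        reasons.append("low_coverage_reference")
    if candidate.aaf_target < thresholds.min_target_aaf:
        reasons.append("low_target_aaf")
    if candidate.aaf_reference >= thresholds.max_reference_aaf:
        reasons.append("high_reference_aaf")
    own = index.count(candidate.key, candidate.target_cell)
    if own > thresholds.max_same_celltype_recurrence:
        reasons.append("recurrent_same_celltype")
    for ct in index.cell_types(candidate.key):
        if ct == candidate.target_cell:
            continue
        if index.count(candidate.key, ct) > thresholds.max_other_celltype_recurrence:
            reasons.append("recurrent_other_celltype")
            break
    plus = vs.alt_plus_strand if vs.alt_plus_strand is not None else 0
    minus = vs.alt_minus_strand if vs.alt_minus_strand is not None else 0
    if plus < thresholds.min_reads_per_strand or minus < thresholds.min_reads_per_strand:
        reasons.append("strand_bias")
    if not mutect_filter_policy(candidate.mutect, thresholds.overruled_mutect_filters):
        for name in sorted(candidate.mutect.mutect_filters or ()):
            canon = _canon_filter(name)
            if canon not in thresholds.overruled_mutect_filters:
                reasons.append(f"mutect_filter_failed:{canon}")
    if not candidate.key.is_snv:
        reasons.append("non_snv")
    return FilterDecision(passed=not reasons, reasons=tuple(reasons))
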