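"""Biological prioritization of technically passing somatic SNV candidates.

Technical filtering removes artifacts; prioritization removes variants
unlikely to matter in a disease context.  A candidate is retained when it

i.   is a single-nucleotide variant in an exon or at a splice site;
ii.  is rare (frequency <= 1%) in every configured population database
     (1000 Genomes, ESP6500, cg69, ExAC, Kaviar);
iii. is not located in a segmental duplication; and
iv.  lies in a gene with a gene damage index (GDI) below 13.84, the
     published all-disease cutoff separating genes frequently mutated in
     the healthy population.

The same operation is reused to build the matched germline comparison set
(germline variants are filtered with identical criteria so that the
somatic/germline contrast is not confounded by the filters themselves).
"""

from __future__ import annotations

from dataclasses import dataclass

from .callsets import AnnotationRecord, CallsetError

__all__ = ["PriorityDecision", "prioritize", "GDI_CUTOFF_ALL_DISEASE"]

#: published all-disease gene-damage-index cutoff
GDI_CUTOFF_ALL_DISEASE = 13.84

_PRIORITIZABLE_EFFECTS = frozenset(
    {"exonic_nonsynonymous", "exonic_synonymous", "splice"}
)


@dataclass(frozen=True)
class PriorityDecision:
    prioritized: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.prioritized != (len(self.reasons) == 0):
            raise CallsetError("prioritized must be equivalent to empty reasons")


def prioritize(
    candidate,
    ann: AnnotationRecord | None,
    max_db_af: float = 0.01,
    gdi_cutoff: float = GDI_CUTOFF_ALL_DISEASE,
) -> PriorityDecision:
    """Decide whether a consensus candidate is biologically prioritized.

    ``candidate`` may be a :class:`~somascreen.filters.ConsensusCandidate`
    or anything exposing a ``key``.  A missing annotation is an error: an
    unannotated variant must never silently pass.  The population rule is
    inclusive (a frequency of exactly ``max_db_af`` still passes); the GDI
    rule is strict (gdi must be < ``gdi_cutoff``).
    """
    key = getattr(candidate, "key", candidate)
    if ann is None:
        raise CallsetError(f"no annotation available for {key}")
    if ann.key != key:
        raise CallsetError(f"annotation key {ann.key} does not match {key}")
    reasons: list[str] = []
    if not key.is_snv:
        reasons.append("not_snv")
    if ann.effect not in _PRIORITIZABLE_EFFECTS:
        reasons.append("not_exonic_or_splice")
    for db in sorted(ann.db_afs):
        if ann.db_afs[db] > max_db_af:
            reasons.append(f"common_in_population:{db}")
    if ann.segdup:
        reasons.append("in_segdup")
    if ann.gdi >= gdi_cutoff:
        reasons.append("high_gdi")
    return PriorityDecision(prioritized=not reasons, reasons=tuple(reasons))
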