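"""Parsing of somatic caller outputs and annotation resources.

This module defines the unified data model for candidate somatic SNVs
observed in a target/reference pair of sorted cell populations (e.g. T
cells called against B cells of the same individual), and readers for the
two caller dialects the pipeline consumes:

* MuTect2-style somatic VCFs (GATK 3.5 FILTER semantics), and
* VarScan2 ``somatic`` tab-delimited output (v2.3.9 column schema).

Neither caller is re-implemented; their outputs are inputs here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantKey",
    "CandidateCall",
    "AnnotationRecord",
    "CohortConfig",
    "CallsetError",
    "VcfParseError",
    "TableParseError",
    "read_mutect2_vcf",
    "read_varscan2_somatic",
    "read_annotation_table",
    "read_segdup_bed",
    "write_variant_report",
    "read_variant_report",
    "VARSCAN_SOMATIC_COLUMNS",
]

_BASES = frozenset("ACGT")


class CallsetError(ValueError):
    """Base class for malformed caller/annotation inputs."""


class VcfParseError(CallsetError):
    pass


class TableParseError(CallsetError):
    pass


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix so b37/hg19 names compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Site identity of a single-nucleotide substitution.

    Coordinates are 1-based and fully closed, as in VCF.  ``ref``/``alt``
    may be longer than one base for records parsed from indel/MNV lines;
    such keys are representable but flagged non-SNV downstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise CallsetError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise CallsetError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _BASES
            and self.alt in _BASES
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CandidateCall:
    """One caller's evidence for one putative somatic SNV in one pair.

    ``target`` is the cell population screened for somatic variants,
    ``reference`` the population from the same individual it is compared
    against (the tumor/normal analogue).  Strand counts and the somatic
    p-value come from VarScan2; the FILTER token set comes from MuTect2.
    """

    key: VariantKey
    patient_id: str
    target_cell: str
    reference_cell: str
    caller: str  # "mutect2" | "varscan2"
    depth_target: int
    alt_reads_target: int
    depth_reference: int
    alt_reads_reference: int
    alt_plus_strand: int | None = None
    alt_minus_strand: int | None = None
    mutect_filters: frozenset[str] | None = None
    somatic_p: float | None = None

    def __post_init__(self) -> None:
        if self.caller not in ("mutect2", "varscan2"):
            raise CallsetError(f"unknown caller {self.caller!r}")
        for d, a, side in (
            (self.depth_target, self.alt_reads_target, "target"),
            (self.depth_reference, self.alt_reads_reference, "reference"),
        ):
            if d < 0 or a < 0 or a > d:
                raise CallsetError(
                    f"{self.key}: bad {side} counts alt={a} depth={d}"
                )
        if self.caller == "mutect2" and self.mutect_filters is None:
            raise CallsetError(f"{self.key}: mutect2 call without FILTER set")
        if self.caller == "varscan2" and self.somatic_p is None:
            raise CallsetError(f"{self.key}: varscan2 call without somatic p-value")
        if self.somatic_p is not None and not (0.0 <= self.somatic_p <= 1.0):
            raise CallsetError(f"{self.key}: somatic p {self.somatic_p} not in [0,1]")
        if (
            self.alt_plus_strand is not None
            and self.alt_minus_strand is not None
            and self.alt_plus_strand + self.alt_minus_strand != self.alt_reads_target
        ):
            raise CallsetError(
                f"{self.key}: strand counts {self.alt_plus_strand}+"
                f"{self.alt_minus_strand} != alt reads {self.alt_reads_target}"
            )

    @property
    def aaf_target(self) -> float:
        return self.alt_reads_target / self.depth_target if self.depth_target else 0.0

    @property
    def aaf_reference(self) -> float:
        return (
            self.alt_reads_reference / self.depth_reference
            if self.depth_reference
            else 0.0
        )


#: database keys recognised in annotation tables (population AF sources)
AF_DATABASES = ("1000g", "esp6500", "cg69", "exac", "kaviar")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant functional and population annotations.

    ``db_afs`` maps database name to germline allele frequency; a database
    missing from the mapping means the allele has never been observed there
    (novel).  ``gdi`` is the gene damage index of the host gene; ``cadd``
    and ``msc`` are phred-scaled, ``gerp`` is the GERP++ RS score.
    """

    key: VariantKey
    gene: str
    effect: str  # exonic_nonsynonymous | exonic_synonymous | splice | other
    aa_change: str = ""
    db_afs: Mapping[str, float] = field(default_factory=dict)
    segdup: bool = False
    gdi: float = 0.0
    cadd: float = 0.0
    msc: float = 0.0
    gerp: float = 0.0
    cosmic: bool = False

    def __post_init__(self) -> None:
        for db, af in self.db_afs.items():
            if not (0.0 <= af <= 1.0):
                raise CallsetError(f"{self.key}: {db} AF {af} not in [0,1]")
        if self.cadd < 0 or self.msc < 0 or self.gdi < 0:
            raise CallsetError(f"{self.key}: CADD/MSC/GDI must be non-negative")

    @property
    def novel(self) -> bool:
        """True when never observed in any configured population database."""
        return all(af == 0.0 for af in self.db_afs.values()) or not self.db_afs

    def db_af(self, db: str) -> float:
        return self.db_afs.get(db, 0.0)


@dataclass
class CohortConfig:
    """Cohort layout plus shared thresholds (see :mod:`somascreen.filters`)."""

    patients: Sequence[str]
    cell_types: Sequence[str]
    thresholds: "object" = None  # FilterThresholds; late import avoids a cycle
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.patients) < 1:
            raise CallsetError("cohort needs at least one patient")
        if len(self.cell_types) < 2:
            raise CallsetError("cohort needs at least two cell types")


# ---------------------------------------------------------------------------
# MuTect2 VCF


def read_mutect2_vcf(
    path: str | Path,
    patient_id: str,
    target_cell: str,
    reference_cell: str,
    target_sample: str | None = None,
) -> list[CandidateCall]:
    """Read a MuTect2-style somatic VCF into candidate calls.

    One :class:`CandidateCall` is emitted per ALT allele per record;
    multi-allelic records are decomposed.  The FILTER column becomes the
    ``mutect_filters`` token set (empty for PASS).  Allele depths are taken
    from the per-sample ``AD`` field of the target sample (the only sample
    in artifact-detection/PoN mode; otherwise ``target_sample`` selects it).
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    calls: list[CandidateCall] = []
    with vf:
        samples = list(vf.header.samples)
        if target_sample is None:
            target_sample = samples[0] if samples else None
        rec_iter = vf.fetch() if vf.index is not None else vf
        for rec in rec_iter:
            try:
                calls.extend(
                    _decompose_mutect_record(
                        rec, patient_id, target_cell, reference_cell, target_sample
                    )
                )
            except CallsetError:
                raise
            except Exception as exc:  # malformed record
                raise VcfParseError(
                    f"{path}: malformed record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return calls


def _decompose_mutect_record(
    rec, patient_id, target_cell, reference_cell, target_sample
) -> Iterable[CandidateCall]:
    filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
    if target_sample is None:
        raise VcfParseError(f"record {rec.chrom}:{rec.pos} has no sample column")
    sample = rec.samples[target_sample]
    ad = sample.get("AD")
    if ad is None or any(x is None for x in ad):
        raise VcfParseError(
            f"record {rec.chrom}:{rec.pos} lacks allele depths (AD) for "
            f"sample {target_sample}"
        )
    ref_reads = int(ad[0])
    for i, alt in enumerate(rec.alts or ()):
        alt_reads = int(ad[i + 1]) if len(ad) > i + 1 else 0
        yield CandidateCall(
            key=VariantKey(rec.chrom, rec.pos, rec.ref, alt),
            patient_id=patient_id,
            target_cell=target_cell,
            reference_cell=reference_cell,
            caller="mutect2",
            depth_target=ref_reads + alt_reads,
            alt_reads_target=alt_reads,
            depth_reference=0,
            alt_reads_reference=0,
            mutect_filters=filters,
        )


# ---------------------------------------------------------------------------
# VarScan2 somatic table

#: native VarScan2 v2.3.9 `somatic` output columns (reference dialect);
#: "normal" is the reference cell type, "tumor" the target cell type.
VARSCAN_SOMATIC_COLUMNS = (
    "chrom",
    "position",
    "ref",
    "var",
    "normal_reads1",
    "normal_reads2",
    "normal_var_freq",
    "normal_gt",
    "tumor_reads1",
    "tumor_reads2",
    "tumor_var_freq",
    "tumor_gt",
    "somatic_status",
    "variant_p_value",
    "somatic_p_value",
    "tumor_reads1_plus",
    "tumor_reads1_minus",
    "tumor_reads2_plus",
    "tumor_reads2_minus",
    "normal_reads1_plus",
    "normal_reads1_minus",
    "normal_reads2_plus",
    "normal_reads2_minus",
)


def read_varscan2_somatic(
    path: str | Path,
    patient_id: str,
    target_cell: str,
    reference_cell: str,
    column_map: Mapping[str, str] | None = None,
) -> list[CandidateCall]:
    """Read a VarScan2 ``somatic`` table into candidate calls.

    Per-sample depth is reconstructed as reads1 + reads2 (reference-
    plus alternate-supporting reads).  ``column_map`` renames a non-native
    dialect's headers onto :data:`VARSCAN_SOMATIC_COLUMNS` names.
    Rows whose alleles are not single bases are kept (flagged non-SNV via
    the key) so that filtering counts stay transparent.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:
        raise TableParseError(f"{path}: cannot read table: {exc}") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in VARSCAN_SOMATIC_COLUMNS[:4] if c not in df.columns]
    required = (
        "normal_reads1",
        "normal_reads2",
        "tumor_reads1",
        "tumor_reads2",
        "somatic_p_value",
        "tumor_reads2_plus",
        "tumor_reads2_minus",
    )
    missing += [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(
            f"{path}: missing VarScan2 somatic columns {missing}; expected "
            f"schema {VARSCAN_SOMATIC_COLUMNS[:8]}..."
        )
    count_cols = [c for c in df.columns if "reads" in c]
    if (df[count_cols] < 0).any().any():
        raise TableParseError(f"{path}: negative read counts")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CandidateCall(
                key=VariantKey(str(row.chrom), int(row.position), row.ref, row.var),
                patient_id=patient_id,
                target_cell=target_cell,
                reference_cell=reference_cell,
                caller="varscan2",
                depth_target=int(row.tumor_reads1) + int(row.tumor_reads2),
                alt_reads_target=int(row.tumor_reads2),
                depth_reference=int(row.normal_reads1) + int(row.normal_reads2),
                alt_reads_reference=int(row.normal_reads2),
                alt_plus_strand=int(row.tumor_reads2_plus),
                alt_minus_strand=int(row.tumor_reads2_minus),
                somatic_p=float(row.somatic_p_value),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Annotation table

_ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "aa_change",
    "af_1000g",
    "af_esp6500",
    "af_cg69",
    "af_exac",
    "af_kaviar",
    "segdup",
    "gdi",
    "cadd",
    "msc",
    "gerp",
    "cosmic",
)


def _parse_af(value) -> float | None:
    """Empty cell or '.' means never observed (novel)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "-"):
        return None
    return float(s)


def read_annotation_table(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read a per-variant annotation table (Annovar-derived columns).

    Absent population frequencies are treated as never observed: the
    database is simply omitted from ``db_afs`` so ``novel`` is true and
    the effective frequency is 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing annotation columns {missing}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in out:
            raise TableParseError(f"{path}: duplicate annotation for {key}")
        db_afs = {}
        for db in AF_DATABASES:
            af = _parse_af(getattr(row, f"af_{db}"))
            if af is not None:
                db_afs[db] = af
        out[key] = AnnotationRecord(
            key=key,
            gene=str(row.gene),
            effect=str(row.effect),
            aa_change="" if pd.isna(row.aa_change) else str(row.aa_change),
            db_afs=db_afs,
            segdup=_parse_bool(row.segdup),
            gdi=float(row.gdi),
            cadd=float(row.cadd),
            msc=float(row.msc),
            gerp=float(row.gerp),
            cosmic=_parse_bool(row.cosmic),
        )
    return out


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    return s in ("1", "true", "yes", "+", "y")


def read_segdup_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read segmental-duplication intervals from BED.

    BED is 0-based half-open; intervals are converted to the package's
    1-based closed convention at read time.
    """
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise TableParseError(f"{path}:{line_no}: BED line with <3 columns")
            chrom, start, end = normalize_chrom(parts[0]), int(parts[1]), int(parts[2])
            intervals.append((chrom, start + 1, end))
    return intervals


# ---------------------------------------------------------------------------
# Report writing

_REPORT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "patient_id",
    "target_cell",
    "reference_cell",
    "depth_target",
    "alt_reads_target",
    "depth_reference",
    "alt_reads_reference",
    "aaf_target_pct",
    "aaf_reference_pct",
    "passed",
    "reasons",
)


def write_variant_report(records, decisions, path: str | Path) -> None:
    """Write one TSV row per candidate with its filter decision.

    ``records`` are consensus candidates (anything exposing ``key``,
    ``patient_id``, cell labels and AAFs); ``decisions`` align 1:1.
    Column order and row order are deterministic so repeated runs are
    byte-identical.  AAFs are reported as percent to 2 decimals.
    """
    records = list(records)
    decisions = list(decisions)
    if len(records) != len(decisions):
        raise CallsetError(
            f"records ({len(records)}) and decisions ({len(decisions)}) differ"
        )
    rows = []
    for rec, dec in zip(records, decisions):
        vs = rec.varscan if hasattr(rec, "varscan") else rec
        rows.append(
            {
                "chrom": rec.key.chrom,
                "pos": rec.key.pos,
                "ref": rec.key.ref,
                "alt": rec.key.alt,
                "patient_id": rec.patient_id,
                "target_cell": rec.target_cell,
                "reference_cell": rec.reference_cell,
                "depth_target": vs.depth_target,
                "alt_reads_target": vs.alt_reads_target,
                "depth_reference": vs.depth_reference,
                "alt_reads_reference": vs.alt_reads_reference,
                "aaf_target_pct": f"{100 * rec.aaf_target:.2f}",
                "aaf_reference_pct": f"{100 * rec.aaf_reference:.2f}",
                "passed": str(bool(dec.passed)).lower(),
                "reasons": ";".join(dec.reasons),
            }
        )
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df = df.sort_values(
        ["patient_id", "target_cell", "chrom", "pos", "ref", "alt"],
        kind="mergesort",
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_variant_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_variant_report`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "reasons": str})
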