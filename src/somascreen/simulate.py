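"""Synthetic cohorts of paired caller outputs with known truth labels.

The generator emulates the screening design: per patient, two sorted cell
populations (T and B by default) each act in turn as target and reference,
and every injected site is emitted in the dialects the readers consume
(MuTect2-style VCF, VarScan2 ``somatic`` table, annotation table).  Truth
labels make the filter engine's sensitivity and specificity measurable.

Injected site classes and the filter rule expected to remove each:

* ``true_somatic``          — present only in the target cell type; should pass.
* ``artifact:strand_biased``       — all alternate reads on one strand.
* ``artifact:recurrent_cross_sample`` — same site in >2 samples of a cell type.
* ``artifact:low_coverage_site``   — depth below the coverage floor.
* ``germline``  (leakage)          — high AAF in both cell types of a patient;
  caught by the reference-AAF rule.
* ``artifact:caller_discordant``   — emitted by a single caller only;
  removed by the consensus intersection.

Artifacts outnumber true variants roughly 10:1, the regime the pipeline
is designed for.  All randomness flows from one seeded generator with
deterministic per-patient substreams, so identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .callsets import (
    AnnotationRecord,
    CandidateCall,
    CallsetError,
    VariantKey,
)
from .filters import ConsensusCandidate, FilterDecision
from .replication import fisher_exact_one_sided

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SyntheticPair",
    "SyntheticCohort",
    "simulate_site_counts",
    "generate_cohort",
    "score_against_truth",
    "sample_gene_table",
]

_CHROMS = [str(c) for c in range(1, 23)] + ["X"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic screening cohort.

    Defaults mirror the screening design the pipeline targets: 10
    patients, T and B cells, mean on-target depth 342x, true somatic
    AAFs log-uniform on [0.5%, 20%], and a per-base error rate of 1e-3
    (post-deduplication short-read substitution noise).
    """

    n_patients: int = 10
    cell_types: tuple[str, str] = ("T", "B")
    depth_mean: float = 342.0
    depth_sd: float = 40.0
    n_true_variants: int = 8
    true_aaf_range: tuple[float, float] = (0.005, 0.20)
    #: fraction of true variants arising in the first (T) cell type
    target_cell_bias: float = 0.8
    n_strand_biased: int = 15
    n_recurrent_keys: int = 6
    recurrent_samples_per_key: int = 3
    n_low_coverage: int = 12
    n_germline_leaks: int = 8
    n_varscan_only: int = 40
    n_mutect_only: int = 10
    error_rate: float = 1e-3
    clustered_events_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or len(self.cell_types) < 2:
            raise CallsetError("need >= 1 patient and >= 2 cell types")
        lo, hi = self.true_aaf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise CallsetError("true AAF range must lie within (0, 0.5]")
        for name in ("error_rate", "clustered_events_fraction", "target_cell_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CallsetError(f"{name} must be in [0,1]")

    @property
    def patients(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted candidate instance."""

    key: VariantKey
    patient_id: str
    cell_type: str
    true_class: str  # true_somatic | germline | artifact:<class>
    true_aaf: float
    depth_target: int = 0
    depth_reference: int = 0


@dataclass
class SyntheticPair:
    """Caller outputs for one patient/target/reference combination."""

    patient_id: str
    target_cell: str
    reference_cell: str
    mutect_calls: list[CandidateCall] = field(default_factory=list)
    varscan_calls: list[CandidateCall] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    pairs: list[SyntheticPair]
    annotations: dict[VariantKey, AnnotationRecord]
    truth: list[TruthRecord]

    def truth_index(self) -> dict[tuple[VariantKey, str, str], TruthRecord]:
        return {(t.key, t.patient_id, t.cell_type): t for t in self.truth}

    def write(self, outdir: str | Path) -> dict[str, list[str]]:
        """Write caller dialects, annotation table and truth set as text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, list[str]] = {
            "mutect2_vcf": [],
            "varscan2_tsv": [],
            "annotation": [],
            "truth": [],
        }
        for pair in self.pairs:
            stem = f"{pair.patient_id}_{pair.target_cell}_vs_{pair.reference_cell}"
            vcf = outdir / f"{stem}.mutect2.vcf"
            _write_mutect_vcf(pair.mutect_calls, vcf)
            manifest["mutect2_vcf"].append(str(vcf))
            tsv = outdir / f"{stem}.varscan2.tsv"
            _write_varscan_table(pair.varscan_calls, tsv)
            manifest["varscan2_tsv"].append(str(tsv))
        ann_path = outdir / "annotations.tsv"
        _write_annotation_table(self.annotations, ann_path)
        manifest["annotation"].append(str(ann_path))
        truth_path = outdir / "truth.tsv"
        _write_truth_table(self.truth, truth_path)
        manifest["truth"].append(str(truth_path))
        return manifest


# ---------------------------------------------------------------------------
# site-level read-count model


def simulate_site_counts(
    true_aaf: float,
    depth: int,
    error_rate: float,
    strand_bias: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[int, int, int]:
    """Draw (alt_reads, alt_plus, alt_minus) for one sample at one site.

    Alternate reads are binomial at the true AAF plus the error
    contribution; the plus-strand share of alternate reads is binomial
    with parameter ``strand_bias`` (0.5 = unbiased, 1.0 = fully biased).
    """
    if not (0.0 <= true_aaf <= 1.0) or depth < 1:
        raise CallsetError("true_aaf must be in [0,1] and depth >= 1")
    if not (0.0 <= strand_bias <= 1.0) or not (0.0 <= error_rate <= 1.0):
        raise CallsetError("strand_bias and error_rate must be in [0,1]")
    rng = rng or np.random.default_rng()
    p_alt = min(1.0, true_aaf + error_rate)
    alt = int(rng.binomial(depth, p_alt))
    plus = int(rng.binomial(alt, strand_bias)) if alt else 0
    return alt, plus, alt - plus


# ---------------------------------------------------------------------------
# gene model


def sample_gene_table(
    n_genes: int,
    rng: np.random.Generator,
    high_gdi_fraction: float = 0.0325,
) -> pd.DataFrame:
    """Gene panel with heavy-tailed mutability and GDI tied to it.

    Per-gene mutability is Pareto-distributed (a small set of large,
    repetitive or highly polymorphic genes soak up a disproportionate
    share of calls).  GDI increases with mutability (genes frequently
    mutated in the healthy population score high) and is scaled so that
    ``high_gdi_fraction`` of genes exceed the 13.84 all-disease cutoff.
    """
    mutability = rng.pareto(1.5, size=n_genes) + 1.0
    noise = rng.lognormal(0.0, 0.4, size=n_genes)
    raw = mutability * noise
    cut = float(np.quantile(raw, 1.0 - high_gdi_fraction))
    gdi = raw * (13.84 / cut)
    return pd.DataFrame(
        {
            "gene": [f"GENE{i + 1:04d}" for i in range(n_genes)],
            "mutability": mutability / mutability.sum(),
            "gdi": gdi,
        }
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return int(max(50, round(rng.normal(cfg.depth_mean, cfg.depth_sd))))


def _loguniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


class _SiteFactory:
    """Allocates unique genomic sites deterministically."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._used: set[tuple[str, int]] = set()

    def new_key(self) -> VariantKey:
        while True:
            chrom = _CHROMS[int(self._rng.integers(len(_CHROMS)))]
            pos = int(self._rng.integers(1_000_000, 200_000_000))
            if (chrom, pos) in self._used:
                continue
            self._used.add((chrom, pos))
            ref, alt = self._rng.choice(list("ACGT"), size=2, replace=False)
            return VariantKey(chrom, pos, str(ref), str(alt))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic screening cohort with truth labels."""
    root_rng = np.random.default_rng(config.seed)
    site_factory = _SiteFactory(np.random.default_rng(root_rng.integers(2**31)))
    gene_rng = np.random.default_rng(root_rng.integers(2**31))
    genes = sample_gene_table(400, gene_rng)
    ann_rng = np.random.default_rng(root_rng.integers(2**31))

    patients = config.patients
    ct_a, ct_b = config.cell_types[0], config.cell_types[1]
    pairs: dict[tuple[str, str], SyntheticPair] = {}
    for pt in patients:
        for target, reference in ((ct_a, ct_b), (ct_b, ct_a)):
            pairs[(pt, target)] = SyntheticPair(pt, target, reference)

    truth: list[TruthRecord] = []
    annotations: dict[VariantKey, AnnotationRecord] = {}
    per_patient_rngs = {
        pt: np.random.default_rng(int(root_rng.integers(2**31))) for pt in patients
    }

    def emit(
        pair: SyntheticPair,
        key: VariantKey,
        rng: np.random.Generator,
        *,
        true_class: str,
        aaf_target: float,
        aaf_reference: float = 0.0,
        depth_target: int | None = None,
        depth_reference: int | None = None,
        strand_bias: float = 0.5,
        callers: tuple[str, ...] = ("mutect2", "varscan2"),
        mutect_filters: frozenset[str] = frozenset(),
        min_alt: int = 1,
    ) -> None:
        d_t = depth_target if depth_target is not None else _draw_depth(rng, config)
        d_r = (
            depth_reference
            if depth_reference is not None
            else _draw_depth(rng, config)
        )
        alt_t, plus, minus = simulate_site_counts(
            aaf_target, d_t, config.error_rate, strand_bias, rng
        )
        if alt_t < min_alt:  # ensure the site is actually callable
            alt_t = min_alt
            plus = alt_t if strand_bias >= 1.0 else max(1, alt_t - alt_t // 2)
            minus = alt_t - plus
            if strand_bias <= 0.0:
                plus, minus = 0, alt_t
        alt_r = int(
            rng.binomial(d_r, min(1.0, aaf_reference + config.error_rate))
        )
        if "varscan2" in callers:
            p_som = fisher_exact_one_sided(alt_t, d_t - alt_t, alt_r, d_r - alt_r)
            pair.varscan_calls.append(
                CandidateCall(
                    key=key,
                    patient_id=pair.patient_id,
                    target_cell=pair.target_cell,
                    reference_cell=pair.reference_cell,
                    caller="varscan2",
                    depth_target=d_t,
                    alt_reads_target=alt_t,
                    depth_reference=d_r,
                    alt_reads_reference=alt_r,
                    alt_plus_strand=plus,
                    alt_minus_strand=minus,
                    somatic_p=p_som,
                )
            )
        if "mutect2" in callers:
            pair.mutect_calls.append(
                CandidateCall(
                    key=key,
                    patient_id=pair.patient_id,
                    target_cell=pair.target_cell,
                    reference_cell=pair.reference_cell,
                    caller="mutect2",
                    depth_target=d_t,
                    alt_reads_target=alt_t,
                    depth_reference=0,
                    alt_reads_reference=0,
                    mutect_filters=mutect_filters,
                )
            )
        truth.append(
            TruthRecord(
                key=key,
                patient_id=pair.patient_id,
                cell_type=pair.target_cell,
                true_class=true_class,
                true_aaf=aaf_target,
                depth_target=d_t,
                depth_reference=d_r,
            )
        )
        if key not in annotations:
            annotations[key] = _annotate(key, true_class, genes, ann_rng)

    lo, hi = config.true_aaf_range
    for pt in patients:
        rng = per_patient_rngs[pt]
        # --- true somatic variants
        for _ in range(config.n_true_variants):
            cell = ct_a if rng.random() < config.target_cell_bias else ct_b
            filt = (
                frozenset({"clustered_events"})
                if rng.random() < config.clustered_events_fraction
                else frozenset()
            )
            emit(
                pairs[(pt, cell)],
                site_factory.new_key(),
                rng,
                true_class="true_somatic",
                aaf_target=_loguniform(rng, lo, hi),
                mutect_filters=filt,
            )
        # --- strand-biased artifacts
        for _ in range(config.n_strand_biased):
            cell = ct_a if rng.random() < 0.5 else ct_b
            emit(
                pairs[(pt, cell)],
                site_factory.new_key(),
                rng,
                true_class="artifact:strand_biased",
                aaf_target=_loguniform(rng, 0.01, 0.05),
                strand_bias=1.0 if rng.random() < 0.5 else 0.0,
            )
        # --- low-coverage sites
        for _ in range(config.n_low_coverage):
            cell = ct_a if rng.random() < 0.5 else ct_b
            emit(
                pairs[(pt, cell)],
                site_factory.new_key(),
                rng,
                true_class="artifact:low_coverage_site",
                aaf_target=_loguniform(rng, 0.02, 0.10),
                depth_target=int(rng.integers(80, 300)),
                depth_reference=int(rng.integers(80, 300)),
            )
        # --- germline leakage: high AAF in both cell types of this patient
        for _ in range(config.n_germline_leaks):
            key = site_factory.new_key()
            g_aaf = float(rng.uniform(0.40, 0.60))
            for cell in (ct_a, ct_b):
                emit(
                    pairs[(pt, cell)],
                    key,
                    rng,
                    true_class="germline",
                    aaf_target=g_aaf,
                    aaf_reference=g_aaf,
                )
        # --- single-caller noise (removed by the consensus intersection)
        for _ in range(config.n_varscan_only):
            cell = ct_a if rng.random() < 0.5 else ct_b
            emit(
                pairs[(pt, cell)],
                site_factory.new_key(),
                rng,
                true_class="artifact:caller_discordant",
                aaf_target=_loguniform(rng, 0.002, 0.02),
                callers=("varscan2",),
            )
        for _ in range(config.n_mutect_only):
            cell = ct_a if rng.random() < 0.5 else ct_b
            emit(
                pairs[(pt, cell)],
                site_factory.new_key(),
                rng,
                true_class="artifact:caller_discordant",
                aaf_target=_loguniform(rng, 0.005, 0.03),
                callers=("mutect2",),
            )

    # --- recurrent cross-sample artifacts: one site in several samples of
    #     the same cell type, different patients
    rec_rng = np.random.default_rng(root_rng.integers(2**31))
    n_carriers = min(config.recurrent_samples_per_key, config.n_patients)
    for _ in range(config.n_recurrent_keys):
        key = site_factory.new_key()
        cell = ct_a if rec_rng.random() < 0.5 else ct_b
        carriers = rec_rng.choice(len(patients), size=n_carriers, replace=False)
        for idx in sorted(int(i) for i in carriers):
            pt = patients[idx]
            emit(
                pairs[(pt, cell)],
                key,
                rec_rng,
                true_class="artifact:recurrent_cross_sample",
                aaf_target=_loguniform(rec_rng, 0.01, 0.05),
            )

    ordered_pairs = [pairs[(pt, ct)] for pt in patients for ct in (ct_a, ct_b)]
    for pair in ordered_pairs:
        pair.mutect_calls.sort(key=lambda c: (c.key.chrom, c.key.pos, c.key.alt))
        pair.varscan_calls.sort(key=lambda c: (c.key.chrom, c.key.pos, c.key.alt))
    truth.sort(key=lambda t: (t.patient_id, t.cell_type, t.key.chrom, t.key.pos))
    return SyntheticCohort(
        config=config, pairs=ordered_pairs, annotations=annotations, truth=truth
    )


def _annotate(
    key: VariantKey,
    true_class: str,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> AnnotationRecord:
    """Plausible functional/population annotations for a synthetic site."""
    gi = int(rng.choice(len(genes), p=genes["mutability"].to_numpy()))
    gene, gdi = str(genes["gene"].iloc[gi]), float(genes["gdi"].iloc[gi])
    effect = str(
        rng.choice(
            ["exonic_nonsynonymous", "exonic_synonymous", "splice", "other"],
            p=[0.55, 0.25, 0.05, 0.15],
        )
    )
    db_afs: dict[str, float] = {}
    if true_class == "germline":
        af = float(rng.uniform(0.05, 0.5))
        db_afs = {db: min(0.5, af * float(rng.uniform(0.8, 1.2))) for db in
                  ("1000g", "exac", "kaviar")}
    elif rng.random() < 0.3:  # most synthetic somatic/artifact sites are novel
        db_afs = {"kaviar": _loguniform(rng, 1e-6, 5e-3)}
    return AnnotationRecord(
        key=key,
        gene=gene,
        effect=effect,
        db_afs=db_afs,
        segdup=bool(rng.random() < 0.02),
        gdi=gdi,
        cadd=float(rng.uniform(0.0, 40.0)),
        msc=float(rng.uniform(0.0, 30.0)),
        gerp=float(rng.uniform(-12.0, 6.2)),
        cosmic=bool(rng.random() < 0.05),
    )


# ---------------------------------------------------------------------------
# scoring


def score_against_truth(
    decisions: Iterable[tuple[ConsensusCandidate, FilterDecision]],
    truth: Sequence[TruthRecord],
    min_true_aaf: float = 0.0,
    min_depth: int = 0,
) -> dict:
    """Confusion matrix of filter decisions against the generator's truth.

    Truth records with no consensus decision were removed by the caller
    intersection: false negatives when true somatic, true negatives
    otherwise.  ``min_true_aaf``/``min_depth`` additionally report
    sensitivity restricted to well-powered true variants (the regime the
    screening design guarantees coverage for).
    """
    if not truth:
        raise CallsetError("empty truth set")
    truth_index = {(t.key, t.patient_id, t.cell_type): t for t in truth}
    decided: dict[tuple, bool] = {}
    reason_lists: dict[tuple, tuple[str, ...]] = {}
    for cand, dec in decisions:
        stamp = (cand.key, cand.patient_id, cand.target_cell)
        if stamp not in truth_index:
            raise CallsetError(f"decision for unknown candidate {stamp}")
        decided[stamp] = dec.passed
        reason_lists[stamp] = dec.reasons

    tp = fn = tn = fp = 0
    restricted_tp = restricted_fn = 0
    reasons_by_class: dict[str, Counter] = {}
    for stamp, rec in truth_index.items():
        passed = decided.get(stamp, False)
        removed_by = reason_lists.get(stamp, ("caller_discordant",))
        if rec.true_class == "true_somatic":
            if passed:
                tp += 1
            else:
                fn += 1
            if rec.true_aaf >= min_true_aaf and min(
                rec.depth_target, rec.depth_reference
            ) >= min_depth:
                restricted_tp += int(passed)
                restricted_fn += int(not passed)
        else:
            if passed:
                fp += 1
            else:
                tn += 1
                tally = reasons_by_class.setdefault(rec.true_class, Counter())
                tally.update(removed_by)
    n_restricted = restricted_tp + restricted_fn
    passed_total = tp + fp
    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "restricted_sensitivity": (
            restricted_tp / n_restricted if n_restricted else float("nan")
        ),
        "n_restricted_true": n_restricted,
        "replication_rate_analogue": (
            tp / passed_total if passed_total else float("nan")
        ),
        "reasons_by_class": reasons_by_class,
    }


# ---------------------------------------------------------------------------
# text emission (same dialects the readers consume)


def _write_mutect_vcf(calls: Sequence[CandidateCall], path: Path) -> None:
    chroms = sorted({c.key.chrom for c in calls}, key=_chrom_order)
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=clustered_events,Description="Clustered events observed in the tumor">',
        '##FILTER=<ID=homologous_mapping_event,Description="More than three events observed in the tumor">',
        '##FILTER=<ID=t_lod_fstar,Description="Tumor does not meet likelihood threshold">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTARGET"
    )
    for c in sorted(calls, key=lambda c: (_chrom_order(c.key.chrom), c.key.pos)):
        filt = ";".join(sorted(c.mutect_filters)) if c.mutect_filters else "PASS"
        ref_reads = c.depth_target - c.alt_reads_target
        lines.append(
            f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t.\t"
            f"{filt}\t.\tAD:DP\t{ref_reads},{c.alt_reads_target}:{c.depth_target}"
        )
    path.write_text("\n".join(lines) + "\n")


def _chrom_order(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _write_varscan_table(calls: Sequence[CandidateCall], path: Path) -> None:
    from .callsets import VARSCAN_SOMATIC_COLUMNS

    rows = []
    for c in sorted(calls, key=lambda c: (_chrom_order(c.key.chrom), c.key.pos)):
        n_ref = c.depth_reference - c.alt_reads_reference
        t_ref = c.depth_target - c.alt_reads_target
        plus = c.alt_plus_strand or 0
        minus = c.alt_minus_strand or 0
        rows.append(
            {
                "chrom": c.key.chrom,
                "position": c.key.pos,
                "ref": c.key.ref,
                "var": c.key.alt,
                "normal_reads1": n_ref,
                "normal_reads2": c.alt_reads_reference,
                "normal_var_freq": f"{100 * c.aaf_reference:.2f}%",
                "normal_gt": c.key.ref,
                "tumor_reads1": t_ref,
                "tumor_reads2": c.alt_reads_target,
                "tumor_var_freq": f"{100 * c.aaf_target:.2f}%",
                "tumor_gt": f"{c.key.ref}/{c.key.alt}",
                "somatic_status": "Somatic",
                "variant_p_value": 1.0,
                "somatic_p_value": f"{c.somatic_p:.6g}",
                "tumor_reads1_plus": t_ref - t_ref // 2,
                "tumor_reads1_minus": t_ref // 2,
                "tumor_reads2_plus": plus,
                "tumor_reads2_minus": minus,
                "normal_reads1_plus": n_ref - n_ref // 2,
                "normal_reads1_minus": n_ref // 2,
                "normal_reads2_plus": c.alt_reads_reference
                - c.alt_reads_reference // 2,
                "normal_reads2_minus": c.alt_reads_reference // 2,
            }
        )
    df = pd.DataFrame(rows, columns=list(VARSCAN_SOMATIC_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_annotation_table(
    annotations: Mapping[VariantKey, AnnotationRecord], path: Path
) -> None:
    rows = []
    for key in sorted(
        annotations, key=lambda k: (_chrom_order(k.chrom), k.pos, k.alt)
    ):
        a = annotations[key]
        row = {
            "chrom": key.chrom,
            "pos": key.pos,
            "ref": key.ref,
            "alt": key.alt,
            "gene": a.gene,
            "effect": a.effect,
            "aa_change": a.aa_change or ".",
        }
        for db in ("1000g", "esp6500", "cg69", "exac", "kaviar"):
            row[f"af_{db}"] = (
                f"{a.db_afs[db]:.6g}" if db in a.db_afs else "."
            )
        row.update(
            segdup=int(a.segdup),
            gdi=f"{a.gdi:.4f}",
            cadd=f"{a.cadd:.2f}",
            msc=f"{a.msc:.2f}",
            gerp=f"{a.gerp:.2f}",
            cosmic=int(a.cosmic),
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_truth_table(truth: Sequence[TruthRecord], path: Path) -> None:
    rows = [
        {
            "chrom": t.key.chrom,
            "pos": t.key.pos,
            "ref": t.key.ref,
            "alt": t.key.alt,
            "patient_id": t.patient_id,
            "cell_type": t.cell_type,
            "true_class": t.true_class,
            "true_aaf": f"{t.true_aaf:.6g}",
            "depth_target": t.depth_target,
            "depth_reference": t.depth_reference,
        }
        for t in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        TruthRecord(
            key=VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt),
            patient_id=str(r.patient_id),
            cell_type=str(r.cell_type),
            true_class=str(r.true_class),
            true_aaf=float(r.true_aaf),
            depth_target=int(r.depth_target),
            depth_reference=int(r.depth_reference),
        )
        for r in df.itertuples(index=False)
    ]
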