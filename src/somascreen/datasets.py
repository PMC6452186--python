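"""Packaged example data.

Two small tables ship with the package, both transcribed from a published
10-patient multiple sclerosis screening study of somatic variants in
sorted CD3+ T and CD19+ B cells:

* :func:`load_replicated_variants` — the 36 somatic SNVs confirmed in the
  amplicon replication phase, with screening/replication AAFs, the
  replication p-value, CADD/MSC/GERP++ scores, Kaviar frequency and
  COSMIC status.  Rows replicated in a blood sample drawn about one year
  after screening carry ``timepoint == "later"``.
* :func:`load_ddpcr_wells` — droplet digital PCR ALT/REF channel
  concentrations for two of those variants across sorted T-cell subsets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .callsets import VariantKey
from .characterize import VariantProfile
from .ddpcr import DdpcrWell

__all__ = [
    "load_replicated_variants",
    "load_replicated_profiles",
    "load_ddpcr_wells",
    "COHORT_PATIENTS",
]

#: the full screening cohort, including the four patients in whom no
#: somatic variant was confirmed
COHORT_PATIENTS = tuple(f"MS-{i}" for i in range(1, 11))


def _data_path(name: str):
    return resources.files("somascreen.data").joinpath(name)


def load_replicated_variants() -> pd.DataFrame:
    """The 36 confirmed somatic variants as a DataFrame (AAFs in percent)."""
    with resources.as_file(_data_path("replicated_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def _is_synonymous(aa_change: str) -> bool:
    aa = aa_change.strip()
    return len(aa) >= 2 and aa[0].isalpha() and aa[0] == aa[-1]


def load_replicated_profiles() -> list[VariantProfile]:
    """The confirmed variants as :class:`VariantProfile` records.

    AAFs are converted to fractions; the synonymous/non-synonymous effect
    is derived from the amino-acid change notation (identical residue on
    both sides, e.g. P988P).  Dinucleotide context is not recorded in the
    source table, so ``cpg_context`` is None.
    """
    df = load_replicated_variants()
    profiles = []
    for row in df.itertuples(index=False):
        profiles.append(
            VariantProfile(
                key=VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt),
                patient_id=str(row.patient),
                cell_type=str(row.cell),
                effect=(
                    "synonymous" if _is_synonymous(row.aa_change) else "non-synonymous"
                ),
                aaf_screen=float(row.aaf_screen_pct) / 100.0,
                aaf_repl=float(row.aaf_repl_pct) / 100.0,
                kaviar_af=float(row.kaviar),
                novel=float(row.kaviar) == 0.0,
                cadd=float(row.cadd),
                msc=float(row.msc),
                gerp=float(row.gerp),
                cosmic=str(row.cosmic).strip() == "+",
                gene=str(row.gene),
            )
        )
    return profiles


def load_ddpcr_wells() -> dict[str, list[DdpcrWell]]:
    """Packaged ddPCR wells grouped by assay.

    Channel values are instrument-reported concentrations; fractional
    entries stem from merged replicate wells.
    """
    with resources.as_file(_data_path("ddpcr_wells.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    wells: dict[str, list[DdpcrWell]] = {}
    for row in df.itertuples(index=False):
        wells.setdefault(str(row.assay), []).append(
            DdpcrWell(
                sample_label=str(row.sample_label),
                alt_value=float(row.alt),
                ref_value=float(row.ref),
                provided_as="concentrations",
            )
        )
    return wells
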