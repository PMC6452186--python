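"""Droplet digital PCR quantification of individual somatic variants.

A ddPCR reaction partitions ~13 000 droplets; each droplet is read as
positive or negative per channel (ALT and REF assays).  Because a droplet
may hold several template copies, the positive-droplet fraction is
converted to a mean copy number per droplet by the Poisson occupancy
correction lambda = -ln(1 - p).  Allele fractions are then ratios of ALT
to REF concentrations.

Two allele-fraction conventions are supported.  The default,
``ratio_to_ref`` (ALT/REF), is the convention the packaged well tables
are reported in; ``ratio_to_total`` (ALT/(ALT+REF)) is the textbook
definition and agrees with it to first order at low allele fractions.
Wells may arrive as raw droplet counts or as instrument-exported
concentrations; both converge on the same allele-fraction operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .callsets import CallsetError

__all__ = [
    "DdpcrWell",
    "StandardCurve",
    "poisson_concentration",
    "allele_fraction",
    "cell_fraction",
    "fit_standard_curve",
    "quantify_well",
    "DEFAULT_LOD",
]

#: default limit of detection as an allele fraction (0.1%)
DEFAULT_LOD = 0.001


class SaturatedWellError(CallsetError):
    """All droplets positive: the Poisson correction diverges."""


@dataclass(frozen=True)
class DdpcrWell:
    """One ddPCR well (or merged replicate wells) for one assay.

    Provide either droplet counts (``droplets_total`` with per-channel
    positives) or pre-computed channel concentrations; ``provided_as``
    records which.  Fractional positives are permitted: merged replicate
    wells are averaged by the exporting software.
    """

    sample_label: str
    alt_value: float
    ref_value: float
    provided_as: str = "concentrations"  # "droplet_counts" | "concentrations"
    droplets_total: int | None = None

    def __post_init__(self) -> None:
        if self.provided_as not in ("droplet_counts", "concentrations"):
            raise CallsetError(f"unknown provided_as {self.provided_as!r}")
        if self.alt_value < 0 or self.ref_value < 0:
            raise CallsetError(f"{self.sample_label}: negative channel values")
        if self.provided_as == "droplet_counts":
            if not self.droplets_total or self.droplets_total < 1:
                raise CallsetError(
                    f"{self.sample_label}: droplet counts need droplets_total >= 1"
                )
            if max(self.alt_value, self.ref_value) > self.droplets_total:
                raise CallsetError(
                    f"{self.sample_label}: positives exceed total droplets"
                )


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of observed against expected allele fractions."""

    expected_af: tuple[float, ...]
    observed_af: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float


def poisson_concentration(n_positive: float, n_total: int) -> float:
    """Mean template copies per droplet from the positive-droplet count.

    lambda = -ln(1 - n_positive / n_total).  A saturated well (every
    droplet positive) carries no upper-bound information and is rejected.
    """
    if n_total < 1:
        raise CallsetError("n_total must be >= 1")
    if not (0 <= n_positive <= n_total):
        raise CallsetError("n_positive must lie in [0, n_total]")
    if n_positive == n_total:
        raise SaturatedWellError(
            f"unquantifiable well: all {n_total} droplets positive"
        )
    return -math.log1p(-n_positive / n_total)


def allele_fraction(
    alt_conc: float, ref_conc: float, convention: str = "ratio_to_ref"
) -> float:
    """Alternate-allele fraction from channel concentrations.

    ``ratio_to_ref`` returns ALT/REF (the reporting convention of the
    packaged well tables); ``ratio_to_total`` returns ALT/(ALT+REF).
    """
    if alt_conc < 0 or ref_conc < 0:
        raise CallsetError("concentrations must be non-negative")
    if convention == "ratio_to_ref":
        if ref_conc == 0:
            raise CallsetError("ratio_to_ref undefined for REF concentration 0")
        return alt_conc / ref_conc
    if convention == "ratio_to_total":
        total = alt_conc + ref_conc
        if total == 0:
            raise CallsetError("ratio_to_total undefined for ALT+REF = 0")
        return alt_conc / total
    raise CallsetError(f"unknown allele-fraction convention {convention!r}")


@dataclass(frozen=True)
class CellFraction:
    value: float
    warning: str | None = None


def cell_fraction(af: float, zygosity: str = "heterozygous") -> CellFraction:
    """Fraction of cells carrying the variant, from its allele fraction.

    Under the heterozygous assumption each mutant cell contributes one
    mutant and one wild-type allele, so the cell fraction is 2 x AF.  An
    AF above 50% is inconsistent with pure heterozygosity; the value is
    still returned (capped arithmetic is not applied) with a warning.
    """
    if zygosity != "heterozygous":
        raise CallsetError(f"unsupported zygosity {zygosity!r}")
    if af < 0:
        raise CallsetError("allele fraction must be non-negative")
    warning = None
    if af > 0.5:
        warning = (
            f"allele fraction {af:.4f} exceeds 0.5; inconsistent with a "
            "purely heterozygous variant"
        )
    return CellFraction(value=2.0 * af, warning=warning)


def fit_standard_curve(
    expected: Sequence[float], observed: Sequence[float]
) -> StandardCurve:
    """Fit observed = slope * expected + intercept by ordinary least squares."""
    if len(expected) != len(observed) or len(expected) < 2:
        raise CallsetError("need >= 2 aligned (expected, observed) points")
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if np.all(x == x[0]):
        raise CallsetError("expected values are constant; curve is unidentifiable")
    res = stats.linregress(x, y)
    return StandardCurve(
        expected_af=tuple(float(v) for v in x),
        observed_af=tuple(float(v) for v in y),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify_well(
    well: DdpcrWell,
    convention: str = "ratio_to_ref",
    lod: float = DEFAULT_LOD,
) -> dict:
    """Allele fraction for one well, flagging values below the limit of
    detection rather than reporting them as zero."""
    if well.provided_as == "droplet_counts":
        alt = poisson_concentration(well.alt_value, well.droplets_total)
        ref = poisson_concentration(well.ref_value, well.droplets_total)
    else:
        alt, ref = well.alt_value, well.ref_value
    af = allele_fraction(alt, ref, convention=convention)
    return {
        "sample_label": well.sample_label,
        "alt_concentration": alt,
        "ref_concentration": ref,
        "allele_fraction": af,
        "af_percent": round(100.0 * af, 2),
        "convention": convention,
        "below_lod": 0.0 < af < lod,
    }
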