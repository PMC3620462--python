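"""Concordance of sequencing calls with SNP-array genotypes.

A sequencing call's implied unordered diploid genotype ({alt, alt} for HOM,
{ref, alt} for HET) is compared with the two chip alleles at the same site.
Sites absent from the chip are NOT_ON_CHIP and excluded from rate
denominators; chip hom-ref genotypes at sequenced SNV sites count as
chip-discordant (the call asserts a variant the chip denies) and are flagged
distinctly.

The discordance pattern matrix is the 2x2 cross-tabulation of chip zygosity
against sequencing zygosity over chip-discordant sites; on real data its
mass concentrates in the (chip HOM, sequencing HET) cell, the signature of
het-to-hom genotyping error on the chip side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal

from .io_formats import ChipGenotype, SiteKey, VariantCall, Zygosity
from .rounding import percentage, round_half_away


class ChipStatusKind(str, enum.Enum):
    CHIP_CONCORDANT = "CHIP_CONCORDANT"
    CHIP_DISCORDANT = "CHIP_DISCORDANT"
    NOT_ON_CHIP = "NOT_ON_CHIP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ChipStatus:
    site: SiteKey
    status: ChipStatusKind
    chip_zygosity: Zygosity | None = None
    chip_is_hom_ref: bool = False


class ReferenceMismatchError(ValueError):
    """The call's stored ref allele disagrees with the reference sequence."""


def chip_status(
    call: VariantCall, chip: ChipGenotype | None, ref_base: str
) -> ChipStatus:
    """Compare one sequencing call with the chip genotype at its site.

    ``chip`` is ``None`` when the site is not assayed.  ``ref_base`` is the
    reference base at the site and must match the call's ref allele.
    """
    if ref_base != call.ref_allele:
        raise ReferenceMismatchError(
            f"reference base {ref_base!r} != call ref {call.ref_allele!r} "
            f"at {call.contig}:{call.position}"
        )
    if chip is None:
        return ChipStatus(call.site, ChipStatusKind.NOT_ON_CHIP)
    concordant = tuple(call.genotype) == chip.genotype
    hom_ref = chip.genotype == (ref_base, ref_base)
    return ChipStatus(
        call.site,
        ChipStatusKind.CHIP_CONCORDANT if concordant
        else ChipStatusKind.CHIP_DISCORDANT,
        chip.zygosity,
        chip_is_hom_ref=hom_ref,
    )


def concordance_rate(n_concordant: int, n_discordant: int) -> float | None:
    """Chip-concordance percentage, 100*c/(c+d), half-away-from-zero at 2 dp;
    zero denominator -> None."""
    return percentage(n_concordant, n_concordant + n_discordant)


@dataclass(frozen=True)
class PatternMatrix:
    """2x2 chip-zygosity x sequencing-zygosity counts over chip-discordant
    sites, with cell percentages of the grand total."""

    chip_hom_seq_hom: int
    chip_hom_seq_het: int
    chip_het_seq_hom: int
    chip_het_seq_het: int

    @property
    def total(self) -> int:
        return (self.chip_hom_seq_hom + self.chip_hom_seq_het
                + self.chip_het_seq_hom + self.chip_het_seq_het)

    def percentages(self) -> dict[str, float | None]:
        t = self.total
        return {
            name: percentage(getattr(self, name), t) if t else None
            for name in (
                "chip_hom_seq_hom", "chip_hom_seq_het",
                "chip_het_seq_hom", "chip_het_seq_het",
            )
        }


def pattern_matrix(pairs) -> PatternMatrix:
    """Tally (chip zygosity, sequencing zygosity) pairs into the 2x2 matrix.

    ``pairs`` is an iterable of ``(chip_zygosity, seq_zygosity)`` for the
    chip-discordant sites of interest (typically the concordant-between-
    platforms category).
    """
    counts = {
        (Zygosity.HOM, Zygosity.HOM): 0,
        (Zygosity.HOM, Zygosity.HET): 0,
        (Zygosity.HET, Zygosity.HOM): 0,
        (Zygosity.HET, Zygosity.HET): 0,
    }
    for chip_z, seq_z in pairs:
        counts[(Zygosity(chip_z), Zygosity(seq_z))] += 1
    return PatternMatrix(
        counts[(Zygosity.HOM, Zygosity.HOM)],
        counts[(Zygosity.HOM, Zygosity.HET)],
        counts[(Zygosity.HET, Zygosity.HOM)],
        counts[(Zygosity.HET, Zygosity.HET)],
    )


def median_depth(depths) -> float | None:
    """Median with the mean-of-middle-two convention for even n (so a list
    like [10, 11] reports 10.5); empty -> None."""
    depths = sorted(depths)
    n = len(depths)
    if n == 0:
        return None
    mid = n // 2
    if n % 2 == 1:
        return float(depths[mid])
    exact = (Decimal(depths[mid - 1]) + Decimal(depths[mid])) / 2
    return round_half_away(exact, 2)


def status_by_site(
    calls, chip: set[ChipGenotype], reference: dict[str, str]
) -> dict[SiteKey, ChipStatus]:
    """Chip status for every call in a call set, keyed by site."""
    chip_by_site = {g.site: g for g in chip}
    out: dict[SiteKey, ChipStatus] = {}
    for call in calls:
        ref_base = reference[call.contig][call.position - 1]
        out[call.site] = chip_status(call, chip_by_site.get(call.site), ref_base)
    return out
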