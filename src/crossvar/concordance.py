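"""Three-way classification of SNV calls between two sequencing platforms.

Every site called by either platform falls in exactly one of four
categories:

* ``CONCORDANT`` — called by both with the same alt allele and zygosity;
* ``DISCORDANT`` — called by both, but with differing zygosity or differing
  alt allele (alt disagreement is folded in and flagged on the record);
* ``P1_SPECIFIC`` / ``P2_SPECIFIC`` — called by exactly one platform.

Companion statistics: the heterozygosity rate within a category and the
fraction of a category's sites overlapping a repeat annotation, the two
signatures that distinguish platform-specific calls (high heterozygosity,
strong repeat enrichment) from the concordant bulk.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io_formats import RegionSet, SiteKey, VariantCall, Zygosity
from .rounding import percentage


class Category(str, enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"
    P1_SPECIFIC = "P1_SPECIFIC"
    P2_SPECIFIC = "P2_SPECIFIC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ConcordanceRecord:
    """A site's classification plus per-platform genotype bookkeeping.

    ``zygosity_p*`` / ``alt_p*`` / ``depth_p*`` are ``None`` for the absent
    platform of a *_SPECIFIC site.  ``alt_mismatch`` flags DISCORDANT sites
    whose two platforms reported different alt alleles.
    """

    site: SiteKey
    category: Category
    ref_allele: str
    zygosity_p1: Zygosity | None
    zygosity_p2: Zygosity | None
    alt_p1: str | None
    alt_p2: str | None
    depth_p1: int | None
    depth_p2: int | None
    alt_mismatch: bool = False

    def zygosity(self, platform: int) -> Zygosity | None:
        return self.zygosity_p1 if platform == 1 else self.zygosity_p2

    def depth(self, platform: int) -> int | None:
        return self.depth_p1 if platform == 1 else self.depth_p2

    def call(self, platform: int) -> VariantCall | None:
        zyg = self.zygosity(platform)
        if zyg is None:
            return None
        alt = self.alt_p1 if platform == 1 else self.alt_p2
        return VariantCall(
            self.site[0], self.site[1], self.ref_allele, alt, zyg,
            self.depth(platform) or 0,
        )


def _by_site(calls, label: str) -> dict[SiteKey, VariantCall]:
    out: dict[SiteKey, VariantCall] = {}
    for call in calls:
        if call.site in out:
            raise ValueError(
                f"duplicate site {call.site[0]}:{call.site[1]} in {label} call set"
            )
        out[call.site] = call
    return out


def classify_sites(p1, p2) -> list[ConcordanceRecord]:
    """Classify the union of two call sets into the four categories.

    Each input must contain at most one call per site.  The output covers
    every site present in either input exactly once.
    """
    c1 = _by_site(p1, "platform-1")
    c2 = _by_site(p2, "platform-2")
    records: list[ConcordanceRecord] = []
    for site in sorted(set(c1) | set(c2)):
        a, b = c1.get(site), c2.get(site)
        if a is not None and b is not None:
            if a.ref_allele != b.ref_allele:
                raise ValueError(
                    f"ref allele mismatch between call sets at {site[0]}:{site[1]}"
                )
            same = a.alt_allele == b.alt_allele and a.zygosity == b.zygosity
            records.append(ConcordanceRecord(
                site,
                Category.CONCORDANT if same else Category.DISCORDANT,
                a.ref_allele,
                a.zygosity, b.zygosity, a.alt_allele, b.alt_allele,
                a.depth, b.depth,
                alt_mismatch=a.alt_allele != b.alt_allele,
            ))
        elif a is not None:
            records.append(ConcordanceRecord(
                site, Category.P1_SPECIFIC, a.ref_allele,
                a.zygosity, None, a.alt_allele, None, a.depth, None,
            ))
        else:
            records.append(ConcordanceRecord(
                site, Category.P2_SPECIFIC, b.ref_allele,
                None, b.zygosity, None, b.alt_allele, None, b.depth,
            ))
    return records


def category_counts(records) -> dict[Category, int]:
    counts = {cat: 0 for cat in Category}
    for rec in records:
        counts[rec.category] += 1
    return counts


def _category_platform(category: Category) -> int:
    """The platform whose zygosity defines a category's stratification."""
    return 2 if category is Category.P2_SPECIFIC else 1


def heterozygosity_rate(
    records, category: Category, platform: int | None = None
) -> float | None:
    """Percentage of HET calls among a category's sites (2 dp), judged by
    the given platform's zygosity (default: the platform that defines the
    category; platform 1 for CONCORDANT/DISCORDANT).  Empty category -> None.
    """
    if platform is None:
        platform = _category_platform(category)
    zygs = [r.zygosity(platform) for r in records if r.category is category]
    if any(z is None for z in zygs):
        raise ValueError(f"zygosity undefined for platform {platform} in {category}")
    return percentage(sum(z is Zygosity.HET for z in zygs), len(zygs))


def repeat_overlap(records, category: Category, repeats: RegionSet) -> float | None:
    """Percentage of a category's sites falling inside a repeat interval.

    A 1-based variant position p occupies 0-based offset p-1, tested against
    the half-open repeat intervals.  Empty category -> None.
    """
    sites = [r.site for r in records if r.category is category]
    if not sites:
        return None
    inside = 0
    by_contig: dict[str, list[int]] = {}
    for contig, pos in sites:
        by_contig.setdefault(contig, []).append(pos - 1)
    for contig, offsets in by_contig.items():
        inside += int(repeats.membership(contig, np.asarray(offsets)).sum())
    return percentage(inside, len(sites))
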