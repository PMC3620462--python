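"""High-confidence heterozygote filtering on pileup base counts, and
depth-stratified summaries of heterozygous calls.

A heterozygous call is *highly confident* when the pileup at its site shows
more than ``min_depth`` reads (default 20) AND the second most frequent base
exceeds ``min_second_fraction`` of the total (default 0.30).  Both
comparisons are strict: a depth of exactly 20 or a second-base fraction of
exactly 30% fails.  A genuine het sampled at adequate depth shows both
alleles near 50%, so passing the filter is strong evidence the het call is
real even when an orthogonal genotyping platform disagrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SiteKey
from .rounding import percentage


@dataclass(frozen=True)
class PileupCounts:
    """Observed counts of the four bases at one site; their total is the
    depth used by the confidence criterion."""

    contig: str
    position: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != {"A", "C", "G", "T"}:
            raise ValueError("counts must have exactly the keys A, C, G, T")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("base counts must be non-negative")

    @property
    def site(self) -> SiteKey:
        return (self.contig, self.position)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def second_fraction(p: PileupCounts) -> float:
    """Fraction of the total held by the second most frequent base.

    When bases tie for second place, any base other than the single most
    frequent may serve; the maximum qualifying fraction is used (ties for
    first mean that fraction equals the top fraction).  Total 0 -> 0.0.
    """
    total = p.total
    if total == 0:
        return 0.0
    ordered = sorted(p.counts.values(), reverse=True)
    return ordered[1] / total


def is_confident_het(
    p: PileupCounts, min_depth: int = 20, min_second_fraction: float = 0.30
) -> bool:
    """True iff total > min_depth and second-base fraction > min_second_fraction
    (both strict)."""
    total = p.total
    if total <= min_depth:
        return False
    ordered = sorted(p.counts.values(), reverse=True)
    # strict comparison on the exact ratio: ordered[1]/total > f  <=>
    # ordered[1] > f*total, kept in integer arithmetic where possible
    return ordered[1] > min_second_fraction * total


def confident_fraction(
    sites, min_depth: int = 20, min_second_fraction: float = 0.30
) -> tuple[int, float] | None:
    """Count of sites passing the confidence filter and its percentage of
    the list (2 dp; round to whole percent for headline figures).  Empty
    list -> None."""
    sites = list(sites)
    if not sites:
        return None
    n_pass = sum(
        is_confident_het(p, min_depth, min_second_fraction) for p in sites
    )
    return n_pass, percentage(n_pass, len(sites))


def depth_cumulative_curve(groups: dict[str, list[int]]) -> dict[str, np.ndarray]:
    """Per-group cumulative depth distributions.

    For each named group of integer depths, returns an array of
    ``(depth, cumulative_fraction)`` rows: the fraction of the group with
    depth <= d at each observed depth d.  Curves are monotone non-decreasing
    and reach 1.  Used to compare heterozygous calls across concordance
    strata, where a left-shifted curve marks the low-depth group in which
    het-to-hom undercalling concentrates.
    """
    out: dict[str, np.ndarray] = {}
    for name, depths in groups.items():
        if not depths:
            raise ValueError(f"group {name!r} is empty")
        d = np.sort(np.asarray(depths))
        uniq, counts = np.unique(d, return_counts=True)
        cum = np.cumsum(counts) / len(d)
        out[name] = np.column_stack([uniq, cum])
    return out


def median_from_curve(curve: np.ndarray) -> float:
    """Median recovered from a cumulative curve (mean-of-middle-two
    convention, consistent with :func:`crossvar.chip_compare.median_depth`)."""
    depths, cum = curve[:, 0], curve[:, 1]
    lo = depths[np.searchsorted(cum, 0.5 - 1e-12)]
    hi = depths[np.searchsorted(cum, 0.5 + 1e-12)]
    return float((lo + hi) / 2)
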