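"""Recovering simulator parameters from pipeline outputs.

These estimators close the loop between the synthetic-data generator and
the analysis stages: each reads off one generator parameter from the
statistics the pipeline reports, so agreement between estimate and
parameter is an end-to-end check of both.
"""

from __future__ import annotations

from .chip_compare import ChipStatus, ChipStatusKind
from .concordance import Category, ConcordanceRecord
from .io_formats import SiteKey, Zygosity


def recover_het_fraction(records: list[ConcordanceRecord]) -> float:
    """Heterozygous fraction of the concordant category (platform 1's
    zygosity), an estimate of the genome's true het fraction when
    sequencing error rates are low."""
    conc = [r for r in records if r.category is Category.CONCORDANT]
    if not conc:
        raise ValueError("no concordant sites")
    return sum(r.zygosity_p1 is Zygosity.HET for r in conc) / len(conc)


def recover_chip_het_to_hom(
    records: list[ConcordanceRecord],
    statuses: dict[SiteKey, ChipStatus],
) -> float:
    """Chip het-to-hom error rate estimated from the pattern-matrix side:
    among chip-assayed concordant sequencing hets, the fraction the chip
    reports homozygous.  ``statuses`` are platform-1 chip statuses."""
    n_flip = n_het = 0
    for r in records:
        if r.category is not Category.CONCORDANT:
            continue
        if r.zygosity_p1 is not Zygosity.HET:
            continue
        st = statuses.get(r.site)
        if st is None or st.status is ChipStatusKind.NOT_ON_CHIP:
            continue
        n_het += 1
        if (st.status is ChipStatusKind.CHIP_DISCORDANT
                and st.chip_zygosity is Zygosity.HOM):
            n_flip += 1
    if n_het == 0:
        raise ValueError("no chip-assayed concordant het calls")
    return n_flip / n_het
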