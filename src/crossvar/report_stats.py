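"""Summary tables and test statistics for the two-platform comparison.

Three report families:

* a classification table — per concordance category and chip status, counts
  stratified by zygosity with chip-concordance rates and per-platform
  median depths;
* the 2x2 chip-discordance pattern matrix with cell percentages;
* the callability summary — per-dataset callable fractions, the merged
  gain over the platform average, and a chi-square / odds-ratio comparison
  of chip-concordance between merged and single-platform callable regions.

All percentages are computed from exact integer counts and rounded only at
render time; empty cells render "NA", never "0.00%".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np
from scipy.stats import chi2_contingency

from .chip_compare import (
    ChipStatus, ChipStatusKind, PatternMatrix, concordance_rate, median_depth,
)
from .concordance import Category, ConcordanceRecord
from .io_formats import SiteKey, Zygosity
from .rounding import fmt_pct, percentage, round_half_toward_zero


@dataclass(frozen=True)
class Table1Cell:
    count: int
    rate: float | None          # chip-concordance % within the chip substatus
    share: float | None         # % of the (category, chip-status) group total
    median_depth_p1: float | None
    median_depth_p2: float | None


@dataclass
class SummaryReport:
    """Everything the rendered reports need, as exact counts plus derived
    rates; every printed percentage is recomputable from the printed counts."""

    table1: dict[tuple[str, ChipStatusKind, str], Table1Cell] = field(
        default_factory=dict
    )
    pattern: PatternMatrix | None = None
    callability: dict[str, float | None] = field(default_factory=dict)
    callability_gain_pp: float | None = None
    gain_bases: float | None = None
    tests: dict[str, dict[str, float | None]] = field(default_factory=dict)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: dataset 1/2; columns: chip-concordant / chip-discordant."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def margins_positive(self) -> bool:
        return (self.a + self.b > 0 and self.c + self.d > 0
                and self.a + self.c > 0 and self.b + self.d > 0)


# ---------------------------------------------------------------------------
# classification table
# ---------------------------------------------------------------------------

_CHIP_STRATA = (ChipStatusKind.CHIP_CONCORDANT, ChipStatusKind.CHIP_DISCORDANT)

# Report rows: (row label, concordance category, platform whose call/chip
# comparison the row reports).  The DISCORDANT category appears once per
# platform because the two platforms' genotypes — and hence their chip
# statuses — differ there by construction.
TABLE1_ROWS: tuple[tuple[str, Category, int], ...] = (
    ("CONCORDANT", Category.CONCORDANT, 1),
    ("DISCORDANT_P1", Category.DISCORDANT, 1),
    ("DISCORDANT_P2", Category.DISCORDANT, 2),
    ("P1_SPECIFIC", Category.P1_SPECIFIC, 1),
    ("P2_SPECIFIC", Category.P2_SPECIFIC, 2),
)


def build_table1(
    records: list[ConcordanceRecord],
    statuses: dict[int, dict[SiteKey, ChipStatus]],
) -> dict[tuple[str, ChipStatusKind, str], Table1Cell]:
    """Tally (group x chip-status x zygosity) cells.

    ``statuses`` maps platform number (1/2) to per-site chip statuses of
    that platform's calls.  Rows follow :data:`TABLE1_ROWS`: the DISCORDANT
    category is reported separately per platform, and the stratifying
    zygosity is always the sequencing zygosity of the platform whose column
    is being reported.  Chip-concordance rates use only sites on the chip;
    NOT_ON_CHIP sites are excluded from denominators.
    """
    cells: dict[tuple[str, ChipStatusKind, str], Table1Cell] = {}
    for label, category, platform in TABLE1_ROWS:
        recs = [r for r in records if r.category is category]
        status_map = statuses[platform]
        on_chip = [
            r for r in recs
            if status_map.get(r.site) is not None
            and status_map[r.site].status is not ChipStatusKind.NOT_ON_CHIP
        ]
        group_total = len(on_chip)
        n_conc = sum(
            status_map[r.site].status is ChipStatusKind.CHIP_CONCORDANT
            for r in on_chip
        )
        n_disc = group_total - n_conc
        for chip_kind in _CHIP_STRATA:
            sel = [r for r in on_chip if status_map[r.site].status is chip_kind]
            strata: dict[str, list[ConcordanceRecord]] = {
                "Total": sel,
                "HOM": [r for r in sel if r.zygosity(platform) is Zygosity.HOM],
                "HET": [r for r in sel if r.zygosity(platform) is Zygosity.HET],
            }
            for zname, zrecs in strata.items():
                # rate: within the chip-concordant stratum this is the
                # group-level chip-concordance for "Total" and the share of
                # the group for HOM/HET sub-rows (the table's convention);
                # chip-discordant rows carry no rate.
                if chip_kind is ChipStatusKind.CHIP_CONCORDANT:
                    if zname == "Total":
                        rate = concordance_rate(n_conc, n_disc)
                    else:
                        rate = percentage(len(zrecs), group_total) \
                            if group_total else None
                else:
                    rate = None
                d1 = [r.depth_p1 for r in zrecs if r.depth_p1 is not None]
                d2 = [r.depth_p2 for r in zrecs if r.depth_p2 is not None]
                cells[(label, chip_kind, zname)] = Table1Cell(
                    count=len(zrecs),
                    rate=rate,
                    share=percentage(len(zrecs), group_total)
                    if group_total else None,
                    median_depth_p1=median_depth(d1),
                    median_depth_p2=median_depth(d2),
                )
    return cells


# ---------------------------------------------------------------------------
# callability gain
# ---------------------------------------------------------------------------

def callability_gain(frac1: float, frac2: float, frac_merged: float) -> float:
    """Merged callability minus the mean of the two platform callabilities,
    in percentage points at 2 dp.

    The final rounding breaks ties toward zero so a reported gain is never
    overstated (the inputs are themselves 2-dp percentages, so exact
    midpoints like 1.435 occur routinely).
    """
    for v in (frac1, frac2, frac_merged):
        if not 0 <= v <= 100:
            raise ValueError("callability fractions must be in [0, 100]")
    exact = callability_gain_exact(frac1, frac2, frac_merged)
    return round_half_toward_zero(exact, 2)


def callability_gain_exact(
    frac1: float, frac2: float, frac_merged: float
) -> Decimal:
    return (Decimal(str(frac_merged))
            - (Decimal(str(frac1)) + Decimal(str(frac2))) / 2)


def gain_bases(gain_pp: float | Decimal, genome_length: int) -> float:
    """A gain in percentage points expressed as reference bases."""
    return float(Decimal(str(gain_pp)) * genome_length / 100)


# ---------------------------------------------------------------------------
# chi-square and odds ratio
# ---------------------------------------------------------------------------

def chi_square_or(
    t: ContingencyTable2x2, yates: bool = False
) -> tuple[float | None, float | None, float | None]:
    """Pearson chi-square (1 df, no continuity correction by default) and
    the odds ratio (a*d)/(b*c) for a 2x2 table.

    Chi-square is defined only when all margins are positive; the odds
    ratio is None when b*c == 0 (no Haldane correction is applied).
    """
    chi2 = p = None
    if t.margins_positive:
        stat, pval, _, _ = chi2_contingency(
            np.array([[t.a, t.b], [t.c, t.d]]), correction=yates
        )
        chi2, p = float(stat), float(pval)
    odds = (t.a * t.d) / (t.b * t.c) if t.b * t.c > 0 else None
    return chi2, p, odds


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt_num(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return str(x)


def render_table1(
    cells: dict[tuple[str, ChipStatusKind, str], Table1Cell]
) -> str:
    """Deterministic TSV of the classification table."""
    lines = ["group\tchip_status\tzygosity\tcount\tchip_concordance"
             "\tshare_of_group\tmedian_depth_p1\tmedian_depth_p2"]
    for label, _category, _platform in TABLE1_ROWS:
        for chip_kind in _CHIP_STRATA:
            for zname in ("Total", "HOM", "HET"):
                cell = cells.get((label, chip_kind, zname))
                if cell is None:
                    continue
                lines.append("\t".join([
                    label,
                    chip_kind.value, zname, str(cell.count),
                    fmt_pct(cell.rate), fmt_pct(cell.share),
                    _fmt_num(cell.median_depth_p1),
                    _fmt_num(cell.median_depth_p2),
                ]))
    return "\n".join(lines) + "\n"


def render_table2(matrix: PatternMatrix) -> str:
    pct = matrix.percentages()
    rows = [
        ("HOM", "HOM", matrix.chip_hom_seq_hom, pct["chip_hom_seq_hom"]),
        ("HOM", "HET", matrix.chip_hom_seq_het, pct["chip_hom_seq_het"]),
        ("HET", "HOM", matrix.chip_het_seq_hom, pct["chip_het_seq_hom"]),
        ("HET", "HET", matrix.chip_het_seq_het, pct["chip_het_seq_het"]),
    ]
    lines = ["chip_zygosity\tseq_zygosity\tcount\tpercent_of_total"]
    for chip_z, seq_z, n, p in rows:
        lines.append(f"{chip_z}\t{seq_z}\t{n}\t{fmt_pct(p)}")
    lines.append(f"Total\t\t{matrix.total}\t{fmt_pct(percentage(matrix.total, matrix.total) if matrix.total else None)}")
    return "\n".join(lines) + "\n"


def render_callability(report: SummaryReport) -> str:
    lines = ["dataset\tcallable_percent"]
    for name, frac in report.callability.items():
        lines.append(f"{name}\t{fmt_pct(frac)}")
    if report.callability_gain_pp is not None:
        lines.append(f"merged_gain_pp\t{report.callability_gain_pp:.2f}")
    if report.gain_bases is not None:
        lines.append(f"merged_gain_bases\t{report.gain_bases:.0f}")
    return "\n".join(lines) + "\n"


def render_tests(tests: dict[str, dict[str, float | None]]) -> str:
    lines = ["comparison\tchi2\tp_value\todds_ratio"]
    for name, vals in tests.items():
        chi2 = "NA" if vals.get("chi2") is None else f"{vals['chi2']:.6g}"
        p = "NA" if vals.get("p") is None else f"{vals['p']:.3g}"
        odds = "NA" if vals.get("or") is None else f"{vals['or']:.2f}"
        lines.append(f"{name}\t{chi2}\t{p}\t{odds}")
    return "\n".join(lines) + "\n"


def render_reports(report: SummaryReport) -> dict[str, str]:
    """All rendered report files keyed by name; same input, byte-identical
    output."""
    out: dict[str, str] = {}
    if report.table1:
        out["table1.tsv"] = render_table1(report.table1)
    if report.pattern is not None:
        out["table2.tsv"] = render_table2(report.pattern)
    if report.callability:
        out["callability.tsv"] = render_callability(report)
    if report.tests:
        out["table3_tests.tsv"] = render_tests(report.tests)
    return out
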