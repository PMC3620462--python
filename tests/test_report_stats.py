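import re
from decimal import Decimal

import numpy as np
import pytest

from crossvar.chip_compare import ChipStatusKind, pattern_matrix, status_by_site
from crossvar.concordance import classify_sites
from crossvar.io_formats import ChipGenotype, VariantCall, Zygosity
from crossvar.report_stats import (
    ContingencyTable2x2, SummaryReport, build_table1, callability_gain,
    callability_gain_exact, chi_square_or, gain_bases, render_reports,
    render_table1, render_table2,
)


def brute_force_chi2(a, b, c, d):
    """Sum of (O-E)^2/E over the 2x2 with expected counts from margins."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows * cols / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


class TestChiSquareOr:
    def test_odds_ratio_example(self):
        _, _, odds = chi_square_or(ContingencyTable2x2(10, 10, 5, 20))
        assert odds == 4.0

    def test_equal_row_proportions_null(self):
        chi2, p, odds = chi_square_or(ContingencyTable2x2(30, 10, 60, 20))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert odds == 1.0
        assert p == pytest.approx(1.0)

    def test_zero_cell_or_is_na(self):
        _, _, odds = chi_square_or(ContingencyTable2x2(10, 0, 5, 20))
        assert odds is None

    def test_degenerate_margin_chi2_na(self):
        chi2, p, _ = chi_square_or(ContingencyTable2x2(0, 0, 5, 20))
        assert chi2 is None and p is None

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 500, size=4)
            chi2, _, _ = chi_square_or(ContingencyTable2x2(a, b, c, d))
            assert chi2 == pytest.approx(brute_force_chi2(a, b, c, d), abs=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestCallabilityGain:
    def test_published_style_example(self):
        assert callability_gain(98.30, 98.15, 99.66) == 1.43

    def test_no_gain_when_equal(self):
        assert callability_gain(97.0, 97.0, 97.0) == 0.00

    def test_gain_in_bases(self):
        exact = callability_gain_exact(98.30, 98.15, 99.66)
        assert exact == Decimal("1.435")
        # ~40 million bases on a 2.85 Gb genome
        assert gain_bases(exact, 2_850_000_000) == pytest.approx(40.9e6, rel=0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            callability_gain(101, 98, 99)


class TestBuildTable1:
    @staticmethod
    def synthetic_discordant_cells(n_chip_conc, n_chip_disc):
        """Discordant sites (p1 HOM vs p2 HET) with a chosen p1 chip split."""
        reference = {"c": "A" * (n_chip_conc + n_chip_disc + 2)}
        p1, p2, chip = [], [], set()
        for i in range(n_chip_conc + n_chip_disc):
            pos = i + 1
            p1.append(VariantCall("c", pos, "A", "G", Zygosity.HOM, 20))
            p2.append(VariantCall("c", pos, "A", "G", Zygosity.HET, 30))
            if i < n_chip_conc:
                chip.add(ChipGenotype("c", pos, "G", "G"))   # matches p1 HOM
            else:
                chip.add(ChipGenotype("c", pos, "C", "C"))   # matches neither
        records = classify_sites(p1, p2)
        statuses = {
            1: status_by_site(p1, chip, reference),
            2: status_by_site(p2, chip, reference),
        }
        return build_table1(records, statuses)

    def test_injected_counts_reproduce_90_08(self):
        cells = self.synthetic_discordant_cells(2_489, 274)
        cell = cells[("DISCORDANT_P1", ChipStatusKind.CHIP_CONCORDANT, "Total")]
        assert cell.count == 2_489
        assert cell.rate == 90.08

    def test_hom_plus_het_equals_total(self, sim_analysis):
        records, statuses = sim_analysis
        cells = build_table1(records, statuses)
        for (label, kind, zyg), cell in cells.items():
            if zyg != "Total":
                continue
            hom = cells[(label, kind, "HOM")].count
            het = cells[(label, kind, "HET")].count
            assert hom + het == cell.count

    def test_error_free_bundle_has_empty_discordant_cells(self):
        from test_synthetic_data import no_error_config
        from crossvar.synthetic_data import (
            designate_specific, simulate_chip, simulate_platform,
            simulate_reference, simulate_truth,
        )

        cfg = no_error_config()
        ref, reps = simulate_reference(cfg)
        truth = simulate_truth(cfg, ref, reps)
        spec = designate_specific(cfg, truth)
        p1, *_ = simulate_platform(cfg, truth, ref, reps, "p1", spec)
        p2, *_ = simulate_platform(cfg, truth, ref, reps, "p2", spec)
        chip = simulate_chip(cfg, truth)
        records = classify_sites(p1, p2)
        statuses = {1: status_by_site(p1, chip, ref),
                    2: status_by_site(p2, chip, ref)}
        cells = build_table1(records, statuses)
        for (label, kind, _), cell in cells.items():
            if "DISCORDANT" in label or kind is ChipStatusKind.CHIP_DISCORDANT:
                assert cell.count == 0
            if label == "CONCORDANT" and kind is ChipStatusKind.CHIP_CONCORDANT:
                pass
        assert cells[("CONCORDANT", ChipStatusKind.CHIP_CONCORDANT, "Total")].rate \
            == 100.00


class TestRendering:
    def test_same_input_byte_identical(self, sim_analysis):
        records, statuses = sim_analysis
        report = SummaryReport()
        report.table1 = build_table1(records, statuses)
        assert render_reports(report) == render_reports(report)

    def test_empty_cells_render_na_not_zero(self):
        cells = TestBuildTable1.synthetic_discordant_cells(3, 0)
        text = render_table1(cells)
        conc_rows = [l for l in text.splitlines() if l.startswith("CONCORDANT")]
        assert all("\tNA\t" in row for row in conc_rows)
        assert "0.00%" not in "".join(conc_rows)

    def test_printed_rates_rederivable_from_printed_counts(self, sim_analysis):
        from crossvar.rounding import percentage

        records, statuses = sim_analysis
        cells = build_table1(records, statuses)
        text = render_table1(cells)
        lines = text.splitlines()[1:]
        parsed = {}
        for line in lines:
            label, kind, zyg, count, rate, share, *_ = line.split("\t")
            parsed[(label, kind, zyg)] = (int(count), rate, share)
        for (label, kind, zyg), (count, rate, share) in parsed.items():
            group_total = (parsed[(label, "CHIP_CONCORDANT", "Total")][0]
                           + parsed[(label, "CHIP_DISCORDANT", "Total")][0])
            if share != "NA":
                assert share == f"{percentage(count, group_total):.2f}%"

    def test_pattern_matrix_percentages_in_render(self):
        m = pattern_matrix(
            [(Zygosity.HOM, Zygosity.HET)] * 3 + [(Zygosity.HET, Zygosity.HOM)]
        )
        text = render_table2(m)
        assert "75.00%" in text and "25.00%" in text and "Total\t\t4" in text
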