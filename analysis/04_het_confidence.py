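"""High-confidence heterozygote filtering and depth stratification.

Applies the stringent pileup criterion (more than 20x coverage and a
second-base fraction above 30%) to heterozygous calls, and writes the
cumulative depth distributions of heterozygous calls stratified by
concordance and chip status.  Chip-discordant het calls that pass the
filter are strong candidates for chip-side genotyping error; a left-shifted
depth curve marks the stratum where low coverage drives het undercalling.
"""

from common import RESULTS, load_bundle

from crossvar.chip_compare import ChipStatusKind, status_by_site
from crossvar.concordance import Category, classify_sites
from crossvar.het_confidence import confident_fraction, depth_cumulative_curve
from crossvar.io_formats import Zygosity
from crossvar.rounding import fmt_pct


def main() -> None:
    bundle = load_bundle()
    records = classify_sites(bundle["p1"], bundle["p2"])
    statuses2 = status_by_site(bundle["p2"], bundle["chip"], bundle["reference"])
    pileups2 = {p.site: p for p in bundle["p2_pileups"]}

    def stratum(category, chip_kind):
        return [
            r for r in records
            if r.category is category and r.zygosity_p2 is Zygosity.HET
            and r.site in statuses2 and statuses2[r.site].status is chip_kind
        ]

    strata = {
        "concordant_chip_concordant":
            stratum(Category.CONCORDANT, ChipStatusKind.CHIP_CONCORDANT),
        "concordant_chip_discordant":
            stratum(Category.CONCORDANT, ChipStatusKind.CHIP_DISCORDANT),
        "discordant_chip_discordant":
            stratum(Category.DISCORDANT, ChipStatusKind.CHIP_DISCORDANT),
    }

    lines = ["stratum\tn_het\tn_confident\tpercent"]
    for name, recs in strata.items():
        piles = [pileups2[r.site] for r in recs if r.site in pileups2]
        if not piles:
            lines.append(f"{name}\t0\t0\tNA")
            continue
        n_pass, pct = confident_fraction(piles)
        print(f"{name}: {n_pass}/{len(piles)} highly confident ({fmt_pct(pct)})")
        lines.append(f"{name}\t{len(piles)}\t{n_pass}\t{fmt_pct(pct)}")
    (RESULTS / "het_confidence.tsv").write_text("\n".join(lines) + "\n")

    groups = {
        name: [r.depth_p2 for r in recs]
        for name, recs in strata.items() if recs
    }
    curves = depth_cumulative_curve(groups)
    with open(RESULTS / "het_depth_curves.tsv", "w", newline="\n") as fh:
        fh.write("stratum\tdepth\tcumulative_fraction\n")
        for name in sorted(curves):
            for depth, frac in curves[name]:
                fh.write(f"{name}\t{int(depth)}\t{frac:.6f}\n")
    print(f"wrote {RESULTS / 'het_confidence.tsv'} and "
          f"{RESULTS / 'het_depth_curves.tsv'}")


if __name__ == "__main__":
    main()
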