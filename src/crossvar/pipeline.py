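"""End-to-end pipeline: simulate (optional) -> compare -> chip-concordance
-> het-confidence -> callability -> report.

Every stage consumes and produces plain files, so any stage can be rerun
alone; :func:`run_all` chains them, validates inputs up front (paths exist,
thresholds within their invariants, contig names identical across all
inputs), logs per-stage record counts to stderr, and writes a machine-
readable run manifest next to the outputs.  Identical config + seed gives a
byte-identical output bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats as io
from .callability import (
    CallabilityThresholds, State, build_track, callability_fraction,
    export_regions, merge_tracks, noncallable_base_composition,
)
from .chip_compare import ChipStatusKind, pattern_matrix, status_by_site
from .concordance import (
    Category, category_counts, classify_sites, heterozygosity_rate,
    repeat_overlap,
)
from .het_confidence import confident_fraction, depth_cumulative_curve
from .io_formats import Zygosity
from .report_stats import (
    ContingencyTable2x2, SummaryReport, build_table1, callability_gain,
    callability_gain_exact, chi_square_or, gain_bases, render_reports,
)
from .rounding import fmt_pct

log = logging.getLogger("crossvar")


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    out_dir: Path
    # inputs (filled automatically when simulate=True)
    reference: Path | None = None
    repeats: Path | None = None
    p1_vcf: Path | None = None
    p2_vcf: Path | None = None
    p1_depth: Path | None = None
    p1_mq: Path | None = None
    p2_depth: Path | None = None
    p2_mq: Path | None = None
    chip: Path | None = None
    p1_pileup: Path | None = None
    p2_pileup: Path | None = None
    # behaviour
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    min_depth: int = 4
    min_mq: float = 10.0
    het_min_depth: int = 20
    het_min_second_fraction: float = 0.30
    seed: int = 2013

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        paths = {
            k: Path(v) for k, v in raw.items()
            if k in ("out_dir", "reference", "repeats", "p1_vcf", "p2_vcf",
                     "p1_depth", "p1_mq", "p2_depth", "p2_mq", "chip",
                     "p1_pileup", "p2_pileup")
        }
        rest = {k: v for k, v in raw.items() if k not in paths}
        return cls(**paths, **rest)

    def validate(self) -> None:
        CallabilityThresholds(self.min_depth, self.min_mq)  # raises if invalid
        if self.het_min_depth < 1:
            raise ValueError("het_min_depth must be >= 1")
        if not 0 <= self.het_min_second_fraction <= 1:
            raise ValueError("het_min_second_fraction must be in [0, 1]")
        if not self.simulate:
            required = ("reference", "repeats", "p1_vcf", "p2_vcf", "p1_depth",
                        "p1_mq", "p2_depth", "p2_mq", "chip")
            missing = [
                name for name in required
                if getattr(self, name) is None or not Path(getattr(self, name)).exists()
            ]
            if missing:
                raise FileNotFoundError(
                    f"missing input files: {', '.join(missing)}"
                )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> SummaryReport:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        from .synthetic_data import SimConfig, simulate_bundle

        sim = SimConfig(seed=config.seed, **config.sim_overrides)
        paths = simulate_bundle(sim, out / "sim")
        config.reference = paths["reference"]
        config.repeats = paths["repeats"]
        config.p1_vcf, config.p2_vcf = paths["p1_vcf"], paths["p2_vcf"]
        config.p1_depth, config.p1_mq = paths["p1_depth"], paths["p1_mq"]
        config.p2_depth, config.p2_mq = paths["p2_depth"], paths["p2_mq"]
        config.chip = paths["chip"]
        config.p1_pileup, config.p2_pileup = paths["p1_pileup"], paths["p2_pileup"]
        log.info("simulate: wrote %d files to %s", len(paths), out / "sim")

    reference = io.read_fasta(config.reference)
    lengths = {c: len(s) for c, s in reference.items()}
    repeats = io.read_bed(config.repeats)
    p1 = io.read_snvs(config.p1_vcf)
    p2 = io.read_snvs(config.p2_vcf)
    chip = io.read_chip(config.chip)
    # every non-reference input must stay within the reference's contig
    # namespace (no chr-prefix aliasing)
    offending = {
        name: sorted(contigs - set(lengths))
        for name, contigs in (
            ("p1_vcf", {c.contig for c in p1}),
            ("p2_vcf", {c.contig for c in p2}),
            ("chip", {g.contig for g in chip}),
            ("repeats", {c for c, _, _ in repeats}),
        )
        if contigs - set(lengths)
    }
    if offending:
        raise io.FormatError(
            "contig names not in reference: "
            + "; ".join(f"{k}: {v}" for k, v in offending.items())
        )
    log.info("inputs: %d p1 calls, %d p2 calls, %d chip sites, %d contigs",
             len(p1), len(p2), len(chip), len(lengths))

    # --- concordance ------------------------------------------------------
    records = classify_sites(p1, p2)
    counts = category_counts(records)
    log.info("compare: %s", {k.value: v for k, v in counts.items()})
    with open(out / "concordance.tsv", "w", newline="\n") as fh:
        fh.write("contig\tposition\tcategory\tzygosity_p1\tzygosity_p2"
                 "\talt_p1\talt_p2\tdepth_p1\tdepth_p2\n")
        for r in records:
            fh.write("\t".join(str(x) if x is not None else "." for x in (
                r.site[0], r.site[1], r.category.value,
                r.zygosity_p1 and r.zygosity_p1.value,
                r.zygosity_p2 and r.zygosity_p2.value,
                r.alt_p1, r.alt_p2, r.depth_p1, r.depth_p2,
            )) + "\n")

    # --- chip concordance -------------------------------------------------
    statuses = {
        1: status_by_site(p1, chip, reference),
        2: status_by_site(p2, chip, reference),
    }
    report = SummaryReport()
    report.table1 = build_table1(records, statuses)
    conc_disc_pairs = [
        (statuses[1][r.site].chip_zygosity, r.zygosity_p1)
        for r in records
        if r.category is Category.CONCORDANT
        and statuses[1].get(r.site) is not None
        and statuses[1][r.site].status is ChipStatusKind.CHIP_DISCORDANT
    ]
    report.pattern = pattern_matrix(conc_disc_pairs)

    # --- het confidence ---------------------------------------------------
    het_lines = []
    for pnum, pileup_path in ((1, config.p1_pileup), (2, config.p2_pileup)):
        if pileup_path is None or not Path(pileup_path).exists():
            continue
        pileups = io.read_pileups(pileup_path)
        het_sites = {
            r.site for r in records if r.zygosity(pnum) is Zygosity.HET
        }
        het_pile = [p for p in pileups if p.site in het_sites]
        res = confident_fraction(
            het_pile, config.het_min_depth, config.het_min_second_fraction
        )
        if res is not None:
            het_lines.append(f"p{pnum}\t{res[0]}\t{len(het_pile)}\t{fmt_pct(res[1])}")
    if het_lines:
        (out / "het_confidence.tsv").write_text(
            "platform\tn_confident\tn_het\tpercent\n" + "\n".join(het_lines) + "\n"
        )

    # depth stratification of het calls (cumulative curves)
    groups: dict[str, list[int]] = {}
    for r in records:
        if r.category is Category.CONCORDANT and r.zygosity_p2 is Zygosity.HET:
            st = statuses[2].get(r.site)
            if st is not None and st.status is ChipStatusKind.CHIP_CONCORDANT:
                groups.setdefault("concordant_chip_concordant", []).append(r.depth_p2)
            elif st is not None and st.status is ChipStatusKind.CHIP_DISCORDANT:
                groups.setdefault("concordant_chip_discordant", []).append(r.depth_p2)
        elif r.category is Category.DISCORDANT and r.zygosity_p2 is Zygosity.HET:
            st = statuses[2].get(r.site)
            if st is not None and st.status is ChipStatusKind.CHIP_DISCORDANT:
                groups.setdefault("discordant_chip_discordant", []).append(r.depth_p2)
    curves = depth_cumulative_curve({k: v for k, v in groups.items() if v})
    with open(out / "het_depth_curves.tsv", "w", newline="\n") as fh:
        fh.write("group\tdepth\tcumulative_fraction\n")
        for name in sorted(curves):
            for depth, frac in curves[name]:
                fh.write(f"{name}\t{int(depth)}\t{frac:.6f}\n")

    # --- callability ------------------------------------------------------
    thresholds = CallabilityThresholds(config.min_depth, config.min_mq)
    d1 = io.read_track(config.p1_depth, lengths)
    m1 = io.read_track(config.p1_mq, lengths)
    d2 = io.read_track(config.p2_depth, lengths)
    m2 = io.read_track(config.p2_mq, lengths)
    tracks = {
        "p1": build_track(d1, m1, thresholds),
        "p2": build_track(d2, m2, thresholds),
        "merged": merge_tracks(d1, m1, d2, m2, thresholds),
    }
    for name, track in tracks.items():
        io.write_bed(export_regions(track, State.CALLABLE),
                     out / f"{name}.callable.bed", labels="CALLABLE")
    report.callability = {
        name: callability_fraction(track) for name, track in tracks.items()
    }
    f1, f2, fm = (report.callability[k] for k in ("p1", "p2", "merged"))
    report.callability_gain_pp = callability_gain(f1, f2, fm)
    report.gain_bases = gain_bases(
        callability_gain_exact(f1, f2, fm), sum(lengths.values())
    )
    comp_lines = ["dataset\tA\tC\tG\tT\tN"]
    for name, track in tracks.items():
        comp = noncallable_base_composition(track, reference)
        if comp is None:
            comp_lines.append(f"{name}\tNA\tNA\tNA\tNA\tNA")
        else:
            comp_lines.append(
                f"{name}\t" + "\t".join(f"{comp[b]:.4f}" for b in "ACGT")
                + f"\t{comp['N']}"
            )
    (out / "noncallable_composition.tsv").write_text("\n".join(comp_lines) + "\n")
    log.info("callability: %s", {k: v for k, v in report.callability.items()})

    # --- merged-vs-platform chip-concordance in callable regions ----------
    merged_calls = _merged_call_set(records)
    statuses["merged"] = status_by_site(merged_calls, chip, reference)
    call_sets = {"p1": p1, "p2": p2, "merged": merged_calls}
    conc_disc: dict[str, tuple[int, int]] = {}
    for name, calls in call_sets.items():
        callable_regions = export_regions(tracks[name], State.CALLABLE)
        key = 1 if name == "p1" else 2 if name == "p2" else "merged"
        ordered = sorted(calls)
        by_contig: dict[str, list] = {}
        for call in ordered:
            by_contig.setdefault(call.contig, []).append(call)
        n_c = n_d = 0
        for contig, contig_calls in by_contig.items():
            offsets = np.array([c.position - 1 for c in contig_calls])
            inside = callable_regions.membership(contig, offsets)
            for call, ok in zip(contig_calls, inside):
                if not ok:
                    continue
                st = statuses[key].get(call.site)
                if st is None or st.status is ChipStatusKind.NOT_ON_CHIP:
                    continue
                if st.status is ChipStatusKind.CHIP_CONCORDANT:
                    n_c += 1
                else:
                    n_d += 1
        conc_disc[name] = (n_c, n_d)
    for other in ("p1", "p2"):
        a, b = conc_disc["merged"]
        c, d = conc_disc[other]
        chi2, p, odds = chi_square_or(ContingencyTable2x2(a, b, c, d))
        report.tests[f"merged_vs_{other}"] = {"chi2": chi2, "p": p, "or": odds}

    # --- category summary + rendered reports ------------------------------
    summary_lines = ["metric\tvalue"]
    for cat in Category:
        summary_lines.append(f"n_{cat.value.lower()}\t{counts[cat]}")
    for cat in (Category.P1_SPECIFIC, Category.P2_SPECIFIC):
        summary_lines.append(
            f"het_rate_{cat.value.lower()}\t"
            f"{fmt_pct(heterozygosity_rate(records, cat))}"
        )
        summary_lines.append(
            f"repeat_overlap_{cat.value.lower()}\t"
            f"{fmt_pct(repeat_overlap(records, cat, repeats))}"
        )
    (out / "summary.tsv").write_text("\n".join(summary_lines) + "\n")

    for name, text in render_reports(report).items():
        (out / name).write_text(text)

    manifest = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("reference", config.reference), ("repeats", config.repeats),
                ("p1_vcf", config.p1_vcf), ("p2_vcf", config.p2_vcf),
                ("chip", config.chip),
            )
        },
        "parameters": {
            "min_depth": config.min_depth, "min_mq": config.min_mq,
            "het_min_depth": config.het_min_depth,
            "het_min_second_fraction": config.het_min_second_fraction,
            "seed": config.seed,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("report: wrote bundle to %s", out)
    return report


def _merged_call_set(records):
    """The merged-platform call set: concordant and specific calls taken as
    is; discordant sites resolved in favour of the deeper platform's call
    (a calls-level stand-in for re-calling from a merged alignment)."""
    merged = set()
    for r in records:
        if r.category is Category.CONCORDANT:
            merged.add(r.call(1))
        elif r.category is Category.P1_SPECIFIC:
            merged.add(r.call(1))
        elif r.category is Category.P2_SPECIFIC:
            merged.add(r.call(2))
        else:
            pick = 1 if (r.depth_p1 or 0) >= (r.depth_p2 or 0) else 2
            merged.add(r.call(pick))
    return merged
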