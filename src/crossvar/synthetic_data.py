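"""Synthetic two-platform re-sequencing bundles.

Generates everything the downstream pipeline consumes — a diploid reference
with repeat regions, a truth genotype set, two platform call sets with
platform-specific error structure, per-base depth/MQ tracks, pileup counts,
and chip genotypes — so the whole analysis is testable without any external
download.

The generator emulates the error structure seen when one genome is
re-sequenced on two short-read platforms:

* ~60% of true variant sites are heterozygous (typical of a human genome's
  SNV set);
* per-base depth is Poisson around each platform's mean (defaults 20 and
  35, echoing the two platforms' median depths), zeroed in platform-
  specific dropout regions — AT-biased windows for platform 1 (emulating
  coverage bias of sequencing-by-synthesis chemistry), uniform for
  platform 2;
* true heterozygotes are undercalled to homozygous with probability
  ``base_rate * exp(-depth / depth_scale)``, the depth-dependent het-to-hom
  error mode: the functional form is a simulator choice, chosen to decay
  with depth;
* a fraction of each platform's callable sites is platform-specific
  (suppressed from the other platform's call set), with 70% of those sites
  placed in repeat regions, matching the strong repeat enrichment of
  platform-specific calls;
* chip genotypes cover a fraction of truth sites and carry their own
  het-to-hom genotyping error (default 10%).

Proportions that downstream stages are expected to *recover* (het fraction,
chip het-to-hom error, repeat enrichment of specific calls) are realised by
exact-count sampling (a conditioned binomial): the requested fraction of a
shuffled list is designated rather than flipping an independent coin per
site.  Marginals are unchanged and recovery is limited only by downstream
error processes, not by designation noise.

Each output file draws from its own RNG stream seeded from ``(seed, file
role)``, so adding one output never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    ChipGenotype, DepthMQTrack, RegionSet, VariantCall, Zygosity,
    write_bed, write_chip, write_fasta, write_pileups, write_track, write_vcf,
)
from .het_confidence import PileupCounts

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """A simulation parameter outside its feasible range."""


@dataclass(frozen=True)
class PlatformModel:
    """Depth and dropout behaviour of one sequencing platform."""

    mean_depth: float = 20.0
    dropout_model: str = "uniform"  # "at_biased" | "uniform"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.dropout_model not in ("at_biased", "uniform"):
            raise ConfigError(f"unknown dropout model {self.dropout_model!r}")
        if not 0 <= self.dropout_rate <= 1:
            raise ConfigError("dropout_rate must be in [0, 1]")


def _default_platforms() -> dict[str, PlatformModel]:
    return {
        "p1": PlatformModel(mean_depth=20.0, dropout_model="at_biased",
                            dropout_rate=0.005),
        "p2": PlatformModel(mean_depth=35.0, dropout_model="uniform",
                            dropout_rate=0.002),
    }


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 200_000
    n_contigs: int = 2
    repeat_fraction: float = 0.30
    n_variant_sites: int = 5_000
    het_fraction: float = 0.60
    platforms: dict[str, PlatformModel] = field(default_factory=_default_platforms)
    het_to_hom_base_rate: float = 0.20
    het_to_hom_depth_scale: float = 5.0
    min_call_depth: int = 4
    platform_specific_rate: float = 0.15
    repeat_enrichment: float = 0.70
    chip_site_fraction: float = 0.50
    chip_het_to_hom_error: float = 0.10
    low_mq_repeat_fraction: float = 0.05
    pileup_error_rate: float = 0.01
    seed: int = 2013

    def __post_init__(self) -> None:
        for name in ("repeat_fraction", "het_fraction", "platform_specific_rate",
                     "repeat_enrichment", "chip_site_fraction",
                     "chip_het_to_hom_error", "low_mq_repeat_fraction",
                     "pileup_error_rate", "het_to_hom_base_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.repeat_fraction > 0.9:
            raise ConfigError("repeat_fraction > 0.9 is infeasible")
        if self.genome_length < 1000:
            raise ConfigError("genome_length must be >= 1000")
        if self.n_variant_sites >= self.genome_length / 10:
            raise ConfigError("n_variant_sites must be < genome_length / 10")
        if len(self.platforms) != 2:
            raise ConfigError("exactly two platforms are required")


@dataclass(frozen=True, order=True)
class TruthRecord:
    """One simulated variant site's true genotype."""

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity
    repeat_flag: bool


def _rng(seed: int, role: str) -> np.random.Generator:
    """One RNG stream per output role, stable in the role name."""
    return np.random.default_rng([seed % 2**31, zlib.crc32(role.encode())])


def _contig_lengths(config: SimConfig) -> dict[str, int]:
    base, extra = divmod(config.genome_length, config.n_contigs)
    return {
        f"contig{i + 1}": base + (1 if i < extra else 0)
        for i in range(config.n_contigs)
    }


# ---------------------------------------------------------------------------
# reference and repeats
# ---------------------------------------------------------------------------

def simulate_reference(config: SimConfig) -> tuple[dict[str, str], RegionSet]:
    """Simulate contig sequences and their repeat annotation.

    Non-repeat sequence is i.i.d. uniform over ACGT.  Repeats are tandem
    copies of short random motifs drawn AT-rich (70% A/T), the composition
    typical of the satellite and low-complexity repeats where short-read
    coverage degrades; repeat intervals are placed to cover
    ``repeat_fraction`` of each contig up to block-size rounding (within
    +/- 2% genome-wide).
    """
    rng = _rng(config.seed, "reference")
    seqs: dict[str, str] = {}
    intervals: list[tuple[str, int, int]] = []
    for contig, length in _contig_lengths(config).items():
        target = int(round(config.repeat_fraction * length))
        blocks: list[int] = []
        while sum(blocks) < target:
            blocks.append(int(rng.integers(100, 401)))
        if blocks and sum(blocks) > target:
            blocks[-1] -= sum(blocks) - target
            if blocks[-1] < 20:  # too small to be a sensible repeat block
                blocks.pop()
        nonrep_total = length - sum(blocks)
        # split the non-repeat sequence into len(blocks)+1 gaps
        cuts = np.sort(rng.integers(0, nonrep_total + 1, size=len(blocks)))
        gaps = np.diff(np.concatenate([[0], cuts, [nonrep_total]]))
        parts: list[str] = []
        pos = 0
        for i, gap in enumerate(gaps):
            parts.append("".join(rng.choice(BASES, size=gap)))
            pos += int(gap)
            if i < len(blocks):
                # motifs carry a controlled 70% A/T composition, so every
                # repeat block is reliably AT-rich (not just on average)
                m = int(rng.integers(2, 7))
                n_at = max(1, round(0.7 * m))
                letters = list(rng.choice(["A", "T"], size=n_at)) + \
                    list(rng.choice(["C", "G"], size=m - n_at))
                motif = "".join(rng.permutation(letters))
                block = (motif * (blocks[i] // len(motif) + 1))[: blocks[i]]
                parts.append(block)
                intervals.append((contig, pos, pos + blocks[i]))
                pos += blocks[i]
        seqs[contig] = "".join(parts)
        assert len(seqs[contig]) == length
    return seqs, RegionSet.from_intervals(intervals) if intervals else RegionSet()


# ---------------------------------------------------------------------------
# truth genotypes
# ---------------------------------------------------------------------------

def simulate_truth(
    config: SimConfig, reference: dict[str, str], repeats: RegionSet
) -> list[TruthRecord]:
    """Draw variant sites without replacement and assign true genotypes.

    Exactly ``round(het_fraction * n)`` sites are heterozygous; alt alleles
    are uniform over the three non-reference bases.
    """
    rng = _rng(config.seed, "truth")
    contigs = list(reference)
    lengths = np.array([len(reference[c]) for c in contigs])
    total = int(lengths.sum())
    n = config.n_variant_sites
    if n == 0:
        return []
    flat = rng.choice(total, size=n, replace=False)
    flat.sort()
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    n_het = int(round(config.het_fraction * n))
    het_flags = np.zeros(n, dtype=bool)
    het_flags[rng.permutation(n)[:n_het]] = True
    records: list[TruthRecord] = []
    for i, f in enumerate(flat):
        ci = int(np.searchsorted(bounds, f, side="right") - 1)
        contig = contigs[ci]
        offset = int(f - bounds[ci])
        ref = reference[contig][offset]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        records.append(TruthRecord(
            contig, offset + 1, ref, alt,
            Zygosity.HET if het_flags[i] else Zygosity.HOM,
            bool(repeats.contains(contig, offset)),
        ))
    return records


# ---------------------------------------------------------------------------
# platform-specific designation
# ---------------------------------------------------------------------------

def designate_specific(
    config: SimConfig, truth: list[TruthRecord]
) -> dict[str, set[tuple[str, int]]]:
    """Choose the disjoint truth-site subsets designated specific to each
    platform (to be suppressed in the *other* platform's call set).

    Exactly ``round(platform_specific_rate * n)`` sites per platform, with
    ``round(repeat_enrichment * k)`` of them drawn from repeat-flagged
    sites.
    """
    rng = _rng(config.seed, "specific")
    k = int(round(config.platform_specific_rate * len(truth)))
    in_rep = [t for t in truth if t.repeat_flag]
    out_rep = [t for t in truth if not t.repeat_flag]
    rng.shuffle(in_rep)
    rng.shuffle(out_rep)
    k_rep = int(round(config.repeat_enrichment * k))
    k_non = k - k_rep
    if 2 * k_rep > len(in_rep) or 2 * k_non > len(out_rep):
        raise ConfigError(
            "not enough repeat/non-repeat truth sites for the requested "
            "platform_specific_rate and repeat_enrichment"
        )
    out: dict[str, set[tuple[str, int]]] = {}
    for i, platform in enumerate(config.platforms):
        chosen = in_rep[i * k_rep:(i + 1) * k_rep] + out_rep[i * k_non:(i + 1) * k_non]
        out[platform] = {(t.contig, t.position) for t in chosen}
    return out


# ---------------------------------------------------------------------------
# platform call sets and tracks
# ---------------------------------------------------------------------------

def _dropout_mask(
    rng: np.random.Generator, model: PlatformModel, reference: dict[str, str],
    window: int = 50,
) -> dict[str, np.ndarray]:
    """Per-contig boolean masks of dropout windows.

    AT-biased dropout samples windows with probability proportional to
    (AT fraction + 0.01)^4, concentrating coverage loss in AT-rich
    sequence; uniform dropout samples windows uniformly.
    """
    masks = {c: np.zeros(len(s), dtype=bool) for c, s in reference.items()}
    if model.dropout_rate == 0:
        return masks
    windows: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for contig, seq in reference.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_at = (arr == ord("A")) | (arr == ord("T"))
        for s in range(0, len(seq), window):
            e = min(s + window, len(seq))
            windows.append((contig, s, e))
            at_frac = float(is_at[s:e].mean())
            weights.append((at_frac + 0.01) ** 4)
    w = np.asarray(weights)
    p = None if model.dropout_model == "uniform" else w / w.sum()
    total = sum(len(s) for s in reference.values())
    n_windows = max(1, int(round(model.dropout_rate * total / window)))
    idx = rng.choice(len(windows), size=min(n_windows, len(windows)),
                     replace=False, p=p)
    for i in idx:
        contig, s, e = windows[i]
        masks[contig][s:e] = True
    return masks


def _low_mq_mask(
    rng: np.random.Generator, config: SimConfig, reference: dict[str, str],
    repeats: RegionSet,
) -> dict[str, np.ndarray]:
    """Mark whole repeat intervals as low-MQ until ``low_mq_repeat_fraction``
    of repeat bases is covered."""
    masks = {c: np.zeros(len(s), dtype=bool) for c, s in reference.items()}
    total_rep = repeats.total_length()
    if total_rep == 0 or config.low_mq_repeat_fraction == 0:
        return masks
    target = config.low_mq_repeat_fraction * total_rep
    intervals = list(repeats)
    order = rng.permutation(len(intervals))
    covered = 0
    for i in order:
        if covered >= target:
            break
        contig, s, e = intervals[i]
        masks[contig][s:e] = True
        covered += e - s
    return masks


def simulate_platform(
    config: SimConfig,
    truth: list[TruthRecord],
    reference: dict[str, str],
    repeats: RegionSet,
    platform_id: str,
    specific: dict[str, set[tuple[str, int]]] | None = None,
) -> tuple[set[VariantCall], DepthMQTrack, DepthMQTrack, list[PileupCounts]]:
    """Simulate one platform's call set, depth/MQ tracks and pileups.

    Per-base depth is Poisson around the platform mean and zero inside the
    platform's dropout windows.  A truth site is uncalled when its depth is
    below ``min_call_depth`` or when it is designated specific to the other
    platform; a true het of depth d is miscalled homozygous-alt with
    probability ``base_rate * exp(-d / depth_scale)``.  MQ is 60 outside
    repeats and 5 over a configurable fraction of repeat bases.
    """
    if not truth:
        raise ValueError("truth set must be nonempty")
    model = config.platforms[platform_id]
    rng = _rng(config.seed, f"platform:{platform_id}")
    if specific is None:
        specific = designate_specific(config, truth)
    suppressed: set[tuple[str, int]] = set()
    for other, sites in specific.items():
        if other != platform_id:
            suppressed |= sites

    dropout = _dropout_mask(rng, model, reference)
    depth_arrays = {}
    for contig, seq in reference.items():
        d = rng.poisson(model.mean_depth, size=len(seq)).astype(float)
        d[dropout[contig]] = 0
        depth_arrays[contig] = d
    low_mq = _low_mq_mask(rng, config, reference, repeats)
    mq_arrays = {}
    for contig, seq in reference.items():
        mq = np.full(len(seq), 60.0)
        mq[low_mq[contig]] = 5.0
        mq[depth_arrays[contig] == 0] = 0.0  # MQ undefined without reads
        mq_arrays[contig] = mq

    calls: set[VariantCall] = set()
    pileups: list[PileupCounts] = []
    for t in truth:
        if (t.contig, t.position) in suppressed:
            continue
        d = int(depth_arrays[t.contig][t.position - 1])
        if d < config.min_call_depth:
            continue
        zyg = t.zygosity
        if zyg is Zygosity.HET:
            p_err = config.het_to_hom_base_rate * np.exp(
                -d / config.het_to_hom_depth_scale
            )
            if rng.random() < p_err:
                zyg = Zygosity.HOM
        calls.add(VariantCall(t.contig, t.position, t.ref_allele,
                              t.alt_allele, zyg, d))
        pileups.append(_draw_pileup(rng, config, t, zyg, d))
    return calls, DepthMQTrack(depth_arrays), DepthMQTrack(mq_arrays), pileups


def _draw_pileup(
    rng: np.random.Generator, config: SimConfig, t: TruthRecord,
    called_zygosity: Zygosity, depth: int,
) -> PileupCounts:
    """Base counts consistent with the call: an even ref/alt split for het
    calls, all-alt for hom calls, plus a small uniform miscall rate."""
    counts = {b: 0 for b in "ACGT"}
    if called_zygosity is Zygosity.HET:
        n_alt = int(rng.binomial(depth, 0.5))
        counts[t.alt_allele] += n_alt
        counts[t.ref_allele] += depth - n_alt
    else:
        counts[t.alt_allele] += depth
    n_err = int(rng.binomial(depth, config.pileup_error_rate))
    for _ in range(n_err):
        src = max(counts, key=counts.get)
        if counts[src] == 0:
            break
        counts[src] -= 1
        counts[str(rng.choice([b for b in "ACGT" if b != src]))] += 1
    return PileupCounts(t.contig, t.position, counts)


# ---------------------------------------------------------------------------
# chip genotypes
# ---------------------------------------------------------------------------

def simulate_chip(config: SimConfig, truth: list[TruthRecord]) -> set[ChipGenotype]:
    """Assay ``chip_site_fraction`` of truth sites; exactly
    ``round(chip_het_to_hom_error * n_het_assayed)`` true hets are reported
    homozygous, the duplicated allele chosen at random."""
    if not truth:
        raise ValueError("truth set must be nonempty")
    rng = _rng(config.seed, "chip")
    n_assay = int(round(config.chip_site_fraction * len(truth)))
    if n_assay == 0:
        return set()
    order = rng.permutation(len(truth))
    assayed = [truth[i] for i in sorted(order[:n_assay])]
    het_idx = [i for i, t in enumerate(assayed) if t.zygosity is Zygosity.HET]
    n_flip = int(round(config.chip_het_to_hom_error * len(het_idx)))
    flip = set(
        np.array(het_idx)[rng.permutation(len(het_idx))[:n_flip]].tolist()
    ) if n_flip else set()
    out: set[ChipGenotype] = set()
    for i, t in enumerate(assayed):
        if t.zygosity is Zygosity.HOM:
            a = b = t.alt_allele
        elif i in flip:
            a = b = str(rng.choice([t.ref_allele, t.alt_allele]))
        else:
            a, b = t.ref_allele, t.alt_allele
        out.add(ChipGenotype(t.contig, t.position, a, b))
    return out


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("contig\tposition\tref\talt\tzygosity\trepeat\n")
        for t in sorted(truth):
            fh.write(
                f"{t.contig}\t{t.position}\t{t.ref_allele}\t{t.alt_allele}\t"
                f"{t.zygosity.value}\t{int(t.repeat_flag)}\n"
            )


def simulate_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write the full input bundle for the pipeline.

    Returns a dict of written paths.  Fixed seed implies byte-identical
    output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, repeats = simulate_reference(config)
    lengths = {c: len(s) for c, s in reference.items()}
    truth = simulate_truth(config, reference, repeats)
    specific = designate_specific(config, truth) if truth else {}
    paths: dict[str, Path] = {}

    paths["reference"] = outdir / "reference.fa"
    write_fasta(reference, paths["reference"])
    paths["repeats"] = outdir / "repeats.bed"
    write_bed(repeats, paths["repeats"], labels="repeat")
    paths["truth"] = outdir / "truth.tsv"
    write_truth(truth, paths["truth"])

    for pid in config.platforms:
        calls, depth, mq, pile = simulate_platform(
            config, truth, reference, repeats, pid, specific
        )
        paths[f"{pid}_vcf"] = outdir / f"{pid}.vcf"
        write_vcf(calls, paths[f"{pid}_vcf"], lengths, sample=pid)
        paths[f"{pid}_depth"] = outdir / f"{pid}.depth.bedgraph"
        write_track(depth, paths[f"{pid}_depth"])
        paths[f"{pid}_mq"] = outdir / f"{pid}.mq.bedgraph"
        write_track(mq, paths[f"{pid}_mq"])
        paths[f"{pid}_pileup"] = outdir / f"{pid}.pileup.tsv"
        write_pileups(pile, paths[f"{pid}_pileup"])

    paths["chip"] = outdir / "chip.tsv"
    write_chip(simulate_chip(config, truth), paths["chip"])
    return paths
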