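"""Readers and writers for the external formats, and the shared coordinate
and allele conventions.

Conventions used throughout the package:

* VCF and chip positions are 1-based; BED and bedGraph-like track intervals
  are 0-based half-open.  All internal site keys are ``(contig, 1-based
  position)``; conversion happens only at format boundaries.
* Only biallelic single-nucleotide records are representable.  Multiallelic
  VCF records are split and any allele that is not a single A/C/G/T base is
  dropped.
* Contig names must match exactly across all inputs: there is no
  ``chr``-prefix aliasing (see :func:`validate_contigs`).

The chip genotype table is a bespoke 4-column TSV (``contig  position
allele_a  allele_b``) because SNP-array vendors do not share a standard
per-site export; to produce one from Affymetrix 6.0 birdseed calls, join the
call file with the array annotation to obtain the two called alleles per
probeset and emit one row per genomic site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")

SiteKey = tuple[str, int]


class FormatError(ValueError):
    """An input file violates its format contract."""


class Zygosity(str, enum.Enum):
    HOM = "HOM"
    HET = "HET"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class VariantCall:
    """One biallelic SNV call from a single-sample call set.

    ``position`` is 1-based.  ``depth`` is the number of reads covering the
    site (0 when the caller reported none).
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity
    depth: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def site(self) -> SiteKey:
        return (self.contig, self.position)

    @property
    def genotype(self) -> frozenset[str] | tuple[str, str]:
        """The implied unordered diploid genotype as a sorted pair."""
        if self.zygosity is Zygosity.HOM:
            return (self.alt_allele, self.alt_allele)
        return tuple(sorted((self.ref_allele, self.alt_allele)))


@dataclass(frozen=True, order=True)
class ChipGenotype:
    """A SNP-array genotype: two called alleles at a 1-based site."""

    contig: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a not in BASES or self.allele_b not in BASES:
            raise ValueError(
                f"chip alleles must be A/C/G/T, got "
                f"{self.allele_a!r}/{self.allele_b!r}"
            )

    @property
    def site(self) -> SiteKey:
        return (self.contig, self.position)

    @property
    def zygosity(self) -> Zygosity:
        return Zygosity.HET if self.allele_a != self.allele_b else Zygosity.HOM

    @property
    def genotype(self) -> tuple[str, str]:
        return tuple(sorted((self.allele_a, self.allele_b)))


class DepthMQTrack:
    """Per-base values (depth or mean mapping quality) for a set of contigs.

    Values are dense numpy arrays indexed by 0-based offset; a contig of
    length L has exactly L values.  Uncovered positions carry 0.
    """

    def __init__(self, values: Mapping[str, np.ndarray]):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @property
    def contigs(self) -> list[str]:
        return list(self.values)

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.values[contig]

    def spans(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def at(self, contig: str, position: int) -> float:
        """Value at a 1-based position."""
        return float(self.values[contig][position - 1])


@dataclass
class RegionSet:
    """Sorted, non-overlapping 0-based half-open intervals."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        return cls(list(intervals)).normalized()

    def normalized(self) -> "RegionSet":
        """Sort and merge overlapping or adjacent intervals."""
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((start, end))
        merged: list[tuple[str, int, int]] = []
        for contig in sorted(by_contig):
            ivs = sorted(by_contig[contig])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((contig, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((contig, cur_s, cur_e))
        return RegionSet(merged)

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        idx: dict[str, list[list[int]]] = {}
        for contig, s, e in self.intervals:
            idx.setdefault(contig, [[], []])
            idx[contig][0].append(s)
            idx[contig][1].append(e)
        return {c: (np.array(s), np.array(e)) for c, (s, e) in idx.items()}

    def contains(self, contig: str, offset: int) -> bool:
        """Membership of a 0-based offset."""
        for c, s, e in self.intervals:
            if c == contig and s <= offset < e:
                return True
        return False

    def membership(self, contig: str, offsets: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 0-based offsets."""
        starts_ends = self._index().get(contig)
        if starts_ends is None:
            return np.zeros(len(offsets), dtype=bool)
        starts, ends = starts_ends
        i = np.searchsorted(starts, offsets, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(offsets), dtype=bool)
        out[ok] = offsets[ok] < ends[i[ok]]
        return out

    def mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean per-base mask over ``[0, length)`` for one contig."""
        m = np.zeros(length, dtype=bool)
        for c, s, e in self.intervals:
            if c == contig:
                m[s:min(e, length)] = True
        return m

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_snvs(path: str | Path) -> set[VariantCall]:
    """Read biallelic SNVs from a single-sample VCF.

    Multiallelic records are split per alt; non-SNV alleles (indels, symbolic
    alleles, multi-base refs) are dropped.  Zygosity comes from the GT field
    (het genotypes -> HET, non-ref homozygous -> HOM); depth from FORMAT DP,
    falling back to INFO DP, absent -> 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    if n_samples != 1:
        raise FormatError(
            f"expected a single-sample VCF, got {n_samples} samples in {path}"
        )
    calls: set[VariantCall] = set()
    for rec in vcf:
        if len(rec.REF) != 1 or rec.REF not in BASES:
            continue
        gt = rec.genotypes[0]
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        if not alleles or all(a == 0 for a in alleles):
            continue
        try:
            depth = int(rec.format("DP")[0][0])
        except (TypeError, KeyError):
            depth = int(rec.INFO.get("DP", 0) or 0)
        if depth < 0:
            depth = 0
        # split multiallelic: report the alt the genotype actually carries
        alt_idx = {a for a in alleles if a > 0}
        for ai in alt_idx:
            alt = rec.ALT[ai - 1]
            if len(alt) != 1 or alt not in BASES:
                continue
            zyg = Zygosity.HOM if all(a == ai for a in alleles) else Zygosity.HET
            calls.add(
                VariantCall(rec.CHROM, rec.POS, rec.REF, alt, zyg, depth)
            )
    return calls


def read_chip(path: str | Path) -> set[ChipGenotype]:
    """Read chip genotypes from a 4-column TSV (contig, 1-based position,
    allele_a, allele_b).  Duplicate sites are an error."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        names=["contig", "position", "allele_a", "allele_b"],
        dtype={"contig": str, "allele_a": str, "allele_b": str},
        comment="#",
    )
    out: set[ChipGenotype] = set()
    seen: set[SiteKey] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if row.allele_a not in BASES or row.allele_b not in BASES:
            raise FormatError(
                f"{path}: line {lineno}: non-ACGT allele "
                f"{row.allele_a!r}/{row.allele_b!r}"
            )
        key = (row.contig, int(row.position))
        if key in seen:
            raise FormatError(f"{path}: duplicate chip site {key[0]}:{key[1]}")
        seen.add(key)
        out.add(ChipGenotype(row.contig, int(row.position), row.allele_a, row.allele_b))
    return out


def read_track(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> DepthMQTrack:
    """Read a bedGraph-like 4-column TSV (contig, start, end, value; 0-based
    half-open) into dense per-base arrays over the declared contig spans.

    Positions not covered by any interval get 0.  Overlapping intervals are
    a format error.
    """
    arrays = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    try:
        df = pd.read_csv(
            str(path),
            sep=r"\s+",
            header=None,
            names=["contig", "start", "end", "value"],
            dtype={"contig": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return DepthMQTrack(arrays)
    for row in df.itertuples(index=False):
        contig, start, end = row.contig, int(row.start), int(row.end)
        if contig not in arrays:
            raise FormatError(f"{path}: undeclared contig {contig!r}")
        if end <= start or end > len(arrays[contig]):
            raise FormatError(
                f"{path}: interval {contig}:{start}-{end} outside declared span"
            )
        if covered[contig][start:end].any():
            raise FormatError(
                f"{path}: overlapping intervals at {contig}:{start}-{end}"
            )
        covered[contig][start:end] = True
        arrays[contig][start:end] = float(row.value)
    return DepthMQTrack(arrays)


def read_bed(path: str | Path) -> RegionSet:
    """Read BED intervals (first three columns; 0-based half-open)."""
    try:
        df = pd.read_csv(
            str(path), sep="\t", header=None, usecols=[0, 1, 2],
            names=["contig", "start", "end"], dtype={"contig": str}, comment="#",
        )
    except pd.errors.EmptyDataError:
        return RegionSet()
    return RegionSet.from_intervals(
        (r.contig, int(r.start), int(r.end)) for r in df.itertuples(index=False)
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a dict of upper-case sequences keyed by contig."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_pileups(path: str | Path) -> "list":
    """Read a pileup-count TSV (contig, position, A, C, G, T) into
    :class:`~crossvar.het_confidence.PileupCounts` records."""
    from .het_confidence import PileupCounts

    df = pd.read_csv(
        str(path), sep="\t", header=0, dtype={"contig": str}, comment=None,
    )
    needed = {"contig", "position", "A", "C", "G", "T"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: pileup TSV must have columns {sorted(needed)}")
    return [
        PileupCounts(
            r.contig, int(r.position),
            {"A": int(r.A), "C": int(r.C), "G": int(r.G), "T": int(r.T)},
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bed(
    regions: RegionSet, path: str | Path, labels: str | Sequence[str] | None = None
) -> None:
    """Write a RegionSet as BED (0-based half-open, tab-separated, Unix
    newlines).  ``labels`` is a single name applied to every interval, a
    per-interval sequence, or None for 3-column BED."""
    ivs = regions.intervals
    if isinstance(labels, str):
        labels = [labels] * len(ivs)
    with open(path, "w", newline="\n") as fh:
        for i, (contig, start, end) in enumerate(ivs):
            if labels is None:
                fh.write(f"{contig}\t{start}\t{end}\n")
            else:
                fh.write(f"{contig}\t{start}\t{end}\t{labels[i]}\n")


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    contig_lengths: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write calls as a minimal single-sample VCF v4.2 with GT and DP."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for call in sorted(calls):
        gt = "1/1" if call.zygosity is Zygosity.HOM else "0/1"
        lines.append(
            f"{call.contig}\t{call.position}\t.\t{call.ref_allele}\t"
            f"{call.alt_allele}\t.\tPASS\t.\tGT:DP\t{gt}:{call.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def write_chip(genotypes: Iterable[ChipGenotype], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for g in sorted(genotypes):
            fh.write(f"{g.contig}\t{g.position}\t{g.allele_a}\t{g.allele_b}\n")


def write_track(track: DepthMQTrack, path: str | Path) -> None:
    """Write per-base values as a run-length-compressed bedGraph-like TSV.

    Zero-valued runs are omitted (uncovered positions default to 0 on read).
    """
    with open(path, "w", newline="\n") as fh:
        for contig, vals in track.values.items():
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v == 0:
                    continue
                out = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{contig}\t{s}\t{e}\t{out}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def write_pileups(pileups: Iterable, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("contig\tposition\tA\tC\tG\tT\n")
        for p in sorted(pileups, key=lambda p: (p.contig, p.position)):
            c = p.counts
            fh.write(
                f"{p.contig}\t{p.position}\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}\n"
            )


def validate_contigs(named_contig_sets: Mapping[str, Iterable[str]]) -> None:
    """Check that every input uses exactly the same contig names.

    ``named_contig_sets`` maps an input label to its contig names; any
    difference from the union raises with the offending inputs listed.
    """
    sets = {name: set(contigs) for name, contigs in named_contig_sets.items()}
    universe = set.union(*sets.values()) if sets else set()
    offending = {
        name: sorted(universe - s) for name, s in sets.items() if universe - s
    }
    if offending:
        detail = "; ".join(f"{k} missing {v}" for k, v in offending.items())
        raise FormatError(f"contig names differ across inputs: {detail}")
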