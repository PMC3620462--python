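"""Per-base callability classification, multi-platform merging and interval
export.

Each reference base is classified from its sequencing depth and mean
mapping quality (MQ), mirroring the behaviour of GATK's CallableLoci
walker with its default thresholds:

* depth 0                      -> NO_COVERAGE
* 0 < depth < min_depth (4)    -> LOW_COVERAGE
* depth >= min_depth, MQ < 10  -> POOR_MQ
* otherwise                    -> CALLABLE

Thresholds are inclusive (a base at exactly depth 4 and MQ 10 is callable)
and coverage conditions are evaluated before MQ, so a 2-read base with MQ 0
is LOW_COVERAGE, not POOR_MQ.

Merging two platforms sums their depths per base and takes the
depth-weighted mean of their mean MQs (bases with zero depth contribute
nothing), approximating classification of a merged alignment; bases low-
covered by each platform alone can clear the depth threshold jointly, which
is the source of the merged callability gain.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io_formats import DepthMQTrack, RegionSet


class State(enum.IntEnum):
    CALLABLE = 0
    POOR_MQ = 1
    LOW_COVERAGE = 2
    NO_COVERAGE = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


NON_CALLABLE_STATES = (State.POOR_MQ, State.LOW_COVERAGE, State.NO_COVERAGE)


@dataclass(frozen=True)
class CallabilityThresholds:
    min_depth: int = 4
    min_mq: float = 10.0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")
        if self.min_mq < 0:
            raise ValueError(f"min_mq must be >= 0, got {self.min_mq}")


class CallabilityTrack:
    """Run-length encoded per-base states, one run list per contig.

    Runs tile each contig exactly with no gaps or overlaps, and adjacent
    runs always differ in state.
    """

    def __init__(self, runs: dict[str, list[tuple[State, int]]]):
        self.runs = runs

    @classmethod
    def from_states(cls, states: dict[str, np.ndarray]) -> "CallabilityTrack":
        return cls({c: rle_encode(v) for c, v in states.items()})

    def decode(self) -> dict[str, np.ndarray]:
        return {c: rle_decode(r) for c, r in self.runs.items()}

    def spans(self) -> dict[str, int]:
        return {c: sum(n for _, n in runs) for c, runs in self.runs.items()}

    def state_counts(self) -> dict[State, int]:
        counts = {s: 0 for s in State}
        for runs in self.runs.values():
            for state, n in runs:
                counts[state] += n
        return counts

    def total_bases(self) -> int:
        return sum(self.spans().values())


def rle_encode(states: np.ndarray) -> list[tuple[State, int]]:
    """Run-length encode a vector of states."""
    states = np.asarray(states, dtype=np.int8)
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states)]])
    return [(State(int(states[s])), int(e - s)) for s, e in zip(starts, ends)]


def rle_decode(runs: list[tuple[State, int]]) -> np.ndarray:
    if not runs:
        return np.zeros(0, dtype=np.int8)
    return np.repeat(
        np.array([int(s) for s, _ in runs], dtype=np.int8),
        np.array([n for _, n in runs]),
    )


def classify_base(
    depth: int, mq: float, t: CallabilityThresholds = CallabilityThresholds()
) -> State:
    """Classify a single base; see module docstring for the precedence."""
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    if depth == 0:
        return State.NO_COVERAGE
    if depth < t.min_depth:
        return State.LOW_COVERAGE
    if mq < t.min_mq:
        return State.POOR_MQ
    return State.CALLABLE


def classify_arrays(
    depth: np.ndarray, mq: np.ndarray, t: CallabilityThresholds
) -> np.ndarray:
    """Vectorized :func:`classify_base` over per-base arrays."""
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    states = np.full(len(depth), int(State.CALLABLE), dtype=np.int8)
    states[mq < t.min_mq] = int(State.POOR_MQ)
    states[depth < t.min_depth] = int(State.LOW_COVERAGE)
    states[depth == 0] = int(State.NO_COVERAGE)
    return states


def _check_spans(a: DepthMQTrack, b: DepthMQTrack) -> None:
    if a.spans() != b.spans():
        raise ValueError(
            f"track spans differ: {a.spans()} vs {b.spans()}"
        )


def build_track(
    depth: DepthMQTrack, mq: DepthMQTrack,
    t: CallabilityThresholds = CallabilityThresholds(),
) -> CallabilityTrack:
    """Classify every base of the covered contigs and run-length encode."""
    _check_spans(depth, mq)
    return CallabilityTrack.from_states({
        contig: classify_arrays(depth[contig], mq[contig], t)
        for contig in depth.contigs
    })


def callability_fraction(
    tracks, states_of_interest=(State.CALLABLE,)
) -> float | None:
    """Percentage of bases (2 dp) in the chosen state set across one track
    or a list of tracks tiling the genome under analysis."""
    from .rounding import percentage

    if isinstance(tracks, CallabilityTrack):
        tracks = [tracks]
    wanted = set(State(s) for s in states_of_interest)
    n_in, n_total = 0, 0
    for track in tracks:
        for state, count in (
            (s, c) for runs in track.runs.values() for s, c in runs
        ):
            n_total += count
            if state in wanted:
                n_in += count
    return percentage(n_in, n_total) if n_total else None


def merge_depth_mq(
    depth1: DepthMQTrack, mq1: DepthMQTrack,
    depth2: DepthMQTrack, mq2: DepthMQTrack,
) -> tuple[DepthMQTrack, DepthMQTrack]:
    """Merged per-base depth (sum) and MQ (depth-weighted mean)."""
    _check_spans(depth1, depth2)
    _check_spans(depth1, mq1)
    _check_spans(depth2, mq2)
    depths, mqs = {}, {}
    for contig in depth1.contigs:
        d1, d2 = depth1[contig], depth2[contig]
        dm = d1 + d2
        with np.errstate(invalid="ignore"):
            wm = np.where(dm > 0, (d1 * mq1[contig] + d2 * mq2[contig])
                          / np.where(dm > 0, dm, 1), 0.0)
        depths[contig] = dm
        mqs[contig] = wm
    return DepthMQTrack(depths), DepthMQTrack(mqs)


def merge_tracks(
    depth1: DepthMQTrack, mq1: DepthMQTrack,
    depth2: DepthMQTrack, mq2: DepthMQTrack,
    t: CallabilityThresholds = CallabilityThresholds(),
) -> CallabilityTrack:
    """Classify the merged depth/MQ of two platforms (see module docstring)."""
    depth_m, mq_m = merge_depth_mq(depth1, mq1, depth2, mq2)
    return build_track(depth_m, mq_m, t)


def noncallable_base_composition(
    track: CallabilityTrack, reference: dict[str, str]
) -> dict[str, float] | None:
    """Base composition (fractions of A/C/G/T summing to 1) of the reference
    positions whose state is not CALLABLE; N bases reported separately under
    ``"N"``.  No non-callable bases -> None."""
    tallies = {b: 0 for b in "ACGTN"}
    for contig, states in track.decode().items():
        seq = reference[contig]
        if len(seq) < len(states):
            raise ValueError(
                f"reference for {contig} shorter than track span"
            )
        offs = np.flatnonzero(states != int(State.CALLABLE))
        for off in offs:
            base = seq[off]
            tallies[base if base in tallies else "N"] += 1
    n_acgt = sum(tallies[b] for b in "ACGT")
    if n_acgt == 0 and tallies["N"] == 0:
        return None
    out = {b: (tallies[b] / n_acgt if n_acgt else 0.0) for b in "ACGT"}
    out["N"] = tallies["N"]
    return out


def export_regions(track: CallabilityTrack, state: State) -> RegionSet:
    """Maximal intervals of one state as 0-based half-open regions; their
    total length equals the state's base count."""
    intervals = []
    for contig, runs in track.runs.items():
        pos = 0
        for s, n in runs:
            if s is State(state):
                intervals.append((contig, pos, pos + n))
            pos += n
    return RegionSet(intervals)
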