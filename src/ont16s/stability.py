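"""Consensus stability versus read count.

How many reads does a stable consensus need?  Build the "expected"
consensus from every available read, then rebuild the consensus from
growing prefix subsets of the read file (the first 500 reads, the first
1,000, ... up to 20,500) and record the Hamming distance of each subset
consensus to the expected one.  Where the distance curve flattens to ~0,
additional reads no longer change the call.

Hamming distance here is alignment-aware: sequences of unequal length are
globally aligned and the distance counts substitution columns plus gap
columns, so it is zero exactly when the sequences are identical.  Masked
(N) positions compare unequal to any base but equal to N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .consensus import (
    ConsensusError,
    ConsensusParams,
    ConsensusSequence,
    FrequencyMatrix,
    GenusProfile,
    add_read,
    call_consensus,
)
from .seqio import Read


@dataclass
class StabilityParams:
    increment: int = 500
    max_reads: int = 20500
    consensus_params: ConsensusParams = field(default_factory=ConsensusParams)

    def __post_init__(self) -> None:
        if self.increment < 1:
            raise ValueError("increment must be >= 1")
        if self.max_reads % self.increment:
            raise ValueError("max_reads must be a multiple of increment")


@dataclass
class StabilityCurve:
    subset_sizes: list[int]
    hd_values: list[int]
    identical_flags: list[bool]
    expected_consensus: ConsensusSequence

    def __post_init__(self) -> None:
        if not (len(self.subset_sizes) == len(self.hd_values) == len(self.identical_flags)):
            raise ValueError("curve lists must have equal length")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("subset_size\thd\tidentical\n")
            for n, hd, ident in zip(
                self.subset_sizes, self.hd_values, self.identical_flags
            ):
                fh.write(f"{n}\t{hd}\t{int(ident)}\n")


def expected_consensus(
    reads: list[Read],
    profile: GenusProfile,
    params: ConsensusParams = ConsensusParams(),
) -> ConsensusSequence:
    """The consensus over all reads — the reference point for stability."""
    from .consensus import accumulate_frequencies

    return call_consensus(accumulate_frequencies(reads, profile), params)


def hamming_distance(a: ConsensusSequence | str, b: ConsensusSequence | str) -> int:
    """Mismatching columns between two consensus sequences.

    Equal-length inputs are compared position-wise; unequal lengths are
    globally aligned first and gap columns count as mismatches.  Zero if
    and only if the sequences are identical strings.
    """
    sa = a.sequence if isinstance(a, ConsensusSequence) else a
    sb = b.sequence if isinstance(b, ConsensusSequence) else b
    if not sa or not sb:
        raise ValueError("cannot compute distance of empty sequence")
    if len(sa) == len(sb):
        return sum(x != y for x, y in zip(sa, sb))
    # symbols compare literally (N == N only), so plain edit distance
    # equals substitutions + gap columns of the global alignment
    return int(edlib.align(sa, sb, mode="NW", task="distance")["editDistance"])


def stability_series(
    reads: list[Read],
    profile: GenusProfile,
    params: StabilityParams = StabilityParams(),
) -> StabilityCurve:
    """Consensus and Hamming distance for every prefix subset of the reads.

    Subsets are file-order prefixes (first increment, first 2x increment,
    ...), truncated at min(total reads, max_reads).  The frequency matrix
    is accumulated incrementally, so each read is aligned once.
    """
    if not reads:
        raise ValueError("no reads")
    total = min(len(reads), params.max_reads)
    boundaries = list(range(params.increment, total, params.increment)) + [total]
    expected = expected_consensus(reads[:total], profile, params.consensus_params)
    matrix = FrequencyMatrix.empty(profile.n_columns)
    sizes: list[int] = []
    hds: list[int] = []
    flags: list[bool] = []
    done = 0
    for b in boundaries:
        for read in reads[done:b]:
            add_read(matrix, read, profile)
        done = b
        try:
            cons = call_consensus(matrix, params.consensus_params)
            hd = hamming_distance(cons, expected)
        except ConsensusError:
            cons, hd = None, len(expected.sequence)
        sizes.append(b)
        hds.append(hd)
        flags.append(hd == 0)
    return StabilityCurve(sizes, hds, flags, expected)


def min_reads_for_stability(
    curves: list[StabilityCurve], tolerance: int = 4
) -> tuple[int, bool]:
    """Smallest subset size from which every curve stays within tolerance.

    Returns (size, stable).  The default tolerance of 4 bp reflects that
    consensus differences of that order do not change an identification.
    When no size qualifies, the largest observed size is returned with
    ``stable=False``.
    """
    if not curves:
        raise ValueError("need at least one curve")
    candidates: set[int] = set()
    for c in curves:
        candidates.update(c.subset_sizes)
    for size in sorted(candidates):
        ok = all(
            hd <= tolerance
            for c in curves
            for s, hd in zip(c.subset_sizes, c.hd_values)
            if s >= size
        )
        if ok:
            return size, True
    return max(candidates), False


def plot_stability(
    curves: list[StabilityCurve], path: str | Path
) -> None:
    """Sum of Hamming distances and identical-consensus count vs reads."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = sorted({s for c in curves for s in c.subset_sizes})
    hd_sum = []
    n_identical = []
    for s in sizes:
        tot = 0
        ident = 0
        for c in curves:
            for ss, hd, fl in zip(c.subset_sizes, c.hd_values, c.identical_flags):
                if ss == s:
                    tot += hd
                    ident += fl
        hd_sum.append(tot)
        n_identical.append(ident)
    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.plot(sizes, hd_sum, "o-", color="tab:blue", label="sum of HDs")
    ax1.set_xlabel("reads in subset")
    ax1.set_ylabel("sum of Hamming distances", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(sizes, n_identical, "s--", color="tab:orange",
             label="identical consensuses")
    ax2.set_ylabel("identical consensus count", color="tab:orange")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
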