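"""Quality filtering, subsampling and the dominant-genus stop rule.

A pure isolate should yield reads that overwhelmingly classify to one
genus.  The screen filters reads (length >= 20, mean Phred >= 7), takes a
random 1,000-read subsample, assigns each read the genus of its single
best database hit, and proceeds only if one genus accounts for strictly
more than 50% of the subsample — otherwise the pipeline halts.

Reads whose best hit falls below an identity floor (default 80%), or whose
best hits tie across genera, are "unassignable": they join no genus but
stay in the denominator, so junk reads cannot vote a genus past the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align
from .seqio import Read, ReferenceDB

UNASSIGNED = "__unassigned__"


@dataclass
class QcParams:
    min_length: int = 20
    min_mean_phred: float = 7.0

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_mean_phred < 0:
            raise ValueError("invalid QC parameters")


@dataclass
class GenusCall:
    genus: str | None
    genus_read_count: int
    subsample_size: int
    halted: bool
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.genus_read_count / self.subsample_size


def filter_reads(reads: list[Read], params: QcParams = QcParams()) -> list[Read]:
    """Keep reads with length >= min_length and mean Phred >= min_mean_phred.

    Boundaries are inclusive (the removal rule is "shorter than" /
    "below"); order is preserved and the operation is idempotent.
    """
    return [
        r
        for r in reads
        if len(r) >= params.min_length and r.mean_quality >= params.min_mean_phred
    ]


def subsample_reads(reads: list[Read], n: int = 1000, seed: int = 1) -> list[Read]:
    """Uniform sample of n reads without replacement, reproducible per seed.

    Fewer than n reads are returned in full — small samples are still
    processed, they just skip downsampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(reads) <= n:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


def classify_read(
    read: Read, db: ReferenceDB, min_identity: float = 80.0
) -> str:
    """Genus of the read's best database hit, or UNASSIGNED.

    Classification uses unit-cost (edit-distance) alignment for speed; a
    read is unassignable when its best identity is below ``min_identity``
    or when equally good best hits belong to different genera.
    """
    dists = [
        align.edlib.align(read.sequence, rec.sequence, mode="NW",
                          task="distance")["editDistance"]
        for rec in db.records
    ]
    best = min(dists)
    best_genera = {db.records[i].genus for i, d in enumerate(dists) if d == best}
    if len(best_genera) > 1:
        return UNASSIGNED
    i_best = dists.index(best)
    identity = align.edit_identity(read.sequence, db.records[i_best].sequence)
    if identity < min_identity:
        return UNASSIGNED
    return db.records[i_best].genus


def dominant_genus(
    sample: list[Read],
    db: ReferenceDB,
    threshold: float = 0.5,
    min_identity: float = 80.0,
) -> GenusCall:
    """Determine the most abundant genus in a read subsample.

    The denominator is the full subsample size, unassignable reads
    included; the call halts (``halted=True``) unless the top genus's
    fraction strictly exceeds ``threshold``.
    """
    if not sample:
        raise ValueError("empty read sample")
    if not db.records:
        raise ValueError("empty reference database")
    counts: dict[str, int] = {}
    for read in sample:
        genus = classify_read(read, db, min_identity)
        counts[genus] = counts.get(genus, 0) + 1
    assigned = {g: c for g, c in counts.items() if g != UNASSIGNED}
    if not assigned:
        return GenusCall(None, 0, len(sample), True, counts)
    # deterministic winner: max count, ties broken alphabetically
    genus = min(assigned, key=lambda g: (-assigned[g], g))
    n_top = assigned[genus]
    halted = not (n_top / len(sample) > threshold)
    return GenusCall(genus if not halted else genus, n_top, len(sample), halted, counts)
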