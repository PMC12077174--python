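"""Genus profile construction and cutoff-based consensus calling.

The pipeline builds, per dominant genus, a multiple alignment of that
genus's centroid sequences (a "genetic profile" reflecting intra-genus
diversity), aligns every QC-passing read to it, tallies per-column base
and gap counts into a frequency matrix, and calls a consensus column by
column: bases whose frequency reaches the interpretation cutoff (default
40%) form the call set; a single qualifying base is emitted as-is,
several become the IUPAC ambiguity code of the set.  Columns covered by
fewer reads than the minimum depth (default 5) are never called — trimmed
at the ends, masked as N internally.

Reads are placed against the profile's column-wise majority string rather
than the full MSA; read insertions relative to the profile are dropped, so
the consensus lives in the profile's coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .align import IUPAC, Scoring, align_semiglobal
from .seqio import CentroidRecord, Read

_CODE_OF = {frozenset(bases): code for code, bases in IUPAC.items()}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_IDX_BASE = "ACGT-"


class ConsensusError(RuntimeError):
    """No consensus obtainable (e.g. too few reads at every position)."""


@dataclass
class GenusProfile:
    """Aligned centroid rows for one genus plus derived per-column data."""

    genus: str
    rows: list[str]  # aligned centroid sequences, equal length, '-' gaps
    source_accessions: list[str]
    majority: str = ""  # per-column majority base (gap columns keep a base)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("profile needs at least one centroid")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("profile rows differ in length")
        if not self.majority:
            self.majority = _majority_string(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column_composition(self, col: int) -> set[str]:
        return {row[col] for row in self.rows}


def _majority_string(rows: list[str]) -> str:
    out = []
    for col in range(len(rows[0])):
        counts: dict[str, int] = {}
        for row in rows:
            c = row[col]
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if counts:
            out.append(min(counts, key=lambda b: (-counts[b], b)))
        else:  # all-gap column cannot arise from a center-star merge
            out.append("N")
    return "".join(out)


def build_genus_profile(
    centroids: list[CentroidRecord], scoring: Scoring = Scoring()
) -> GenusProfile:
    """Center-star multiple alignment of one genus's centroids.

    The center is the centroid with the greatest summed pairwise alignment
    score to the others (ties to the lexicographically first accession);
    the pairwise center alignments are merged under "once a gap, always a
    gap" on center coordinates.  Deterministic for fixed input.
    """
    genera = {c.genus for c in centroids}
    if len(genera) != 1:
        raise ValueError(f"centroids span multiple genera: {sorted(genera)}")
    genus = centroids[0].genus
    order = sorted(range(len(centroids)), key=lambda i: centroids[i].accession)
    centroids = [centroids[i] for i in order]
    if len(centroids) == 1:
        c = centroids[0]
        return GenusProfile(genus, [c.sequence], [c.accession])

    n = len(centroids)
    scores = np.zeros(n)
    alns: dict[tuple[int, int], object] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a = align_semiglobal(centroids[i].sequence, centroids[j].sequence, scoring)
            alns[(i, j)] = a
            scores[i] += a.score
            scores[j] += a.score
    center = int(scores.argmax())

    # per pairwise alignment: gaps inserted into the center, keyed by the
    # center position they precede (len(center) means trailing)
    center_seq = centroids[center].sequence
    pair_ops: dict[int, list[str]] = {}
    ins_needed = np.zeros(len(center_seq) + 1, dtype=int)
    for k in range(n):
        if k == center:
            continue
        key = (center, k) if center < k else (k, center)
        a = alns[key]
        if center < k:
            a_center, a_other = a.aligned_query, a.aligned_target
        else:
            a_center, a_other = a.aligned_target, a.aligned_query
        pair_ops[k] = list(zip(a_center, a_other))
        run, cpos = 0, 0
        for cc, _ in pair_ops[k]:
            if cc == "-":
                run += 1
            else:
                ins_needed[cpos] = max(ins_needed[cpos], run)
                run, cpos = 0, cpos + 1
        ins_needed[len(center_seq)] = max(ins_needed[len(center_seq)], run)

    def expand(seq_pairs: list[tuple[str, str]] | None) -> str:
        """Render one row onto the merged column grid."""
        out: list[str] = []
        if seq_pairs is None:  # the center itself
            for cpos, base in enumerate(center_seq):
                out.append("-" * ins_needed[cpos] + base)
            out.append("-" * ins_needed[len(center_seq)])
            return "".join(out)
        run: list[str] = []
        cpos = 0
        for cc, oc in seq_pairs:
            if cc == "-":
                run.append(oc)
            else:
                out.append("-" * (ins_needed[cpos] - len(run)) + "".join(run))
                out.append(oc)
                run, cpos = [], cpos + 1
        out.append("-" * (ins_needed[len(center_seq)] - len(run)) + "".join(run))
        return "".join(out)

    rows_by_index: dict[int, str] = {center: expand(None)}
    for k in range(n):
        if k != center:
            rows_by_index[k] = expand(pair_ops[k])
    rows = [rows_by_index[k] for k in range(n)]
    return GenusProfile(genus, rows, [c.accession for c in centroids])


@dataclass
class FrequencyMatrix:
    """Per-profile-column counts of A, C, G, T and gap."""

    counts: np.ndarray  # shape (n_columns, 5), dtype int64
    n_placed: int = 0
    n_skipped: int = 0

    @classmethod
    def empty(cls, n_columns: int) -> "FrequencyMatrix":
        return cls(np.zeros((n_columns, 5), dtype=np.int64))

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def copy(self) -> "FrequencyMatrix":
        return FrequencyMatrix(self.counts.copy(), self.n_placed, self.n_skipped)

    def to_tsv(self, path: str | Path) -> None:
        depth = self.depth
        with open(path, "w") as fh:
            fh.write("column\tA\tC\tG\tT\tgap\tdepth\n")
            for i, row in enumerate(self.counts):
                fh.write(
                    f"{i}\t" + "\t".join(str(int(x)) for x in row)
                    + f"\t{int(depth[i])}\n"
                )


@dataclass
class ConsensusParams:
    interpretation_cutoff: float = 0.40
    min_depth: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.interpretation_cutoff <= 1):
            raise ValueError("cutoff must be in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class ConsensusSequence:
    sequence: str  # may contain IUPAC ambiguity codes and N, never gaps
    per_position_depth: list[int]
    masked_positions: list[int]  # indices into `sequence` masked for low depth

    def __post_init__(self) -> None:
        if "-" in self.sequence:
            raise ValueError("consensus must not contain gap characters")
        if len(self.sequence) != len(self.per_position_depth):
            raise ValueError("depth list must match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def fraction_clean(self) -> float:
        """Fraction of positions that are plain unambiguous bases."""
        if not self.sequence:
            return 0.0
        good = sum(c in "ACGT" for c in self.sequence)
        return good / len(self.sequence)


def add_read(
    matrix: FrequencyMatrix,
    read: Read,
    profile: GenusProfile,
    min_identity: float = 80.0,
) -> bool:
    """Place one read against the profile majority string and add its
    bases/gaps to the matrix.  Returns False (and counts the skip) when the
    read's identity to the profile falls below the placement floor.

    Terminal indel runs of the alignment are end gaps: the read simply does
    not cover those columns.  Read insertions are dropped.
    """
    res = edlib.align(read.sequence, profile.majority, mode="NW", task="path")
    ops = _parse_cigar(res["cigar"])
    lead = 0
    while lead < len(ops) and ops[lead][1] in "ID":
        lead += 1
    trail = len(ops)
    while trail > lead and ops[trail - 1][1] in "ID":
        trail -= 1
    span = ops[lead:trail]
    n_match = sum(c for c, op in span if op == "=")
    n_span = sum(c for c, op in span)
    if n_span == 0 or 100.0 * n_match / n_span < min_identity:
        matrix.n_skipped += 1
        return False
    qpos = sum(c for c, op in ops[:lead] if op in "=XI")
    tpos = sum(c for c, op in ops[:lead] if op in "=XD")
    enc = _encode_read(read.sequence)
    for count, op in span:
        if op in "=X":
            chunk = enc[qpos : qpos + count]
            ok = chunk < 4  # N bases cover the column but do not vote
            cols = np.arange(tpos, tpos + count)[ok]
            np.add.at(matrix.counts, (cols, chunk[ok]), 1)
            qpos += count
            tpos += count
        elif op == "I":
            qpos += count
        else:  # D: read has a gap over these profile columns
            matrix.counts[tpos : tpos + count, 4] += 1
            tpos += count
    matrix.n_placed += 1
    return True


_READ_LUT = np.full(128, 9, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _READ_LUT[ord(_c)] = _i
_READ_LUT[ord("N")] = 4  # sentinel >= 4: ignored when voting


def _encode_read(seq: str) -> np.ndarray:
    return _READ_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def accumulate_frequencies(
    reads: list[Read], profile: GenusProfile, min_identity: float = 80.0
) -> FrequencyMatrix:
    """Align all reads to the profile and tally the frequency matrix."""
    matrix = FrequencyMatrix.empty(profile.n_columns)
    for read in reads:
        add_read(matrix, read, profile, min_identity)
    return matrix


def call_consensus(
    freq: FrequencyMatrix, params: ConsensusParams = ConsensusParams()
) -> ConsensusSequence:
    """Call the consensus from a frequency matrix.

    Per column with depth >= min_depth: symbols (four bases + gap) with
    frequency >= cutoff form the call set.  A lone base is emitted; several
    bases become their IUPAC code; a gap that qualifies and strictly beats
    every base deletes the column, otherwise the gap is discarded in favour
    of the bases.  If nothing reaches the cutoff the single most frequent
    symbol is used (base preferred over gap, then alphabetical).  Columns
    below min_depth are trimmed at the ends and masked as N internally.
    """
    depth = freq.depth
    called = depth >= params.min_depth
    if not called.any():
        raise ConsensusError(
            "no consensus obtainable: no position reaches the minimum read depth"
        )
    first, last = int(np.argmax(called)), len(called) - 1 - int(np.argmax(called[::-1]))
    seq: list[str] = []
    depths: list[int] = []
    masked: list[int] = []
    for col in range(first, last + 1):
        d = int(depth[col])
        if d < params.min_depth:
            masked.append(len(seq))
            seq.append("N")
            depths.append(d)
            continue
        counts = freq.counts[col]
        frac = counts / d
        call = [i for i in range(5) if frac[i] >= params.interpretation_cutoff]
        if not call:
            # nothing reaches the cutoff: fall back to the plurality symbol,
            # preferring a base over a gap on ties
            best = min(range(5), key=lambda i: (-frac[i], i == 4, _IDX_BASE[i]))
            call = [best]
        gap_in = 4 in call
        bases = [i for i in call if i != 4]
        if gap_in and (not bases or all(counts[4] > counts[b] for b in bases)):
            continue  # gap dominates: column deleted from the consensus
        if not bases:  # gap was sole winner of the fallback
            continue
        if len(bases) == 1:
            seq.append(_IDX_BASE[bases[0]])
        else:
            seq.append(_CODE_OF[frozenset(_IDX_BASE[b] for b in bases)])
        depths.append(d)
    return ConsensusSequence("".join(seq), depths, masked)
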