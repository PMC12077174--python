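"""Pairwise alignment kernel with BLAST-like identity accounting.

Two engines back the module:

* :func:`align_semiglobal` — an affine-gap (Gotoh) dynamic-programming
  aligner with free end gaps on both sequences, vectorised row-by-row in
  numpy.  It is exact (no banding) and IUPAC-aware: an ambiguity code in
  one sequence matches a base contained in its set.
* edlib — bit-parallel edit-distance alignment used to prescreen database
  records and to classify individual long reads, where thousands of
  alignments per sample make the scored DP uneconomical.

Identity is reported BLAST-style: the matched span runs from the first to
the last aligned (match or mismatch) column; internal gap columns count as
mismatches and sit in the denominator, end gaps do not.
"""

from __future__ import annotations

from dataclasses import dataclass
import edlib
import numpy as np

NEG = -(10**7)  # -inf stand-in; safe under int32 accumulation

#: IUPAC nucleotide codes mapped to the base sets they denote.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ALPHABET = "ACGTRYSWKMBDHVN"
_SYM_INDEX = {c: i for i, c in enumerate(_ALPHABET)}

#: equality pairs handed to edlib so ambiguity codes match their base sets
EDLIB_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC.items()
    if len(bases) > 1
    for base in bases
]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap of length L costs open + (L-1)·extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class AlignmentResult:
    aligned_query: str
    aligned_target: str
    score: int
    matches: int
    mismatches: int  # substitutions + internal gap columns
    match_length: int  # columns in the matched span

    @property
    def percent_identity(self) -> float:
        if self.match_length == 0:
            return 0.0
        return 100.0 * self.matches / self.match_length


@dataclass
class SpeciesMatch:
    """One ranked database hit for a query sequence."""

    species: str
    accession: str
    percent_identity: float
    mismatches: int
    match_length: int
    target_length: int
    query_length: int
    genus: str = ""


def _match_table(scoring: Scoring) -> np.ndarray:
    n = len(_ALPHABET)
    tab = np.full((n, n), scoring.mismatch, dtype=np.int32)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            if set(IUPAC[a]) & set(IUPAC[b]):
                tab[i, j] = scoring.match
    return tab


def _encode(seq: str, what: str) -> np.ndarray:
    try:
        return np.fromiter((_SYM_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"{what}: invalid symbol {exc.args[0]!r}") from exc


def symbols_match(a: str, b: str) -> bool:
    """True when the IUPAC sets of the two symbols intersect."""
    return bool(set(IUPAC[a]) & set(IUPAC[b]))


def align_semiglobal(
    query: str, target: str, scoring: Scoring = Scoring()
) -> AlignmentResult:
    """Optimal affine-gap alignment with free end gaps on both sequences.

    Either sequence may overhang the other at no cost; the score is the
    maximum over all cells in the last row and last column of the DP
    matrices.  Deterministic: ties are broken toward diagonal moves, then
    vertical (gap in target), then horizontal.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    n, m = len(query), len(target)
    q = _encode(query, "query")
    t = _encode(target, "target")
    tab = _match_table(scoring)
    go, ge = scoring.gap_open, scoring.gap_extend

    # M: q[i-1] aligned to t[j-1]; X: gap in target (vertical move);
    # Y: gap in query (horizontal move).  Row 0 / col 0 of M are free starts.
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    M[0, :] = 0
    M[:, 0] = 0

    js = np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = tab[q[i - 1], t] + prev_best[:-1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] + go, X[i - 1, 1:] + ge)
        # gaps open from M only (no adjacent insertion/deletion switch);
        # Y[i,j] = max(M[i,j-1]+go, Y[i,j-1]+ge) solved as a prefix max
        a = M[i, :-1] + go
        Y[i, 1:] = np.maximum.accumulate(a - ge * np.arange(m, dtype=np.int32)) \
            + ge * (js - 1)

    H = np.maximum(np.maximum(M, X), Y)
    last_row = H[n, :]
    last_col = H[:, m]
    if last_row.max() >= last_col.max():
        i, j = n, int(last_row.argmax())
    else:
        i, j = int(last_col.argmax()), m
    score = int(H[i, j])
    end_i, end_j = i, j

    # traceback by recomputing which predecessor achieved each value
    if M[i, j] >= score:
        state = "M"
    elif X[i, j] >= score:
        state = "X"
    else:
        state = "Y"
    ops: list[str] = []  # 'D' diagonal, 'U' up (gap in target), 'L' left
    while i > 0 and j > 0:
        if state == "M":
            ops.append("D")
            prev = M[i, j] - int(tab[q[i - 1], t[j - 1]])
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif X[i, j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            ops.append("U")
            state = "M" if M[i - 1, j] + go == X[i, j] else "X"
            i -= 1
        else:
            ops.append("L")
            state = "M" if M[i, j - 1] + go == Y[i, j] else "Y"
            j -= 1
    start_i, start_j = i, j

    ops.reverse()
    aq = ["-"] * start_j + list(query[:start_i])
    at = list(target[:start_j]) + ["-"] * start_i
    qi, tj = start_i, start_j
    for op in ops:
        if op == "D":
            aq.append(query[qi]); at.append(target[tj]); qi += 1; tj += 1
        elif op == "U":
            aq.append(query[qi]); at.append("-"); qi += 1
        else:
            aq.append("-"); at.append(target[tj]); tj += 1
    aq += list(query[end_i:]) + ["-"] * (m - end_j)
    at += ["-"] * (n - end_i) + list(target[end_j:])

    matches = mismatches = 0
    # trim gap columns at the span edges: end gaps are free, not mismatches
    first = next((k for k, op in enumerate(ops) if op == "D"), None)
    if first is not None:
        last = max(k for k, op in enumerate(ops) if op == "D")
        span = ops[first : last + 1]
        si, sj = start_i, start_j
        for op in ops[:first]:
            si += op != "L"
            sj += op != "U"
        for op in span:
            if op == "D":
                matches += symbols_match(query[si], target[sj])
                mismatches += not symbols_match(query[si], target[sj])
                si += 1
                sj += 1
            else:
                mismatches += 1
                si += op != "L"
                sj += op != "U"
    return AlignmentResult(
        "".join(aq), "".join(at), score, matches, mismatches, matches + mismatches
    )


# ---------------------------------------------------------------------------
# edlib-backed fast path

def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches incl. internal gaps, span length) from an
    extended cigar, with leading/trailing indel runs treated as end gaps."""
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    matches = mismatches = 0
    for count, op in ops:
        if op == "=":
            matches += count
        else:
            mismatches += count
    return matches, mismatches, matches + mismatches


def edit_alignment(
    query: str, target: str, mode: str = "NW", iupac: bool = True
) -> tuple[int, int, int, str]:
    """Unit-cost alignment via edlib.

    Returns (matches, mismatches, match_length, cigar); identity accounting
    follows the same matched-span convention as the scored aligner.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    extra = EDLIB_EQUALITIES if iupac else None
    res = edlib.align(query, target, mode=mode, task="path",
                      additionalEqualities=extra)
    m, mm, span = _cigar_stats(res["cigar"])
    return m, mm, span, res["cigar"]


def edit_identity(query: str, target: str, mode: str = "NW") -> float:
    m, mm, span, _ = edit_alignment(query, target, mode=mode)
    return 100.0 * m / span if span else 0.0


def best_hits(
    query: str,
    db,
    k: int = 1,
    scoring: Scoring = Scoring(),
    scored: bool = True,
    prescreen: int = 12,
) -> list[SpeciesMatch]:
    """Rank database centroids against a query.

    Ordering is (percent identity desc, mismatches asc, accession asc) —
    the accession tiebreak makes the order total and reproducible.  With
    ``scored=True`` an edlib edit-distance prescreen selects the
    ``max(prescreen, 3k)`` closest records, which are then re-aligned with
    the scored semi-global DP; ``scored=False`` takes identity straight
    from the unit-cost alignment (used for per-read classification).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = db.records
    if not records:
        raise ValueError("empty reference database")
    dists = [
        edlib.align(query, rec.sequence, mode="NW", task="distance",
                    additionalEqualities=EDLIB_EQUALITIES)["editDistance"]
        for rec in records
    ]
    order = sorted(range(len(records)), key=lambda i: (dists[i], records[i].accession))
    if scored:
        order = order[: max(prescreen, 3 * k)]
    hits: list[SpeciesMatch] = []
    for i in order:
        rec = records[i]
        if scored:
            aln = align_semiglobal(query, rec.sequence, scoring)
            m, mm, span = aln.matches, aln.mismatches, aln.match_length
        else:
            m, mm, span, _ = edit_alignment(query, rec.sequence)
        pid = 100.0 * m / span if span else 0.0
        hits.append(
            SpeciesMatch(rec.species, rec.accession, pid, mm, span,
                         len(rec.sequence), len(query), genus=rec.genus)
        )
    hits.sort(key=lambda h: (-h.percent_identity, h.mismatches, h.accession))
    return hits[:k]


def format_pairwise(aln: AlignmentResult, width: int = 60) -> str:
    """Human-readable pairwise alignment block, for debugging."""
    lines = []
    for i in range(0, len(aln.aligned_query), width):
        q = aln.aligned_query[i : i + width]
        t = aln.aligned_target[i : i + width]
        bars = "".join(
            "|" if a != "-" and b != "-" and symbols_match(a, b) else " "
            for a, b in zip(q, t)
        )
        lines += [q, bars, t, ""]
    return "\n".join(lines)
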