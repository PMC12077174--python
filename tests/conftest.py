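"""Shared fixtures: a tiny reference database, simulated reads, and an
independent pure-python alignment oracle used to check the numpy aligner."""

from __future__ import annotations

import random

import pytest

from ont16s.align import Scoring, symbols_match
from ont16s.seqio import CentroidRecord, ReferenceDB
from ont16s.simulate import DivergenceSpec, ErrorModel, make_reference, simulate_reads


def oracle_score(q: str, t: str, sc: Scoring = Scoring()) -> int:
    """Full O(nm) Gotoh DP, free end gaps on both sequences, gaps opening
    from the match state only — deliberately naive and independent of the
    vectorised implementation."""
    NEG = -(10**9)
    n, m = len(q), len(t)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0
    for i in range(n + 1):
        M[i][0] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if symbols_match(q[i - 1], t[j - 1]) else sc.mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + sc.gap_open, X[i - 1][j] + sc.gap_extend)
            Y[i][j] = max(M[i][j - 1] + sc.gap_open, Y[i][j - 1] + sc.gap_extend)
    best = max(max(M[n][j], X[n][j], Y[n][j]) for j in range(m + 1))
    return max(best, max(max(M[i][m], X[i][m], Y[i][m]) for i in range(n + 1)))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture(scope="session")
def toy_db() -> ReferenceDB:
    """Hand-built two-genus database with known divergences."""
    base = "ACGTACGTGGCCATATCGCGATTACCGGA" * 10  # 290 bp
    close = base[:50] + "T" + base[51:]  # 1 substitution from base
    far = "".join("ACGT"[(("ACGT".index(c)) + 1) % 4] for c in base[:100]) + base[100:]
    return ReferenceDB(
        [
            CentroidRecord("A001", "Alphamonas", "Alphamonas primus", base),
            CentroidRecord("A002", "Alphamonas", "Alphamonas secundus", close),
            CentroidRecord("B001", "Betabacter", "Betabacter primus", far),
        ]
    )


@pytest.fixture(scope="session")
def synthetic_db():
    """Default-condition synthetic reference: 5 genera x 3 species,
    1.5% intra-genus and 10% inter-genus divergence, 1,500 bp."""
    return make_reference(DivergenceSpec(seed=11))


@pytest.fixture(scope="session")
def isolate_reads(synthetic_db):
    """300 reads from one species at the default ~5% total error."""
    db, truth = synthetic_db
    species = "Betabacter secundus"
    reads = simulate_reads(truth[species], 300, ErrorModel(seed=42))
    return species, reads
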