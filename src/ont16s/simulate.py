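"""Synthetic data: centroid-style references and error-bearing reads.

The generator emulates the structure the pipeline depends on: a reference
of genera whose congeneric species sit at a controlled small divergence
(16S species within a genus typically differ by ~0.5–3%), genera separated
by a much larger divergence (>=5%), long reads (~1,500 bp, the full gene)
corrupted by independent per-base substitution / insertion / deletion
draws, and ~500 bp fragments standing in for Sanger-style V1–V3 consensus
sequences.

A "challenge" construction places all species-distinguishing substitutions
beyond position 500, so the species signal is invisible to the short arm
but resolved by the full-length gene.

All randomness flows from explicit seeds; there is no global RNG state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import CentroidRecord, Read, ReferenceDB

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class DivergenceSpec:
    """Shape of a synthetic centroid reference."""

    n_genera: int = 5
    species_per_genus: int = 3
    intra_genus_divergence: float = 0.015
    inter_genus_divergence: float = 0.10
    seq_length: int = 1500
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.intra_genus_divergence < self.inter_genus_divergence):
            raise ValueError("intra-genus divergence must be below inter-genus")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")


@dataclass
class ErrorModel:
    """Per-base read corruption rates and quality distribution.

    Defaults emulate mid-accuracy nanopore long reads at ~5% total error
    (3% substitutions, 1% insertions, 1% deletions) with mean Q12.
    """

    substitution_rate: float = 0.03
    insertion_rate: float = 0.01
    deletion_rate: float = 0.01
    quality_mean: float = 12.0
    quality_sd: float = 3.0
    read_length_sd: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be >= 0 and sum below 0.5")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


_GENUS_NAMES = [
    "Alphamonas", "Betabacter", "Gammacoccus", "Deltavibrio", "Epsilonella",
    "Zetabacillus", "Etamyces", "Thetaspira", "Iotagenes", "Kappatorquens",
]
_EPITHETS = [
    "primus", "secundus", "tertius", "quartus", "quintus",
    "sextus", "septimus", "octavus", "nonus", "decimus",
]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(seq: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute round(fraction * len) distinct positions to new bases."""
    out = seq.copy()
    k = int(round(fraction * len(seq)))
    if k == 0:
        return out
    pos = rng.choice(len(seq), size=k, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def make_reference(
    spec: DivergenceSpec,
    genus_names: list[str] | None = None,
    challenge_boundary: int | None = None,
) -> tuple[ReferenceDB, dict[str, str]]:
    """Build a synthetic centroid database plus a species -> sequence truth table.

    Each genus descends from an independent random ancestor mutated to the
    inter-genus target divergence from a common root; each species mutates
    its genus ancestor at the intra-genus target.  With
    ``challenge_boundary`` set, species-distinguishing substitutions are
    confined to positions at or beyond that index (0-based), producing
    congeneric species identical over the first ``challenge_boundary``
    bases.
    """
    rng = np.random.default_rng(spec.seed)
    names = genus_names or _GENUS_NAMES
    if spec.n_genera > len(names):
        names = [f"Genus{i:03d}" for i in range(spec.n_genera)]
    root = _random_sequence(rng, spec.seq_length)
    records: list[CentroidRecord] = []
    truth: dict[str, str] = {}
    acc = 0
    for g in range(spec.n_genera):
        genus = names[g]
        ancestor = _mutate(root, spec.inter_genus_divergence, rng)
        for s in range(spec.species_per_genus):
            epithet = _EPITHETS[s] if s < len(_EPITHETS) else f"sp{s:03d}"
            if challenge_boundary is not None and s > 0:
                tail = ancestor[challenge_boundary:]
                frac = spec.intra_genus_divergence * len(ancestor) / max(len(tail), 1)
                derived = ancestor.copy()
                derived[challenge_boundary:] = _mutate(tail, min(frac, 0.75), rng)
            elif s == 0:
                derived = ancestor.copy()
            else:
                derived = _mutate(ancestor, spec.intra_genus_divergence, rng)
            species = f"{genus} {epithet}"
            seq = _to_str(derived)
            acc += 1
            records.append(CentroidRecord(f"C{acc:04d}", genus, species, seq))
            truth[species] = seq
    return ReferenceDB(records), truth


def simulate_reads(
    template: str, n: int, model: ErrorModel, id_prefix: str = "read"
) -> list[Read]:
    """Draw reads from a template under the i.i.d. per-base error model.

    Each template base independently suffers a substitution or deletion;
    insertions of a single random base occur after a position with the
    insertion rate.  Qualities are normal draws (mean/sd in Phred units)
    clipped to [2, 41], one per emitted base.
    """
    if not template:
        raise ValueError("template must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(model.seed)
    tmpl = np.frombuffer(template.encode(), dtype="S1")
    codes = np.searchsorted(_BASES, tmpl)  # ACGT are sorted
    reads: list[Read] = []
    L = len(codes)
    for i in range(n):
        start, end = 0, L
        if model.read_length_sd > 0:
            trim = int(abs(rng.normal(0, model.read_length_sd)))
            end = max(start + 1, L - trim)
        base = codes[start:end].copy()
        u = rng.random(len(base))
        sub = u < model.substitution_rate
        dele = (u >= model.substitution_rate) & (
            u < model.substitution_rate + model.deletion_rate
        )
        base[sub] = (base[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
        ins = rng.random(len(base)) < model.insertion_rate
        keep = ~dele
        # expand: kept base, then any insertion after it
        pieces = base[keep]
        ins_after = np.flatnonzero(ins & keep)
        if len(ins_after) == 0:
            emitted = pieces
        else:
            kept_idx = np.flatnonzero(keep)
            rank = np.searchsorted(kept_idx, ins_after)
            emitted = np.insert(
                pieces, rank + 1, rng.integers(0, 4, size=len(ins_after))
            )
        if len(emitted) == 0:
            emitted = np.array([rng.integers(0, 4)])
        quals = np.rint(np.clip(
            rng.normal(model.quality_mean, model.quality_sd, size=len(emitted)),
            2, 41,
        )).astype(int)
        reads.append(Read(f"{id_prefix}_{i:05d}", _to_str(emitted), quals.tolist()))
    return reads


def simulate_sanger(
    template: str, length: int = 500, error_rate: float = 0.0, seed: int = 1
) -> str:
    """A Sanger-style consensus: the template's first ``length`` bases,
    optionally with a small substitution rate (Sanger traces are nearly
    error-free, so the default is 0)."""
    if length > len(template):
        warnings.warn(
            f"template shorter ({len(template)}) than requested length {length}; "
            "returning full template"
        )
        frag = template
    else:
        frag = template[:length]
    if error_rate > 0:
        rng = np.random.default_rng(seed)
        codes = np.searchsorted(_BASES, np.frombuffer(frag.encode(), dtype="S1"))
        frag = _to_str(_mutate(codes, error_rate, rng))
    return frag


def write_truth_tsv(truth: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tsequence\n")
        for sp, seq in truth.items():
            fh.write(f"{sp}\t{seq}\n")
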