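"""Paired method comparison: cross-tabulation, McNemar's test, concordance.

Two sequencing arms (e.g. ~500 bp Sanger-style vs full-length long-read)
each report an identification level — species, genus, family or no_id —
and a taxon for the same isolates.  The comparison cross-tabulates the
paired levels, tests whether one arm reaches a given level significantly
more often (McNemar's test for paired proportions on the discordant
counts), and measures taxon concordance among pairs where both arms
reached the rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .identify import Level

LEVELS = [Level.NO_ID, Level.FAMILY, Level.GENUS, Level.SPECIES]


@dataclass
class PairedResult:
    sample_id: str
    level_a: Level  # arm A, e.g. short-read Sanger
    level_b: Level  # arm B, e.g. long-read
    taxon_a: str = ""
    taxon_b: str = ""

    def __post_init__(self) -> None:
        self.level_a = Level(self.level_a)
        self.level_b = Level(self.level_b)


@dataclass
class CrossTab:
    """4x4 level table; rows are arm B, columns arm A."""

    counts: pd.DataFrame  # index/columns: no_id, family, genus, species
    n: int

    def marginals(self, arm: str) -> dict[str, int]:
        if arm == "a":
            sums = self.counts.sum(axis=0)
        elif arm == "b":
            sums = self.counts.sum(axis=1)
        else:
            raise ValueError("arm must be 'a' or 'b'")
        return {lvl.value: int(sums[lvl.value]) for lvl in LEVELS}

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def cross_tabulate(pairs: list[PairedResult]) -> CrossTab:
    names = [lvl.value for lvl in LEVELS]
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for p in pairs:
        counts.loc[p.level_b.value, p.level_a.value] += 1
    return CrossTab(counts, len(pairs))


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the discordant counts.

    Binomial test of min(b, c) successes in b + c trials at probability
    one half; 1.0 when there is no discordance.  Symmetric in b and c.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    return float(_sm_mcnemar(table, exact=True).pvalue)


def mcnemar_chi2(b: int, c: int, correction: bool = True) -> float:
    """Chi-square McNemar variant (optionally continuity-corrected).

    Exposed for completeness; the exact form is the default everywhere
    because discordant counts in this setting are small.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    return float(_sm_mcnemar(table, exact=False, correction=correction).pvalue)


def discordant_counts(tab: CrossTab, at_least: Level | str) -> tuple[int, int]:
    """(b, c) for the binary outcome "identified to >= at_least".

    b counts pairs where arm B reached the level but arm A did not;
    c the converse.
    """
    lvl = Level(at_least)
    if lvl is Level.NO_ID:
        raise ValueError("at_least must be family, genus or species")
    b = c = 0
    for rb in LEVELS:
        for ra in LEVELS:
            n = int(tab.counts.loc[rb.value, ra.value])
            hit_b, hit_a = rb.rank >= lvl.rank, ra.rank >= lvl.rank
            if hit_b and not hit_a:
                b += n
            elif hit_a and not hit_b:
                c += n
    return b, c


def level_improvement_test(tab: CrossTab, at_least: Level | str) -> float:
    """Exact McNemar p-value for reaching >= at_least in arm B vs arm A."""
    b, c = discordant_counts(tab, at_least)
    return mcnemar_exact(b, c)


def _taxon_at_rank(taxon: str, level: Level) -> set[str]:
    """Comparable name set at a rank; slash groups list alternatives.

    "Mycobacterium phocaicum/mucogenicum" at species rank yields both
    binomials, so a pair is concordant when any alternative matches.
    """
    taxon = taxon.strip()
    if not taxon:
        return set()
    if level is Level.GENUS:
        return {taxon.split()[0].rstrip("/")}
    if level is Level.FAMILY:
        return {taxon}
    parts = taxon.split()
    if len(parts) < 2:
        return {taxon}
    genus, rest = parts[0], " ".join(parts[1:])
    return {f"{genus} {epi}" for epi in rest.split("/")}


def concordance(
    pairs: list[PairedResult], level: Level | str = Level.SPECIES
) -> tuple[float, int, int]:
    """(fraction, numerator, denominator) of taxon agreement at a rank.

    The denominator counts pairs where both arms reached at least the
    rank; the numerator those whose taxa agree at that rank.  A zero
    denominator returns (nan, 0, 0).
    """
    lvl = Level(level)
    num = den = 0
    for p in pairs:
        if p.level_a.rank >= lvl.rank and p.level_b.rank >= lvl.rank:
            den += 1
            if _taxon_at_rank(p.taxon_a, lvl) & _taxon_at_rank(p.taxon_b, lvl):
                num += 1
    if den == 0:
        return float("nan"), 0, 0
    return num / den, num, den


def read_pairs_tsv(path: str | Path) -> list[PairedResult]:
    """Parse a TSV with columns sample_id, level_a, taxon_a, level_b, taxon_b."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "level_a", "level_b"}
    if not required <= set(df.columns):
        raise ValueError(f"pairs TSV must contain columns {sorted(required)}")
    pairs = []
    for _, row in df.iterrows():
        try:
            pairs.append(
                PairedResult(
                    row["sample_id"],
                    Level(row["level_a"]),
                    Level(row["level_b"]),
                    row.get("taxon_a", ""),
                    row.get("taxon_b", ""),
                )
            )
        except ValueError as exc:
            raise ValueError(
                f"sample {row['sample_id']!r}: unknown level label"
            ) from exc
    return pairs


def pairs_from_cell_counts(
    cells: dict[tuple[str, str], int]
) -> list[PairedResult]:
    """Expand {(level_b, level_a): count} into anonymous paired results."""
    pairs = []
    i = 0
    for (lb, la), n in cells.items():
        for _ in range(n):
            i += 1
            pairs.append(PairedResult(f"s{i:03d}", Level(la), Level(lb)))
    return pairs
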