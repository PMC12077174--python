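"""Database matching and CLSI-style interpretation of a consensus.

The consensus is compared against every centroid; the five closest species
are reported sorted by percent identity then mismatch count.  The level of
identification follows an interpretive ladder in the style of CLSI MM18:

* species — top identity at or above the species threshold (group
  specific: 99.0% general default, 99.6% aerobic actinomycetes, 100%
  *Mycobacterium*); in standard mode actinomycetes additionally need a
  separation greater than 0.4 percentage points to the next distinct
  species, a clause the "modified" mode waives; an exact tie between two
  species (same identity, same mismatches) is unresolvable and demotes to
  genus;
* genus — top identity >= 97.0%;
* family — top identity >= 95.0%;
* no identification below that.

Hits whose matched span is too short are excluded before interpretation:
under 1,250 bp for the long-read arm, under 400 bp for the ~500 bp
Sanger-style arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .align import Scoring, SpeciesMatch, best_hits
from .consensus import ConsensusSequence
from .genus_screen import GenusCall
from .seqio import ReferenceDB


class Level(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    NO_ID = "no_id"

    @property
    def rank(self) -> int:
        return {"no_id": 0, "family": 1, "genus": 2, "species": 3}[self.value]


class OrganismGroup(str, Enum):
    GENERAL = "general"
    ACTINOMYCETE = "actinomycete"
    MYCOBACTERIUM = "mycobacterium"


@dataclass
class InterpretationParams:
    family_min: float = 95.0
    genus_min: float = 97.0
    species_min: float = 99.0
    actino_species_min: float = 99.6
    actino_separation: float = 0.4  # percentage points to next distinct species
    myco_species_min: float = 100.0
    min_match_len_long: int = 1250
    min_match_len_short: int = 400
    mode: str = "standard"  # or "modified"

    def __post_init__(self) -> None:
        if not (self.family_min <= self.genus_min <= self.species_min <= 100):
            raise ValueError("thresholds must satisfy family <= genus <= species <= 100")
        if self.mode not in ("standard", "modified"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def species_threshold(self, group: OrganismGroup) -> float:
        if group is OrganismGroup.ACTINOMYCETE:
            return self.actino_species_min
        if group is OrganismGroup.MYCOBACTERIUM:
            return self.myco_species_min
        return self.species_min


@dataclass
class Interpretation:
    level: Level
    reported_taxon: str
    rule_fired: str
    excluded_matches: list[SpeciesMatch] = field(default_factory=list)
    confidence: float = 0.0
    matches: list[SpeciesMatch] = field(default_factory=list)


def rank_matches(
    consensus: ConsensusSequence | str,
    db: ReferenceDB,
    k: int = 5,
    scoring: Scoring = Scoring(),
) -> list[SpeciesMatch]:
    """Top-k species for a consensus, one row per species (its best centroid),
    sorted by (percent identity desc, mismatches asc, accession)."""
    query = consensus.sequence if isinstance(consensus, ConsensusSequence) else consensus
    if not query:
        raise ValueError("empty consensus sequence")
    raw = best_hits(query, db, k=max(k, 5), scoring=scoring,
                    prescreen=max(12, 3 * k))
    per_species: dict[str, SpeciesMatch] = {}
    for hit in raw:
        if hit.species not in per_species:
            per_species[hit.species] = hit
    ranked = sorted(
        per_species.values(),
        key=lambda h: (-h.percent_identity, h.mismatches, h.accession),
    )
    return ranked[:k]


def apply_length_filter(
    matches: list[SpeciesMatch],
    arm: str = "long",
    params: InterpretationParams = InterpretationParams(),
) -> tuple[list[SpeciesMatch], list[SpeciesMatch]]:
    """Drop hits whose matched span is below the arm's minimum length."""
    if arm not in ("long", "short"):
        raise ValueError(f"arm must be 'long' or 'short', got {arm!r}")
    cutoff = params.min_match_len_long if arm == "long" else params.min_match_len_short
    kept = [m for m in matches if m.match_length >= cutoff]
    excluded = [m for m in matches if m.match_length < cutoff]
    return kept, excluded


def interpret(
    matches: list[SpeciesMatch],
    organism_group: OrganismGroup | str = OrganismGroup.GENERAL,
    params: InterpretationParams = InterpretationParams(),
    excluded: list[SpeciesMatch] | None = None,
) -> Interpretation:
    """Apply the interpretive ladder to length-filtered, ranked matches."""
    group = OrganismGroup(organism_group)
    excluded = excluded or []
    if not matches:
        return Interpretation(Level.NO_ID, "", "all matches excluded", excluded)
    top = matches[0]
    identity = top.percent_identity
    genus = top.genus or top.species.split()[0]

    if identity >= params.species_threshold(group):
        runner = next((m for m in matches[1:] if m.species != top.species), None)
        # an exact tie (same identity, same mismatch count) between two
        # species is unresolvable: demote to genus in either mode
        if (
            runner is not None
            and runner.percent_identity == identity
            and runner.mismatches == top.mismatches
        ):
            return Interpretation(
                Level.GENUS, genus, "genus:ambiguous_species_tie",
                excluded, matches=matches,
            )
        sep_ok = True
        if group is OrganismGroup.ACTINOMYCETE and params.mode == "standard":
            sep = identity - runner.percent_identity if runner else float("inf")
            sep_ok = sep > params.actino_separation
        if sep_ok:
            return Interpretation(
                Level.SPECIES, top.species,
                f"species:{group.value}:{params.mode}", excluded, matches=matches,
            )
        if identity >= params.genus_min:
            return Interpretation(
                Level.GENUS, genus, "genus:separation_too_small",
                excluded, matches=matches,
            )
    if identity >= params.genus_min:
        return Interpretation(Level.GENUS, genus, "genus:identity",
                              excluded, matches=matches)
    if identity >= params.family_min:
        return Interpretation(
            Level.FAMILY, f"family of {genus}", "family:identity",
            excluded, matches=matches,
        )
    return Interpretation(Level.NO_ID, "", "no_id:identity_below_family_min",
                          excluded, matches=matches)


def confidence_score(
    matches: list[SpeciesMatch],
    genus_call: GenusCall | None = None,
    consensus: ConsensusSequence | None = None,
    params: InterpretationParams = InterpretationParams(),
    weights: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2),
) -> float:
    """Composite species-attribution confidence in [0, 1].

    Weighted mean of four monotone components: (i) top identity rescaled
    from [family_min, 100] to [0, 1]; (ii) identity separation to the best
    hit of a different species, capped at one percentage point; (iii) the
    genus dominance fraction; (iv) the fraction of consensus positions
    that are unmasked, unambiguous bases.  Components without data (no
    genus call / no consensus) count as 1 so they never penalise.
    """
    if not matches:
        raise ValueError("confidence requires at least one match")
    top = matches[0]
    span = 100.0 - params.family_min
    c_identity = min(max((top.percent_identity - params.family_min) / span, 0.0), 1.0)
    runner = next((m for m in matches[1:] if m.species != top.species), None)
    c_sep = 1.0 if runner is None else min(
        max(top.percent_identity - runner.percent_identity, 0.0), 1.0
    )
    c_dom = genus_call.fraction if genus_call is not None else 1.0
    c_clean = consensus.fraction_clean if consensus is not None else 1.0
    w = weights
    score = (w[0] * c_identity + w[1] * c_sep + w[2] * c_dom + w[3] * c_clean) / sum(w)
    return min(max(score, 0.0), 1.0)
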