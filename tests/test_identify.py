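"""Species ranking, match-length exclusion and the interpretive ladder."""

import itertools

import pytest

from ont16s.align import SpeciesMatch
from ont16s.consensus import ConsensusSequence
from ont16s.genus_screen import GenusCall
from ont16s.identify import (
    Interpretation,
    InterpretationParams,
    Level,
    OrganismGroup,
    apply_length_filter,
    confidence_score,
    interpret,
    rank_matches,
)
from ont16s.simulate import DivergenceSpec, make_reference


def match(species, identity, mism=0, length=1400, genus=None):
    genus = genus or species.split()[0]
    return SpeciesMatch(species, species.replace(" ", "_"), identity, mism,
                        length, 1500, 1500, genus=genus)


class TestRankMatches:
    def test_exact_centroid_first(self, synthetic_db):
        db, truth = synthetic_db
        hits = rank_matches(truth["Alphamonas primus"], db, k=5)
        assert hits[0].species == "Alphamonas primus"
        assert hits[0].percent_identity == 100.0

    def test_five_rows_from_larger_database(self, synthetic_db):
        db, truth = synthetic_db  # 15 species
        hits = rank_matches(truth["Deltavibrio tertius"], db, k=5)
        assert len(hits) == 5
        assert len({h.species for h in hits}) == 5  # one row per species

    def test_ordering_matches_exhaustive_pairwise_identity(self, synthetic_db):
        from ont16s.align import align_semiglobal

        db, truth = synthetic_db
        query = truth["Epsilonella primus"]
        hits = rank_matches(query, db, k=5)
        oracle = sorted(
            ((align_semiglobal(query, r.sequence).percent_identity, r.species)
             for r in db.records),
            reverse=True,
        )
        # identities agree with brute force; species sets agree per tier
        assert [h.percent_identity for h in hits[:3]] == pytest.approx(
            [pid for pid, _ in oracle[:3]]
        )
        assert {h.species for h in hits[:3]} == {sp for _, sp in oracle[:3]}


class TestLengthFilter:
    @pytest.mark.parametrize(
        "arm,length,kept",
        [
            ("long", 1243, False),  # below the 1,250 bp long-read floor
            ("long", 1250, True),   # boundary inclusive (exclusion is strict <)
            ("short", 286, False),  # ~500 bp arm floor is 400 bp
            ("short", 400, True),
        ],
    )
    def test_boundaries(self, arm, length, kept):
        hits = [match("Aus bus", 99.9, length=length)]
        k, x = apply_length_filter(hits, arm)
        assert (len(k) == 1) is kept
        assert (len(x) == 1) is not kept

    def test_kept_preserves_ranking(self):
        hits = [match("Aus a", 99.9, length=1400), match("Aus b", 99.0, length=100),
                match("Aus c", 98.5, length=1400)]
        kept, excluded = apply_length_filter(hits, "long")
        assert [m.species for m in kept] == ["Aus a", "Aus c"]
        assert [m.species for m in excluded] == ["Aus b"]


def hand_coded_level(identity, sep, group, mode):
    """Independent rule table for the interpretive ladder."""
    thresholds = {"general": 99.0, "actinomycete": 99.6, "mycobacterium": 100.0}
    if identity >= thresholds[group]:
        if sep == 0:  # exact species tie is unresolvable
            return "genus"
        if group != "actinomycete" or mode == "modified" or sep > 0.4:
            return "species"
    if identity >= 97.0:
        return "genus"
    if identity >= 95.0:
        return "family"
    return "no_id"


class TestInterpret:
    def test_general_species_call(self):
        hits = [match("Aus bus", 99.7), match("Aus cus", 99.2)]
        r = interpret(hits)
        assert r.level is Level.SPECIES and r.reported_taxon == "Aus bus"

    def test_actinomycete_separation_clause(self):
        # 99.66 vs 99.39: separation 0.27 <= 0.4 -> genus under the standard
        # rule, species when the separation clause is waived
        hits = [match("Rhodus corynus", 99.66), match("Rhodus kroppus", 99.39)]
        std = interpret(hits, OrganismGroup.ACTINOMYCETE)
        assert std.level is Level.GENUS and std.reported_taxon == "Rhodus"
        mod = interpret(hits, OrganismGroup.ACTINOMYCETE,
                        InterpretationParams(mode="modified"))
        assert mod.level is Level.SPECIES and mod.reported_taxon == "Rhodus corynus"

    def test_exact_species_tie_demotes_to_genus(self):
        # two species at identical identity and mismatch count cannot be
        # told apart: the call drops to genus in both modes
        hits = [match("Aus bus", 100.0, mism=0), match("Aus cus", 100.0, mism=0)]
        assert interpret(hits).level is Level.GENUS
        assert interpret(hits, params=InterpretationParams(mode="modified")
                         ).level is Level.GENUS
        # equal identity over different spans (fewer mismatches on top)
        # is resolvable and stays a species call
        hits2 = [match("Aus bus", 99.0, mism=14, length=1400),
                 match("Aus cus", 99.0, mism=15, length=1500)]
        assert interpret(hits2).level is Level.SPECIES

    def test_below_family_threshold_is_no_id(self):
        r = interpret([match("Dus vus", 94.85)])
        assert r.level is Level.NO_ID

    def test_mycobacterium_requires_full_identity(self):
        assert interpret([match("Mycus aus", 99.9)],
                         OrganismGroup.MYCOBACTERIUM).level is Level.GENUS
        assert interpret([match("Mycus aus", 100.0)],
                         OrganismGroup.MYCOBACTERIUM).level is Level.SPECIES

    def test_all_matches_excluded(self):
        r = interpret([], excluded=[match("Aus bus", 99.9, length=100)])
        assert r.level is Level.NO_ID and r.rule_fired == "all matches excluded"

    def test_exhaustive_grid_matches_hand_coded_table(self):
        """Exactly one rule fires for every identity x separation x group x
        mode combination, and it agrees with an independent rule table."""
        identities = [(9000 + 5 * k) / 100 for k in range(201)]  # 90.00..100.00
        separations = [5 * k / 100 for k in range(21)]  # 0.00..1.00
        for group, mode in itertools.product(
            ("general", "actinomycete", "mycobacterium"), ("standard", "modified")
        ):
            params = InterpretationParams(mode=mode)
            for identity, sep in itertools.product(identities, separations):
                runner_id = max(identity - sep, 0.0)
                hits = [match("Aus bus", identity),
                        match("Aus cus", runner_id)]
                got = interpret(hits, group, params).level.value
                # feed the rule table the same realised separation the
                # matches encode, so both sides see identical floats
                want = hand_coded_level(identity, identity - runner_id,
                                        group, mode)
                assert got == want, (identity, sep, group, mode)

    def test_raising_species_min_only_demotes(self):
        hits = [match("Aus bus", 99.3), match("Aus cus", 98.0)]
        order = [Level(v).rank for v in (
            interpret(hits, params=InterpretationParams(species_min=s)).level.value
            for s in (99.0, 99.5, 100.0)
        )]
        assert order == sorted(order, reverse=True)

    def test_filter_then_interpret_composes(self):
        hits = [match("Aus a", 99.9, length=1200), match("Aus b", 99.1, length=1400)]
        kept, excl = apply_length_filter(hits, "long")
        via_filter = interpret(kept, excluded=excl)
        direct = interpret([hits[1]])
        assert via_filter.level == direct.level
        assert via_filter.reported_taxon == direct.reported_taxon


class TestConfidence:
    def consensus(self, seq="ACGT" * 100):
        return ConsensusSequence(seq, [10] * len(seq), [])

    def test_perfect_case_scores_one(self):
        hits = [match("Aus bus", 100.0), match("Aus cus", 98.5)]
        call = GenusCall("Aus", 100, 100, False)
        assert confidence_score(hits, call, self.consensus()) == pytest.approx(1.0)

    def test_identity_component_zero_at_family_min(self):
        hits = [match("Aus bus", 95.0), match("Aus cus", 95.0)]
        call = GenusCall("Aus", 100, 100, False)
        score = confidence_score(hits, call, self.consensus())
        # identity and separation components are both 0; dominance and
        # cleanliness carry weights 0.2 each of a total 1.0
        assert score == pytest.approx(0.4)

    def test_monotone_in_dominance(self):
        hits = [match("Aus bus", 99.8), match("Aus cus", 99.0)]
        lo = confidence_score(hits, GenusCall("Aus", 60, 100, False), self.consensus())
        hi = confidence_score(hits, GenusCall("Aus", 90, 100, False), self.consensus())
        assert hi >= lo

    def test_monotone_in_each_component(self):
        base = confidence_score(
            [match("Aus bus", 99.0), match("Aus cus", 98.8)],
            GenusCall("Aus", 80, 100, False), self.consensus("ACGT" * 50 + "N" * 20),
        )
        better_identity = confidence_score(
            [match("Aus bus", 99.5), match("Aus cus", 98.8)],
            GenusCall("Aus", 80, 100, False), self.consensus("ACGT" * 50 + "N" * 20),
        )
        cleaner = confidence_score(
            [match("Aus bus", 99.0), match("Aus cus", 98.8)],
            GenusCall("Aus", 80, 100, False), self.consensus("ACGT" * 55),
        )
        assert better_identity >= base and cleaner >= base
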