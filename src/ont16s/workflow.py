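"""End-to-end workflows tying the pipeline stages together.

``run_identify`` executes the full identification chain on one sample:
quality filter -> random 1,000-read subsample -> dominant-genus screen ->
genus profile -> all-read consensus -> database ranking -> interpretation.
If no genus exceeds the dominance threshold the pipeline halts with a
structured report rather than an identification.

Every run returns a report dict that is JSON-serialisable and carries a
provenance block (parameters, seed, per-stage read counts) sufficient to
reproduce the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .compare import (
    concordance,
    cross_tabulate,
    discordant_counts,
    level_improvement_test,
    read_pairs_tsv,
)
from .consensus import (
    ConsensusError,
    ConsensusParams,
    accumulate_frequencies,
    build_genus_profile,
    call_consensus,
)
from .genus_screen import QcParams, dominant_genus, filter_reads, subsample_reads
from .identify import (
    Interpretation,
    InterpretationParams,
    Level,
    OrganismGroup,
    apply_length_filter,
    confidence_score,
    interpret,
    rank_matches,
)
from .seqio import ReferenceDB, read_fastq, read_reference_fasta
from .stability import StabilityParams, min_reads_for_stability, stability_series


class PipelineHalted(RuntimeError):
    """Raised when the dominant-genus stop rule fires."""

    def __init__(self, report: dict):
        super().__init__("pipeline stopped: no dominant genus")
        self.report = report


@dataclass
class RunConfig:
    qc: QcParams = field(default_factory=QcParams)
    subsample_n: int = 1000
    dominance_threshold: float = 0.5
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    interpretation: InterpretationParams = field(default_factory=InterpretationParams)
    stability: StabilityParams = field(default_factory=StabilityParams)
    seed: int = 1
    arm: str = "long"
    organism_group: str = "general"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "qc" in d:
            d["qc"] = QcParams(**d["qc"])
        if "consensus" in d:
            d["consensus"] = ConsensusParams(**d["consensus"])
        if "interpretation" in d:
            d["interpretation"] = InterpretationParams(**d["interpretation"])
        if "stability" in d:
            st = dict(d["stability"])
            if "consensus_params" in st:
                st["consensus_params"] = ConsensusParams(**st["consensus_params"])
            d["stability"] = StabilityParams(**st)
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: RunConfig, stage_counts: dict[str, int]) -> dict:
    return {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_read_counts": stage_counts,
    }


def identify_sample(
    reads,
    db: ReferenceDB,
    config: RunConfig = RunConfig(),
    sample_id: str = "sample",
) -> dict[str, Any]:
    """Run the identification pipeline on in-memory reads.

    Returns the result report dict; raises :class:`PipelineHalted` (with
    the report attached) when no genus dominates, and
    :class:`~ont16s.consensus.ConsensusError` when no position reaches the
    minimum depth.
    """
    counts = {"input": len(reads)}
    passed = filter_reads(reads, config.qc)
    counts["qc_passed"] = len(passed)
    if not passed:
        raise ConsensusError("no reads pass quality filtering")
    sample = subsample_reads(passed, config.subsample_n, config.seed)
    counts["subsample"] = len(sample)
    call = dominant_genus(sample, db, config.dominance_threshold)
    counts["dominant_genus_reads"] = call.genus_read_count
    if call.halted:
        report = {
            "sample_id": sample_id,
            "status": "halted",
            "reason": "pipeline stopped: no dominant genus",
            "genus_counts": call.counts,
            "subsample_size": call.subsample_size,
            "provenance": _provenance(config, counts),
        }
        raise PipelineHalted(report)

    profile = build_genus_profile(db.records_for_genus(call.genus))
    freq = accumulate_frequencies(passed, profile)
    counts["reads_placed"] = freq.n_placed
    counts["reads_unplaced"] = freq.n_skipped
    cons = call_consensus(freq, config.consensus)

    matches = rank_matches(cons, db, k=5)
    kept, excluded = apply_length_filter(matches, config.arm, config.interpretation)
    result = interpret(kept, config.organism_group, config.interpretation,
                       excluded=excluded)
    conf = confidence_score(matches, call, cons, config.interpretation) if matches else 0.0
    report = {
        "sample_id": sample_id,
        "status": "ok",
        "level": result.level.value,
        "reported_taxon": result.reported_taxon,
        "rule_fired": result.rule_fired,
        "confidence": round(conf, 4),
        "dominant_genus": call.genus,
        "dominance_fraction": round(call.fraction, 4),
        "consensus_length": len(cons.sequence),
        "consensus_masked_positions": len(cons.masked_positions),
        "top_matches": [
            {
                "species": m.species,
                "accession": m.accession,
                "percent_identity": round(m.percent_identity, 2),
                "mismatches": m.mismatches,
                "match_length": m.match_length,
                "target_length": m.target_length,
            }
            for m in kept
        ],
        "excluded_matches": [
            {
                "species": m.species,
                "match_length": m.match_length,
                "reason": "match length below arm minimum",
            }
            for m in excluded
        ],
        "provenance": _provenance(config, counts),
    }
    report["_consensus"] = cons
    report["_frequency_matrix"] = freq
    return report


def run_identify(
    fastq: str | Path,
    reference: str | Path,
    config: RunConfig = RunConfig(),
    taxonomy: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """File-level identification workflow; optionally writes report files."""
    reads = read_fastq(fastq)
    db = read_reference_fasta(reference, taxonomy)
    report = identify_sample(reads, db, config, sample_id=Path(fastq).stem)
    if out_dir is not None:
        _write_identify_outputs(report, out_dir)
    return report


def _write_identify_outputs(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cons = report.pop("_consensus", None)
    freq = report.pop("_frequency_matrix", None)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    rows = ["species\tpercent_identity\tmismatches\tmatch_length\ttarget_length"]
    for m in report.get("top_matches", []):
        rows.append(
            f"{m['species']}\t{m['percent_identity']}\t{m['mismatches']}"
            f"\t{m['match_length']}\t{m['target_length']}"
        )
    (out / "report.tsv").write_text("\n".join(rows) + "\n")
    if cons is not None:
        from .seqio import write_consensus_fasta

        write_consensus_fasta(report["sample_id"], cons.sequence,
                              out / "consensus.fasta")
    if freq is not None:
        freq.to_tsv(out / "frequency.tsv")


def run_stability(
    fastq: str | Path,
    reference: str | Path,
    config: RunConfig = RunConfig(),
    taxonomy: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Stability workflow: prefix-subset consensus curve for one sample."""
    reads = read_fastq(fastq)
    db = read_reference_fasta(reference, taxonomy)
    passed = filter_reads(reads, config.qc)
    sample = subsample_reads(passed, config.subsample_n, config.seed)
    call = dominant_genus(sample, db, config.dominance_threshold)
    if call.halted:
        raise PipelineHalted({"status": "halted", "genus_counts": call.counts})
    profile = build_genus_profile(db.records_for_genus(call.genus))
    curve = stability_series(passed, profile, config.stability)
    min_reads, stable = min_reads_for_stability([curve])
    report = {
        "sample_id": Path(fastq).stem,
        "subset_sizes": curve.subset_sizes,
        "hd_values": curve.hd_values,
        "identical_flags": curve.identical_flags,
        "min_reads_for_stability": min_reads,
        "stable": stable,
        "provenance": _provenance(config, {"input": len(reads), "qc_passed": len(passed)}),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve.to_tsv(out / "stability.tsv")
        with open(out / "stability.json", "w") as fh:
            json.dump(report, fh, indent=2)
        from .stability import plot_stability

        plot_stability([curve], out / "stability.png")
    return report


def run_compare(
    pairs_tsv: str | Path, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Comparison workflow: cross-tab, McNemar tests, concordances."""
    pairs = read_pairs_tsv(pairs_tsv)
    tab = cross_tabulate(pairs)
    tests = {}
    for lvl in (Level.FAMILY, Level.GENUS, Level.SPECIES):
        b, c = discordant_counts(tab, lvl)
        tests[lvl.value] = {
            "b": b,
            "c": c,
            "p_value": level_improvement_test(tab, lvl),
        }
    conc = {}
    for lvl in (Level.SPECIES, Level.GENUS, Level.FAMILY):
        frac, num, den = concordance(pairs, lvl)
        conc[lvl.value] = {"fraction": frac, "numerator": num, "denominator": den}
    report = {
        "n": tab.n,
        "cross_tab": {
            row: {col: int(tab.counts.loc[row, col]) for col in tab.counts.columns}
            for row in tab.counts.index
        },
        "marginals_a": tab.marginals("a"),
        "marginals_b": tab.marginals("b"),
        "improvement_tests": tests,
        "concordance": conc,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tab.to_tsv(out / "cross_tab.tsv")
        with open(out / "comparison.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
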