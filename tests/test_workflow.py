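"""End-to-end workflows and the command-line surface."""

import json

import pytest
from click.testing import CliRunner

from ont16s.cli import main
from ont16s.consensus import ConsensusError
from ont16s.seqio import write_fastq, write_reference_fasta
from ont16s.simulate import DivergenceSpec, ErrorModel, make_reference, simulate_reads
from ont16s.workflow import (
    PipelineHalted,
    RunConfig,
    identify_sample,
    run_compare,
    run_identify,
)


@pytest.fixture(scope="module")
def small_world():
    """A compact synthetic world: 3 genera x 2 species, 800 bp gene."""
    spec = DivergenceSpec(n_genera=3, species_per_genus=2, seq_length=800, seed=19)
    db, truth = make_reference(spec)
    return db, truth


class TestIdentifySample:
    def test_pure_isolate_reported_at_species_level(self, small_world):
        db, truth = small_world
        species = "Betabacter secundus"
        reads = simulate_reads(truth[species], 120, ErrorModel(seed=31))
        # the 800 bp test gene sits below the long-arm match-length floor,
        # so interpretation runs under the short-arm (400 bp) rule
        report = identify_sample(reads, db, RunConfig(seed=2, arm="short"))
        assert report["status"] == "ok"
        assert report["level"] == "species"
        assert report["reported_taxon"] == species
        assert report["dominance_fraction"] > 0.9
        assert report["top_matches"][0]["percent_identity"] >= 99.0

    def test_even_mixture_halts_pipeline(self, small_world):
        db, truth = small_world
        r1 = simulate_reads(truth["Alphamonas primus"], 50, ErrorModel(seed=1))
        r2 = simulate_reads(truth["Gammacoccus primus"], 50, ErrorModel(seed=2))
        with pytest.raises(PipelineHalted) as err:
            identify_sample(r1 + r2, db, RunConfig(seed=3))
        assert err.value.report["status"] == "halted"
        assert "no dominant genus" in err.value.report["reason"]

    def test_too_few_reads_no_consensus(self, small_world):
        db, truth = small_world
        reads = simulate_reads(truth["Alphamonas primus"], 3, ErrorModel(seed=7))
        with pytest.raises(ConsensusError, match="no consensus obtainable"):
            identify_sample(reads, db, RunConfig(seed=4))

    def test_provenance_reproducibility(self, small_world):
        db, truth = small_world
        reads = simulate_reads(truth["Alphamonas secundus"], 80, ErrorModel(seed=8))
        cfg = RunConfig(seed=9)
        r1 = identify_sample(reads, db, cfg)
        r2 = identify_sample(reads, db, RunConfig.from_dict(cfg.to_dict()))
        assert r1["provenance"]["config_hash"] == r2["provenance"]["config_hash"]
        assert r1["top_matches"] == r2["top_matches"]
        assert r1["_consensus"].sequence == r2["_consensus"].sequence

    def test_short_arm_excludes_short_matches(self, small_world):
        db, truth = small_world
        reads = simulate_reads(truth["Alphamonas primus"], 80, ErrorModel(seed=12))
        cfg = RunConfig(seed=5, arm="long")
        # 800 bp consensus < 1,250 bp long-arm floor: everything excluded
        report_long = identify_sample(reads, db, cfg)
        assert report_long["level"] == "no_id"
        assert report_long["rule_fired"] == "all matches excluded"
        cfg_short = RunConfig(seed=5, arm="short")
        report_short = identify_sample(reads, db, cfg_short)
        assert report_short["level"] == "species"


class TestCli:
    def make_inputs(self, tmp_path, small_world, n_reads=80):
        db, truth = small_world
        ref = tmp_path / "ref.fasta"
        write_reference_fasta(db, ref)
        reads = simulate_reads(truth["Alphamonas primus"], n_reads, ErrorModel(seed=23))
        fq = tmp_path / "reads.fastq"
        write_fastq(reads, fq)
        return ref, fq

    def test_identify_command(self, tmp_path, small_world):
        ref, fq = self.make_inputs(tmp_path, small_world)
        out = tmp_path / "out"
        res = CliRunner().invoke(main, [
            "identify", "--fastq", str(fq), "--reference", str(ref),
            "--arm", "short", "--seed", "3", "--out-dir", str(out),
        ])
        assert res.exit_code == 0, res.output
        report = json.loads((out / "report.json").read_text())
        assert report["level"] == "species"
        assert (out / "consensus.fasta").exists()
        assert (out / "frequency.tsv").exists()

    def test_identify_halt_exit_code(self, tmp_path, small_world):
        db, truth = small_world
        ref = tmp_path / "ref.fasta"
        write_reference_fasta(db, ref)
        r1 = simulate_reads(truth["Alphamonas primus"], 30, ErrorModel(seed=1))
        r2 = simulate_reads(truth["Gammacoccus primus"], 30, ErrorModel(seed=2))
        fq = tmp_path / "mix.fastq"
        write_fastq(r1 + r2, fq)
        res = CliRunner().invoke(main, [
            "identify", "--fastq", str(fq), "--reference", str(ref),
        ])
        assert res.exit_code == 3
        assert "no dominant genus" in res.output

    def test_stability_command(self, tmp_path, small_world):
        ref, fq = self.make_inputs(tmp_path, small_world, n_reads=60)
        out = tmp_path / "stab"
        res = CliRunner().invoke(main, [
            "stability", "--fastq", str(fq), "--reference", str(ref),
            "--config", str(self.write_config(tmp_path)), "--out-dir", str(out),
        ])
        assert res.exit_code == 0, res.output
        report = json.loads(res.output)
        assert report["hd_values"][-1] == 0
        assert (out / "stability.tsv").exists()

    @staticmethod
    def write_config(tmp_path):
        cfg = RunConfig()
        cfg.stability.increment = 20
        cfg.stability.max_reads = 200
        p = tmp_path / "config.json"
        p.write_text(json.dumps(cfg.to_dict()))
        return p

    def test_compare_command(self, tmp_path):
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text(
            "sample_id\tlevel_a\ttaxon_a\tlevel_b\ttaxon_b\n"
            + "\n".join(
                f"s{i}\tgenus\tAus\tspecies\tAus bus" for i in range(8)
            )
            + "\ns9\tspecies\tAus bus\tspecies\tAus bus\n"
        )
        res = CliRunner().invoke(main, ["compare", "--pairs", str(pairs)])
        assert res.exit_code == 0, res.output
        report = json.loads(res.output)
        assert report["n"] == 9
        assert report["improvement_tests"]["species"]["b"] == 8
        assert report["improvement_tests"]["species"]["p_value"] < 0.01

    def test_simulate_command_roundtrips(self, tmp_path):
        out = tmp_path / "sim"
        res = CliRunner().invoke(main, [
            "simulate", "--out-dir", str(out), "--seed", "5",
            "--n-genera", "2", "--species-per-genus", "2",
            "--seq-length", "600", "--n-reads", "25",
        ])
        assert res.exit_code == 0, res.output
        from ont16s.seqio import read_fastq, read_reference_fasta

        db = read_reference_fasta(out / "reference.fasta")
        reads = read_fastq(out / "reads.fastq")
        assert len(db) == 4 and len(reads) == 25


def test_run_compare_report(tmp_path):
    pairs = tmp_path / "pairs.tsv"
    pairs.write_text(
        "sample_id\tlevel_a\ttaxon_a\tlevel_b\ttaxon_b\n"
        "s1\tspecies\tAus bus\tspecies\tAus bus\n"
        "s2\tno_id\t\tgenus\tAus\n"
    )
    report = run_compare(pairs, out_dir=tmp_path / "cmp")
    assert report["marginals_a"]["species"] == 1
    assert report["concordance"]["species"]["denominator"] == 1
    assert (tmp_path / "cmp" / "cross_tab.tsv").exists()
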