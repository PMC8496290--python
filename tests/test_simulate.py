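"""Simulator determinism, construction guarantees, and recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from naive_oracle import revcomp
from ygscan import (
    ConfigError,
    InputError,
    KmerParams,
    ScanParams,
    ScanResult,
    SimSpec,
    TruthTable,
    VerdictRule,
    call_system,
    evaluate_recovery,
    read_kmer_set_from_sequences,
    run_dual_scan,
    simulate_dataset,
    simulate_genome,
    simulate_reads,
    summarize_candidates,
)
from ygscan.ygs_core import ScaffoldRecord

SMALL = SimSpec(
    autosome_lengths=(30_000, 20_000),
    x_length=15_000,
    y_length=8_000,
    repeat_unit_len=500,
    scaffold_length=1_000,
    seed=11,
)


class TestSimulateGenome:
    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = simulate_dataset(SMALL, d1)
        p2 = simulate_dataset(SMALL, d2)
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, key

    def test_sex_limited_chromosome_only_in_heterogametic_sex(self):
        sim = simulate_genome(SMALL)
        assert "Y" in sim.male_chromosomes
        assert "Y" not in sim.female_chromosomes
        assert set(sim.female_chromosomes) == {"A1", "A2", "X"}
        zw = simulate_genome(
            SimSpec(**{**SMALL.__dict__, "system": "ZW"})
        )
        assert "W" in zw.female_chromosomes
        assert "W" not in zw.male_chromosomes

    def test_unique_y_sequence_absent_from_female_genome(self):
        sim = simulate_genome(SMALL)
        female_cat = "#".join(sim.female_chromosomes.values())
        truth = sim.truth.table.set_index("scaffold_id")
        for sid, seq in sim.scaffolds:
            if truth.loc[sid, "chromosome"] == "Y" and truth.loc[sid, "repeat_fraction"] == 0.0:
                assert seq not in female_cat
                assert revcomp(seq) not in female_cat

    def test_y_repeat_mass_matches_spec_fraction(self):
        sim = simulate_genome(SimSpec(seed=5))
        t = sim.truth.table
        y = t[t.chromosome == "Y"]
        lengths = np.array(
            [len(s) for sid, s in sim.scaffolds if sid.startswith("Y_")]
        )
        rep_bases = float((y.repeat_fraction.to_numpy() * lengths).sum())
        frac = rep_bases / lengths.sum()
        assert abs(frac - 0.2) <= 0.05  # 1 - y_unique_fraction, within 5 pp

    def test_truth_covers_every_scaffold_once(self):
        sim = simulate_genome(SMALL)
        ids = [sid for sid, _ in sim.scaffolds]
        assert sorted(sim.truth.table.scaffold_id) == sorted(ids)
        assert len(set(ids)) == len(ids)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            SimSpec(error_rate=0.5)
        with pytest.raises(ConfigError):
            SimSpec(y_unique_fraction=1.5)
        with pytest.raises(ConfigError):
            SimSpec(system="XO")


class TestSimulateReads:
    def test_read_count_is_depth_times_bp_over_length(self):
        genome = {"c": "ACGT" * 1000}
        reads = list(simulate_reads(genome, SimSpec(depth=5.0, seed=1)))
        assert len(reads) == round(5.0 * 4000 / 100)
        assert all(len(seq) == 100 for _, seq in reads)

    def test_error_free_reads_are_exact_genomic_substrings(self):
        sim = simulate_genome(SMALL)
        spec0 = SimSpec(**{**SMALL.__dict__, "error_rate": 0.0, "depth": 0.5})
        cat = "#".join(sim.male_chromosomes.values())
        for _rid, seq in simulate_reads(sim.male_chromosomes, spec0, seed=3):
            assert seq in cat or revcomp(seq) in cat

    def test_too_short_chromosome_is_config_error(self):
        with pytest.raises(ConfigError):
            list(simulate_reads({"c": "ACGT"}, SimSpec(seed=1)))

    def test_full_coverage_error_free_autosomes_fully_matched(self):
        """With no errors, presence threshold 1, and guaranteed coverage of
        every position, autosomal and X scaffolds are 0% unmatched on both
        sides."""
        spec = SimSpec(
            autosome_lengths=(6_000,),
            x_length=3_000,
            y_length=2_000,
            repeat_unit_len=300,
            scaffold_length=1_000,
            error_rate=0.0,
            depth=50.0,
            seed=21,
        )
        sim = simulate_genome(spec)
        params = ScanParams(
            kmer=KmerParams(k=16, min_read_count=1, min_scaffold_len=200)
        )

        def reads_for(chroms, seed):
            out = [seq for _rid, seq in simulate_reads(chroms, spec, seed=seed)]
            # guarantee the chromosome ends are covered too
            for s in chroms.values():
                out.append(s[: spec.read_length])
                out.append(s[-spec.read_length :])
            return out

        male = read_kmer_set_from_sequences(
            reads_for(sim.male_chromosomes, 100), params.kmer, "male"
        )
        female = read_kmer_set_from_sequences(
            reads_for(sim.female_chromosomes, 200), params.kmer, "female"
        )
        scan = run_dual_scan(sim.scaffolds, male, female, params)
        truth = sim.truth.table.set_index("scaffold_id")
        for rec in scan.records:
            if truth.loc[rec.scaffold_id, "chromosome"] != "Y":
                assert rec.pct_unmatched_female == 0.0
                assert rec.pct_unmatched_male == 0.0
                assert rec.pct_absent_both == 0.0


class TestRecovery:
    def test_perfect_classification_scores_one_and_zero(self):
        truth = TruthTable(
            table=pd.DataFrame(
                {
                    "scaffold_id": ["A1_0", "X_0", "Y_0"],
                    "chromosome": ["A1", "X", "Y"],
                    "repeat_fraction": [0.0, 0.0, 0.1],
                }
            ),
            system="XY",
        )
        records = [
            ScaffoldRecord("A1_0", 100, 10, 0, 10, 0.0, 0.0, 0.0, qc_pass=True),
            ScaffoldRecord("X_0", 100, 10, 0, 10, 0.0, 0.0, 0.0, qc_pass=True),
            ScaffoldRecord(
                "Y_0", 100, 10, 0, 10, 0.0, 100.0, 0.0,
                qc_pass=True, is_candidate_xy=True,
            ),
        ]
        scan = ScanResult(records=records, params=ScanParams())
        from ygscan import CandidateSummary

        v = call_system(
            CandidateSummary("XY", 40, 200_000), CandidateSummary("ZW", 0, 0)
        )
        m = evaluate_recovery(scan, truth, v)
        assert m.sensitivity == 1.0
        assert m.false_positive_rate == 0.0
        assert m.verdict_correct

    def test_unknown_scaffold_id_is_input_error(self):
        truth = TruthTable(
            table=pd.DataFrame(
                {"scaffold_id": ["A1_0"], "chromosome": ["A1"], "repeat_fraction": [0.0]}
            ),
            system="XY",
        )
        records = [
            ScaffoldRecord("mystery", 100, 10, 0, 10, 0.0, 0.0, 0.0, qc_pass=True)
        ]
        scan = ScanResult(records=records, params=ScanParams())
        from ygscan import CandidateSummary

        v = call_system(CandidateSummary("XY", 0, 0), CandidateSummary("ZW", 0, 0))
        with pytest.raises(InputError):
            evaluate_recovery(scan, truth, v)

    def test_small_simulation_end_to_end_recovery(self, tmp_path):
        paths = simulate_dataset(SMALL, tmp_path / "sim")
        scan = run_dual_scan(
            paths["assembly"],
            paths["male_reads"],
            paths["female_reads"],
            ScanParams(),
        )
        rule = VerdictRule(min_candidates=4, min_bp=3_000)
        verdict = call_system(
            summarize_candidates(scan, "XY"),
            summarize_candidates(scan, "ZW"),
            rule,
        )
        truth = TruthTable.from_tsv(paths["truth"])
        m = evaluate_recovery(scan, truth, verdict)
        assert m.verdict_correct
        assert m.sensitivity >= 0.9
        assert m.false_positive_rate <= 0.02
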