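import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seminoquant.cohort_qc import RosGroup
from seminoquant.psm_io import (
    Engine,
    PSMRecord,
    ProteinRecord,
    consensus_filter,
    consensus_proteins,
    coverage,
    evidence_to_frame,
    frame_to_evidence,
    read_fasta,
    read_psm_table,
    tally_evidence,
    tally_evidence_frame,
    write_fasta,
    write_psm_table,
)


def make_psm(spectrum_id="sp1", pool=RosGroup.ROS_MINUS, engine=Engine.ENGINE_A,
             peptide="PEPTIDEK", protein="P1", score=100.0, start=None, end=None):
    return PSMRecord(spectrum_id, pool, engine, peptide, protein, score, start, end)


@pytest.fixture
def two_proteins():
    return {
        "P1": ProteinRecord("P1", "GENE1", sequence="A" * 50),
        "P2": ProteinRecord("P2", "GENE2", sequence="C" * 100),
    }


class TestFasta:
    def test_roundtrip_with_pipe_headers(self, tmp_path):
        records = [
            ProteinRecord("ACC1", "GENE1", "U1", sequence="MKTAYIAKQR",
                          description="test protein"),
            ProteinRecord("ACC2", "GENE2", None, sequence="M" + "A" * 99),
        ]
        path = tmp_path / "db.fasta"
        write_fasta(records, path)
        loaded = read_fasta(path)
        assert [r.ncbi_accession for r in loaded] == ["ACC1", "ACC2"]
        assert loaded[0].length == 10 and loaded[1].length == 100
        assert loaded[0].uniprot_accession == "U1"
        assert loaded[1].uniprot_accession is None
        assert loaded[0].mw > 0 and loaded[0].pi > 0

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">A1|G1|\nMKT\n>A1|G2|\nMRT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_reference_proteome_has_14_records(self, tmp_path, rng):
        # synthetic sequences tagged with the 14 reference gene symbols
        from seminoquant.synthetic_data import SimConfig, generate_proteome

        genes = ["FN1", "MIF", "LGALS3BP", "CST4", "ALB", "LTF", "KLK3",
                 "PIP", "SEMG2", "ACPP", "CLU", "AZGP1", "KLK3", "SEMG1"]
        config = SimConfig(n_proteins=14, length_range=(50, 200))
        proteome = generate_proteome(config, rng, gene_symbols=genes)
        path = tmp_path / "ref.fasta"
        write_fasta(proteome, path)
        assert len(read_fasta(path)) == 14


class TestPsmTable:
    def test_roundtrip(self, tmp_path):
        records = [
            make_psm("sp1", start=1, end=8),
            make_psm("sp2", pool=RosGroup.ROS_PLUS, engine=Engine.ENGINE_B),
            make_psm("sp3", peptide="AK"),
        ]
        path = tmp_path / "psm.tsv"
        write_psm_table(records, path)
        assert read_psm_table(path) == records

    def test_end_before_start_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "spectrum_id\tpool\tengine\tpeptide\tprotein_accession\tscore\tstart\tend\n"
            "sp1\tROS_minus\tengine_a\tPEPK\tP1\t10\t9\t4\n"
        )
        with pytest.raises(ValueError, match="line 1"):
            read_psm_table(path)

    def test_engine_mismatch_rejected(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_psm_table([make_psm(engine=Engine.ENGINE_B)], path)
        with pytest.raises(ValueError, match="engine"):
            read_psm_table(path, Engine.ENGINE_A)


class TestConsensus:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"P1", "P2"}, {"P2", "P3"}, {"P2"}),
            ({"P1"}, {"P1"}, {"P1"}),
            ({"P1"}, {"P2"}, set()),
        ],
    )
    def test_intersection(self, a, b, expected):
        assert consensus_proteins(a, b) == expected
        assert consensus_proteins(b, a) == consensus_proteins(a, b)
        assert consensus_proteins(a, b) <= a and consensus_proteins(a, b) <= b

    def test_consensus_filter_requires_both_engines(self, two_proteins):
        psms = [
            make_psm("s1", engine=Engine.ENGINE_A, protein="P1"),
            make_psm("s1", engine=Engine.ENGINE_B, protein="P1"),
            make_psm("s2", engine=Engine.ENGINE_A, protein="P2"),
        ]
        kept = consensus_filter(tally_evidence(psms, two_proteins))
        assert {e.protein_accession for e in kept} == {"P1"}


class TestCoverage:
    @pytest.mark.parametrize(
        "intervals,length,expected",
        [
            ([(1, 5)], 10, 50.0),
            ([(1, 5), (3, 8)], 10, 80.0),
            ([], 10, 0.0),
            ([(1, 10)], 10, 100.0),
            ([(1, 2), (4, 5)], 10, 40.0),  # non-adjacent intervals
        ],
    )
    def test_examples(self, intervals, length, expected):
        assert coverage(intervals, length) == pytest.approx(expected)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            coverage([(0, 5)], 10)
        with pytest.raises(ValueError):
            coverage([(5, 11)], 10)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_boolean_mask_oracle(self, data):
        length = data.draw(st.integers(1, 500))
        n = data.draw(st.integers(0, 20))
        intervals = []
        for _ in range(n):
            start = data.draw(st.integers(1, length))
            end = data.draw(st.integers(start, length))
            intervals.append((start, end))
        mask = np.zeros(length, dtype=bool)
        for start, end in intervals:
            mask[start - 1:end] = True
        assert coverage(intervals, length) == pytest.approx(
            100.0 * mask.sum() / length
        )


class TestTally:
    def test_counts_and_distinct_peptides(self, two_proteins):
        psms = [make_psm(f"s{i}", peptide=p) for i, p in
                enumerate(["AAAK", "AAAK", "CCCK", "DDDK", "AAAK"])]
        (ev,) = tally_evidence(psms, two_proteins, count_engine="sum")
        assert ev.n_spectra == 5 and ev.n_peptides == 3

    def test_same_peptide_from_both_engines(self, two_proteins):
        psms = [
            make_psm("s1", engine=Engine.ENGINE_A),
            make_psm("s1", engine=Engine.ENGINE_B),
        ]
        (ev,) = tally_evidence(psms, two_proteins, count_engine="max")
        assert ev.engines == frozenset(Engine)
        assert ev.n_peptides == 1 and ev.n_spectra == 1

    def test_unknown_protein_rejected(self, two_proteins):
        with pytest.raises(ValueError, match="unknown"):
            tally_evidence([make_psm(protein="P9")], two_proteins)

    def test_pool_totals_match_row_counts(self, two_proteins, rng):
        psms = []
        for i in range(300):
            psms.append(
                make_psm(
                    f"s{i}",
                    pool=RosGroup(rng.choice(["ROS_minus", "ROS_plus"])),
                    engine=Engine(rng.choice(["engine_a", "engine_b"])),
                    protein=str(rng.choice(["P1", "P2"])),
                    peptide=str(rng.choice(["AAAK", "CCCK", "DDDR"])),
                )
            )
        evidence = tally_evidence(psms, two_proteins, count_engine="sum")
        for pool in RosGroup:
            total = sum(e.n_spectra for e in evidence if e.pool is pool)
            assert total == sum(1 for p in psms if p.pool is pool)

    def test_frame_tally_matches_record_recount_oracle(self, rng):
        """DataFrame fast path equals an independent hash-map recount."""
        from seminoquant.synthetic_data import SimConfig, simulate_experiment

        config = SimConfig(n_proteins=20, depth=2000.0, seed=7)
        proteome, _, psms, _ = simulate_experiment(config)
        proteins = {p.ncbi_accession: p for p in proteome}
        frame = pd.concat(psms.values(), ignore_index=True)

        # independent recount with plain dictionaries
        counts, peptides = {}, {}
        for row in frame.itertuples(index=False):
            key = (row.protein_accession, row.pool, row.engine)
            counts[key] = counts.get(key, 0) + 1
            peptides.setdefault(
                (row.protein_accession, row.pool), set()
            ).add(row.peptide)

        evidence = tally_evidence_frame(frame, proteins, count_engine="sum")
        for ev in evidence:
            expected_sc = sum(
                counts.get((ev.protein_accession, ev.pool.value, e.value), 0)
                for e in Engine
            )
            assert ev.n_spectra == expected_sc
            assert ev.n_peptides == len(
                peptides[(ev.protein_accession, ev.pool.value)]
            )

    def test_frame_and_record_paths_agree(self, rng):
        from seminoquant.synthetic_data import SimConfig, simulate_experiment

        config = SimConfig(n_proteins=15, depth=1500.0, seed=3)
        proteome, _, psms, _ = simulate_experiment(config)
        proteins = {p.ncbi_accession: p for p in proteome}
        frame = pd.concat(psms.values(), ignore_index=True)
        records = read_psm_table_from_frame(frame)
        by_key = lambda evs: {
            (e.protein_accession, e.pool): (e.n_spectra, e.n_peptides, e.engines)
            for e in evs
        }
        assert by_key(tally_evidence_frame(frame, proteins)) == by_key(
            tally_evidence(records, proteins)
        )

    def test_coverage_lower_bound_when_positions_missing(self, two_proteins):
        psms = [
            make_psm("s1", start=1, end=10),
            make_psm("s2"),  # no positions: counts but not coverage
        ]
        (ev,) = tally_evidence(psms, two_proteins, count_engine="sum")
        assert ev.coverage == pytest.approx(20.0)
        (ev,) = tally_evidence([make_psm("s1")], two_proteins)
        assert ev.coverage is None


def read_psm_table_from_frame(frame):
    """Build PSMRecord objects from a frame (test helper)."""
    return [
        PSMRecord(
            spectrum_id=row.spectrum_id,
            pool=RosGroup(row.pool),
            engine=Engine(row.engine),
            peptide=row.peptide,
            protein_accession=row.protein_accession,
            score=float(row.score),
            start=int(row.start) if pd.notna(row.start) else None,
            end=int(row.end) if pd.notna(row.end) else None,
        )
        for row in frame.itertuples(index=False)
    ]


class TestEvidenceFrame:
    def test_roundtrip(self, two_proteins):
        psms = [
            make_psm("s1", start=1, end=10),
            make_psm("s1", engine=Engine.ENGINE_B, start=1, end=10),
            make_psm("s2", pool=RosGroup.ROS_PLUS, protein="P2"),
        ]
        evidence = tally_evidence(psms, two_proteins)
        frame = evidence_to_frame(evidence)
        back = frame_to_evidence(frame)
        assert {(e.protein_accession, e.pool, e.n_spectra) for e in back} == {
            (e.protein_accession, e.pool, e.n_spectra) for e in evidence
        }
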