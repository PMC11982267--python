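import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtail.counting import (
    CountTable,
    MiRNARecord,
    ReferenceSet,
    assign_read,
    build_references,
    count_reads,
    hamming,
    trim_adapter,
)
from mirtail.simulate import generate_reference, simulate_reads, write_fastq
from mirtail.simulate import SampleSpec, SimulationConfig

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)

# module-level refset for hypothesis tests (function-scoped fixtures are
# re-created per example and rejected by hypothesis health checks)
TINY = ReferenceSet.from_records(
    [
        MiRNARecord("mir-a", "ACGTACGTACGTACGTACGT"),
        MiRNARecord("mir-b", "TTGCATTGCATTGCATTGCA"),
        MiRNARecord("mir-c", "GGGCCCGGGCCCGGGCCCGG"),
    ]
)


def brute_force_assign(read: str, refset: ReferenceSet, max_mismatch: int = 0):
    """Independent oracle: compare read against every reference sequence."""
    hits = set()
    for rec in refset.canonical:
        if len(rec.sequence) == len(read) and hamming(read, rec.sequence) <= max_mismatch:
            hits.add((rec.mirna_id, "canonical"))
    for can, ade in zip(refset.canonical, refset.adenylated):
        if len(ade.sequence) == len(read) and hamming(read, ade.sequence) <= max_mismatch:
            hits.add((can.mirna_id, "adenylated"))
    if not hits:
        return ("unassigned", None)
    if len(hits) == 1:
        ((mid, status),) = hits
        return (status, mid)
    return ("ambiguous", None)


class TestBuildReferences:
    def test_mir7_mimic_gets_plus_a(self, tmp_path):
        # mature sequence (DNA-space) and its expected +A counterpart
        fa = tmp_path / "ref.fa"
        fa.write_text(">mir-7-5p\nTGGAAGACTAGTGATTTTGTT\n")
        rs = build_references(fa)
        assert rs.adenylated[0].sequence == "TGGAAGACTAGTGATTTTGTTA"
        assert rs.adenylated[0].mirna_id == "mir-7-5p+A"

    def test_rna_space_input_converted(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">x\nUGGAAGACUAGUGAUUUUGUU\n")
        rs = build_references(fa, convert_u=True)
        assert rs.canonical[0].sequence == "TGGAAGACTAGTGATTTTGTT"

    def test_duplicate_sequences_reported(self):
        rs = ReferenceSet.from_records(
            [MiRNARecord("x", "ACGTACGT"), MiRNARecord("y", "ACGTACGT")]
        )
        kinds = {c.kind for c in rs.collisions}
        assert "duplicate" in kinds

    def test_canonical_equals_adenylated_collision(self):
        rs = ReferenceSet.from_records(
            [MiRNARecord("x", "ACGTACG"), MiRNARecord("y", "ACGTACGA")]
        )
        assert any(
            c.kind == "canonical-equals-adenylated" and {c.id_a, c.id_b} == {"x", "y"}
            for c in rs.collisions
        )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReferenceSet.from_records(
                [MiRNARecord("x", "ACGT"), MiRNARecord("x", "TTTT")]
            )

    def test_empty_fasta_rejected(self, tmp_path):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            build_references(fa)

    def test_bad_alphabet_rejected(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">x\nACGTN\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            build_references(fa)


class TestTrimAdapter:
    ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGTA"
        trimmed, found = trim_adapter(insert + self.ADAPTER, self.ADAPTER)
        assert found and trimmed == insert

    def test_no_adapter_unchanged_and_flagged(self):
        read = "ACGTACGTACGTACGTACGTA"
        trimmed, found = trim_adapter(read, self.ADAPTER)
        assert not found and trimmed == read

    def test_one_substitution_with_tolerance(self):
        insert = "ACGTACGTACGTACGTACGTA"
        mutated = "A" + self.ADAPTER[1:] if self.ADAPTER[0] != "A" else "C" + self.ADAPTER[1:]
        trimmed, found = trim_adapter(insert + mutated, self.ADAPTER, max_mismatch=1)
        assert found and trimmed == insert

    def test_partial_adapter_at_read_end(self):
        insert = "ACGTACGTACGTACGTACGTA"
        trimmed, found = trim_adapter(insert + self.ADAPTER[:6], self.ADAPTER)
        assert found and trimmed == insert

    def test_overlap_below_minimum_not_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTC"
        read = insert + self.ADAPTER[:2]
        trimmed, found = trim_adapter(read, self.ADAPTER, min_overlap=3)
        assert not found and trimmed == read

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", "")

    @given(insert=DNA, cut=st.integers(min_value=3, max_value=21))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_cut_scan(self, insert, cut):
        # oracle: leftmost position whose suffix matches an adapter prefix
        adapter = self.ADAPTER
        read = insert + adapter[:cut]
        n = len(read)
        expected = None
        for i in range(n):
            k = min(len(adapter), n - i)
            if k < 3:
                break
            if read[i : i + k] == adapter[:k]:
                expected = read[:i]
                break
        trimmed, found = trim_adapter(read, adapter, max_mismatch=0, min_overlap=3)
        if expected is None:
            assert not found
        else:
            assert found and trimmed == expected


class TestAssignRead:
    def test_canonical_hit(self, tiny_refset):
        a = assign_read("ACGTACGTACGTACGTACGT", tiny_refset)
        assert (a.status, a.mirna_id) == ("canonical", "mir-a")

    def test_adenylated_hit(self, tiny_refset):
        a = assign_read("ACGTACGTACGTACGTACGTA", tiny_refset)
        assert (a.status, a.mirna_id) == ("adenylated", "mir-a")

    def test_double_a_unassigned(self, tiny_refset):
        a = assign_read("ACGTACGTACGTACGTACGTAA", tiny_refset)
        assert a.status == "unassigned"

    def test_duplicate_sequences_ambiguous(self):
        rs = ReferenceSet.from_records(
            [MiRNARecord("x", "ACGTACGT"), MiRNARecord("y", "ACGTACGT")]
        )
        assert assign_read("ACGTACGT", rs).status == "ambiguous"

    def test_canonical_priority_policy(self):
        # canonical(y) == canonical(x)+"A": read matches both references
        rs = ReferenceSet.from_records(
            [MiRNARecord("x", "ACGTACG"), MiRNARecord("y", "ACGTACGA")]
        )
        assert assign_read("ACGTACGA", rs).status == "ambiguous"
        a = assign_read("ACGTACGA", rs, policy="canonical")
        assert (a.status, a.mirna_id) == ("canonical", "y")

    def test_one_mismatch_tolerance(self, tiny_refset):
        read = "CCGTACGTACGTACGTACGT"
        assert assign_read(read, tiny_refset).status == "unassigned"
        a = assign_read(read, tiny_refset, max_mismatch=1)
        assert (a.status, a.mirna_id, a.mismatches) == ("canonical", "mir-a", 1)

    def test_short_read_unassigned(self, tiny_refset):
        assert assign_read("ACGT", tiny_refset).status == "unassigned"

    @given(read=DNA, mm=st.integers(min_value=0, max_value=2))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force(self, read, mm):
        got = assign_read(read, TINY, max_mismatch=mm)
        status, mid = brute_force_assign(read, TINY, mm)
        assert (got.status, got.mirna_id) == (status, mid)

    @given(read=DNA)
    @settings(max_examples=100, deadline=None)
    def test_mismatch_monotonicity(self, read):
        hit = []
        for mm in (0, 1, 2):
            a = assign_read(read, TINY, max_mismatch=mm)
            hit.append(a.status != "unassigned")
        assert hit == sorted(hit)


class TestCountReads:
    def _simulate_library(self, tmp_path, seed=0, reads=1000, error_rate=0.0):
        cfg = SimulationConfig(
            n_mirnas=8,
            samples=[SampleSpec("s1", "c", reads)],
            adenylation_prob={"*": {"c": 0.3}},
            error_rate=error_rate,
            seed=seed,
        )
        rs = generate_reference(cfg)
        libs, truth = simulate_reads(rs, cfg)
        fq = tmp_path / "s1.fastq"
        write_fastq(libs["s1"], fq)
        return rs, fq, truth

    def test_round_trip_equals_truth(self, tmp_path):
        rs, fq, truth = self._simulate_library(tmp_path)
        table = count_reads({"s1": fq}, rs)
        assert (table.canonical == truth.canonical_counts).all().all()
        assert (table.adenylated == truth.adenylated_counts).all().all()
        table.check_conservation()

    def test_empty_fastq(self, tmp_path, tiny_refset):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        table = count_reads({"s1": fq}, tiny_refset)
        assert table.canonical.values.sum() == 0
        assert table.totals.loc["s1", "total"] == 0

    def test_single_adenylated_sequence(self, tmp_path, tiny_refset):
        seq = "ACGTACGTACGTACGTACGTA"
        fq = tmp_path / "r.fastq"
        fq.write_text("".join(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n" for i in range(25)))
        table = count_reads({"s1": fq}, tiny_refset)
        assert table.adenylated.loc["mir-a", "s1"] == 25
        assert table.canonical.values.sum() == 0
        assert table.adenylated.values.sum() == 25

    def test_truncated_fastq_names_file_and_record(self, tmp_path, tiny_refset):
        fq = tmp_path / "trunc.fastq"
        fq.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n")
        with pytest.raises(ValueError, match="trunc.fastq.*record 2"):
            count_reads({"s1": fq}, tiny_refset)

    def test_adapter_trimming_recovers_truth(self, tmp_path):
        cfg = SimulationConfig(
            n_mirnas=6,
            samples=[SampleSpec("s1", "c", 800)],
            adenylation_prob={"*": {"c": 0.25}},
            adapter="TGGAATTCTCGGGTGCCAAGG",
            seed=9,
        )
        rs = generate_reference(cfg)
        libs, truth = simulate_reads(rs, cfg)
        fq = tmp_path / "s1.fastq"
        write_fastq(libs["s1"], fq)
        table = count_reads({"s1": fq}, rs, adapter=cfg.adapter)
        assert (table.canonical == truth.canonical_counts).all().all()
        assert (table.adenylated == truth.adenylated_counts).all().all()

    def test_gzipped_fastq(self, tmp_path):
        cfg = SimulationConfig(
            n_mirnas=4,
            samples=[SampleSpec("s1", "c", 200)],
            adenylation_prob={"*": {"c": 0.5}},
            seed=2,
        )
        rs = generate_reference(cfg)
        libs, truth = simulate_reads(rs, cfg)
        fq = tmp_path / "s1.fastq.gz"
        write_fastq(libs["s1"], fq)
        table = count_reads({"s1": fq}, rs)
        assert (table.adenylated == truth.adenylated_counts).all().all()

    def test_tsv_round_trip(self, tmp_path):
        rs, fq, _ = self._simulate_library(tmp_path)
        table = count_reads({"s1": fq}, rs)
        out = tmp_path / "counts.tsv"
        table.to_tsv(out)
        back = CountTable.from_tsv(out)
        assert (back.canonical == table.canonical).all().all()
        assert (back.adenylated == table.adenylated).all().all()

    def test_oracle_equivalence_with_errors(self, tmp_path):
        # substitution errors push reads off-reference; oracle must agree
        rs, fq, _ = self._simulate_library(tmp_path, seed=4, reads=500, error_rate=0.05)
        table = count_reads({"s1": fq}, rs)
        from mirtail.counting import iter_fastq

        canon = {m: 0 for m in rs.mirna_ids}
        aden = {m: 0 for m in rs.mirna_ids}
        n = 0
        for _, seq in iter_fastq(fq):
            n += 1
            status, mid = brute_force_assign(seq, rs)
            if status == "canonical":
                canon[mid] += 1
            elif status == "adenylated":
                aden[mid] += 1
        assert n == table.totals.loc["s1", "total"]
        for m in rs.mirna_ids:
            assert table.canonical.loc[m, "s1"] == canon[m]
            assert table.adenylated.loc[m, "s1"] == aden[m]
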