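"""Exact-match marker counting in reads and the typability filter."""

import gzip

import pytest

import oracles
from conftest import random_dna
from oligotyper import (
    KmerSet,
    MarkerCountTable,
    Oligomer,
    canonicalize,
    count_in_library,
    extract_single_copy,
    filter_typable,
    revcomp,
    simulate_reads,
)
from oligotyper.typability import iter_fastq


def _kmer_set(gene_id, markers):
    return KmerSet(gene_id, "src", [Oligomer(m, gene_id, i) for i, m in enumerate(markers)])


def test_empty_library_counts_nothing(rng):
    markers = {canonicalize(random_dna(rng, 80)) for _ in range(5)}
    table = count_in_library(markers, [])
    assert table.counts == {} and table.n_reads == 0


def test_single_read_equal_to_marker(rng):
    m = canonicalize(random_dna(rng, 80))
    other = canonicalize(random_dna(rng, 80))
    table = count_in_library({m, other}, [m])
    assert table.get(m) == 1 and table.get(other) == 0


def test_marker_twice_in_one_read_counts_two(rng):
    m = random_dna(rng, 80)
    read = m + random_dna(rng, 30) + revcomp(m)  # second hit on opposite strand
    table = count_in_library({canonicalize(m)}, [read])
    assert table.get(canonicalize(m)) == 2


def test_counts_match_bruteforce_on_simulated_reads(rng):
    source = random_dna(rng, 5_000)
    gene = source[1_000:1_300]
    markers = {canonicalize(w) for _off, w in oracles.naive_windows(gene, 80)}
    reads = [seq for _n, seq in simulate_reads({"chr1": source}, 10.0, 100, 0.0, 77)]
    assert 400 <= len(reads) <= 600  # ~500 expected
    table = count_in_library(markers, reads)
    assert table.counts == oracles.naive_read_counts(markers, reads, 80)


def test_counting_is_strand_and_order_independent(rng):
    source = random_dna(rng, 3_000)
    markers = {canonicalize(w) for _o, w in oracles.naive_windows(source[500:700], 80)}
    reads = [seq for _n, seq in simulate_reads({"c": source}, 8.0, 120, 0.0, 5)]
    base = count_in_library(markers, reads).counts
    assert count_in_library(markers, [revcomp(r) for r in reads]).counts == base
    assert count_in_library(markers, list(reversed(reads))).counts == base


def test_short_reads_are_skipped(rng):
    m = random_dna(rng, 80)
    table = count_in_library({canonicalize(m)}, [m[:79], m])
    assert table.get(canonicalize(m)) == 1
    assert table.n_short_reads == 1


def test_fastq_files_and_gzip_round_trip(rng, tmp_path):
    m = random_dna(rng, 80)
    record = f"@r1\n{m}\n+\n{'I' * 80}\n"
    plain = tmp_path / "r.fastq"
    plain.write_text(record * 3)
    gz = tmp_path / "r.fastq.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write(record * 3)
    for path in (plain, gz):
        assert count_in_library({canonicalize(m)}, path).get(canonicalize(m)) == 3


def test_malformed_fastq_names_record_index(tmp_path):
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n")  # record 1 lacks '+'
    with pytest.raises(ValueError, match="index 1"):
        list(iter_fastq(bad))
    truncated = tmp_path / "trunc.fastq"
    truncated.write_text("@r0\nACGT\n+\n")
    with pytest.raises(ValueError, match="record at index 0"):
        list(iter_fastq(truncated))


def _table(lib, counts):
    return MarkerCountTable(lib, counts)


def test_filter_count_bounds_and_other_absence(rng):
    ms = [random_dna(rng, 80) for _ in range(5)]
    canon = [canonicalize(m) for m in ms]
    ks = _kmer_set("gene", ms)
    source = _table("src", {canon[0]: 0, canon[1]: 1, canon[2]: 100,
                            canon[3]: 101, canon[4]: 5})
    other = _table("other", {canon[4]: 1})
    panel = filter_typable([ks], source, [other], min_count=1, max_count=100)
    kept = {m.sequence for m in panel.markers["gene"]}
    assert kept == {ms[1], ms[2]}  # 0 too low, 101 too high, 5-but-seen-elsewhere out


def test_filter_monotone_in_other_library_reads(rng):
    ms = [random_dna(rng, 80) for _ in range(10)]
    ks = _kmer_set("gene", ms)
    source = _table("src", {canonicalize(m): 3 for m in ms})
    before = filter_typable([ks], source, []).total()
    other = _table("o", {canonicalize(m): 1 for m in ms[:4]})
    after = filter_typable([ks], source, [other]).total()
    assert after <= before and after == 6


def test_empty_source_gives_empty_panel_with_warning(rng, caplog):
    ks = _kmer_set("gene", [random_dna(rng, 80)])
    with caplog.at_level("WARNING"):
        panel = filter_typable([ks], _table("src", {}), [])
    assert panel.total() == 0
    assert any("empty" in r.message for r in caplog.records)


def test_source_unique_sequence_survives_shared_sequence_dropped(small_pangenome):
    """End-to-end filter semantics on an error-free simulated pangenome:

    markers from sequence private to the source survive; markers shared
    with any other assembly (paralog-shared windows) are dropped.
    """
    pg = small_pangenome
    src = pg.source_assembly
    sets = [extract_single_copy(g, pg.gene_sequences[g], pg.assemblies[src],
                                source_assembly=src)
            for g in pg.truth.target_genes]
    universe = set().union(*(s.canonical_forms() for s in sets))
    libs = {a: [s for _n, s in simulate_reads(c, 20.0, 150, 0.0, i)]
            for i, (a, c) in enumerate(pg.assemblies.items())}
    source_counts = count_in_library(universe, libs[src], src)
    others = [count_in_library(universe, libs[a], a) for a in libs if a != src]
    panel = filter_typable(sets, source_counts, others)
    other_contigs = {a: c["chr1"] for a, c in pg.assemblies.items() if a != src}
    for gene, members in panel.markers.items():
        assert members, gene
        for m in members:
            assert all(oracles.naive_genome_count(m.sequence, {"c": contig}) == 0
                       for contig in other_contigs.values())
    # and any candidate occurring verbatim in another assembly was dropped
    kept = {m.canonical for ms in panel.markers.values() for m in ms}
    for s in sets:
        for m in s.members:
            shared = any(oracles.naive_genome_count(m.sequence, {"c": c}) > 0
                         for c in other_contigs.values())
            if shared:
                assert m.canonical not in kept
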