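"""Synthetic pangenome generator: determinism, truth invariants, read model."""

import numpy as np
import pytest

from oligotyper import (
    SimulationConfig,
    simulate_cohort,
    simulate_pangenome,
    simulate_reads,
)
from oligotyper.simulate import write_fasta, write_fastq, write_gff3, write_truth_tsv
from oligotyper.kmers import revcomp


def _tiny(**kw):
    defaults = dict(n_assemblies=3, background_length=2_000, n_cluster_genes=3,
                    n_target_genes=1, gene_length=300, copy_number_range=(1, 4),
                    coverage=5.0, read_length=100, error_rate=0.0, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_config_validation():
    with pytest.raises(ValueError, match="gene_length"):
        _tiny(gene_length=79)
    with pytest.raises(ValueError, match="copy_number_range"):
        _tiny(copy_number_range=(0, 4))
    with pytest.raises(ValueError, match="copy_number_range"):
        _tiny(copy_number_range=(5, 2))
    with pytest.raises(ValueError, match="pav_probability"):
        _tiny(pav_probability=1.5)
    with pytest.raises(ValueError, match="n_target_genes"):
        _tiny(n_target_genes=5)


def test_forced_presence_truth_all_true():
    cfg = SimulationConfig(n_assemblies=1, background_length=2_000,
                           n_cluster_genes=2, n_target_genes=1, gene_length=300,
                           copy_number_range=(2, 4), pav_probability=1.0, seed=1)
    pg = simulate_pangenome(cfg)
    assert pg.truth.pav.values.all()
    assert pg.truth.source_assembly in pg.assemblies


def test_copy_number_stays_in_configured_range():
    cfg = SimulationConfig(n_assemblies=30, background_length=1_000,
                           n_cluster_genes=8, gene_length=100,
                           copy_number_range=(2, 8), pav_probability=0.4, seed=3)
    pg = simulate_pangenome(cfg)
    assert ((pg.truth.copy_number >= 2) & (pg.truth.copy_number <= 8)).all()
    # source carries all target genes; targets are private to the source
    src = pg.truth.source_assembly
    for g in pg.truth.target_genes:
        row = pg.truth.pav.loc[g]
        assert row[src] and not row.drop(src).any()


def test_annotation_matches_embedded_sequence():
    pg = simulate_pangenome(_tiny())
    for asm_id, features in pg.annotations.items():
        contig = pg.assemblies[asm_id]["chr1"]
        for f in features:
            span = contig[f.start - 1 : f.end]  # GFF3 1-based inclusive
            expected = pg.gene_sequences[f.gene_id]
            assert span == (expected if f.strand == "+" else revcomp(expected))


def test_byte_identical_outputs_for_same_seed(tmp_path):
    dirs = []
    for run in ("a", "b"):
        cfg = _tiny(seed=7)
        pg = simulate_pangenome(cfg)
        out = tmp_path / run
        out.mkdir()
        for asm_id, contigs in pg.assemblies.items():
            write_fasta(contigs, out / f"{asm_id}.fasta")
            write_gff3(pg.annotations[asm_id], out / f"{asm_id}.gff3")
        write_truth_tsv(pg.truth, out / "truth.tsv")
        reads = simulate_reads(pg.assemblies[pg.truth.source_assembly],
                               5.0, 100, 0.01, 99)
        write_fastq(reads, out / "reads.fastq")
        dirs.append(out)
    a, b = dirs
    for f in sorted(a.iterdir()):
        assert f.read_bytes() == (b / f.name).read_bytes(), f.name


def test_read_count_tracks_coverage(rng):
    genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))}
    reads = simulate_reads(genome, 10.0, 100, 0.0, 13)
    assert abs(len(reads) - 1000) <= 5 * np.sqrt(1000)  # Poisson tolerance


def test_error_free_reads_are_exact_substrings(rng):
    genome_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5_000))
    reads = simulate_reads({"chr1": genome_seq}, 3.0, 120, 0.0, 21)
    rc = revcomp(genome_seq)
    strands = set()
    for _name, seq in reads:
        fwd = seq in genome_seq
        rev = seq in rc
        assert fwd or rev
        strands.add("+" if fwd else "-")
    assert strands == {"+", "-"}  # both strands drawn


def test_empirical_error_rate_within_three_se(rng):
    genome_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 8_000))
    rate = 0.01
    reads = simulate_reads({"chr1": genome_seq}, 30.0, 150, rate, 5)
    rc = revcomp(genome_seq)
    mismatches = bases = 0
    for _n, seq in reads:
        # place the read by an error-free 20-mer anchor (unique in random DNA)
        placed = False
        for ref in (genome_seq, rc):
            for aoff in range(0, len(seq) - 20 + 1, 20):
                idx = ref.find(seq[aoff : aoff + 20])
                if idx >= 0 and 0 <= idx - aoff <= len(ref) - len(seq):
                    ref_seq = ref[idx - aoff : idx - aoff + len(seq)]
                    mismatches += sum(a != b for a, b in zip(seq, ref_seq))
                    bases += len(seq)
                    placed = True
                    break
            if placed:
                break
    assert bases >= 100_000
    se = np.sqrt(rate * (1 - rate) / bases)
    assert abs(mismatches / bases - rate) < 3 * se


def test_read_simulation_contracts(rng):
    genome = {"chr1": "ACGT" * 100}
    with pytest.raises(ValueError, match="coverage"):
        simulate_reads(genome, 0.0, 100, 0.0, 1)
    with pytest.raises(ValueError, match="shortest contig"):
        simulate_reads(genome, 1.0, 500, 0.0, 1)
    with pytest.raises(ValueError, match="empty"):
        simulate_reads({}, 1.0, 100, 0.0, 1)


def test_cohort_truth_reflects_carried_alleles():
    pg = simulate_pangenome(_tiny(pav_probability=0.5, seed=15))
    libs, truth = simulate_cohort(pg, n_libraries=12, error_rate=0.0,
                                  coverage=8.0)
    assert set(truth.columns) == set(pg.truth.target_genes)
    assert len(libs) == 12
    assert truth.values.any() and not truth.values.all()  # segregating
    # re-run is deterministic
    libs2, truth2 = simulate_cohort(pg, n_libraries=12, error_rate=0.0,
                                    coverage=8.0)
    assert truth.equals(truth2)
    assert libs["lib000"] == libs2["lib000"]
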