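"""Synthetic pangenome, gene-cluster and short-read simulation.

The generator emulates the data structure the marker-genotyping pipeline
assumes: a multi-assembly pangenome in which one *source* assembly
carries a tandem cluster of near-identical paralogs (including the
target genes), the other reference assemblies carry varying subsets and
copy numbers of the non-target paralogs (copy number variation within a
configured range), and a resequencing cohort of individuals segregates
for the target genes.  Reads are uniform-coverage, substitution-error
only — sufficient for a pipeline built on exact 80-mer matching.

All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning: child streams are taken in a
fixed documented order (gene family, then per-assembly layout, then
per-library reads), so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import revcomp

BASES = np.array(list("ACGT"))
_SPACER_RANGE = (100, 300)  # bp between tandem cluster genes


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pangenome and its read libraries.

    Defaults reproduce the study conditions the pipeline targets:
    a 30-member pangenome, a tandem cluster whose copy number varies
    between 2 and 8 per assembly, paralogs at ~4% pairwise nucleotide
    divergence (near-identical tandem array), and Illumina-like 150-bp
    reads at 15-fold coverage with 0.5% substitution error.  Genome and
    gene lengths are desk-scale stand-ins for the real chromosomes.
    """

    n_assemblies: int = 30
    background_length: int = 8_000
    n_cluster_genes: int = 8
    n_target_genes: int = 2
    gene_length: int = 1_500
    paralog_divergence: float = 0.04  # pairwise substitution fraction
    pav_probability: float = 0.5
    copy_number_range: tuple[int, int] = (2, 8)
    read_length: int = 150
    coverage: float = 15.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.copy_number_range
        if self.gene_length < 80:
            raise ValueError("gene_length must be >= 80 (no extractable 80mers)")
        if self.background_length < 80 or self.read_length < 80:
            raise ValueError("all lengths must be >= 80")
        for name in ("pav_probability", "error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.paralog_divergence <= 1.0:
            raise ValueError("paralog_divergence must be in [0, 1]")
        if low < 1 or low > high:
            raise ValueError(f"copy_number_range must satisfy 1 <= low <= high, "
                             f"got {self.copy_number_range}")
        if not 1 <= self.n_target_genes <= self.n_cluster_genes:
            raise ValueError("need 1 <= n_target_genes <= n_cluster_genes")
        if not low <= self.n_cluster_genes <= high:
            raise ValueError("n_cluster_genes must lie within copy_number_range "
                             "(the source assembly carries every paralog once)")
        if self.n_assemblies < 1:
            raise ValueError("n_assemblies must be >= 1")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["copy_number_range"] = list(self.copy_number_range)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["copy_number_range"] = tuple(d["copy_number_range"])
        return cls(**d)


@dataclass
class GeneFeature:
    """A gene placement in an assembly (GFF3 semantics: 1-based inclusive)."""

    gene_id: str
    feature_id: str  # unique per assembly (extra copies get .copyN suffix)
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class SimulatedTruth:
    """Ground truth recorded by the generator."""

    pav: pd.DataFrame           # genes x assemblies, boolean presence
    copy_number: pd.Series      # cluster copies per assembly
    source_assembly: str
    target_genes: list[str]


@dataclass
class SimulatedPangenome:
    config: SimulationConfig
    assemblies: dict[str, dict[str, str]]     # assembly -> {contig: seq}
    annotations: dict[str, list[GeneFeature]]
    gene_sequences: dict[str, str]            # paralog id -> 5'->3' sequence
    truth: SimulatedTruth

    @property
    def source_assembly(self) -> str:
        return self.truth.source_assembly


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Independent substitutions at ``rate`` per base (always to a new base)."""
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _assembly_copies(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    target_genes: Sequence[str],
    pav_probability: float,
    copy_range: tuple[int, int],
) -> list[str]:
    """Cluster copies for one non-source assembly.

    Non-target paralogs are present per independent Bernoulli draws;
    the copy count is then brought into ``copy_range`` by adding tandem
    duplicates of present paralogs (or extra paralogs) or by dropping
    random copies.  Target genes are never included: they are private to
    the source assembly among references, which is what makes their
    markers diagnostic.
    """
    low, high = copy_range
    nontarget = [g for g in gene_ids if g not in target_genes]
    copies = [g for g in nontarget if rng.random() < pav_probability]
    while len(copies) < low:
        copies.append(nontarget[rng.integers(0, len(nontarget))])
    while len(copies) > high:
        copies.pop(rng.integers(0, len(copies)))
    return sorted(copies)


def _place_cluster(
    rng: np.random.Generator,
    background: str,
    copies: Sequence[str],
    gene_sequences: dict[str, str],
) -> tuple[str, list[GeneFeature]]:
    """Insert a tandem array of gene copies into the background sequence."""
    pieces: list[str] = []
    features: list[GeneFeature] = []
    insert_at = int(rng.integers(0, len(background) + 1))
    pieces.append(background[:insert_at])
    pos = insert_at
    seen: dict[str, int] = {}
    for gene_id in copies:
        spacer = _random_dna(rng, int(rng.integers(*_SPACER_RANGE)))
        pieces.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = gene_sequences[gene_id]
        placed = seq if strand == "+" else revcomp(seq)
        start = pos + 1  # GFF3 1-based
        end = pos + len(seq)
        seen[gene_id] = seen.get(gene_id, 0) + 1
        feature_id = gene_id if seen[gene_id] == 1 else f"{gene_id}.copy{seen[gene_id]}"
        features.append(GeneFeature(gene_id=gene_id, feature_id=feature_id,
                                    contig="chr1", start=start, end=end,
                                    strand=strand))
        pieces.append(placed)
        pos = end
    pieces.append(background[insert_at:])
    return "".join(pieces), features


def simulate_pangenome(config: SimulationConfig) -> SimulatedPangenome:
    """Generate reference assemblies, annotations and ground truth.

    Assembly ``asm00`` is the marker source: it carries every cluster
    paralog exactly once, including all target genes.  Each other
    assembly carries a copy-number-varying tandem array of non-target
    paralogs only (see :func:`_assembly_copies`).
    """
    root = np.random.SeedSequence(config.seed)
    fam_ss, *asm_ss = root.spawn(1 + config.n_assemblies)
    fam_rng = np.random.default_rng(fam_ss)

    gene_ids = [f"gene{g:02d}" for g in range(config.n_cluster_genes)]
    target_genes = gene_ids[: config.n_target_genes]
    ancestor = _random_dna(fam_rng, config.gene_length)
    # each lineage accumulates d/2 so a random pair differs at ~d
    per_lineage = config.paralog_divergence / 2.0
    gene_sequences = {g: _mutate(fam_rng, ancestor, per_lineage) for g in gene_ids}

    assembly_ids = [f"asm{i:02d}" for i in range(config.n_assemblies)]
    source = assembly_ids[0]
    assemblies: dict[str, dict[str, str]] = {}
    annotations: dict[str, list[GeneFeature]] = {}
    pav = pd.DataFrame(False, index=gene_ids, columns=assembly_ids)
    copy_number = pd.Series(0, index=assembly_ids)

    for asm_id, ss in zip(assembly_ids, asm_ss):
        rng = np.random.default_rng(ss)
        background = _random_dna(rng, config.background_length)
        if asm_id == source:
            copies: list[str] = list(gene_ids)
        else:
            copies = _assembly_copies(rng, gene_ids, target_genes,
                                      config.pav_probability,
                                      config.copy_number_range)
        contig, features = _place_cluster(rng, background, copies, gene_sequences)
        assemblies[asm_id] = {"chr1": contig}
        annotations[asm_id] = features
        pav.loc[sorted(set(copies)), asm_id] = True
        copy_number[asm_id] = len(copies)

    truth = SimulatedTruth(pav=pav, copy_number=copy_number,
                           source_assembly=source, target_genes=target_genes)
    return SimulatedPangenome(config=config, assemblies=assemblies,
                              annotations=annotations,
                              gene_sequences=gene_sequences, truth=truth)


def simulate_reads(
    assembly: dict[str, str],
    coverage: float,
    read_length: int,
    error_rate: float,
    seed,
) -> list[tuple[str, str]]:
    """Uniform-coverage substitution-error reads from an assembly.

    Read starts are uniform over valid positions of both strands; the
    expected read count is ``coverage * genome_length / read_length``
    (drawn Poisson).  Substitutions are i.i.d. per base at ``error_rate``
    and always change the base.  Returns (name, sequence) pairs.

    ``seed`` may be an int, SeedSequence or Generator.
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be > 0, got {coverage}")
    if not assembly or all(len(s) == 0 for s in assembly.values()):
        raise ValueError("empty assembly")
    contigs = [(name, seq) for name, seq in assembly.items()]
    if any(len(seq) < read_length for _, seq in contigs):
        raise ValueError("read_length exceeds the shortest contig")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    genome_length = sum(len(s) for _, s in contigs)
    n_reads = int(rng.poisson(coverage * genome_length / read_length))
    # choose contig proportionally to its number of valid start positions
    starts_per_contig = np.array([len(s) - read_length + 1 for _, s in contigs])
    p = starts_per_contig / starts_per_contig.sum()
    which = rng.choice(len(contigs), size=n_reads, p=p) if n_reads else np.array([], int)
    reads: list[tuple[str, str]] = []
    for r in range(n_reads):
        name, seq = contigs[int(which[r])]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        fragment = seq[start : start + read_length]
        if rng.random() < 0.5:
            fragment = revcomp(fragment)
        if error_rate > 0:
            fragment = _mutate(rng, fragment, error_rate)
        reads.append((f"read{r:07d}/{name}", fragment))
    return reads


def simulate_polishing_libraries(
    pangenome: SimulatedPangenome,
    coverage: float | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """One error-bearing read library per reference assembly.

    These emulate the per-reference Illumina polishing libraries the
    typability filter consumes.  Seeds derive from the config seed with
    a fixed per-assembly offset so the libraries are reproducible and
    independent of the assembly-layout streams.
    """
    cfg = pangenome.config
    cov = cfg.coverage if coverage is None else coverage
    root = np.random.SeedSequence((cfg.seed, 1))  # stream family 1: polishing
    seeds = root.spawn(len(pangenome.assemblies))
    return {
        asm_id: simulate_reads(contigs, cov, cfg.read_length, cfg.error_rate, ss)
        for (asm_id, contigs), ss in zip(pangenome.assemblies.items(), seeds)
    }


def simulate_cohort(
    pangenome: SimulatedPangenome,
    n_libraries: int = 20,
    carrier_probability: float | None = None,
    coverage: float | None = None,
    error_rate: float | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Resequencing cohort segregating for the target genes.

    Each individual genome is a fresh random background into which each
    target gene's source allele is inserted (random position and strand)
    with probability ``carrier_probability`` (default: the config's
    pav_probability).  Returns the read libraries and a library x gene
    boolean truth table of carrier status.
    """
    cfg = pangenome.config
    p = cfg.pav_probability if carrier_probability is None else carrier_probability
    cov = cfg.coverage if coverage is None else coverage
    err = cfg.error_rate if error_rate is None else error_rate
    targets = pangenome.truth.target_genes
    root = np.random.SeedSequence((cfg.seed, 2))  # stream family 2: cohort
    seeds = root.spawn(n_libraries)
    libraries: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        lib_id = f"lib{i:03d}"
        carried = {g: bool(rng.random() < p) for g in targets}
        genome = _random_dna(rng, cfg.background_length)
        copies = [g for g in targets if carried[g]]
        genome, _ = _place_cluster(rng, genome, copies, pangenome.gene_sequences)
        libraries[lib_id] = simulate_reads({"chr1": genome}, cov,
                                           cfg.read_length, err, rng)
        truth_rows.append({"library": lib_id, **carried})
    truth = pd.DataFrame(truth_rows).set_index("library")
    return libraries, truth


# ---------------------------------------------------------------------------
# plain-text writers for the standard formats

def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: Iterable[GeneFeature], path, source: str = "oligotyper") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f"{f.contig}\t{source}\tgene\t{f.start}\t{f.end}\t.\t"
                     f"{f.strand}\t.\tID={f.feature_id};gene_id={f.gene_id}\n")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """4-line FASTQ records; constant placeholder qualities (nothing reads them)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth_tsv(truth: SimulatedTruth, path) -> None:
    """Ground truth as TSV (gene, assembly, present, copy_number)."""
    with open(path, "w") as fh:
        fh.write("gene\tassembly\tpresent\tcopy_number\n")
        for asm in truth.pav.columns:
            for gene in truth.pav.index:
                fh.write(f"{gene}\t{asm}\t{int(truth.pav.loc[gene, asm])}\t"
                         f"{int(truth.copy_number[asm])}\n")
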