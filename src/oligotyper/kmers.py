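"""Extraction of single-copy diagnostic oligomers (80-mers) from genes.

A diagnostic marker is an exact k-bp substring of a target gene whose
canonical form (lexicographic minimum of the sequence and its reverse
complement) occurs exactly once in the source assembly, counting both
strands.  Such markers can be typed by exact matching in unaligned
short-read libraries, which is what the downstream modules do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

DEFAULT_K = 80

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ACGT = frozenset("ACGT")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def canonicalize(oligomer: str) -> str:
    """Return the canonical form: min(sequence, reverse complement).

    Canonical matching makes marker lookup strand-independent, which is
    required because sequencing reads come from either strand.  The
    operation is idempotent.

    Raises
    ------
    ValueError
        If the input contains characters outside {A, C, G, T}.
    """
    if not oligomer or not _ACGT.issuperset(oligomer):
        raise ValueError(
            f"canonicalize requires a non-empty A/C/G/T string, got {oligomer!r}"
        )
    rc = oligomer.translate(_COMPLEMENT)[::-1]
    return oligomer if oligomer <= rc else rc


@dataclass(frozen=True)
class Oligomer:
    """A k-bp marker candidate taken from a gene.

    ``offset`` is the 0-based start of the window within the gene
    sequence (the annotated genomic span, read 5'->3' on the gene
    strand).  ``sequence`` is the as-extracted (gene-strand) window;
    use :func:`canonicalize` for strand-independent identity.
    """

    sequence: str
    gene_id: str = ""
    offset: int = 0

    @property
    def canonical(self) -> str:
        return canonicalize(self.sequence)


@dataclass
class KmerSet:
    """Per-gene collection of single-copy marker oligomers."""

    gene_id: str
    source_assembly: str
    members: list[Oligomer] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def canonical_forms(self) -> set[str]:
        return {m.canonical for m in self.members}


def enumerate_kmers(sequence: str, k: int = DEFAULT_K, gene_id: str = "") -> list[Oligomer]:
    """All k-bp windows of ``sequence`` at offsets 0..len-k.

    Windows containing non-ACGT characters (ambiguity codes such as N)
    are skipped; the number skipped is logged.  A sequence shorter than
    ``k`` yields an empty list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sequence = sequence.upper()
    out: list[Oligomer] = []
    skipped = 0
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if _ACGT.issuperset(window):
            out.append(Oligomer(sequence=window, gene_id=gene_id, offset=i))
        else:
            skipped += 1
    if skipped:
        log.info("enumerate_kmers(%s): skipped %d windows with ambiguity codes",
                 gene_id or "<anon>", skipped)
    return out


def _assembly_contigs(assembly) -> dict[str, str]:
    """Normalize an assembly argument to {contig_id: uppercase sequence}.

    Accepts a mapping of contig -> sequence, or a FASTA path.
    """
    if isinstance(assembly, (str, Path)):
        fa = Fasta(str(assembly), rebuild=True)
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    return {name: str(seq).upper() for name, seq in assembly.items()}


def count_occurrences(candidates: set[str], contigs: Mapping[str, str], k: int) -> dict[str, int]:
    """Occurrence count of each canonical candidate across all contigs.

    Both strands are counted through canonicalization of every k-bp
    assembly window; overlapping occurrences each count.
    """
    counts = dict.fromkeys(candidates, 0)
    for seq in contigs.values():
        rc = revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            rev = rc[n - k - i : n - i]
            canon = fwd if fwd <= rev else rev
            if canon in counts:
                counts[canon] += 1
    return counts


def extract_single_copy(
    gene_id: str,
    gene_sequence: str,
    assembly,
    k: int = DEFAULT_K,
    source_assembly: str = "",
) -> KmerSet:
    """Markers from ``gene_sequence`` occurring exactly once in the assembly.

    ``gene_sequence`` must be the annotated genomic span of the gene as it
    appears in ``assembly`` (reverse-complemented for minus-strand genes);
    every window therefore occurs at least once.  A window whose canonical
    form occurs more than once genome-wide — e.g. shared with a tandem
    paralog or repeated on the opposite strand — is not diagnostic and is
    dropped.

    Parameters
    ----------
    assembly
        FASTA path or mapping of contig id -> sequence.
    """
    contigs = _assembly_contigs(assembly)
    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValueError("empty assembly")
    windows = enumerate_kmers(gene_sequence, k=k, gene_id=gene_id)
    if not windows:
        return KmerSet(gene_id=gene_id, source_assembly=source_assembly)
    candidates = {w.canonical for w in windows}
    counts = count_occurrences(candidates, contigs, k)
    if all(c == 0 for c in counts.values()):
        raise ValueError(
            f"gene {gene_id} not found in assembly: no window occurs in any contig"
        )
    seen: set[str] = set()
    members: list[Oligomer] = []
    for w in windows:
        canon = w.canonical
        if counts[canon] == 1 and canon not in seen:
            seen.add(canon)
            members.append(w)
    return KmerSet(gene_id=gene_id, source_assembly=source_assembly, members=members)


def gene_spans_from_gff(fasta_path, gff_path, gene_ids: Iterable[str]) -> dict[str, str]:
    """Genomic span sequence (5'->3' on the gene strand) per gene ID.

    Reads ``gene`` features from a GFF3 file (1-based inclusive
    coordinates); minus-strand genes are reverse-complemented.
    """
    fa = Fasta(str(fasta_path), rebuild=True)
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    wanted = set(gene_ids)
    out: dict[str, str] = {}
    for feat in db.features_of_type("gene"):
        if feat.id not in wanted:
            continue
        seq = str(fa[feat.seqid][feat.start - 1 : feat.end]).upper()
        if feat.strand == "-":
            seq = revcomp(seq)
        out[feat.id] = seq
    missing = wanted - out.keys()
    if missing:
        raise KeyError(f"gene ids not found in {gff_path}: {sorted(missing)}")
    return out


def write_marker_tsv(kmer_sets: Iterable[KmerSet], path) -> None:
    """Write markers as TSV (gene_id, offset, sequence)."""
    with open(path, "w") as fh:
        fh.write("gene_id\toffset\tsequence\n")
        for ks in kmer_sets:
            for m in ks.members:
                fh.write(f"{ks.gene_id}\t{m.offset}\t{m.sequence}\n")


def read_marker_tsv(path, source_assembly: str = "") -> list[KmerSet]:
    """Read markers written by :func:`write_marker_tsv`, grouped by gene."""
    sets: dict[str, KmerSet] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "offset", "sequence"]:
            raise ValueError(f"unexpected marker TSV header in {path}: {header}")
        for line in fh:
            gene_id, offset, seq = line.rstrip("\n").split("\t")
            ks = sets.setdefault(gene_id, KmerSet(gene_id, source_assembly))
            ks.members.append(Oligomer(sequence=seq, gene_id=gene_id, offset=int(offset)))
    return list(sets.values())
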