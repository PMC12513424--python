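"""Typability filtering of candidate markers against polishing libraries.

A candidate marker is *typable* when it is observed in the source
reference's short-read polishing library within count bounds
(default 1..100) and is absent (count 0) from the polishing library of
every other pangenome reference.  The lower bound guarantees the marker
is recoverable from short reads at all; the upper bound removes
repeat-like sequence; absence elsewhere makes it diagnostic for the
source haplotype.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .kmers import DEFAULT_K, KmerSet, Oligomer, revcomp

log = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 1
DEFAULT_MAX_COUNT = 100


@dataclass
class MarkerCountTable:
    """Exact-match occurrence counts of canonical markers in one library.

    Absent keys mean count 0; ``get`` reflects that.
    """

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_reads: int = 0
    n_short_reads: int = 0  # reads shorter than k, skipped

    def get(self, canonical: str) -> int:
        return self.counts.get(canonical, 0)


@dataclass
class TypableMarkerPanel:
    """Markers surviving the source-presence/other-absence filter, per gene."""

    markers: dict[str, list[Oligomer]]  # gene_id -> surviving oligomers
    min_count: int = DEFAULT_MIN_COUNT
    max_count: int = DEFAULT_MAX_COUNT
    source_library: str = ""
    other_libraries: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.markers)

    def n_typable(self, gene_id: str) -> int:
        return len(self.markers.get(gene_id, []))

    def total(self) -> int:
        return sum(len(v) for v in self.markers.values())

    def canonical_by_gene(self) -> dict[str, set[str]]:
        return {g: {m.canonical for m in ms} for g, ms in self.markers.items()}


def iter_fastq(reads) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ source.

    Accepts a path to a FASTQ/FASTQ.gz file, or any iterable of
    sequences / (name, sequence) pairs (convenient for in-memory reads).
    Malformed 4-line records raise ValueError naming the record index.
    """
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        _validate_fastq_structure(path)
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                yield entry.name, entry.sequence
        return
    for item in reads:
        if isinstance(item, str):
            yield "", item
        else:
            name, seq = item
            yield name, seq


def _validate_fastq_structure(path: Path) -> None:
    """Light structural FASTQ check producing record-indexed errors."""
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if header.strip() == "":
                continue
            lines = [header] + [fh.readline() for _ in range(3)]
            if not lines[0].startswith("@") or not lines[2].startswith("+"):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            if "" in lines[1:]:
                raise ValueError(f"truncated FASTQ record at index {idx} in {path}")
            if len(lines[1].strip()) != len(lines[3].strip()):
                raise ValueError(
                    f"sequence/quality length mismatch at record {idx} in {path}"
                )
            idx += 1


def count_in_library(
    markers: Iterable[str] | set[str],
    reads,
    library_id: str = "",
    k: int = DEFAULT_K,
) -> MarkerCountTable:
    """Count exact canonical matches of markers across all read windows.

    Every k-bp window of every read is canonicalized and looked up in the
    marker set; each occurrence counts (a marker appearing twice in one
    read counts 2).  The result is independent of read order and of read
    strand.  Reads shorter than k are skipped and tallied.

    Parameters
    ----------
    markers
        Canonical marker sequences (use ``Oligomer.canonical``).
    reads
        FASTQ(.gz) path or iterable of sequences / (name, seq) pairs.
    """
    marker_set = set(markers)
    counts: dict[str, int] = {}
    n_reads = 0
    n_short = 0
    for _name, seq in iter_fastq(reads):
        n_reads += 1
        seq = seq.upper()
        n = len(seq)
        if n < k:
            n_short += 1
            continue
        rc = revcomp(seq)
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            rev = rc[n - k - i : n - i]
            canon = fwd if fwd <= rev else rev
            if canon in marker_set:
                counts[canon] = counts.get(canon, 0) + 1
    if n_short:
        log.info("count_in_library(%s): skipped %d reads shorter than %d bp",
                 library_id, n_short, k)
    return MarkerCountTable(library_id=library_id, counts=counts,
                            n_reads=n_reads, n_short_reads=n_short)


def filter_typable(
    kmer_sets: Iterable[KmerSet],
    source_counts: MarkerCountTable,
    other_counts: Iterable[MarkerCountTable],
    min_count: int = DEFAULT_MIN_COUNT,
    max_count: int = DEFAULT_MAX_COUNT,
) -> TypableMarkerPanel:
    """Retain markers with source count in [min_count, max_count] and 0 elsewhere.

    Gene grouping of the input ``kmer_sets`` is preserved.  An empty
    source table produces an empty panel with a warning.
    """
    others = list(other_counts)
    if not source_counts.counts:
        log.warning("filter_typable: source library %r has no marker matches; "
                    "panel is empty", source_counts.library_id)
    panel: dict[str, list[Oligomer]] = {}
    for ks in kmer_sets:
        kept: list[Oligomer] = []
        for m in ks.members:
            canon = m.canonical
            c = source_counts.get(canon)
            if c < min_count or c > max_count:
                continue
            if any(o.get(canon) > 0 for o in others):
                continue
            kept.append(m)
        panel[ks.gene_id] = kept
    return TypableMarkerPanel(
        markers=panel,
        min_count=min_count,
        max_count=max_count,
        source_library=source_counts.library_id,
        other_libraries=tuple(o.library_id for o in others),
    )


def write_counts_tsv(tables: Iterable[MarkerCountTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tlibrary\tcount\n")
        for t in tables:
            for marker, count in sorted(t.counts.items()):
                fh.write(f"{marker}\t{t.library_id}\t{count}\n")


def write_panel_tsv(panel: TypableMarkerPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# min_count={panel.min_count}\tmax_count={panel.max_count}\t"
                 f"source={panel.source_library}\n")
        fh.write("gene_id\toffset\tsequence\n")
        for gene_id, members in panel.markers.items():
            for m in members:
                fh.write(f"{gene_id}\t{m.offset}\t{m.sequence}\n")


def read_panel_tsv(path) -> TypableMarkerPanel:
    markers: dict[str, list[Oligomer]] = {}
    params = {"min_count": DEFAULT_MIN_COUNT, "max_count": DEFAULT_MAX_COUNT,
              "source": ""}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].strip().split("\t"):
                key, _, value = token.partition("=")
                if key in ("min_count", "max_count"):
                    params[key] = int(value)
                elif key == "source":
                    params[key] = value
            header = fh.readline()
        else:
            header = first
        if header.rstrip("\n").split("\t") != ["gene_id", "offset", "sequence"]:
            raise ValueError(f"unexpected panel TSV header in {path}")
        for line in fh:
            gene_id, offset, seq = line.rstrip("\n").split("\t")
            markers.setdefault(gene_id, []).append(
                Oligomer(sequence=seq, gene_id=gene_id, offset=int(offset)))
    return TypableMarkerPanel(markers=markers, min_count=params["min_count"],
                              max_count=params["max_count"],
                              source_library=params["source"])
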