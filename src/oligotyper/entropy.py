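"""Per-column Shannon entropy of protein alignments, stratified by clade.

Phylogenetic clades of a gene-family alignment are treated as allelic
series; per-column entropy (bits) within each clade separates invariant
residues (H = 0) from highly variable ones.  Columns with entropy above
a threshold (default 1.5 bits) are counted per clade, and pairwise
percent identity between named sequences is reported over columns where
at least one of the pair has a residue.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

GAP = "-"
HIGH_ENTROPY_THRESHOLD = 1.5  # bits


def load_alignment(source) -> dict[str, str]:
    """Aligned FASTA (or mapping) -> {sequence_id: aligned residues}.

    All rows must have equal length and there must be at least two.
    """
    if isinstance(source, (str, Path)):
        aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}
    else:
        aln = {k: v.upper() for k, v in source.items()}
    if len(aln) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    return aln


def load_clades(source) -> dict[str, str]:
    """Clade TSV (sequence_id, clade) or mapping -> {sequence_id: clade}."""
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype=str)
        cols = list(df.columns[:2])
        return dict(zip(df[cols[0]], df[cols[1]]))
    return dict(source)


def column_entropy(column) -> float:
    """Shannon entropy H = -sum p log2 p of residue frequencies in a column.

    Gaps are excluded from the frequencies; a column that is all gaps has
    no residue distribution and returns NaN (never 0, which would mean
    "invariant").
    """
    counts = Counter(r for r in column if r != GAP)
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    p = np.array(list(counts.values()), dtype=float) / total
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids -0.0 output


def profile(alignment, clades) -> dict[str, np.ndarray]:
    """Per-clade vector of per-column entropies (bits) over the alignment.

    Clades with fewer than two members are skipped with a warning.
    Columns all-gap within a clade are NaN for that clade.
    """
    aln = load_alignment(alignment)
    assignment = load_clades(clades)
    missing = set(assignment) - set(aln)
    if missing:
        raise KeyError(f"clade table names sequences absent from the alignment: "
                       f"{sorted(missing)}")
    ncol = len(next(iter(aln.values())))
    members: dict[str, list[str]] = {}
    for seq_id, clade in assignment.items():
        members.setdefault(clade, []).append(seq_id)
    out: dict[str, np.ndarray] = {}
    for clade, ids in sorted(members.items()):
        if len(ids) < 2:
            log.warning("clade %s has %d member(s) (<2): skipped", clade, len(ids))
            continue
        rows = [aln[i] for i in ids]
        out[clade] = np.array(
            [column_entropy([row[j] for row in rows]) for j in range(ncol)]
        )
    return out


def count_high_entropy(
    profiles: Mapping[str, np.ndarray],
    threshold: float = HIGH_ENTROPY_THRESHOLD,
) -> dict[str, int]:
    """Number of columns strictly above ``threshold`` bits, per clade.

    NaN columns (all-gap within the clade) are never counted.
    """
    out = {}
    for clade, values in profiles.items():
        v = np.asarray(values, dtype=float)
        out[clade] = int(np.sum(v[~np.isnan(v)] > threshold))
    return out


def pairwise_identity(id_a: str, id_b: str, alignment) -> tuple[int, int, float]:
    """(matches, compared, percent) identity between two aligned sequences.

    matches: columns where both have the same non-gap residue.
    compared: columns where at least one of the two has a residue
    (columns gapped in both are ignored).  percent = 100 * matches /
    compared, rounded to one decimal.
    """
    aln = load_alignment(alignment)
    if id_a == id_b:
        log.warning("pairwise_identity called with the same id twice (%s)", id_a)
    a, b = aln[id_a], aln[id_b]
    matches = compared = 0
    for ra, rb in zip(a, b):
        if ra == GAP and rb == GAP:
            continue
        compared += 1
        if ra == rb and ra != GAP:
            matches += 1
    if compared == 0:
        raise ValueError(f"no comparable columns between {id_a} and {id_b}")
    percent = round(100.0 * matches / compared, 1)
    return matches, compared, percent


def max_entropy(n_symbols: int = 20) -> float:
    """Upper bound log2(alphabet size) for a column, in bits."""
    return math.log2(n_symbols)


def profile_to_frame(profiles: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Long-format table (column, clade, entropy); column index is 1-based."""
    rows = []
    for clade, values in profiles.items():
        for j, h in enumerate(values, start=1):
            rows.append({"column": j, "clade": clade, "entropy": h})
    return pd.DataFrame(rows, columns=["column", "clade", "entropy"])
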