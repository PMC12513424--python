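"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions (sliding windows,
string scanning, frequency tables) without reusing the package's
internals, so agreement is a genuine cross-check.
"""

import math
from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def naive_canonical(s: str) -> str:
    rc = naive_revcomp(s)
    return s if s < rc else rc


def naive_windows(seq: str, k: int) -> list[tuple[int, str]]:
    """All (offset, window) pairs with pure-ACGT windows."""
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            out.append((i, w))
    return out


def naive_count_occurrences(pattern: str, text: str) -> int:
    """Overlapping occurrences of pattern in text (single strand)."""
    count = 0
    start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def naive_genome_count(kmer: str, contigs: dict[str, str]) -> int:
    """Occurrences of kmer on both strands of every contig."""
    total = 0
    rc = naive_revcomp(kmer)
    for seq in contigs.values():
        total += naive_count_occurrences(kmer, seq)
        if rc != kmer:
            total += naive_count_occurrences(rc, seq)
    return total


def naive_single_copy(gene_seq: str, contigs: dict[str, str], k: int) -> list[tuple[int, str]]:
    """Windows of gene_seq occurring exactly once genome-wide (both strands)."""
    kept = []
    seen = set()
    for off, w in naive_windows(gene_seq, k):
        canon = naive_canonical(w)
        if canon in seen:
            continue
        seen.add(canon)
        if naive_genome_count(w, contigs) == 1:
            kept.append((off, w))
    return kept


def naive_read_counts(markers: set[str], reads: list[str], k: int) -> dict[str, int]:
    """Per-occurrence counts of canonical markers across reads (both strands)."""
    counts = {m: 0 for m in markers}
    for _m in markers:
        assert naive_canonical(_m) == _m, "markers must be canonical"
    for read in reads:
        if len(read) < k:
            continue
        for _i, w in naive_windows(read.upper(), k):
            canon = naive_canonical(w)
            if canon in counts:
                counts[canon] += 1
        # windows with N never match ACGT-only markers, matching the package
    return {m: c for m, c in counts.items() if c}


def naive_typable(
    gene_markers: dict[str, list[tuple[int, str]]],
    source_counts: dict[str, int],
    other_counts: list[dict[str, int]],
    min_count: int,
    max_count: int,
) -> dict[str, list[tuple[int, str]]]:
    out = {}
    for gene, markers in gene_markers.items():
        kept = []
        for off, w in markers:
            canon = naive_canonical(w)
            c = source_counts.get(canon, 0)
            if min_count <= c <= max_count and all(
                o.get(canon, 0) == 0 for o in other_counts
            ):
                kept.append((off, w))
        out[gene] = kept
    return out


def naive_presence_calls(
    panel: dict[str, list[tuple[int, str]]],
    reads: list[str],
    k: int,
    threshold: float,
) -> dict[str, tuple[float, bool]]:
    all_markers = {naive_canonical(w) for ms in panel.values() for _o, w in ms}
    counts = naive_read_counts(all_markers, reads, k)
    out = {}
    for gene, markers in panel.items():
        n_obs = sum(1 for _o, w in markers if counts.get(naive_canonical(w), 0) >= 1)
        frac = n_obs / len(markers) if markers else float("nan")
        out[gene] = (frac, frac > threshold)
    return out


def naive_column_entropy(column: str) -> float:
    """Shannon entropy in bits over non-gap residues; NaN if all gaps."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return float("nan")
    freqs = Counter(residues)
    n = len(residues)
    return -sum((c / n) * math.log2(c / n) for c in freqs.values())
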