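"""Presence/absence genotyping of read libraries by typable-marker recovery.

A gene is called *present* in a library when strictly more than a
threshold fraction (default 95%) of its typable markers are observed at
least once by exact canonical matching in the library's reads.  A gene
with no typable markers is *untypable* (never "absent").  The joint
haplotype call (``joint_present``) is the AND over all typable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .kmers import DEFAULT_K
from .typability import MarkerCountTable, TypableMarkerPanel, count_in_library

log = logging.getLogger(__name__)

DEFAULT_PRESENCE_THRESHOLD = 0.95


@dataclass
class GeneCall:
    gene_id: str
    n_typable: int
    n_observed: int

    @property
    def fraction_observed(self) -> float:
        return self.n_observed / self.n_typable if self.n_typable else float("nan")

    def present(self, threshold: float) -> bool | None:
        """True/False call, or None for an untypable gene."""
        if self.n_typable == 0:
            return None
        return self.fraction_observed > threshold


@dataclass
class LibraryGenotype:
    library_id: str
    threshold: float
    calls: dict[str, GeneCall] = field(default_factory=dict)

    @property
    def joint_present(self) -> bool | None:
        """AND of presence over all genes; None if any gene is untypable."""
        states = [c.present(self.threshold) for c in self.calls.values()]
        if any(s is None for s in states):
            return None
        return all(states)

    def fraction(self, gene_id: str) -> float:
        return self.calls[gene_id].fraction_observed


def genotype_library(
    panel: TypableMarkerPanel,
    reads,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    library_id: str = "",
    k: int = DEFAULT_K,
    counts: MarkerCountTable | None = None,
) -> LibraryGenotype:
    """Genotype one read library against a typable marker panel.

    Per gene, ``n_observed`` is the number of panel markers matched at
    least once (marker multiplicity beyond one does not affect the
    call); presence requires fraction_observed strictly above
    ``threshold``.

    Parameters
    ----------
    counts
        Precomputed count table for this library (skips re-scanning).
    """
    by_gene = panel.canonical_by_gene()
    if counts is None:
        universe = set().union(*by_gene.values()) if by_gene else set()
        counts = count_in_library(universe, reads, library_id=library_id, k=k)
    geno = LibraryGenotype(library_id=library_id, threshold=threshold)
    for gene_id, canon_set in by_gene.items():
        n_obs = sum(1 for c in canon_set if counts.get(c) >= 1)
        geno.calls[gene_id] = GeneCall(gene_id, n_typable=len(canon_set),
                                       n_observed=n_obs)
        if not canon_set:
            log.warning("gene %s has no typable markers: call is untypable",
                        gene_id)
    return geno


@dataclass
class GenotypeMatrix:
    """Cohort genotype table plus threshold provenance and diagnostics."""

    table: pd.DataFrame  # library, gene, n_typable, n_observed, fraction, call
    threshold: float
    missing_libraries: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        calls = self.table.pivot(index="library", columns="gene", values="call")
        joint = (calls == "present").all(axis=1) & ~(calls == "untypable").any(axis=1)
        return {
            "threshold": self.threshold,
            "n_libraries": int(self.table["library"].nunique()),
            "n_missing_libraries": len(self.missing_libraries),
            "joint_present_count": int(joint.sum()),
            "present_count_per_gene": {
                g: int((grp["call"] == "present").sum())
                for g, grp in self.table.groupby("gene")
            },
        }

    def fraction_histogram(self, bins: int = 20) -> pd.DataFrame:
        """Per-gene histogram of fraction_observed (threshold diagnostics)."""
        edges = np.linspace(0.0, 1.0, bins + 1)
        rows = []
        for gene, grp in self.table.groupby("gene"):
            hist, _ = np.histogram(grp["fraction"].fillna(0.0), bins=edges)
            for lo, hi, n in zip(edges[:-1], edges[1:], hist):
                rows.append({"gene": gene, "bin_low": lo, "bin_high": hi,
                             "n_libraries": int(n)})
        return pd.DataFrame(rows)


def _call_label(present: bool | None) -> str:
    if present is None:
        return "untypable"
    return "present" if present else "absent"


def genotype_cohort(
    panel: TypableMarkerPanel,
    libraries: Mapping[str, object] | Iterable[tuple[str, object]],
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    k: int = DEFAULT_K,
) -> GenotypeMatrix:
    """Genotype a cohort of read libraries.

    Parameters
    ----------
    libraries
        Mapping (or pairs) of library_id -> reads, where reads is a
        FASTQ(.gz) path or an in-memory read iterable.  Unreadable
        libraries are recorded as missing and excluded.
    """
    items = libraries.items() if isinstance(libraries, Mapping) else libraries
    rows = []
    missing: list[str] = []
    for library_id, reads in items:
        try:
            geno = genotype_library(panel, reads, threshold=threshold,
                                    library_id=library_id, k=k)
        except (OSError, ValueError) as exc:
            log.error("library %s unreadable, excluded: %s", library_id, exc)
            missing.append(library_id)
            continue
        for gene_id, call in geno.calls.items():
            rows.append({
                "library": library_id,
                "gene": gene_id,
                "n_typable": call.n_typable,
                "n_observed": call.n_observed,
                "fraction": call.fraction_observed,
                "call": _call_label(call.present(threshold)),
            })
    table = pd.DataFrame(rows, columns=["library", "gene", "n_typable",
                                        "n_observed", "fraction", "call"])
    return GenotypeMatrix(table=table, threshold=threshold,
                          missing_libraries=missing)


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# presence_threshold={matrix.threshold}\n")
        matrix.table.to_csv(fh, sep="\t", index=False)
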