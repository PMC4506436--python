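"""ChIP-Seq peak → target-gene assignment.

A peak is assigned to every gene whose windowed transcript interval it
overlaps by at least one base.  The window extends a fixed distance
upstream of the transcription start and a (typically shorter) distance
past the transcription end, mirrored for minus-strand genes:

* ``+`` strand: ``[tx_start - upstream, tx_end + downstream)``
* ``-`` strand: ``[tx_start - downstream, tx_end + upstream)``

All coordinates are 0-based half-open (BED convention).  Peaks falling in
no gene's window are left unassigned (counted, not rescued to a nearest
gene).  Assignments from multiple transcripts of the same gene are
unioned, and the result is invariant to peak input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = ["Peak", "GeneModel", "assign_peaks", "peaks_to_gene_sets"]


@dataclass(frozen=True)
class Peak:
    """A genomic interval, 0-based half-open; ``name`` typically carries
    the ChIP experiment identifier."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"malformed peak {self.name or ''} "
                f"{self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A transcript model (refFlat subset): span and strand only."""

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_name}: strand must be + or -")
        if self.tx_start < 0 or self.tx_start >= self.tx_end:
            raise ValueError(
                f"malformed transcript {self.gene_name} "
                f"{self.chrom}:{self.tx_start}-{self.tx_end}"
            )

    def window(self, upstream: int, downstream: int) -> tuple[int, int]:
        """Promoter-extended interval, strand-aware, clipped at zero."""
        if self.strand == "+":
            lo, hi = self.tx_start - upstream, self.tx_end + downstream
        else:
            lo, hi = self.tx_start - downstream, self.tx_end + upstream
        return max(lo, 0), hi


def assign_peaks(
    peaks: Iterable[Peak],
    genes: Iterable[GeneModel],
    upstream: int = 5000,
    downstream: int = 1000,
) -> tuple[list[set[str]], int]:
    """Assign each peak to the genes whose windows it overlaps.

    Returns (per-peak gene sets, in input order; number of unassigned
    peaks).  ``upstream``/``downstream`` are the promoter window sizes in
    bp relative to gene orientation.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be nonnegative")
    peaks = list(peaks)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        lo, hi = g.window(upstream, downstream)
        by_chrom.setdefault(g.chrom, []).append((lo, hi, g.gene_name))
    assignments: list[set[str]] = []
    n_unassigned = 0
    for p in peaks:
        hits = {
            name
            for lo, hi, name in by_chrom.get(p.chrom, ())
            if p.start < hi and lo < p.end
        }
        if not hits:
            n_unassigned += 1
        assignments.append(hits)
    if n_unassigned:
        log.info("%d of %d peaks fell outside every gene window",
                 n_unassigned, len(peaks))
    return assignments, n_unassigned


def peaks_to_gene_sets(
    peaks: Iterable[Peak],
    genes: Iterable[GeneModel],
    upstream: int = 5000,
    downstream: int = 1000,
    default_experiment: str = "peaks",
) -> Mapping[str, set[str]]:
    """Build experiment → target-gene sets from named peaks.

    Peaks sharing a BED name column belong to one ChIP experiment;
    unnamed peaks are pooled under ``default_experiment``.  The returned
    gene sets are deduplicated unions over that experiment's peaks, ready
    to be written as GMT for the enrichment stage.
    """
    peaks = list(peaks)
    per_peak, _ = assign_peaks(peaks, genes, upstream, downstream)
    out: dict[str, set[str]] = {}
    for p, hits in zip(peaks, per_peak):
        exp = p.name or default_experiment
        out.setdefault(exp, set()).update(hits)
    empty = [exp for exp, genes_ in out.items() if not genes_]
    if empty:
        log.info("%d experiments had no assigned genes and were dropped",
                 len(empty))
    return {exp: genes_ for exp, genes_ in out.items() if genes_}
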