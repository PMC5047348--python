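"""Iterative mutational hotspot detection.

A hotspot is a genomic window of at most ``L`` bp (default 100)
concentrating recurrent mutations of one gene. Detection is iterative:
each round extracts the window with the most mutations, removes those
mutations, and repeats until every remaining site carries fewer than two
mutations. If the hotspots jointly capture at least ``min_fraction``
(default 80%) of the gene's protein-affecting mutations, the gene is
represented by its hotspots; otherwise its complete exome is used.

Windows are evaluated in genomic coordinates, ignoring exon boundaries;
indels count at their start position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from oncopanel.cohort_io import GeneModel, MutationRecord
from oncopanel.errors import MissingModelError

DEFAULT_MAX_HOTSPOT_BP = 100
DEFAULT_MIN_CAPTURED_FRACTION = 0.8


@dataclass(frozen=True, slots=True)
class Hotspot:
    """A <=L-bp window of recurrent mutations, shrunk to its minimal span.

    ``start``/``end`` are 1-based inclusive and coincide with mutated
    positions; ``iteration`` records discovery order (0-based).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    n_mutations: int
    iteration: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneRepresentation:
    """How one gene enters a panel: as hotspots or as its whole exome."""

    gene_id: str
    mode: str  # "hotspots" | "whole_exome"
    hotspots: list[Hotspot] = field(default_factory=list)
    captured_fraction: float = 0.0
    n_pams: int = 0


def best_window(
    site_counts: Mapping[int, int], L: int = DEFAULT_MAX_HOTSPOT_BP
) -> tuple[int, int, int]:
    """Return the (start, end, n_mutations) window of width <= L with the
    most mutations, shrunk to the minimal span containing them.

    Ties are broken by smaller span, then smaller start coordinate.
    """
    if not site_counts:
        raise ValueError("site_counts must be non-empty")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    positions = sorted(site_counts)
    counts = [site_counts[p] for p in positions]
    n = len(positions)

    best: tuple[int, int, int] | None = None  # (count, -span, -start) maximized
    best_bounds = (positions[0], positions[0], counts[0])
    j = 0
    total = 0
    for i in range(n):
        if j < i:
            j = i
            total = 0
        # extend window while width (end - start + 1) stays within L
        while j < n and positions[j] - positions[i] + 1 <= L:
            total += counts[j]
            j += 1
        # window covers sites i..j-1; minimal span is [positions[i], positions[j-1]]
        span = positions[j - 1] - positions[i] + 1
        key = (total, -span, -positions[i])
        if best is None or key > best:
            best = key
            best_bounds = (positions[i], positions[j - 1], total)
        total -= counts[i]
    return best_bounds


def find_hotspots(
    gene_mutations: Sequence[MutationRecord], L: int = DEFAULT_MAX_HOTSPOT_BP
) -> list[Hotspot]:
    """Iteratively extract hotspots from one gene's protein-affecting
    mutations until every remaining site has fewer than two mutations."""
    if not gene_mutations:
        return []
    gene_ids = {m.gene_id for m in gene_mutations}
    if len(gene_ids) > 1:
        raise ValueError(f"mutations span multiple genes: {sorted(gene_ids)}")
    gene_id = next(iter(gene_ids))
    chroms = {m.chrom for m in gene_mutations}
    if len(chroms) > 1:
        raise ValueError(f"gene {gene_id!r}: mutations on multiple chromosomes")
    chrom = next(iter(chroms))

    site_counts: dict[int, int] = {}
    for m in gene_mutations:
        site_counts[m.pos] = site_counts.get(m.pos, 0) + 1

    hotspots: list[Hotspot] = []
    iteration = 0
    while any(c >= 2 for c in site_counts.values()):
        start, end, n = best_window(site_counts, L)
        hotspots.append(
            Hotspot(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                n_mutations=n,
                iteration=iteration,
            )
        )
        for pos in [p for p in site_counts if start <= p <= end]:
            del site_counts[pos]
        iteration += 1
    return hotspots


def represent_gene(
    gene_mutations: Sequence[MutationRecord],
    model: GeneModel | None,
    L: int = DEFAULT_MAX_HOTSPOT_BP,
    min_fraction: float = DEFAULT_MIN_CAPTURED_FRACTION,
) -> GeneRepresentation:
    """Decide hotspot vs whole-exome representation for one gene.

    The gene is represented by its hotspots iff they jointly capture at
    least *min_fraction* of its protein-affecting mutations; otherwise
    the complete exome is used (requiring a gene model).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if not gene_mutations:
        raise ValueError("represent_gene requires at least one mutation")
    gene_id = gene_mutations[0].gene_id
    hotspots = find_hotspots(gene_mutations, L=L)
    n_pams = len(gene_mutations)
    captured = sum(h.n_mutations for h in hotspots)
    fraction = captured / n_pams
    if hotspots and fraction >= min_fraction:
        return GeneRepresentation(
            gene_id=gene_id,
            mode="hotspots",
            hotspots=hotspots,
            captured_fraction=fraction,
            n_pams=n_pams,
        )
    if model is None:
        raise MissingModelError(gene_id)
    return GeneRepresentation(
        gene_id=gene_id,
        mode="whole_exome",
        hotspots=[],
        captured_fraction=fraction,
        n_pams=n_pams,
    )
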