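"""Greedy coverage ranking, tier classification and panel assembly.

The panel is assembled by greedy maximum marginal coverage: at each rank
the candidate item (gene or hotspot) covering the most not-yet-covered
samples is selected, and the cumulative mutational frequency (CMF) is

    cmf_n = cmf_{n-1} + |new samples covered by item_n| / |cohort samples|

Items are then split into three tiers by comparing each item's marginal
coverage gain with the slope of the regression line fitted to the CMF
curve: Tier 1 items gain at least the slope (2x the slope under the
stringent option), Tier 2 items gain less but more than zero, and Tier 3
items add nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from oncopanel.cohort_io import Cohort, GeneList, GeneModel, MutationRecord
from oncopanel.errors import ConfigError, EmptyPanelError
from oncopanel.hotspots import (
    DEFAULT_MAX_HOTSPOT_BP,
    DEFAULT_MIN_CAPTURED_FRACTION,
    GeneRepresentation,
    represent_gene,
)


@dataclass
class PanelItem:
    """One unit of panel content: a whole-gene exome or a single hotspot.

    ``intervals`` are 0-based half-open genomic intervals; ``covered_samples``
    are the cohort samples with at least one protein-affecting mutation
    inside them.
    """

    item_id: str
    gene_id: str
    kind: str  # "whole_gene" | "hotspot"
    intervals: list[tuple[str, int, int]]
    covered_samples: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in ("whole_gene", "hotspot"):
            raise ValueError(f"bad item kind {self.kind!r}")
        if self.length_bp <= 0:
            raise ValueError(f"{self.item_id}: zero-length item")
        self.covered_samples = frozenset(self.covered_samples)

    @property
    def length_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)


@dataclass
class RankedItem:
    item: PanelItem
    rank: int
    marginal_new_samples: int
    cmf: float
    tier: int = 0


@dataclass
class PanelDesign:
    """A greedy-ordered panel with coverage and size accounting."""

    cohort_name: str
    n_samples: int
    items: list[RankedItem]
    coverage_k1: float = 0.0
    coverage_k2: float = 0.0
    coverage_k3: float = 0.0
    representations: dict[str, GeneRepresentation] = field(default_factory=dict)

    @property
    def total_kbps(self) -> float:
        return sum(r.item.length_bp for r in self.items) / 1000.0

    def restrict_to_tiers(self, tiers: set[int]) -> "PanelDesign":
        """Sub-panel keeping only items in the given tiers (order kept)."""
        kept = [r for r in self.items if r.tier in tiers]
        sub = PanelDesign(
            cohort_name=self.cohort_name,
            n_samples=self.n_samples,
            items=kept,
            representations=self.representations,
        )
        sub.coverage_k1 = sum(r.marginal_new_samples for r in kept) / self.n_samples
        return sub


@dataclass
class PanelConfig:
    """Tunable knobs of the design pipeline."""

    use_hotspots: bool = True
    max_hotspot_bp: int = DEFAULT_MAX_HOTSPOT_BP
    min_captured_fraction: float = DEFAULT_MIN_CAPTURED_FRACTION
    stringent: bool = False
    tier1_slope_multiplier: float = 1.0
    stringent_slope_multiplier: float = 2.0
    flank_bp: int = 0


# ---------------------------------------------------------------------------
# greedy ranking
# ---------------------------------------------------------------------------


def greedy_rank(items: Sequence[PanelItem], cohort: Cohort) -> list[RankedItem]:
    """Order items by greedy maximum marginal sample coverage.

    Ties are broken by larger total ``covered_samples``, then
    lexicographic ``item_id``. Items with zero marginal gain are
    appended (in tie-break order) with the CMF unchanged.
    """
    if not items:
        raise ValueError("greedy_rank requires at least one item")
    if cohort.n_samples == 0:
        raise ConfigError("cohort has zero samples; CMF denominator undefined")
    n_samples = cohort.n_samples

    remaining = list(items)
    covered: set[str] = set()
    ranked: list[RankedItem] = []
    while remaining:
        best = max(
            remaining,
            key=lambda it: (
                len(it.covered_samples - covered),
                len(it.covered_samples),
                _neg_lex(it.item_id),
            ),
        )
        new = best.covered_samples - covered
        covered |= new
        # integer cumulative count keeps the final CMF bit-exact vs coverage_k
        ranked.append(
            RankedItem(
                item=best,
                rank=len(ranked) + 1,
                marginal_new_samples=len(new),
                cmf=len(covered) / n_samples,
            )
        )
        remaining.remove(best)
    return ranked


class _neg_lex(str):
    """String wrapper that inverts comparison, so max() prefers the
    lexicographically smallest item_id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# tier classification
# ---------------------------------------------------------------------------


def cmf_slope(ranked: Sequence[RankedItem]) -> float:
    """Slope of the least-squares line through the CMF curve.

    Fit over (rank, cmf) of positive-gain items, anchored at the origin
    (rank 0, cmf 0) where the curve starts. With fewer than two
    positive-gain items the fit is degenerate and the slope is 0.
    """
    positive = [r for r in ranked if r.marginal_new_samples > 0]
    if len(positive) < 2:
        return 0.0
    x = np.array([0.0] + [r.rank for r in positive])
    y = np.array([0.0] + [r.cmf for r in positive])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def assign_tiers(
    ranked: Sequence[RankedItem],
    stringent: bool = False,
    n_samples: int | None = None,
    slope_multiplier: float | None = None,
) -> list[RankedItem]:
    """Set the tier of each ranked item in place and return the list.

    Tier 1: marginal gain fraction >= threshold (slope of the CMF
    regression line, doubled when *stringent*). Tier 2: positive gain
    below the threshold. Tier 3: zero gain.
    """
    ranked = list(ranked)
    if not ranked:
        return ranked
    if n_samples is None:
        # recover the denominator from any positive-gain item
        n_samples = _infer_n_samples(ranked)
    positive = [r for r in ranked if r.marginal_new_samples > 0]
    slope = cmf_slope(ranked)
    if slope_multiplier is None:
        slope_multiplier = 2.0 if stringent else 1.0
    threshold = slope * slope_multiplier
    for r in ranked:
        if r.marginal_new_samples == 0:
            r.tier = 3
        elif len(positive) < 2:
            r.tier = 1  # degenerate fit: every contributing item is Tier 1
        else:
            gain = r.marginal_new_samples / n_samples
            # float-tolerant >=: a gain equal to the threshold is Tier 1
            at_least = gain > threshold or math.isclose(
                gain, threshold, rel_tol=1e-9, abs_tol=1e-12
            )
            r.tier = 1 if at_least else 2
    _assert_tier_contiguity(ranked)
    return ranked


def _infer_n_samples(ranked: Sequence[RankedItem]) -> int:
    prev = 0.0
    for r in ranked:
        if r.marginal_new_samples > 0:
            return round(r.marginal_new_samples / (r.cmf - prev))
        prev = r.cmf
    return 1


def _assert_tier_contiguity(ranked: Sequence[RankedItem]) -> None:
    # greedy monotonicity guarantees no Tier-1 item after a Tier-2 item
    seen_tier2 = False
    for r in ranked:
        if r.tier == 2:
            seen_tier2 = True
        elif r.tier == 1 and seen_tier2:
            raise AssertionError("tier contiguity violated: Tier 1 after Tier 2")


# ---------------------------------------------------------------------------
# k-mutation coverage
# ---------------------------------------------------------------------------


def coverage_k(panel_items: Sequence[PanelItem], cohort: Cohort, k: int) -> float:
    """Fraction of cohort samples with PAMs in at least *k* distinct items."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if cohort.n_samples == 0:
        raise ConfigError("cohort has zero samples")
    hits: dict[str, int] = {}
    for item in panel_items:
        for sample in item.covered_samples:
            hits[sample] = hits.get(sample, 0) + 1
    n_hit = sum(1 for count in hits.values() if count >= k)
    return n_hit / cohort.n_samples


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------


def build_panel_items(
    cohort: Cohort,
    genes: set[str],
    models: Mapping[str, GeneModel],
    config: PanelConfig,
) -> tuple[list[PanelItem], dict[str, GeneRepresentation]]:
    """Turn each mutated listed gene into panel items (hotspots or whole gene)."""
    pams_by_gene: dict[str, list[MutationRecord]] = {}
    for m in cohort.pam_mutations():
        if m.gene_id in genes:
            pams_by_gene.setdefault(m.gene_id, []).append(m)

    items: list[PanelItem] = []
    representations: dict[str, GeneRepresentation] = {}
    for gene_id in sorted(pams_by_gene):
        muts = pams_by_gene[gene_id]
        model = models.get(gene_id)
        if config.use_hotspots:
            rep = represent_gene(
                muts,
                model,
                L=config.max_hotspot_bp,
                min_fraction=config.min_captured_fraction,
            )
        else:
            if model is None:
                from oncopanel.errors import MissingModelError

                raise MissingModelError(gene_id)
            rep = GeneRepresentation(
                gene_id=gene_id, mode="whole_exome", n_pams=len(muts)
            )
        representations[gene_id] = rep
        if rep.mode == "hotspots":
            for h in rep.hotspots:
                intervals = [(h.chrom, h.start - 1, h.end)]  # 1-based incl -> 0-based half-open
                covered = frozenset(
                    m.sample_id for m in muts if h.start <= m.pos <= h.end
                )
                items.append(
                    PanelItem(
                        item_id=f"{gene_id}|hotspot_{h.iteration + 1}",
                        gene_id=gene_id,
                        kind="hotspot",
                        intervals=intervals,
                        covered_samples=covered,
                    )
                )
        else:
            intervals = [(model.chrom, start, end) for start, end in model.exons]
            covered = frozenset(
                m.sample_id
                for m in muts
                if any(start < m.pos <= end for _, start, end in intervals)
            )
            items.append(
                PanelItem(
                    item_id=f"{gene_id}|whole_gene",
                    gene_id=gene_id,
                    kind="whole_gene",
                    intervals=intervals,
                    covered_samples=covered,
                )
            )
    return items, representations


def design_panel(
    cohort: Cohort,
    gene_lists: Sequence[GeneList],
    models: Mapping[str, GeneModel],
    config: PanelConfig | None = None,
) -> PanelDesign:
    """Run the full design pipeline on a cohort.

    Restrict to protein-affecting mutations in listed genes, represent
    each gene as hotspots or whole exome, rank by greedy marginal
    coverage, classify tiers, and compute 1/2/3-mutation coverage.
    """
    config = config or PanelConfig()
    if not gene_lists:
        raise ConfigError("at least one gene list is required")
    if cohort.n_samples == 0:
        raise ConfigError("cohort has zero samples")
    genes: set[str] = set()
    for gl in gene_lists:
        genes |= gl.gene_ids

    items, representations = build_panel_items(cohort, genes, models, config)
    if not items:
        n_pams = len(cohort.pam_mutations())
        raise EmptyPanelError(
            f"no listed gene carries a protein-affecting mutation in cohort "
            f"{cohort.name!r} ({len(genes)} listed genes, {len(cohort.mutations)} "
            f"mutations of which {n_pams} protein-affecting)"
        )
    ranked = greedy_rank(items, cohort)
    multiplier = (
        config.stringent_slope_multiplier if config.stringent else config.tier1_slope_multiplier
    )
    assign_tiers(
        ranked,
        stringent=config.stringent,
        n_samples=cohort.n_samples,
        slope_multiplier=multiplier,
    )
    design = PanelDesign(
        cohort_name=cohort.name,
        n_samples=cohort.n_samples,
        items=ranked,
        representations=representations,
    )
    design.coverage_k1 = coverage_k(items, cohort, 1)
    design.coverage_k2 = coverage_k(items, cohort, 2)
    design.coverage_k3 = coverage_k(items, cohort, 3)
    return design
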