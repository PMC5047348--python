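import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from oncopanel.cohort_io import Cohort, GeneModel, MutationRecord


def make_mutation(
    sample="S1",
    gene="GENE1",
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    consequence="missense",
    **kw,
):
    return MutationRecord(
        sample_id=sample,
        gene_id=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        **kw,
    )


def mutations_at(positions, gene="GENE1", chrom="chr1", consequence="missense"):
    """One mutation per (implicitly distinct) sample at each given position."""
    return [
        make_mutation(sample=f"S{i + 1}", gene=gene, chrom=chrom, pos=p, consequence=consequence)
        for i, p in enumerate(positions)
    ]


def cohort_from_coverage(coverage: dict[str, set[str]], n_samples=None, positions=None):
    """Build a cohort + panel items from an item -> covered-samples map.

    Each item becomes a distinct 1 kb gene interval; each covering sample
    gets one missense mutation inside it.
    """
    from oncopanel.design import PanelItem

    samples = sorted(set().union(*coverage.values())) if coverage else []
    if n_samples is not None:
        samples = sorted(set(samples) | {f"S{i + 1}" for i in range(n_samples)})
    items = []
    mutations = []
    for idx, (item_id, covered) in enumerate(sorted(coverage.items())):
        start = idx * 10_000
        for s in sorted(covered):
            mutations.append(
                make_mutation(sample=s, gene=item_id, chrom="chr1", pos=start + 500)
            )
        items.append(
            PanelItem(
                item_id=item_id,
                gene_id=item_id,
                kind="whole_gene",
                intervals=[("chr1", start, start + 1000)],
                covered_samples=frozenset(covered),
            )
        )
    cohort = Cohort(samples=frozenset(samples), mutations=mutations, name="toy")
    return items, cohort


@pytest.fixture
def gene1_model():
    return GeneModel(gene_id="GENE1", chrom="chr1", strand="+", exons=[(0, 3000)])


@pytest.fixture
def sim_small():
    """A small deterministic simulation shared across tests."""
    from oncopanel.simulate import SimulationConfig, simulate_cohort, simulate_gene_models

    config = SimulationConfig(seed=11, n_samples=60, n_genes=12)
    models = simulate_gene_models(
        config.n_genes, config.exons_per_gene, config.exon_len_range, seed=config.seed
    )
    cohort, truth = simulate_cohort(config, models)
    return config, models, cohort, truth
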