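"""Synthetic cohort generator with known ground truth.

Builds gene models on synthetic chromosomes, implants recurrent
mutational hotspots in driver genes, adds per-gene background mutations
and a configurable fraction of non-protein-affecting mutations, and
returns the realized truth (implanted windows, per-sample mutated gene
sets) so every downstream stage can be checked exactly.

All randomness flows through one generator keyed by ``seed``; draws are
ordered by (gene, sample) so realizations do not depend on iteration
order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import yaml

from oncopanel.cohort_io import (
    Cohort,
    GeneList,
    GeneModel,
    MutationRecord,
    write_gene_models,
    write_mutation_table,
    write_sample_manifest,
)
from oncopanel.errors import ConfigError
from oncopanel.util import atomic_write

_BASES = ("A", "C", "G", "T")


@dataclass
class HotspotSpec:
    """Implanted hotspot: width in bp and the share of a carrier's
    mutations placed inside the window."""

    width: int = 30
    share: float = 0.9

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ConfigError(f"hotspot width must be >= 1, got {self.width}")
        if not 0 <= self.share <= 1:
            raise ConfigError(f"hotspot share must be in [0,1], got {self.share}")


@dataclass
class SimulationConfig:
    n_samples: int = 100
    n_genes: int = 20
    driver_prob: float = 0.25
    carrier_prob: float = 0.3
    mutations_per_carrier: int = 1
    hotspot: HotspotSpec = field(default_factory=HotspotSpec)
    hotspot_overrides: dict[str, HotspotSpec] = field(default_factory=dict)
    driver_genes: Optional[list[str]] = None  # explicit list overrides driver_prob
    background_rate: float = 0.005
    non_pam_fraction: float = 0.1
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len_range: tuple[int, int] = (200, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("driver_prob", "carrier_prob", "background_rate", "non_pam_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hotspot" in raw and isinstance(raw["hotspot"], dict):
            raw["hotspot"] = HotspotSpec(**raw["hotspot"])
        if "hotspot_overrides" in raw:
            raw["hotspot_overrides"] = {
                g: HotspotSpec(**spec) for g, spec in raw["hotspot_overrides"].items()
            }
        for key in ("exons_per_gene", "exon_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Realized truth of one simulation (refers to the drawn cohort)."""

    driver_genes: list[str]
    #: gene -> (chrom, start, end) 1-based inclusive implanted window
    hotspot_windows: dict[str, tuple[str, int, int]]
    #: gene -> number of PAMs placed inside its implanted window
    hotspot_pam_counts: dict[str, int]
    #: gene -> sorted 1-based positions of PAMs placed inside its window
    hotspot_pam_positions: dict[str, list[int]]
    #: sample -> set of genes where it carries >=1 PAM
    sample_gene_pams: dict[str, set[str]]
    n_samples: int

    def expected_coverage(self, genes) -> float:
        """Fraction of samples with a PAM in any of *genes* (direct set union)."""
        genes = set(genes)
        hit = sum(1 for s_genes in self.sample_gene_pams.values() if s_genes & genes)
        return hit / self.n_samples

    def to_json(self) -> dict:
        return {
            "driver_genes": self.driver_genes,
            "hotspot_windows": {g: list(w) for g, w in self.hotspot_windows.items()},
            "hotspot_pam_counts": self.hotspot_pam_counts,
            "hotspot_pam_positions": self.hotspot_pam_positions,
            "sample_gene_pams": {s: sorted(gs) for s, gs in self.sample_gene_pams.items()},
            "n_samples": self.n_samples,
        }


def simulate_gene_models(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (2, 4),
    exon_len_range: tuple[int, int] = (200, 600),
    seed: int = 0,
) -> dict[str, GeneModel]:
    """Deterministically lay non-overlapping genes on synthetic chromosomes."""
    if exon_len_range[0] < 1 or exon_len_range[1] < exon_len_range[0]:
        raise ConfigError(f"bad exon_len_range {exon_len_range}")
    if exons_per_gene[0] < 1 or exons_per_gene[1] < exons_per_gene[0]:
        raise ConfigError(f"bad exons_per_gene {exons_per_gene}")
    rng = np.random.default_rng(seed)
    models: dict[str, GeneModel] = {}
    n_chroms = 4
    cursors = {f"chr{c + 1}": 1000 for c in range(n_chroms)}
    for i in range(n_genes):
        gene_id = f"GENE{i + 1:03d}"
        chrom = f"chr{(i % n_chroms) + 1}"
        cursor = cursors[chrom]
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(100, 500))  # intron gap
        cursors[chrom] = cursor + 5000  # intergenic gap
        strand = "+" if rng.random() < 0.5 else "-"
        models[gene_id] = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
    return models


def _exon_offset_to_pos(model: GeneModel, offset: int) -> int:
    """Map a 0-based offset in concatenated exon space to a 1-based genomic pos."""
    for start, end in model.exons:
        length = end - start
        if offset < length:
            return start + offset + 1
        offset -= length
    raise ValueError(f"offset beyond coding length of {model.gene_id}")


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[int(rng.integers(0, 3))]
    if alt == ref:
        alt = _BASES[3]
    return ref, alt


def simulate_cohort(
    config: SimulationConfig, models: Mapping[str, GeneModel]
) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort with implanted hotspots and return it with its truth."""
    gene_ids = sorted(models)[: config.n_genes]
    if len(gene_ids) < config.n_genes:
        raise ConfigError(
            f"models cover {len(gene_ids)} genes but config asks for {config.n_genes}"
        )
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    rng = np.random.default_rng(config.seed)

    if config.driver_genes is not None:
        missing = set(config.driver_genes) - set(gene_ids)
        if missing:
            raise ConfigError(f"driver_genes not in models: {sorted(missing)}")
        driver_genes = sorted(config.driver_genes)
        # burn the per-gene driver draws to keep the stream layout stable
        rng.random(len(gene_ids))
    else:
        draws = rng.random(len(gene_ids))
        driver_genes = [g for g, d in zip(gene_ids, draws) if d < config.driver_prob]

    hotspot_windows: dict[str, tuple[str, int, int]] = {}
    hotspot_pam_positions: dict[str, list[int]] = {}
    records: list[MutationRecord] = []
    seen: set[tuple[str, str, str, int, str]] = set()
    sample_gene_pams: dict[str, set[str]] = {s: set() for s in samples}

    def add_record(sample: str, gene: str, pos: int, in_hotspot: bool) -> None:
        model = models[gene]
        ref, alt = _draw_alleles(rng)
        is_pam = rng.random() >= config.non_pam_fraction
        consequence = "missense" if is_pam else "synonymous"
        key = (sample, gene, model.chrom, pos, alt)
        if key in seen:
            return  # identical duplicate would be dropped by the reader anyway
        seen.add(key)
        records.append(
            MutationRecord(
                sample_id=sample,
                gene_id=gene,
                chrom=model.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                consequence=consequence,
            )
        )
        if is_pam:
            sample_gene_pams[sample].add(gene)
            if in_hotspot:
                hotspot_pam_positions[gene].append(pos)

    # driver mutations, ordered by (gene, sample)
    for gene in driver_genes:
        model = models[gene]
        spec = config.hotspot_overrides.get(gene, config.hotspot)
        fitting = [e for e in model.exons if e[1] - e[0] >= spec.width]
        if not fitting:
            raise ConfigError(
                f"hotspot width {spec.width} does not fit any exon of {gene}"
            )
        exon = fitting[0]
        start0 = int(rng.integers(exon[0], exon[1] - spec.width + 1))
        window = (model.chrom, start0 + 1, start0 + spec.width)  # 1-based inclusive
        hotspot_windows[gene] = window
        hotspot_pam_positions[gene] = []
        for sample in samples:
            if rng.random() >= config.carrier_prob:
                continue
            for _ in range(config.mutations_per_carrier):
                if rng.random() < spec.share:
                    pos = int(rng.integers(window[1], window[2] + 1))
                    add_record(sample, gene, pos, in_hotspot=True)
                else:
                    offset = int(rng.integers(0, model.coding_length))
                    pos = _exon_offset_to_pos(model, offset)
                    add_record(sample, gene, pos, in_hotspot=(window[1] <= pos <= window[2]))

    # background mutations across all genes, ordered by (gene, sample)
    if config.background_rate > 0:
        for gene in gene_ids:
            model = models[gene]
            window = hotspot_windows.get(gene)
            for sample in samples:
                if rng.random() >= config.background_rate:
                    continue
                offset = int(rng.integers(0, model.coding_length))
                pos = _exon_offset_to_pos(model, offset)
                in_hs = window is not None and window[1] <= pos <= window[2]
                add_record(sample, gene, pos, in_hotspot=in_hs)

    records.sort(key=lambda r: (r.sample_id, r.gene_id, r.chrom, r.pos, r.alt, r.consequence))
    cohort = Cohort(
        samples=frozenset(samples),
        mutations=records,
        name=f"sim_seed{config.seed}",
    )
    truth = GroundTruth(
        driver_genes=driver_genes,
        hotspot_windows=hotspot_windows,
        hotspot_pam_counts={g: len(ps) for g, ps in hotspot_pam_positions.items()},
        hotspot_pam_positions={g: sorted(ps) for g, ps in hotspot_pam_positions.items()},
        sample_gene_pams=sample_gene_pams,
        n_samples=config.n_samples,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# synthetic annotation catalogs
# ---------------------------------------------------------------------------


def simulate_catalogs(
    cohort: Cohort, truth: GroundTruth, seed: int = 0, n_drugs: int = 5
) -> dict[str, "object"]:
    """Derive small annotation catalogs from a realized cohort.

    Recurrent mutations become validated-oncogenic entries; a subset of
    those in driver genes become drug biomarkers; drivers alternate
    between loss-of-function and activation modes.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    by_change: dict[tuple[str, str], int] = {}
    for m in cohort.pam_mutations():
        by_change[(m.gene_id, m.genomic_change)] = by_change.get(
            (m.gene_id, m.genomic_change), 0
        ) + 1
    recurrent = sorted(k for k, c in by_change.items() if c >= 2)
    onco_rows = [
        {
            "gene": gene,
            "match_key": "genomic_change",
            "key_value": change,
            "cancer_types": "PANCAN",
            "validated": "true",
        }
        for gene, change in recurrent
    ]
    bm_rows = []
    for i, (gene, change) in enumerate(recurrent):
        if gene in truth.driver_genes and rng.random() < 0.5:
            bm_rows.append(
                {
                    "gene": gene,
                    "match_key": "genomic_change",
                    "key_value": change,
                    "drug": f"drug{(i % n_drugs) + 1}",
                    "effect": "response" if rng.random() < 0.7 else "resistance",
                    "cancer_types": "PANCAN",
                }
            )
    gene_rows = [
        {
            "gene": gene,
            "mode_of_action": "activation" if i % 2 == 0 else "loss_of_function",
            "major_clone": "true" if i % 3 == 0 else "false",
        }
        for i, gene in enumerate(truth.driver_genes)
    ]
    return {
        "oncogenic": pd.DataFrame(
            onco_rows, columns=["gene", "match_key", "key_value", "cancer_types", "validated"]
        ),
        "biomarkers": pd.DataFrame(
            bm_rows,
            columns=["gene", "match_key", "key_value", "drug", "effect", "cancer_types"],
        ),
        "genes": pd.DataFrame(gene_rows, columns=["gene", "mode_of_action", "major_clone"]),
    }


def write_simulation(
    config: SimulationConfig,
    models: Mapping[str, GeneModel],
    cohort: Cohort,
    truth: GroundTruth,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write all files the pipeline consumes; returns name -> path map."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "cohort": os.path.join(outdir, "cohort.tsv"),
        "samples": os.path.join(outdir, "samples.txt"),
        "models": os.path.join(outdir, "exons.bed"),
        "drivers": os.path.join(outdir, "drivers.txt"),
        "truth": os.path.join(outdir, "truth.json"),
        "oncogenic": os.path.join(outdir, "oncogenic.tsv"),
        "biomarkers": os.path.join(outdir, "biomarkers.tsv"),
        "gene_catalog": os.path.join(outdir, "gene_catalog.tsv"),
    }
    write_mutation_table(cohort, paths["cohort"])
    write_sample_manifest(cohort, paths["samples"])
    write_gene_models(dict(models), paths["models"])
    with atomic_write(paths["drivers"]) as fh:
        for gene in sorted(truth.driver_genes):
            fh.write(gene + "\n")
    with atomic_write(paths["truth"]) as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    catalogs = simulate_catalogs(cohort, truth, seed=config.seed)
    for key in ("oncogenic", "biomarkers"):
        with atomic_write(paths[key]) as fh:
            catalogs[key if key != "gene_catalog" else "genes"].to_csv(fh, sep="\t", index=False)
    with atomic_write(paths["gene_catalog"]) as fh:
        catalogs["genes"].to_csv(fh, sep="\t", index=False)
    return paths


def driver_gene_list(truth: GroundTruth) -> GeneList:
    if not truth.driver_genes:
        raise ConfigError("simulation produced no driver genes")
    return GeneList(gene_ids=frozenset(truth.driver_genes), category="driver")
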