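"""Readers/writers for mutation cohorts, gene models, gene lists and BED.

Coordinate conventions: mutation tables are 1-based inclusive (MAF
convention); all BED input/output is 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from oncopanel.errors import FormatError
from oncopanel.util import atomic_write

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# consequence vocabulary
# ---------------------------------------------------------------------------

#: canonical protein-affecting consequence classes
PAM_CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "stop_lost",
        "start_lost",
        "splice_site",
        "frameshift",
        "inframe_indel",
    }
)

#: canonical classes recognized as NOT protein-affecting
NON_PAM_CONSEQUENCES = frozenset(
    {"synonymous", "intronic", "utr", "intergenic", "other"}
)

# Aliases map raw consequence strings (MAF Variant_Classification values,
# VEP/SO terms, shorthand) onto the canonical vocabulary.
_CONSEQUENCE_ALIASES = {
    # missense
    "missense": "missense",
    "missense_mutation": "missense",
    "missense_variant": "missense",
    # nonsense / stop gain
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "stop_gained": "nonsense",
    "stop_gain": "nonsense",
    # stop loss
    "stop_lost": "stop_lost",
    "stop_loss": "stop_lost",
    "nonstop_mutation": "stop_lost",
    # start loss
    "start_lost": "start_lost",
    "start_loss": "start_lost",
    "translation_start_site": "start_lost",
    "initiator_codon_variant": "start_lost",
    # splice
    "splice_site": "splice_site",
    "splice_donor_variant": "splice_site",
    "splice_acceptor_variant": "splice_site",
    "splice_donor": "splice_site",
    "splice_acceptor": "splice_site",
    # frameshift indels
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift_indel": "frameshift",
    # in-frame indels
    "inframe_indel": "inframe_indel",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "inframe_insertion": "inframe_indel",
    # non protein-affecting
    "synonymous": "synonymous",
    "silent": "synonymous",
    "synonymous_variant": "synonymous",
    "intron": "intronic",
    "intronic": "intronic",
    "intron_variant": "intronic",
    "3'utr": "utr",
    "5'utr": "utr",
    "3'flank": "intergenic",
    "5'flank": "intergenic",
    "utr": "utr",
    "3_prime_utr_variant": "utr",
    "5_prime_utr_variant": "utr",
    "igr": "intergenic",
    "intergenic": "intergenic",
    "intergenic_variant": "intergenic",
    "rna": "other",
    "other": "other",
}

_warned_consequences: set[str] = set()


def normalize_consequence(raw: str) -> str:
    """Map a raw consequence string onto the canonical vocabulary.

    Unknown strings normalize to ``"other"`` with a (once-per-token)
    logged warning; this is never fatal.
    """
    key = str(raw).strip().lower()
    canonical = _CONSEQUENCE_ALIASES.get(key)
    if canonical is None:
        if key not in _warned_consequences:
            _warned_consequences.add(key)
            log.warning("unknown consequence %r treated as non-protein-affecting", raw)
        return "other"
    return canonical


def classify_pam(consequence: str) -> bool:
    """True iff *consequence* is a protein-affecting mutation (PAM) class.

    The PAM whitelist covers missense, nonsense/stop-gain, stop-loss,
    start-loss, splice-site, frameshift and in-frame indels. Everything
    else (synonymous, intronic, UTR, intergenic, unknown) is non-PAM.
    """
    return normalize_consequence(consequence) in PAM_CONSEQUENCES


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic mutation observation in one sample.

    ``pos`` is the 1-based genomic start coordinate; indels are located
    at their start position.
    """

    sample_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    protein_pos: Optional[int] = None
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_pam(self) -> bool:
        return classify_pam(self.consequence)

    @property
    def genomic_change(self) -> str:
        """Exact-match key for genomic annotation joins."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class Cohort:
    """A set of tumor samples with their somatic mutations.

    ``samples`` is the coverage denominator: it may include samples with
    zero mutations (e.g. supplied via a manifest).
    """

    samples: frozenset[str]
    mutations: list[MutationRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.samples = frozenset(self.samples)
        missing = {m.sample_id for m in self.mutations} - self.samples
        if missing:
            raise ValueError(f"mutations reference samples not in cohort: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pam_mutations(self) -> list[MutationRecord]:
        return [m for m in self.mutations if m.is_pam]


@dataclass
class GeneModel:
    """Exon intervals of a gene; 0-based half-open, merged and sorted."""

    gene_id: str
    chrom: str
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.gene_id}: exon end {end} <= start {start}")
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon")

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


GENE_LIST_CATEGORIES = ("driver", "biomarker", "user")


@dataclass
class GeneList:
    """A named set of candidate gene symbols with its category label."""

    gene_ids: frozenset[str]
    category: str = "user"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene list must be non-empty")
        if self.category not in GENE_LIST_CATEGORIES:
            raise ValueError(
                f"category must be one of {GENE_LIST_CATEGORIES}, got {self.category!r}"
            )
        self.gene_ids = frozenset(self.gene_ids)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 0-based half-open intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# mutation table reading
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {
    "maf": {
        "sample_id": "Tumor_Sample_Barcode",
        "gene_id": "Hugo_Symbol",
        "chrom": "Chromosome",
        "pos": "Start_Position",
        "ref": "Reference_Allele",
        "alt": "Tumor_Seq_Allele2",
        "consequence": "Variant_Classification",
    },
    "simple_tsv": {
        "sample_id": "sample",
        "gene_id": "gene",
        "chrom": "chrom",
        "pos": "pos",
        "ref": "ref",
        "alt": "alt",
        "consequence": "consequence",
    },
}

_OPTIONAL_COLUMNS = {
    "maf": {"protein_change": "HGVSp_Short"},
    "simple_tsv": {"protein_change": "protein_change"},
}


def read_mutation_table(
    path: str | os.PathLike,
    dialect: str = "simple_tsv",
    sample_manifest: Optional[Iterable[str]] = None,
    name: Optional[str] = None,
) -> Cohort:
    """Read a MAF-like TSV mutation table into a :class:`Cohort`.

    Duplicate rows (same sample/gene/chrom/pos/alt) are deduplicated.
    Rows with unparseable coordinates are skipped with a warning and
    counted. The sample set is the union of observed sample ids and the
    optional *sample_manifest* (which lets zero-mutation samples stay in
    the coverage denominator).
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _DIALECT_COLUMNS[dialect]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty mutation table") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty mutation table")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for dialect {dialect!r}")

    protein_col = _OPTIONAL_COLUMNS[dialect]["protein_change"]
    has_protein = protein_col in df.columns

    records: list[MutationRecord] = []
    seen: set[tuple[str, str, str, int, str]] = set()
    n_skipped = 0
    n_duplicates = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            pos = int(str(row_d[colmap["pos"]]))
            rec = MutationRecord(
                sample_id=str(row_d[colmap["sample_id"]]),
                gene_id=str(row_d[colmap["gene_id"]]),
                chrom=str(row_d[colmap["chrom"]]),
                pos=pos,
                ref=str(row_d[colmap["ref"]]),
                alt=str(row_d[colmap["alt"]]),
                consequence=str(row_d[colmap["consequence"]]),
                protein_change=(
                    str(row_d[protein_col])
                    if has_protein and pd.notna(row_d[protein_col])
                    else None
                ),
            )
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        key = (rec.sample_id, rec.gene_id, rec.chrom, rec.pos, rec.alt)
        if key in seen:
            n_duplicates += 1
            continue
        seen.add(key)
        records.append(rec)
    if n_skipped:
        log.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    if n_duplicates:
        log.warning("%s: dropped %d duplicate mutation row(s)", path, n_duplicates)

    samples = {r.sample_id for r in records}
    if sample_manifest is not None:
        samples |= {str(s) for s in sample_manifest}
    # canonical row order makes parsing independent of input row order
    records.sort(key=lambda r: (r.sample_id, r.gene_id, r.chrom, r.pos, r.alt, r.consequence))
    return Cohort(
        samples=frozenset(samples),
        mutations=records,
        name=name or os.path.splitext(os.path.basename(os.fspath(path)))[0],
    )


def write_mutation_table(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write a cohort in ``simple_tsv`` dialect (round-trips with the reader)."""
    rows = [
        {
            "sample": m.sample_id,
            "gene": m.gene_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "consequence": m.consequence,
            "protein_change": m.protein_change or "",
        }
        for m in sorted(
            cohort.mutations,
            key=lambda r: (r.sample_id, r.gene_id, r.chrom, r.pos, r.alt, r.consequence),
        )
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample", "gene", "chrom", "pos", "ref", "alt", "consequence", "protein_change"],
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


def write_sample_manifest(cohort: Cohort, path: str | os.PathLike) -> None:
    with atomic_write(path) as fh:
        for sample in sorted(cohort.samples):
            fh.write(sample + "\n")


def read_sample_manifest(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


# ---------------------------------------------------------------------------
# gene models / gene lists
# ---------------------------------------------------------------------------


def read_gene_models(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read exon BED (>=4 columns, name column = gene id) into gene models.

    Multiple rows per gene are exons; overlapping exons are merged.
    """
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, gene_id = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: interval end {end} <= start {start}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            entry = raw.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            if entry["chrom"] != chrom:
                raise FormatError(f"{path}:{lineno}: gene {gene_id!r} spans multiple chromosomes")
            entry["exons"].append((start, end))
    return {
        gene_id: GeneModel(gene_id=gene_id, chrom=e["chrom"], strand=e["strand"], exons=e["exons"])
        for gene_id, e in raw.items()
    }


def write_gene_models(models: dict[str, GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for model in models.values():
        for start, end in model.exons:
            rows.append((model.chrom, start, end, model.gene_id, 0, model.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with atomic_write(path) as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_gene_list(path: str | os.PathLike, category: str = "user") -> GeneList:
    """Read a one-symbol-per-line gene list."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            symbol = line.strip()
            if symbol and not symbol.startswith("#"):
                genes.add(symbol.split("\t")[0])
    if not genes:
        raise FormatError(f"{path}: gene list is empty")
    return GeneList(gene_ids=frozenset(genes), category=category)


# ---------------------------------------------------------------------------
# BED output / input for panels
# ---------------------------------------------------------------------------


def write_bed(panel, path: str | os.PathLike, flank_bp: int = 0) -> None:
    """Write a panel design as BED (0-based half-open).

    One row per exon for whole-gene items, one row per hotspot item.
    The name column is ``gene|tierN|hotspot_k`` or ``gene|tierN|whole_gene``.
    *flank_bp* pads each emitted interval on both sides (output only; it
    does not affect panel size accounting).
    """
    rows: list[tuple[str, int, int, str]] = []
    for ranked in panel.items:
        item = ranked.item
        if item.kind == "whole_gene":
            label = f"{item.gene_id}|tier{ranked.tier}|whole_gene"
        else:
            label = f"{item.gene_id}|tier{ranked.tier}|{item.item_id.split('|', 1)[1]}"
        for chrom, start, end in item.intervals:
            rows.append((chrom, max(0, start - flank_bp), end + flank_bp, label))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with atomic_write(path) as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_panel_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read a panel BED into labelled 0-based half-open intervals."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: interval end {end} <= start {start}")
            label = parts[3] if len(parts) >= 4 else f"region_{lineno}"
            intervals.append((parts[0], start, end, label))
    if not intervals:
        raise FormatError(f"{path}: no intervals found")
    return intervals
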