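"""Annotation joins against user-supplied TSV catalogs.

Three catalog kinds are consumed (all plain TSV, schemas below):

* oncogenic mutations — ``gene  match_key  key_value  cancer_types  validated``
* drug biomarkers     — ``gene  match_key  key_value  drug  effect  cancer_types``
* gene annotations    — ``gene  mode_of_action  major_clone``

``match_key`` is ``genomic_change`` (``chrom:pos:ref>alt``) or
``protein_change`` (normalized HGVS-p short form, e.g. ``L858R``);
matching is exact-string, never fuzzy. Annotation is pure decoration: it
never alters panel membership, ranks, tiers, coverage or size.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from oncopanel.cohort_io import Cohort, MutationRecord
from oncopanel.errors import FormatError
from oncopanel.util import atomic_write

log = logging.getLogger(__name__)

MATCH_KEYS = ("genomic_change", "protein_change")
EFFECTS = ("response", "resistance")
MODES_OF_ACTION = ("loss_of_function", "activation", "unknown")


@dataclass(frozen=True)
class OncogenicCatalogEntry:
    gene_id: str
    match_key: str
    key_value: str
    cancer_types: tuple[str, ...] = ()
    validated: bool = True


@dataclass(frozen=True)
class BiomarkerEntry:
    gene_id: str
    match_key: str
    key_value: str
    drug: str
    effect: str
    cancer_types: tuple[str, ...] = ()


@dataclass
class GeneAnnotation:
    gene_id: str
    mode_of_action: str = "unknown"
    major_clone_tendency: Optional[bool] = None


def normalize_protein_change(value: str) -> str:
    """Normalize HGVS-p to short form: strip ``p.`` prefix and parentheses."""
    v = value.strip()
    if v.lower().startswith("p."):
        v = v[2:]
    return v.strip("()")


def _split_cancer_types(raw) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return ()
    return tuple(t.strip() for t in str(raw).split(",") if t.strip())


def read_oncogenic_catalog(path: str | os.PathLike) -> list[OncogenicCatalogEntry]:
    df = _read_catalog(path, ["gene", "match_key", "key_value"])
    entries = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        match_key = str(d["match_key"]).strip()
        if match_key not in MATCH_KEYS:
            log.warning("%s: skipping row with unknown match_key %r", path, match_key)
            continue
        key_value = str(d["key_value"]).strip()
        if not key_value:
            log.warning("%s: skipping row with empty key_value", path)
            continue
        if match_key == "protein_change":
            key_value = normalize_protein_change(key_value)
        entries.append(
            OncogenicCatalogEntry(
                gene_id=str(d["gene"]),
                match_key=match_key,
                key_value=key_value,
                cancer_types=_split_cancer_types(d.get("cancer_types")),
                validated=str(d.get("validated", "true")).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return entries


def read_biomarker_catalog(path: str | os.PathLike) -> list[BiomarkerEntry]:
    df = _read_catalog(path, ["gene", "match_key", "key_value", "drug", "effect"])
    entries = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        effect = str(d["effect"]).strip().lower()
        if effect not in EFFECTS:
            log.warning("%s: skipping row with unknown effect %r", path, d["effect"])
            continue
        match_key = str(d["match_key"]).strip()
        if match_key not in MATCH_KEYS:
            log.warning("%s: skipping row with unknown match_key %r", path, match_key)
            continue
        key_value = str(d["key_value"]).strip()
        if match_key == "protein_change":
            key_value = normalize_protein_change(key_value)
        entries.append(
            BiomarkerEntry(
                gene_id=str(d["gene"]),
                match_key=match_key,
                key_value=key_value,
                drug=str(d["drug"]),
                effect=effect,
                cancer_types=_split_cancer_types(d.get("cancer_types")),
            )
        )
    return entries


def read_gene_catalog(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """Read gene mode-of-action/clonality TSV. First row wins on duplicates."""
    df = _read_catalog(path, ["gene", "mode_of_action"])
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        gene = str(d["gene"])
        if gene in out:
            log.warning("%s: duplicate row for gene %r; first row wins", path, gene)
            continue
        moa = str(d["mode_of_action"]).strip().lower()
        if moa not in MODES_OF_ACTION:
            log.warning("%s: unknown mode_of_action %r for %r; set to unknown", path, moa, gene)
            moa = "unknown"
        clone = d.get("major_clone")
        tendency: Optional[bool] = None
        if clone is not None and not (isinstance(clone, float) and pd.isna(clone)):
            tendency = str(clone).strip().lower() in ("true", "1", "yes")
        out[gene] = GeneAnnotation(gene_id=gene, mode_of_action=moa, major_clone_tendency=tendency)
    return out


def _read_catalog(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty catalog") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# joins
# ---------------------------------------------------------------------------


def _mutation_keys(m: MutationRecord) -> dict[str, str]:
    keys = {"genomic_change": m.genomic_change}
    if m.protein_change:
        keys["protein_change"] = normalize_protein_change(m.protein_change)
    return keys


def annotate_mutations(
    cohort: Cohort,
    oncogenic: Iterable[OncogenicCatalogEntry] = (),
    biomarkers: Iterable[BiomarkerEntry] = (),
) -> pd.DataFrame:
    """Per-mutation annotation table; unmatched mutations are kept with
    empty annotation. The join is deterministic and order-invariant."""
    onco_index: set[tuple[str, str, str]] = {
        (e.gene_id, e.match_key, e.key_value) for e in oncogenic
    }
    bm_index: dict[tuple[str, str, str], list[BiomarkerEntry]] = {}
    for e in biomarkers:
        bm_index.setdefault((e.gene_id, e.match_key, e.key_value), []).append(e)

    rows = []
    muts = sorted(
        cohort.mutations,
        key=lambda m: (m.gene_id, m.chrom, m.pos, m.alt, m.sample_id),
    )
    for m in muts:
        keys = _mutation_keys(m)
        is_onco = any(
            (m.gene_id, mk, kv) in onco_index for mk, kv in keys.items()
        )
        hits: list[BiomarkerEntry] = []
        for mk, kv in keys.items():
            hits.extend(bm_index.get((m.gene_id, mk, kv), []))
        hits.sort(key=lambda e: (e.drug, e.effect))
        rows.append(
            {
                "sample": m.sample_id,
                "gene": m.gene_id,
                "genomic_change": m.genomic_change,
                "protein_change": m.protein_change or "",
                "consequence": m.consequence,
                "oncogenic": is_onco,
                "biomarker_drugs": ";".join(f"{e.drug}:{e.effect}" for e in hits),
                "n_biomarker_hits": len(hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "gene",
            "genomic_change",
            "protein_change",
            "consequence",
            "oncogenic",
            "biomarker_drugs",
            "n_biomarker_hits",
        ],
    )


def annotate_genes(
    genes: Iterable[str], gene_catalog: dict[str, GeneAnnotation]
) -> dict[str, GeneAnnotation]:
    """Total map over *genes*; absent genes default to mode 'unknown'."""
    return {
        g: gene_catalog.get(g, GeneAnnotation(gene_id=g, mode_of_action="unknown"))
        for g in genes
    }


def write_annotation_table(df: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)
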