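"""TSV/JSON report writers for panel designs."""

from __future__ import annotations

import json

import pandas as pd

from oncopanel.design import PanelDesign
from oncopanel.util import atomic_write

PANEL_REPORT_COLUMNS = [
    "rank",
    "item_id",
    "gene",
    "kind",
    "tier",
    "marginal_samples",
    "cmf",
    "length_bp",
]


def panel_table(design: PanelDesign) -> pd.DataFrame:
    rows = [
        {
            "rank": r.rank,
            "item_id": r.item.item_id,
            "gene": r.item.gene_id,
            "kind": r.item.kind,
            "tier": r.tier,
            "marginal_samples": r.marginal_new_samples,
            "cmf": r.cmf,
            "length_bp": r.item.length_bp,
        }
        for r in design.items
    ]
    return pd.DataFrame(rows, columns=PANEL_REPORT_COLUMNS)


def write_panel_report(design: PanelDesign, path) -> None:
    with atomic_write(path) as fh:
        panel_table(design).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def panel_summary(design: PanelDesign) -> dict:
    return {
        "cohort": design.cohort_name,
        "n_samples": design.n_samples,
        "n_items": len(design.items),
        "n_genes": len({r.item.gene_id for r in design.items}),
        "coverage_k1": design.coverage_k1,
        "coverage_k2": design.coverage_k2,
        "coverage_k3": design.coverage_k3,
        "total_kbps": design.total_kbps,
        "tier_counts": {
            str(t): sum(1 for r in design.items if r.tier == t) for t in (1, 2, 3)
        },
    }


def write_panel_summary(design: PanelDesign, path) -> None:
    with atomic_write(path) as fh:
        json.dump(panel_summary(design), fh, indent=2, sort_keys=True)
        fh.write("\n")
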