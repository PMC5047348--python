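"""Cost-effectiveness evaluation of panels against cohorts.

A panel — designed here or supplied as an external BED — is scored by
the fraction of cohort samples with protein-affecting mutations inside
its regions (coverage, also at depth k=2,3 distinct regions) against the
total DNA it targets (Kbps, after merging overlapping intervals).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from oncopanel.cohort_io import Cohort, merge_intervals
from oncopanel.errors import ConfigError
from oncopanel.util import atomic_write

LabelledInterval = tuple[str, int, int, str]


@dataclass
class PanelEvaluation:
    panel_name: str
    coverage: float
    coverage_k2: float
    coverage_k3: float
    kbps: float
    driver_fraction: Optional[float] = None
    n_genes: int = 0

    def as_dict(self) -> dict:
        return {
            "panel": self.panel_name,
            "coverage": self.coverage,
            "coverage_k2": self.coverage_k2,
            "coverage_k3": self.coverage_k3,
            "kbps": self.kbps,
            "driver_fraction": self.driver_fraction,
            "n_genes": self.n_genes,
        }


def panel_bp(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total bp targeted, with overlapping intervals merged per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    return sum(
        end - start
        for ivs in by_chrom.values()
        for start, end in merge_intervals(ivs)
    )


def _label_gene(label: str) -> str:
    """Gene symbol from a panel interval label (``gene|tier|kind`` or bare)."""
    return label.split("|", 1)[0]


def evaluate_panel(
    panel_intervals: Sequence[LabelledInterval],
    cohort: Cohort,
    driver_catalog: Optional[Iterable[str]] = None,
    panel_name: str = "panel",
) -> PanelEvaluation:
    """Score one panel against a cohort.

    A sample is covered iff >=1 of its protein-affecting mutations lies
    inside any panel interval (matched by genomic position). Depth-k
    coverage counts distinct interval labels hit per sample.
    """
    if not panel_intervals:
        raise ConfigError("panel has no intervals")
    # sorted per-chromosome interval lists for bisect lookup
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, label in panel_intervals:
        by_chrom.setdefault(chrom, []).append((start, end, label))
    starts_by_chrom: dict[str, list[int]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts_by_chrom[chrom] = [s for s, _, _ in ivs]

    hits: dict[str, set[str]] = {}
    for m in cohort.pam_mutations():
        ivs = by_chrom.get(m.chrom)
        if not ivs:
            continue
        p = m.pos - 1  # to 0-based
        idx = bisect.bisect_right(starts_by_chrom[m.chrom], p)
        for start, end, label in ivs[:idx]:
            if start <= p < end:
                hits.setdefault(m.sample_id, set()).add(label)

    n = cohort.n_samples
    if n == 0:
        raise ConfigError("cohort has zero samples")
    cov1 = sum(1 for labels in hits.values() if len(labels) >= 1) / n
    cov2 = sum(1 for labels in hits.values() if len(labels) >= 2) / n
    cov3 = sum(1 for labels in hits.values() if len(labels) >= 3) / n

    genes = {_label_gene(label) for _, _, _, label in panel_intervals}
    driver_fraction = None
    if driver_catalog is not None:
        catalog = set(driver_catalog)
        driver_fraction = sum(1 for g in genes if g in catalog) / len(genes)

    return PanelEvaluation(
        panel_name=panel_name,
        coverage=cov1,
        coverage_k2=cov2,
        coverage_k3=cov3,
        kbps=panel_bp((c, s, e) for c, s, e, _ in panel_intervals) / 1000.0,
        driver_fraction=driver_fraction,
        n_genes=len(genes),
    )


def compare_panels(
    panels: Sequence[tuple[str, Sequence[LabelledInterval]]],
    cohort: Cohort,
    driver_catalog: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Evaluate several named panels, sorted by coverage/Kbps descending."""
    if not panels:
        raise ConfigError("compare_panels requires at least one panel")
    names = [name for name, _ in panels]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate panel names: {names}")
    catalog = set(driver_catalog) if driver_catalog is not None else None
    rows = [
        evaluate_panel(intervals, cohort, catalog, panel_name=name).as_dict()
        for name, intervals in panels
    ]
    df = pd.DataFrame(rows)
    df["cost_effectiveness"] = df["coverage"] / df["kbps"]
    df = df.sort_values(
        ["cost_effectiveness", "panel"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def write_comparison_table(df: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_bubble_data(df: pd.DataFrame, path) -> None:
    """Scatter/bubble-plot data: x=coverage, y=kbps, size=driver_fraction."""
    cols = ["coverage", "kbps", "driver_fraction", "panel"]
    with atomic_write(path) as fh:
        df[cols].to_csv(fh, sep="\t", index=False, float_format="%.6g")
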