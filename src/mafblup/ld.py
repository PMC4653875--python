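"""Linkage-disequilibrium r2 between QTLs and their flanking marker SNPs.

r2 is the squared Pearson correlation of allele dosages (composite LD over
unphased genotypes).  For each causal locus the nearest marker on either side
within the same chromosome is located, both r2 values computed, and the
maximum kept; the distribution of that maximum, stratified by QTL MAF
category, summarizes how well a marker panel tags causal variation.  Because
r2 is bounded by allele-frequency agreement, low-MAF QTLs on a common-variant
array are systematically harder to tag — the mechanism behind missing
heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import GenotypePanel
from .qtl import QtlSet

__all__ = ["LdProfile", "dosage_r2", "qtl_flanking_r2", "summarize_r2"]


def dosage_r2(x1, x2) -> float:
    """Squared Pearson correlation of two dosage columns (pairwise complete)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("dosage columns must have equal length")
    both = np.isfinite(x1) & np.isfinite(x2)
    a, b = x1[both], x2[both]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r2 undefined for constant or near-empty columns")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdProfile:
    """Per-QTL flanking-marker r2 records with the category label."""

    records: pd.DataFrame  # qtl_id, chrom, pos, left_r2, right_r2, max_r2, edge
    category: str = "all"

    def __post_init__(self):
        required = {"qtl_id", "chrom", "pos", "left_r2", "right_r2", "max_r2"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"LdProfile records missing columns {missing}")

    @property
    def mean_max_r2(self) -> float:
        return float(self.records["max_r2"].mean())


def qtl_flanking_r2(
    panel: GenotypePanel, qtls: QtlSet, marker_panel_tag: str = "sparse50"
) -> LdProfile:
    """r2 between each QTL and its nearest marker on either side.

    Edge QTLs (no marker on one side of their chromosome) keep the single
    available flank and are flagged; markers that are monomorphic are skipped
    when searching for the nearest informative flank.
    """
    marker_idx = panel.panel_indices(marker_panel_tag)
    if marker_idx.size == 0:
        raise ValueError(f"no markers carry tag {marker_panel_tag!r}")
    chroms = panel.chroms
    pos = panel.positions
    maf = panel.maf()
    informative = marker_idx[maf[marker_idx] > 0]
    rows = []
    for qi in qtls.qtl_indices:
        same = informative[chroms[informative] == chroms[qi]]
        left = same[pos[same] < pos[qi]]
        right = same[pos[same] > pos[qi]]
        left_r2 = right_r2 = np.nan
        if left.size:
            nearest = left[np.argmax(pos[left])]
            left_r2 = dosage_r2(panel.dosages[:, qi], panel.dosages[:, nearest])
        if right.size:
            nearest = right[np.argmin(pos[right])]
            right_r2 = dosage_r2(panel.dosages[:, qi], panel.dosages[:, nearest])
        if np.isnan(left_r2) and np.isnan(right_r2):
            raise ValueError(
                f"QTL {panel.snps[qi].snp_id} has no informative marker on either side"
            )
        rows.append(
            {
                "qtl_id": panel.snps[qi].snp_id,
                "chrom": int(chroms[qi]),
                "pos": int(pos[qi]),
                "left_r2": left_r2,
                "right_r2": right_r2,
                "max_r2": np.nanmax([left_r2, right_r2]),
                "edge": bool(np.isnan(left_r2) or np.isnan(right_r2)),
            }
        )
    return LdProfile(records=pd.DataFrame(rows), category=qtls.category)


def summarize_r2(profile: LdProfile, bins: int = 20):
    """Histogram proportions of max r2 (summing to 1) and the mean."""
    values = profile.records["max_r2"].to_numpy()
    if values.size == 0:
        raise ValueError("empty LD profile")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "proportion": counts / values.size,
        }
    )
    return table, float(values.mean())
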