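"""Site-retention rules and global methylation summaries.

A CpG10 is a cell (site x sample) covered by at least 10 reads. The testing
background is the set of sites that (i) survive the variant mask, (ii) lie on
an allowed chromosome, and (iii) have CpG10 status in at least a per-group
minimum of samples in *both* fertility classes ("auto" = half of the smallest
group, rounded up). The filter report attributes each removed site to the
first rule that removed it, in the order: allow-list, variant mask, group
presence.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import ceil

import numpy as np
import pandas as pd

from .matrix import MethCountMatrix

__all__ = ["FilterReport", "coverage_filter", "group_presence_filter",
           "variant_mask_filter", "global_summary", "apply_filters"]


@dataclass
class FilterReport:
    sites_in: int
    removed_scaffold: int
    removed_variant: int
    removed_group_presence: int
    sites_out: int

    def __post_init__(self) -> None:
        total_removed = (self.removed_scaffold + self.removed_variant
                         + self.removed_group_presence)
        if self.sites_out != self.sites_in - total_removed:
            raise ValueError("filter accounting identity violated")

    def to_dict(self) -> dict:
        return asdict(self)


def coverage_filter(matrix: MethCountMatrix, min_reads: int = 10) -> np.ndarray:
    """Per-cell CpG10 mask: covered with at least ``min_reads`` total reads."""
    return matrix.covered & (matrix.total >= min_reads)


def resolve_group_threshold(class_sizes, min_per_group="auto") -> int:
    """'auto' = ceil(min(class sizes) / 2); else the given count."""
    if min_per_group == "auto":
        return ceil(min(class_sizes) / 2)
    return int(min_per_group)


def group_presence_filter(matrix: MethCountMatrix, classes: pd.Series,
                          min_per_group="auto",
                          min_reads: int = 10) -> tuple[np.ndarray, int]:
    """Background mask: sites CpG10 in >= threshold samples of each class.

    ``classes`` maps sample id -> 'fertile'/'subfertile'. Returns (boolean
    site mask, resolved threshold).
    """
    labels = classes.reindex(matrix.samples)
    if labels.isna().any():
        missing = [s for s in matrix.samples if s not in classes.index]
        raise ValueError(f"samples without class labels: {missing}")
    groups = {}
    for cls in ("fertile", "subfertile"):
        idx = np.flatnonzero((labels == cls).to_numpy())
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} has zero samples")
        groups[cls] = idx
    thr = resolve_group_threshold([len(v) for v in groups.values()], min_per_group)
    cpg10 = coverage_filter(matrix, min_reads)
    keep = np.ones(matrix.n_sites, dtype=bool)
    for idx in groups.values():
        keep &= cpg10[:, idx].sum(axis=1) >= thr
    return keep, thr


def variant_mask_filter(sites: pd.DataFrame,
                        mask: set[tuple[str, int]]) -> np.ndarray:
    """Keep-mask for sites not co-localizing with a masked polymorphism.

    A CpG is removed if its C position or the paired G position (pos + 1) is
    in the mask — a polymorphism affecting either base of the dinucleotide
    disqualifies the site.
    """
    if not mask:
        return np.ones(len(sites), dtype=bool)
    keep = np.array([
        (c, int(p)) not in mask and (c, int(p) + 1) not in mask
        for c, p in zip(sites["chrom"], sites["pos"])
    ])
    return keep


def global_summary(matrix: MethCountMatrix, site_mask=None,
                   min_reads: int = 10) -> pd.DataFrame:
    """Per-sample mean methylation and hypo/intermediate/hyper fractions.

    Computed over CpG10 cells only. Hypomethylated is strict (< 20%),
    intermediate the closed interval [20%, 80%], hypermethylated strict
    (> 80%); the three fractions sum to 1. A sample with no CpG10 cell gets
    NaN summaries and ``defined=False`` rather than zeros.
    """
    cpg10 = coverage_filter(matrix, min_reads)
    if site_mask is not None:
        cpg10 = cpg10 & np.asarray(site_mask, dtype=bool)[:, None]
    pct = matrix.percentages()
    rows = []
    for j, sid in enumerate(matrix.samples):
        vals = pct[cpg10[:, j], j]
        if len(vals) == 0:
            rows.append((sid, 0, np.nan, np.nan, np.nan, np.nan, False))
            continue
        rows.append((
            sid, len(vals), float(vals.mean()),
            float((vals < 20).mean()),
            float(((vals >= 20) & (vals <= 80)).mean()),
            float((vals > 80).mean()),
            True,
        ))
    return pd.DataFrame(rows, columns=[
        "sample_id", "n_cpg10", "mean_methylation",
        "frac_hypo", "frac_intermediate", "frac_hyper", "defined",
    ])


def apply_filters(matrix: MethCountMatrix, classes: pd.Series,
                  variant_mask: set[tuple[str, int]] | None = None,
                  chrom_allowlist=None, min_reads: int = 10,
                  min_per_group="auto"):
    """Compose the retention rules into a background site set.

    Returns ``(site_mask, FilterReport, threshold)``. Removals are attributed
    to the first matching rule in the order: chromosome allow-list, variant
    mask, group presence; the surviving set is the intersection regardless of
    order.
    """
    n = matrix.n_sites
    keep_chrom = (matrix.sites["chrom"].isin(set(chrom_allowlist)).to_numpy()
                  if chrom_allowlist is not None else np.ones(n, dtype=bool))
    keep_var = variant_mask_filter(matrix.sites, variant_mask or set())
    keep_grp, thr = group_presence_filter(matrix, classes, min_per_group, min_reads)

    removed_scaffold = int((~keep_chrom).sum())
    removed_variant = int((keep_chrom & ~keep_var).sum())
    removed_group = int((keep_chrom & keep_var & ~keep_grp).sum())
    keep = keep_chrom & keep_var & keep_grp
    report = FilterReport(
        sites_in=n,
        removed_scaffold=removed_scaffold,
        removed_variant=removed_variant,
        removed_group_presence=removed_group,
        sites_out=int(keep.sum()),
    )
    return keep, report, thr
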