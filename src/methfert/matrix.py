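"""Per-CpG, per-sample methylation count matrix.

The matrix holds two integer count layers (methylated reads, total reads) plus
an explicit coverage mask: "not covered" is a first-class state, distinct from
covered-with-zero-methylation. Methylation percentages are always derived from
the counts (methylated x 100 / total) and never stored independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MethCountMatrix"]


@dataclass
class MethCountMatrix:
    """Sites x samples bisulfite read counts.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str) and ``pos`` (int, 1-based);
        one row per strand-merged CpG, unique within the matrix.
    samples
        Ordered sample identifiers (columns of the count layers).
    meth, total
        Integer arrays of shape ``(n_sites, n_samples)``; methylated and
        total read counts. Values at uncovered cells are 0 and ignored.
    covered
        Boolean array of the same shape; True where the sample has any
        read at the site.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    covered: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.covered is None:
            self.covered = self.total > 0
        self.covered = np.asarray(self.covered, dtype=bool)
        self.validate()

    # -- basic properties ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        shape = (self.n_sites, self.n_samples)
        for name, arr in (("meth", self.meth), ("total", self.total),
                          ("covered", self.covered)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if not {"chrom", "pos"}.issubset(self.sites.columns):
            raise ValueError("sites must have 'chrom' and 'pos' columns")
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in site table")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        cov = self.covered
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative read counts")
        if (self.meth[cov] > self.total[cov]).any():
            raise ValueError("methylated > total at a covered cell")
        if (self.total[cov] < 1).any():
            raise ValueError("covered cell with zero total reads")

    # -- derived layers -----------------------------------------------------

    def percentages(self) -> np.ndarray:
        """Methylation percentage per cell; NaN where not covered."""
        pct = np.full(self.meth.shape, np.nan)
        cov = self.covered
        pct[cov] = 100.0 * self.meth[cov] / self.total[cov]
        return pct

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def sample_indices(self, sample_ids) -> np.ndarray:
        return np.array([self.samples.index(s) for s in sample_ids], dtype=int)

    def site_lookup(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> row index."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.sites["chrom"], self.sites["pos"]))
        }

    def subset_sites(self, idx) -> "MethCountMatrix":
        idx = np.asarray(idx)
        return MethCountMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            meth=self.meth[idx],
            total=self.total[idx],
            covered=self.covered[idx],
        )

    def subset_samples(self, sample_ids) -> "MethCountMatrix":
        j = self.sample_indices(sample_ids)
        return MethCountMatrix(
            sites=self.sites.copy(),
            samples=list(sample_ids),
            meth=self.meth[:, j],
            total=self.total[:, j],
            covered=self.covered[:, j],
        )
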