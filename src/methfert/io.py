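"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are fixed at the boundary: everything internal is
1-based inclusive; BED input/output is converted on read/write (0-based
half-open). Counts are authoritative — a Bismark line whose stated percentage
disagrees with its counts is kept with the recomputed percentage and a
recorded warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MethCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_bismark_cov",
    "write_bismark_cov",
    "assemble_matrix",
    "read_intervals",
    "write_bed",
    "read_sample_sheet",
    "read_variant_mask",
    "write_variant_mask",
]


class ParseError(ValueError):
    """Malformed line in an input file; message carries the line number."""


def read_bismark_cov(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one Bismark coverage file into a per-sample count table.

    Expected columns (tab-separated, no header): chrom, start, end,
    methylation %, count methylated, count unmethylated; per-base records
    with start == end, 1-based. The percentage is recomputed from the counts;
    any line deviating by more than 0.05 points from its stated percentage is
    logged and the recomputed value kept.

    Returns a DataFrame with columns chrom, pos, meth, total. An empty file
    yields an empty table.
    """
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    totals: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, start_s, end_s, pct_s, m_s, u_s = parts
            try:
                start, end = int(start_s), int(end_s)
                m, u = int(m_s), int(u_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start != end:
                raise ParseError(f"{path}:{lineno}: start != end ({start} != {end})")
            if start < 1 or m < 0 or u < 0:
                raise ParseError(f"{path}:{lineno}: negative or zero-based value")
            total = m + u
            if total == 0:
                raise ParseError(f"{path}:{lineno}: zero total reads for a covered site")
            derived = 100.0 * m / total
            if abs(derived - pct) > 0.05:
                logger.warning(
                    "%s:%d: stated percentage %.3f deviates from counts (%.3f); "
                    "counts kept", path, lineno, pct, derived,
                )
            chroms.append(chrom)
            poss.append(start)
            meths.append(m)
            totals.append(total)
    df = pd.DataFrame({"chrom": chroms, "pos": poss, "meth": meths, "total": totals})
    if sample_id is not None:
        df.attrs["sample_id"] = sample_id
    return df


def write_bismark_cov(table: pd.DataFrame, path) -> None:
    """Write a per-sample count table as a Bismark coverage file."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            pct = 100.0 * row.meth / row.total
            unmeth = row.total - row.meth
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:g}\t{row.meth}\t{unmeth}\n")


def assemble_matrix(tables: dict[str, pd.DataFrame],
                    sample_sheet: pd.DataFrame) -> MethCountMatrix:
    """Union single-sample tables into a MethCountMatrix.

    The site universe is the union of all sites across samples; a site absent
    from a sample is marked not-covered. Site order is chromosome by first
    appearance across the inputs, position ascending within a chromosome.
    Every sample listed in the sheet must have a table.
    """
    sample_ids = list(sample_sheet["sample_id"])
    missing = [s for s in sample_ids if s not in tables]
    if missing:
        raise KeyError(f"samples in sheet without coverage tables: {missing}")

    chrom_order: dict[str, int] = {}
    for sid in sample_ids:
        t = tables[sid]
        if t.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError(f"duplicate (chrom, pos) within sample {sid}")
        for c in t["chrom"]:
            if c not in chrom_order:
                chrom_order[c] = len(chrom_order)

    all_sites = (
        pd.concat(
            [tables[s][["chrom", "pos"]] for s in sample_ids],
            ignore_index=True,
        )
        .drop_duplicates()
        .assign(_c=lambda d: d["chrom"].map(chrom_order))
        .sort_values(["_c", "pos"], kind="mergesort")
        .drop(columns="_c")
        .reset_index(drop=True)
    )
    index = {(c, int(p)): i for i, (c, p) in enumerate(zip(all_sites["chrom"], all_sites["pos"]))}

    n_sites, n_samples = len(all_sites), len(sample_ids)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    total = np.zeros((n_sites, n_samples), dtype=np.int64)
    covered = np.zeros((n_sites, n_samples), dtype=bool)
    for j, sid in enumerate(sample_ids):
        t = tables[sid]
        rows = np.fromiter(
            (index[(c, int(p))] for c, p in zip(t["chrom"], t["pos"])),
            dtype=int, count=len(t),
        )
        meth[rows, j] = t["meth"].to_numpy()
        total[rows, j] = t["total"].to_numpy()
        covered[rows, j] = True
    return MethCountMatrix(sites=all_sites, samples=sample_ids,
                           meth=meth, total=total, covered=covered)


def read_intervals(path, dialect: str = "bed") -> pd.DataFrame:
    """Read an interval table; normalize to 1-based inclusive coordinates.

    dialect "bed": 0-based half-open input; "one_based_tsv": already 1-based
    inclusive. Strand (column 6 for BED, column 4 otherwise) is kept when
    present. A zero-length interval after normalization is rejected.
    """
    if dialect not in ("bed", "one_based_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, s_s, e_s = parts[0], parts[1], parts[2]
            try:
                s, e = int(s_s), int(e_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if dialect == "bed":
                start, end = s + 1, e
            else:
                start, end = s, e
            if end < start:
                raise ParseError(
                    f"{path}:{lineno}: empty or inverted interval after normalization"
                )
            name = parts[3] if len(parts) > 3 else None
            strand = None
            if dialect == "bed" and len(parts) > 5 and parts[5] in "+-":
                strand = parts[5]
            elif dialect == "one_based_tsv" and len(parts) > 3 and parts[3] in "+-":
                strand, name = parts[3], None
            recs.append((chrom, start, end, name, strand))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name", "strand"])


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None,
              score_col: str | None = None) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            if name_col is not None:
                fields.append(str(row[name_col]))
            if score_col is not None:
                if name_col is None:
                    fields.append(".")
                fields.append(str(row[score_col]))
            fh.write("\t".join(fields) + "\n")


REQUIRED_SHEET_COLUMNS = ("sample_id", "fertility_class", "batch")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV with a mandatory header.

    Required columns: sample_id, fertility_class, batch; typical optional
    columns: center, age_months, n_ejaculates, corrected_nrr56, corrected_scr.
    """
    sheet = pd.read_csv(path)
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    bad = set(sheet["fertility_class"]) - {"fertile", "subfertile"}
    if bad:
        raise ValueError(f"unknown fertility classes: {sorted(bad)}")
    return sheet


def read_variant_mask(path) -> set[tuple[str, int]]:
    """Two-column chrom/pos (1-based) text file of masked positions."""
    mask: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom and pos")
            try:
                mask.add((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return mask


def write_variant_mask(mask, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in sorted(mask):
            fh.write(f"{chrom}\t{pos}\n")
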