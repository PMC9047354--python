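"""DMR calling, per-sample region means, and genomic annotation.

Differentially methylated regions are maximal runs of at least ``min_dmcs``
DMCs on one chromosome with consecutive inter-DMC distances of at most
``max_gap`` bp. Sites and regions are annotated against gene features
(TSS/promoter/TTS/UTRs/exon/intron/up- and downstream windows), CpG-island
context (island, shore, shelf, open sea) and repeats. Window sizes follow the
conventions of bovine sperm RRBS annotation: TSS +/-100 bp, promoter
-2000..-100 bp, TTS +/-100 bp, 10 kb up/downstream, 2 kb shores, 2 kb
shelves, and a 75% minimum overlap for assigning a region to a CGI context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WINDOWS",
    "AnnotationBundle",
    "call_dmrs",
    "dmr_sample_means",
    "annotate_site",
    "annotate_region",
    "annotate_sites",
    "enrichment",
]

#: Annotation window constants (bp except the overlap fraction).
DEFAULT_WINDOWS: dict[str, float] = {
    "tss": 100,              # TSS window: +/-100 bp around the TSS
    "promoter_near": 100,    # promoter: -2000..-100 bp upstream of the TSS
    "promoter_far": 2000,
    "tts": 100,              # TTS window: +/-100 bp around the TTS
    "upstream": 10_000,      # gene-assignment and upstream window
    "downstream": 10_000,
    "shore": 2000,           # up to 2 kb from a CGI
    "shelf": 2000,           # up to 2 kb from a shore
    "region_overlap_frac": 0.75,
}

GENE_FEATURE_PRECEDENCE = (
    "TSS", "promoter", "TTS", "5UTR", "3UTR",
    "exon", "intron", "upstream", "downstream", "intergenic",
)


@dataclass
class AnnotationBundle:
    """Gene models, CpG islands and repeats plus the window constants.

    ``genes`` needs columns gene_id, chrom, start, end, strand (1-based
    inclusive gene body; TSS = start on '+', end on '-'); ``exons``/``utr5``/
    ``utr3`` need gene_id, chrom, start, end; ``cgis`` chrom, start, end;
    ``repeats`` chrom, start, end, family.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    utr5: pd.DataFrame
    utr3: pd.DataFrame
    cgis: pd.DataFrame
    repeats: pd.DataFrame
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    _trees: dict = field(default_factory=dict, repr=False)

    def chromosomes(self) -> set[str]:
        out: set[str] = set()
        for df in (self.genes, self.cgis, self.repeats):
            out.update(df["chrom"].unique())
        return out

    # interval trees are built lazily per (table, chrom); 1-based inclusive
    # intervals are stored half-open as [start, end+1)
    def _tree(self, which: str, chrom: str) -> IntervalTree:
        key = (which, chrom)
        if key not in self._trees:
            df = getattr(self, which)
            sub = df[df["chrom"] == chrom]
            tree = IntervalTree()
            for row in sub.itertuples(index=False):
                tree.addi(int(row.start), int(row.end) + 1, row)
            self._trees[key] = tree
        return self._trees[key]


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(dmcs: pd.DataFrame, min_dmcs: int = 3, max_gap: int = 100) -> pd.DataFrame:
    """Merge DMCs into DMRs.

    A DMR is a maximal run of consecutive DMCs on one chromosome where each
    inter-DMC distance is <= ``max_gap`` bp (inclusive) and the run contains
    at least ``min_dmcs`` members. The DMR spans the first to the last member.

    ``dmcs`` needs columns chrom and pos; if a ``delta`` column is present the
    region direction is the sign of the mean member delta, and runs mixing
    hyper and hypo members are flagged ``mixed_direction``.
    """
    cols = ["chrom", "start", "end", "n_dmcs", "member_pos", "direction",
            "mean_delta", "mixed_direction"]
    if len(dmcs) == 0:
        return pd.DataFrame(columns=cols)
    df = dmcs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate DMC positions")
    records = []
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        deltas = grp["delta"].to_numpy() if "delta" in grp.columns else None
        run_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                run = slice(run_start, i)
                if i - run_start >= min_dmcs:
                    members = pos[run]
                    if deltas is not None:
                        d = deltas[run]
                        mean_delta = float(np.mean(d))
                        direction = "hyper" if mean_delta > 0 else "hypo"
                        mixed = bool((d > 0).any() and (d < 0).any())
                    else:
                        mean_delta, direction, mixed = np.nan, None, False
                    records.append((chrom, int(members[0]), int(members[-1]),
                                    len(members), list(map(int, members)),
                                    direction, mean_delta, mixed))
                run_start = i
    return pd.DataFrame(records, columns=cols)


def dmr_sample_means(dmr, matrix, min_reads: int = 10) -> pd.Series:
    """Per-sample unweighted mean methylation over a DMR's member CpGs.

    Only cells with CpG10 status (total >= ``min_reads``) contribute; a sample
    covering no member at that depth gets NaN (missing, not zero).
    """
    lookup = matrix.site_lookup()
    rows = [lookup[(dmr["chrom"], int(p))] for p in dmr["member_pos"]]
    pct = matrix.percentages()[rows]
    ok = matrix.total[rows] >= min_reads
    pct = np.where(ok, pct, np.nan)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column = missing
        means = np.nanmean(pct, axis=0)
    return pd.Series(means, index=matrix.samples)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _gene_windows(gene, w) -> dict[str, tuple[int, int]]:
    """Strand-aware feature windows for one gene (1-based inclusive)."""
    strand = gene.strand if gene.strand in ("+", "-") else "+"
    tss = gene.start if strand == "+" else gene.end
    tts = gene.end if strand == "+" else gene.start
    out = {
        "TSS": (tss - w["tss"], tss + w["tss"]),
        "TTS": (tts - w["tts"], tts + w["tts"]),
    }
    if strand == "+":
        out["promoter"] = (tss - w["promoter_far"], tss - w["promoter_near"])
        out["upstream"] = (tss - w["upstream"], tss - 1)
        out["downstream"] = (tts + 1, tts + w["downstream"])
    else:
        out["promoter"] = (tss + w["promoter_near"], tss + w["promoter_far"])
        out["upstream"] = (tss + 1, tss + w["upstream"])
        out["downstream"] = (tts - w["downstream"], tts - 1)
    return out


def _overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _gene_feature_label(chrom: str, start: int, end: int,
                        bundle: AnnotationBundle) -> tuple[str, list[str]]:
    """Feature label (by precedence) and assigned genes for an interval."""
    w = bundle.windows
    genes = bundle.genes[bundle.genes["chrom"] == chrom]
    hits: set[str] = set()
    assigned: list[str] = []
    for gene in genes.itertuples(index=False):
        if gene.strand not in ("+", "-"):
            logger.warning("gene %s unstranded; treated as '+'", gene.gene_id)
        # gene assignment: body +/- 10 kb
        if _overlap_len(start, end, gene.start - w["upstream"],
                        gene.end + w["downstream"]) > 0:
            assigned.append(gene.gene_id)
        gw = _gene_windows(gene, w)
        for label in ("TSS", "promoter", "TTS", "upstream", "downstream"):
            lo, hi = gw[label]
            if _overlap_len(start, end, lo, hi) > 0:
                hits.add(label)
        if _overlap_len(start, end, gene.start, gene.end) > 0:
            hits.add("intron")  # provisional; refined by exon/UTR below
    for which, label in (("utr5", "5UTR"), ("utr3", "3UTR"), ("exons", "exon")):
        tree = bundle._tree(which, chrom)
        if tree.overlap(start, end + 1):
            hits.add(label)
    for label in GENE_FEATURE_PRECEDENCE:
        if label in hits:
            return label, assigned
    return "intergenic", assigned


def _cgi_context_point(chrom: str, pos: int, bundle: AnnotationBundle) -> str:
    w = bundle.windows
    cgis = bundle.cgis[bundle.cgis["chrom"] == chrom]
    if len(cgis) == 0:
        return "open_sea"
    starts = cgis["start"].to_numpy()
    ends = cgis["end"].to_numpy()
    inside = (pos >= starts) & (pos <= ends)
    if inside.any():
        return "CGI"
    dist = np.minimum(np.abs(pos - starts), np.abs(pos - ends)).min()
    if dist <= w["shore"]:
        return "shore"
    if dist <= w["shore"] + w["shelf"]:
        return "shelf"
    return "open_sea"


def _band_overlap(start: int, end: int, cgis: pd.DataFrame, lo: int, hi: int) -> int:
    """Length of [start,end] within {pos: lo <= dist-to-CGI <= hi} (dist 0 = inside)."""
    length = end - start + 1
    covered = np.zeros(length, dtype=bool)
    positions = np.arange(start, end + 1)
    starts = cgis["start"].to_numpy()
    ends = cgis["end"].to_numpy()
    dist = np.full(length, np.inf)
    for s, e in zip(starts, ends):
        d = np.where(positions < s, s - positions,
                     np.where(positions > e, positions - e, 0))
        dist = np.minimum(dist, d)
    covered = (dist >= lo) & (dist <= hi)
    return int(covered.sum())


def _repeat_hit(chrom: str, start: int, end: int, bundle: AnnotationBundle):
    tree = bundle._tree("repeats", chrom)
    hits = tree.overlap(start, end + 1)
    if not hits:
        return False, None
    families = sorted({iv.data.family for iv in hits})
    return True, ",".join(families)


def annotate_site(chrom: str, pos: int, bundle: AnnotationBundle) -> dict:
    """Annotate one CpG position.

    Returns gene_feature (one label by precedence TSS > promoter > TTS >
    5'UTR > 3'UTR > exon > intron > upstream > downstream > intergenic),
    cgi_context (CGI > shore > shelf > open_sea by point membership),
    repeat_overlap (any overlap counts, whatever its extent), repeat_family,
    and genes (every gene whose body +/-10 kb contains the site).
    """
    if chrom not in bundle.chromosomes():
        logger.warning("chromosome %s absent from annotation; site %s:%d "
                       "labelled intergenic/open_sea", chrom, chrom, pos)
        return {"gene_feature": "intergenic", "cgi_context": "open_sea",
                "repeat_overlap": False, "repeat_family": None, "genes": []}
    feature, genes = _gene_feature_label(chrom, pos, pos, bundle)
    context = _cgi_context_point(chrom, pos, bundle)
    rep, fam = _repeat_hit(chrom, pos, pos, bundle)
    return {"gene_feature": feature, "cgi_context": context,
            "repeat_overlap": rep, "repeat_family": fam, "genes": genes}


def annotate_region(chrom: str, start: int, end: int,
                    bundle: AnnotationBundle) -> dict:
    """Annotate an interval.

    The CGI context requires at least ``region_overlap_frac`` (default 75%)
    of the region's length inside the island (resp. shore band, shelf band),
    with the same precedence as sites; gene features use any-overlap; repeat
    overlap counts whatever its extent.
    """
    if chrom not in bundle.chromosomes():
        return {"gene_feature": "intergenic", "cgi_context": "open_sea",
                "repeat_overlap": False, "repeat_family": None, "genes": []}
    w = bundle.windows
    feature, genes = _gene_feature_label(chrom, start, end, bundle)
    cgis = bundle.cgis[bundle.cgis["chrom"] == chrom]
    length = end - start + 1
    context = "open_sea"
    if len(cgis):
        frac_needed = w["region_overlap_frac"]
        shore, shelf = int(w["shore"]), int(w["shelf"])
        for label, lo, hi in (("CGI", 0, 0),
                              ("shore", 1, shore),
                              ("shelf", shore + 1, shore + shelf)):
            if _band_overlap(start, end, cgis, lo, hi) / length >= frac_needed:
                context = label
                break
    rep, fam = _repeat_hit(chrom, start, end, bundle)
    return {"gene_feature": feature, "cgi_context": context,
            "repeat_overlap": rep, "repeat_family": fam, "genes": genes}


def annotate_sites(sites: pd.DataFrame, bundle: AnnotationBundle) -> pd.DataFrame:
    """Annotate a table of sites (chrom, pos); returns appended columns."""
    rows = [annotate_site(c, int(p), bundle)
            for c, p in zip(sites["chrom"], sites["pos"])]
    ann = pd.DataFrame(rows, index=sites.index)
    ann["genes"] = ann["genes"].map(lambda g: ",".join(g))
    return pd.concat([sites.reset_index(drop=True),
                      ann.reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment(dmc_labels: pd.Series, background_labels: pd.Series) -> pd.DataFrame:
    """Category enrichment of DMC annotations against the background.

    For every category in the background universe: proportion among DMCs,
    proportion among background, fold-change (ratio), and a two-sided Fisher
    exact p from the 2x2 table of in/out-of-category counts. A category with
    zero background members yields an undefined (NaN) fold, reported rather
    than raised.
    """
    if len(background_labels) == 0:
        raise ValueError("empty background")
    n_dmc, n_bg = len(dmc_labels), len(background_labels)
    cats = sorted(set(background_labels) | set(dmc_labels))
    rows = []
    for cat in cats:
        a = int((dmc_labels == cat).sum())
        c = int((background_labels == cat).sum())
        p_dmc = a / n_dmc if n_dmc else np.nan
        p_bg = c / n_bg
        fold = p_dmc / p_bg if p_bg > 0 else np.nan
        _, pval = stats.fisher_exact([[a, n_dmc - a], [c, n_bg - c]],
                                     alternative="two-sided")
        rows.append((cat, a, c, p_dmc, p_bg, fold, pval))
    return pd.DataFrame(rows, columns=["category", "n_dmc", "n_background",
                                       "prop_dmc", "prop_background",
                                       "fold", "fisher_p"])
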