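"""Synthetic toy genomes, cohorts, AI records and bisulfite count matrices.

The generator emulates the structure of a two-class bull-sperm RRBS cohort:
two fertility classes (57 fertile vs 43 subfertile by default), ~20-25x mean
per-CpG coverage, a bimodal methylation landscape (about half of the CpGs
below 20% methylation, the low mode concentrated in CpG islands), logit-scale
inter-individual variability, planted differential sites with >=10-point
effects (mostly hypermethylated in the subfertile class, a minority
hypomethylated and spatially clustered), genotype-confounded CpGs whose
readout tracks an underlying 0/1/2 dosage, and missing coverage. Every site
is accounted for in a truth table so downstream recovery is testable.

Sampling model per sample s and site j::

    n_sj ~ NegBin(mean=cov_mean, Var=mean + cov_dispersion * mean^2),
           zeroed with probability missing_rate
    m_sj ~ Binomial(n_sj, p_sj),
    logit(p_sj) = logit(baseline_j) + a_s + delta_j * 1[s subfertile]

with a_s ~ Normal(0, indiv_sd^2) and delta_j the logit offset that moves the
baseline by +/- effect_delta percentage points on the probability scale.
Genotype-confounded sites ignore this model and emit ~100/50/0% methylation
by dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._seeds import child_seed
from .matrix import MethCountMatrix
from .regions import AnnotationBundle

logger = logging.getLogger(__name__)

__all__ = ["SimParams", "simulate_annotation", "simulate_methylation",
           "simulate_ai_records"]

PROB_CLIP = (0.01, 0.99)


@dataclass
class SimParams:
    """Study-condition parameters of the methylation simulator.

    Defaults mirror the emulated cohort: 57 fertile / 43 subfertile samples,
    ~23x mean coverage, a 50/50 mixture of ~5% and ~85% baseline methylation
    (grand mean ~46%, about half of sites hypomethylated), planted effects of
    15 percentage points at 1% of sites with 21% of them hypomethylated in
    the subfertile class, moderate logit-scale individual variability, 5%
    missing coverage and 1% genotype-confounded sites.
    """

    n_fertile: int = 57
    n_subfertile: int = 43
    n_cpg: int = 5000
    frac_dmc: float = 0.01
    effect_delta: float = 15.0          # percentage points
    frac_hypo_dmc: float = 0.21
    indiv_sd: float = 0.5               # logit scale
    cov_mean: float = 23.0              # reads
    cov_dispersion: float = 0.05        # Var = mu + phi * mu^2
    missing_rate: float = 0.05
    frac_variant_sites: float = 0.01
    baseline_mixture: tuple[float, float, float] = (0.05, 0.85, 0.5)
    seed: int = 0
    hypo_cluster_width: int = 1000      # bp span cap for planted hypo clusters
    variant_class_imbalance: float = 0.0  # allele-frequency shift between classes

    def validate(self) -> None:
        for name in ("frac_dmc", "frac_hypo_dmc", "missing_rate",
                     "frac_variant_sites"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        low, high, w = self.baseline_mixture
        if not (0 < low < 1 and 0 < high < 1 and 0 <= w <= 1):
            raise ValueError("baseline_mixture modes in (0,1), weight in [0,1]")
        if self.cov_mean <= 0:
            raise ValueError("cov_mean must be > 0")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if self.n_fertile < 1 or self.n_subfertile < 1:
            raise ValueError("both classes need at least one sample")
        if self.n_fertile + self.n_subfertile < 2:
            raise ValueError("need at least two samples in total")
        if self.indiv_sd < 0 or self.cov_dispersion < 0:
            raise ValueError("indiv_sd and cov_dispersion must be >= 0")


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def simulate_annotation(n_genes: int, genome_length: int = 1_000_000,
                        seed: int = 0, n_chroms: int = 2) -> AnnotationBundle:
    """Generate a toy annotated genome.

    Genes are placed without overlap, each with 2-5 exons, 5'/3' UTR spans
    and a strand; CpG islands are placed near half of the TSSs and at random
    intergenic spots; repeats fill random intervals with a few family labels.
    Deterministic for a fixed seed; raises after bounded retries if the
    genome is too short to place the requested genes.
    """
    rng = np.random.default_rng(child_seed(seed, "annotation"))
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    genes, exons, utr5, utr3, cgis, repeats = [], [], [], [], [], []

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in range(n_genes):
        length = int(rng.integers(5_000, 30_000))
        placed = False
        for _ in range(200):
            chrom = chroms[int(rng.integers(n_chroms))]
            start = int(rng.integers(1, max(2, genome_length - length)))
            end = start + length - 1
            if end > genome_length:
                continue
            if all(end < s - 1000 or start > e + 1000 for s, e in occupied[chrom]):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place gene {g} of length {length} in a genome of "
                f"{genome_length} bp after 200 retries; increase genome_length"
            )
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"GENE{g + 1}"
        genes.append((gid, chrom, start, end, strand))
        n_ex = int(rng.integers(2, 6))
        cuts = np.sort(rng.choice(np.arange(start, end), size=2 * n_ex, replace=False))
        for k in range(n_ex):
            exons.append((gid, chrom, int(cuts[2 * k]), int(cuts[2 * k + 1])))
        first = (gid, chrom, int(cuts[0]), int(cuts[1]))
        last = (gid, chrom, int(cuts[-2]), int(cuts[-1]))
        if strand == "+":
            utr5.append(first)
            utr3.append(last)
        else:
            utr5.append(last)
            utr3.append(first)
        if rng.random() < 0.5:  # CGI over the TSS for half the genes
            tss = start if strand == "+" else end
            half = int(rng.integers(200, 800))
            cgis.append((chrom, max(1, tss - half), min(genome_length, tss + half)))

    n_extra_cgi = max(2, n_genes // 2 + 2)
    for _ in range(n_extra_cgi):
        chrom = chroms[int(rng.integers(n_chroms))]
        start = int(rng.integers(1, genome_length - 2000))
        cgis.append((chrom, start, start + int(rng.integers(300, 1500))))

    families = ["L1", "BovB", "LTR", "tandem"]
    for _ in range(max(4, n_genes * 2)):
        chrom = chroms[int(rng.integers(n_chroms))]
        start = int(rng.integers(1, genome_length - 6000))
        repeats.append((chrom, start, start + int(rng.integers(200, 5000)),
                        families[int(rng.integers(len(families)))]))

    return AnnotationBundle(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
        utr5=pd.DataFrame(utr5, columns=["gene_id", "chrom", "start", "end"]),
        utr3=pd.DataFrame(utr3, columns=["gene_id", "chrom", "start", "end"]),
        cgis=pd.DataFrame(cgis, columns=["chrom", "start", "end"]),
        repeats=pd.DataFrame(repeats, columns=["chrom", "start", "end", "family"]),
    )


# ---------------------------------------------------------------------------
# methylation counts
# ---------------------------------------------------------------------------

def _place_sites(params: SimParams, annotation: AnnotationBundle,
                 rng: np.random.Generator, genome_length: int = 1_000_000):
    """CpG positions: dense inside islands, sparse elsewhere.

    Returns (sites DataFrame, in_island bool array).
    """
    chroms = sorted(annotation.chromosomes()) or ["chr1"]
    n_island = int(round(params.n_cpg * 0.4)) if len(annotation.cgis) else 0
    n_open = params.n_cpg - n_island
    recs: list[tuple[str, int, bool]] = []
    if n_island:
        cgi = annotation.cgis
        weights = (cgi["end"] - cgi["start"] + 1).to_numpy().astype(float)
        weights /= weights.sum()
        picks = rng.choice(len(cgi), size=n_island, p=weights)
        for i in picks:
            row = cgi.iloc[int(i)]
            pos = int(rng.integers(row["start"], row["end"] + 1))
            recs.append((row["chrom"], pos, True))
    for _ in range(n_open):
        chrom = chroms[int(rng.integers(len(chroms)))]
        recs.append((chrom, int(rng.integers(1, genome_length)), False))
    df = (pd.DataFrame(recs, columns=["chrom", "pos", "in_island"])
          .drop_duplicates(subset=["chrom", "pos"])
          .sort_values(["chrom", "pos"], kind="mergesort")
          .reset_index(drop=True))
    while len(df) < params.n_cpg:  # top up collisions deterministically
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, genome_length))
        if not ((df["chrom"] == chrom) & (df["pos"] == pos)).any():
            df.loc[len(df)] = (chrom, pos, False)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df, df["in_island"].to_numpy()


def _plant_dmcs(sites: pd.DataFrame, baseline: np.ndarray, params: SimParams,
                rng: np.random.Generator):
    """Choose planted DMC indices and directions.

    Sites are chosen so the full effect is realizable: a hyper DMC needs
    headroom above its baseline, a hypo DMC room below (otherwise the planted
    shift would be silently clipped into a sub-threshold effect). Hypo DMCs
    are grouped into spatial clusters no wider than ``hypo_cluster_width``
    bp; hyper DMCs are scattered. Returns (is_dmc, direction array of
    '' | 'hyper' | 'hypo', cluster ids).
    """
    n = len(sites)
    n_dmc = int(round(params.frac_dmc * n))
    n_hypo = int(round(params.frac_hypo_dmc * n_dmc))
    n_hyper = n_dmc - n_hypo
    is_dmc = np.zeros(n, dtype=bool)
    direction = np.array([""] * n, dtype=object)
    cluster = np.full(n, -1, dtype=int)

    delta_pp = params.effect_delta / 100.0
    hyper_ok = baseline <= PROB_CLIP[1] - delta_pp
    hypo_ok = baseline >= PROB_CLIP[0] + delta_pp

    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    order = np.arange(n)

    # hypo clusters: pick a feasible anchor, sweep right while within the cap
    remaining = n_hypo
    cluster_id = 0
    available = hypo_ok.copy()
    while remaining > 0 and available.any():
        anchor = int(rng.choice(order[available]))
        members = [anchor]
        j = anchor + 1
        while (j < n and chrom[j] == chrom[anchor]
               and pos[j] - pos[anchor] <= params.hypo_cluster_width
               and len(members) < max(2, remaining)):
            if available[j]:
                members.append(j)
            j += 1
        members = members[:remaining]
        for m in members:
            is_dmc[m] = True
            direction[m] = "hypo"
            cluster[m] = cluster_id
        # keep clusters apart so each stays within its own width cap
        available[max(0, anchor - 1):j] = False
        remaining -= len(members)
        cluster_id += 1
    if remaining > 0:
        logger.warning("only %d of %d hypo DMCs plantable under the baseline",
                       n_hypo - remaining, n_hypo)

    free = order[~is_dmc & hyper_ok]
    if len(free) < n_hyper:
        logger.warning("only %d of %d hyper DMCs plantable under the baseline",
                       len(free), n_hyper)
    hyper_idx = rng.choice(free, size=min(n_hyper, len(free)), replace=False)
    is_dmc[hyper_idx] = True
    direction[hyper_idx] = "hyper"
    return is_dmc, direction, cluster


def simulate_methylation(params: SimParams, annotation: AnnotationBundle,
                         seed: int | None = None,
                         genome_length: int = 1_000_000):
    """Simulate a MethCountMatrix and its TruthTable.

    Returns ``(matrix, truth, sample_sheet)``; ``truth`` has one row per
    simulated site with is_planted_dmc, planted_direction, is_variant_site
    and true_baseline; ``sample_sheet`` carries sample_id, fertility_class,
    center and batch labels.
    """
    params.validate()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(child_seed(seed, "methylation"))

    sites, in_island = _place_sites(params, annotation, rng, genome_length)
    n_sites = len(sites)
    n_samples = params.n_fertile + params.n_subfertile
    is_sub = np.zeros(n_samples, dtype=bool)
    is_sub[params.n_fertile:] = True
    sample_ids = ([f"F{i + 1:03d}" for i in range(params.n_fertile)]
                  + [f"S{i + 1:03d}" for i in range(params.n_subfertile)])

    # baseline: two-mode mixture; the low mode is concentrated inside islands
    # while the marginal low-mode weight stays at w_low
    low, high, w_low = params.baseline_mixture
    f_isl = float(in_island.mean())
    if 0.0 < f_isl < 1.0:
        p_isl = min(1.0, w_low + 0.35)
        p_out = np.clip((w_low - f_isl * p_isl) / (1.0 - f_isl), 0.0, 1.0)
        if p_out == 0.0:  # tilt saturated; renormalize the island side
            p_isl = w_low / f_isl
        p_low = np.where(in_island, p_isl, p_out)
    else:
        p_low = np.full(n_sites, w_low)
    low_mode = rng.random(n_sites) < p_low
    jitter = rng.normal(0.0, 0.015, size=n_sites)
    baseline = np.where(low_mode, low, high) + jitter
    baseline = np.clip(baseline, PROB_CLIP[0], PROB_CLIP[1])

    is_dmc, direction, cluster = _plant_dmcs(sites, baseline, params, rng)

    # planted effect: move the subfertile-class probability by effect_delta
    # points on the percentage scale, realized as a per-site logit offset
    delta_pp = params.effect_delta / 100.0
    target = baseline.copy()
    target[direction == "hyper"] = baseline[direction == "hyper"] + delta_pp
    target[direction == "hypo"] = baseline[direction == "hypo"] - delta_pp
    clipped = (target < PROB_CLIP[0]) | (target > PROB_CLIP[1])
    if clipped[is_dmc].any():
        logger.warning("%d planted effects clipped to [%g, %g]",
                       int(clipped[is_dmc].sum()), *PROB_CLIP)
    target = np.clip(target, PROB_CLIP[0], PROB_CLIP[1])
    logit_offset = np.where(is_dmc, logit(target) - logit(baseline), 0.0)

    # genotype-confounded sites
    n_var = int(round(params.frac_variant_sites * n_sites))
    variant_idx = rng.choice(np.flatnonzero(~is_dmc), size=min(n_var, int((~is_dmc).sum())),
                             replace=False) if n_var else np.array([], dtype=int)
    is_variant = np.zeros(n_sites, dtype=bool)
    is_variant[variant_idx] = True

    # individual effects (logit scale)
    a = rng.normal(0.0, params.indiv_sd, size=n_samples) if params.indiv_sd > 0 \
        else np.zeros(n_samples)

    # coverage: NegBin(mean, Var = mu + phi mu^2) via gamma-Poisson
    mu = params.cov_mean
    phi = params.cov_dispersion
    if phi > 0:
        shape = 1.0 / phi
        lam = rng.gamma(shape, mu / shape, size=(n_sites, n_samples))
        total = rng.poisson(lam)
    else:
        total = rng.poisson(mu, size=(n_sites, n_samples))
    if params.missing_rate > 0:
        total[rng.random((n_sites, n_samples)) < params.missing_rate] = 0

    # success probabilities
    base_logit = logit(baseline)[:, None]
    p = expit(base_logit + a[None, :] + logit_offset[:, None] * is_sub[None, :])

    # variant readout: dosage 0/1/2 -> ~100/50/0% methylation
    if len(variant_idx):
        af = rng.uniform(0.2, 0.8, size=len(variant_idx))
        shift = params.variant_class_imbalance
        af_by_class = np.stack([np.clip(af - shift / 2, 0.02, 0.98),
                                np.clip(af + shift / 2, 0.02, 0.98)])
        for k, site in enumerate(variant_idx):
            freqs = af_by_class[is_sub.astype(int), k]
            dosage = rng.binomial(2, freqs)
            p[site] = np.clip(1.0 - dosage / 2.0, 0.02, 0.98)

    meth = rng.binomial(total, p)
    covered = total > 0
    matrix = MethCountMatrix(sites=sites[["chrom", "pos"]].copy(),
                             samples=sample_ids, meth=meth, total=total,
                             covered=covered)

    truth = sites[["chrom", "pos"]].copy()
    truth["is_planted_dmc"] = is_dmc
    truth["planted_direction"] = [d if d else None for d in direction]
    truth["hypo_cluster_id"] = cluster
    truth["is_variant_site"] = is_variant
    truth["true_baseline"] = baseline
    truth["in_island"] = in_island

    centers = rng.integers(1, 3, size=n_samples)
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "fertility_class": np.where(is_sub, "subfertile", "fertile"),
        "center": centers,
        "batch": [f"b{1 + i % 7}" for i in range(n_samples)],
        "age_months": rng.integers(17, 20, size=n_samples),
        "n_ejaculates": rng.integers(2, 6, size=n_samples),
    })
    return matrix, truth, sheet


# ---------------------------------------------------------------------------
# AI records
# ---------------------------------------------------------------------------

DEFAULT_FIXED_EFFECTS = {
    "herd_year": (40, 0.02),
    "month_year": (24, 0.01),
    "parity": (5, 0.01),
    "interval_class": (4, 0.01),
    "weekday": (7, 0.005),
    "technician": (30, 0.01),
    "semen_category": (2, 0.01),
}


def simulate_ai_records(n_bulls: int, ai_per_bull: int, bull_sd: float = 0.03,
                        fixed_effect_spec: dict | None = None,
                        base_rate: float = 0.68, seed: int = 0):
    """Simulate binary 56-day non-return records.

    Each record's success probability is ``base_rate + bull effect + sampled
    fixed effects`` (linear on the probability scale, clipped to (0,1));
    fixed-effect levels are assigned uniformly per record. Returns
    ``(records, true_effects)`` where ``true_effects`` maps bull id to the
    sampled bull effect.
    """
    if n_bulls < 2:
        raise ValueError("need at least 2 bulls")
    if ai_per_bull < 1:
        raise ValueError("ai_per_bull must be >= 1")
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must be in (0,1)")
    spec = DEFAULT_FIXED_EFFECTS if fixed_effect_spec is None else fixed_effect_spec
    rng = np.random.default_rng(child_seed(seed, "ai_records"))

    bull_ids = [f"bull{i + 1:03d}" for i in range(n_bulls)]
    effects = rng.normal(0.0, bull_sd, size=n_bulls) if bull_sd > 0 \
        else np.zeros(n_bulls)
    level_effects = {
        name: (rng.normal(0.0, sd, size=k) if sd > 0 else np.zeros(k))
        for name, (k, sd) in spec.items()
    }

    n = n_bulls * ai_per_bull
    bull_col = np.repeat(np.arange(n_bulls), ai_per_bull)
    prob = base_rate + effects[bull_col]
    data = {"bull_id": np.array(bull_ids)[bull_col],
            "cow_id": [f"cow{i + 1:06d}" for i in range(n)]}
    for name, (k, _) in spec.items():
        lv = rng.integers(0, k, size=n)
        data[name] = lv
        prob = prob + level_effects[name][lv]
    prob = np.clip(prob, 1e-6, 1 - 1e-6)
    data["score"] = rng.binomial(1, prob)
    records = pd.DataFrame(data)
    true_effects = pd.Series(effects, index=bull_ids, name="true_effect")
    return records, true_effects
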