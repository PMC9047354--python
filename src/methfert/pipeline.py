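"""End-to-end orchestration: simulate -> filter -> dmc -> dmr -> annotate -> classify.

A single resolved configuration drives all stages; every threshold actually
used is logged and serialized verbatim into the output manifest together
with a SHA-256 hash of every file written, so a re-run with the same config
and seed reproduces identical hashes. Each stage draws its randomness from a
child seed derived from the top-level seed and the stage name, so one stage
re-run in isolation matches the full run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import classify as cl
from . import diffmeth, io, regions, sitefilter, synth
from ._seeds import child_seed

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline"]

ALL_STAGES = ("simulate", "filter", "dmc", "dmr", "annotate", "classify")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "min_reads": 10,
    "min_per_group": "auto",
    "test": "pooled",
    "q_threshold": None,          # None -> per-test default (0.01 / 0.1)
    "diff_threshold": 10.0,
    "dmr_min_dmcs": 3,
    "dmr_max_gap": 100,
    "n_trees": 500,
    "iterations": 50,
    "train_frac": 2 / 3,
    "feature_policy": "complete_only",
    "chrom_allowlist": None,
    "annotation": {"n_genes": 8, "genome_length": 1_000_000},
    "simulate_params": {},        # overrides for synth.SimParams fields
    "inputs": {},                 # paths when the simulate stage is disabled
}


def resolve_config(config: dict | None) -> dict:
    resolved = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in resolved:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(resolved[key], dict) and isinstance(value, dict):
            resolved[key].update(value)
        else:
            resolved[key] = value
    unknown = set(resolved["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    return resolved


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: dict):
    paths = cfg["inputs"]
    sheet = io.read_sample_sheet(paths["sample_sheet"])
    cov_dir = Path(paths["coverage_dir"])
    tables = {sid: io.read_bismark_cov(cov_dir / f"{sid}.cov", sid)
              for sid in sheet["sample_id"]}
    matrix = io.assemble_matrix(tables, sheet)
    mask = (io.read_variant_mask(paths["variant_mask"])
            if "variant_mask" in paths else set())
    return matrix, sheet, mask


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run the configured stages; write outputs and a manifest to ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``). A stage
    failure halts the run: partial outputs stay in place, a ``failed``
    marker file names the failing stage, and the exception propagates.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    written: list[Path] = []
    results: dict = {}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    state: dict = {}
    current = None
    try:
        if "simulate" in stages:
            current = "simulate"
            ann = synth.simulate_annotation(seed=seed, **cfg["annotation"])
            params = synth.SimParams(seed=seed, **cfg["simulate_params"])
            matrix, truth, sheet = synth.simulate_methylation(
                params, ann, seed=seed,
                genome_length=cfg["annotation"]["genome_length"])
            mask = {
                (c, int(p))
                for c, p in truth.loc[truth["is_variant_site"], ["chrom", "pos"]]
                .itertuples(index=False)
            }
            state.update(matrix=matrix, sheet=sheet, mask=mask, truth=truth,
                         annotation=ann)
            for j, sid in enumerate(matrix.samples):
                cov = matrix.covered[:, j]
                table = pd.DataFrame({
                    "chrom": matrix.sites["chrom"][cov],
                    "pos": matrix.sites["pos"][cov],
                    "meth": matrix.meth[cov, j],
                    "total": matrix.total[cov, j],
                })
                emit(f"{sid}.cov", lambda p, t=table: io.write_bismark_cov(t, p))
            emit("sample_sheet.csv", lambda p: sheet.to_csv(p, index=False))
            emit("truth.tsv", lambda p: truth.to_csv(p, sep="\t", index=False))
            emit("variant_mask.tsv", lambda p: io.write_variant_mask(mask, p))
            emit("cgi.bed", lambda p: io.write_bed(ann.cgis, p))
            emit("repeats.bed", lambda p: io.write_bed(ann.repeats, p, name_col="family"))
        elif any(s in stages for s in ("filter", "dmc", "dmr", "classify")):
            current = "load"
            matrix, sheet, mask = _load_inputs(cfg)
            state.update(matrix=matrix, sheet=sheet, mask=mask)

        if "filter" in stages:
            current = "filter"
            matrix, sheet, mask = state["matrix"], state["sheet"], state["mask"]
            classes = sheet.set_index("sample_id")["fertility_class"]
            keep, report, thr = sitefilter.apply_filters(
                matrix, classes, variant_mask=mask,
                chrom_allowlist=cfg["chrom_allowlist"],
                min_reads=cfg["min_reads"], min_per_group=cfg["min_per_group"])
            logger.info("filter: min_reads=%d group threshold=%d -> %d/%d sites",
                        cfg["min_reads"], thr, report.sites_out, report.sites_in)
            background = matrix.subset_sites(keep.nonzero()[0])
            state.update(background=background, classes=classes,
                         group_threshold=thr)
            results["filter_report"] = {**report.to_dict(),
                                        "group_threshold": thr}
            emit("filter_report.json",
                 lambda p: p.write_text(json.dumps(results["filter_report"],
                                                   indent=2)))
            summary = sitefilter.global_summary(matrix, min_reads=cfg["min_reads"])
            emit("global_summary.tsv",
                 lambda p: summary.to_csv(p, sep="\t", index=False))

        if "dmc" in stages:
            current = "dmc"
            dmcs = diffmeth.call_dmcs(
                state["background"], state["classes"], test=cfg["test"],
                q_threshold=cfg["q_threshold"],
                diff_threshold=cfg["diff_threshold"],
                min_reads=cfg["min_reads"])
            logger.info("dmc: test=%s q<%s |delta|>=%s -> %d DMCs", cfg["test"],
                        cfg["q_threshold"] or diffmeth.DEFAULT_Q[cfg["test"]],
                        cfg["diff_threshold"], len(dmcs))
            state["dmcs"] = dmcs
            emit("dmcs.tsv", lambda p: dmcs.to_csv(p, sep="\t", index=False))
            bed = dmcs.assign(start=dmcs["pos"], end=dmcs["pos"])
            emit("dmcs.bed", lambda p: io.write_bed(bed, p, score_col="q"))

        if "dmr" in stages:
            current = "dmr"
            dmrs = regions.call_dmrs(state["dmcs"],
                                     min_dmcs=cfg["dmr_min_dmcs"],
                                     max_gap=cfg["dmr_max_gap"])
            state["dmrs"] = dmrs
            if len(dmrs):
                means = pd.DataFrame([
                    regions.dmr_sample_means(row, state["matrix"],
                                             cfg["min_reads"])
                    for _, row in dmrs.iterrows()
                ])
                emit("dmr_sample_means.tsv",
                     lambda p: means.to_csv(p, sep="\t"))
            out = dmrs.drop(columns=["member_pos"], errors="ignore")
            emit("dmrs.tsv", lambda p: out.to_csv(p, sep="\t", index=False))
            if len(dmrs):
                emit("dmrs.bed", lambda p: io.write_bed(dmrs, p))

        if "annotate" in stages and "annotation" in state:
            current = "annotate"
            ann = state["annotation"]
            if "dmcs" in state and len(state["dmcs"]):
                annotated = regions.annotate_sites(
                    state["dmcs"][["chrom", "pos"]], ann)
                annotated = pd.concat(
                    [state["dmcs"].reset_index(drop=True),
                     annotated.drop(columns=["chrom", "pos"])], axis=1)
                emit("dmcs_annotated.tsv",
                     lambda p: annotated.to_csv(p, sep="\t", index=False))
            if "dmrs" in state and len(state["dmrs"]):
                rows = [regions.annotate_region(r["chrom"], r["start"], r["end"], ann)
                        for _, r in state["dmrs"].iterrows()]
                dmr_ann = pd.concat(
                    [state["dmrs"].drop(columns=["member_pos"]),
                     pd.DataFrame(rows).assign(
                         genes=lambda d: d["genes"].map(",".join))],
                    axis=1)
                emit("dmrs_annotated.tsv",
                     lambda p: dmr_ann.to_csv(p, sep="\t", index=False))

        if "classify" in stages:
            current = "classify"
            if len(state["dmcs"]) == 0:
                raise RuntimeError("no DMCs available for classification")
            feats = cl.prepare_features(
                state["matrix"], state["dmcs"], policy=cfg["feature_policy"],
                min_reads=cfg["min_reads"],
                seed=child_seed(seed, "features"))
            labels = state["classes"].reindex(feats.index)
            summary = cl.crossvalidate_resampled(
                feats, labels, iterations=cfg["iterations"],
                train_frac=cfg["train_frac"],
                seed=child_seed(seed, "classify"),
                n_trees=cfg["n_trees"])
            results["model_report"] = {
                k: v for k, v in summary.items() if k != "reports"}
            emit("model_report.json",
                 lambda p: p.write_text(json.dumps(results["model_report"],
                                                   indent=2)))
    except Exception:
        (outdir / "failed").write_text(f"failed stage: {current}\n")
        raise

    manifest = {
        "config": _jsonable(cfg),
        "stages_run": stages,
        "outputs": {p.name: _sha256(p) for p in written},
        "results": {k: v for k, v in results.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
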