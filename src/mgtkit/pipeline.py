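"""End-to-end orchestration: simulate -> windows -> quantify -> DEG ->
multivariate -> cross-species -> gene-PROMPT concordance -> qPCR validation.

A run is driven by a :class:`RunConfig` (flat key=value file or keyword
arguments), executes the enabled stages in dependency order inside one
output directory, and finishes by writing ``manifest.json`` listing every
output file with a SHA-256 checksum and row count. Reruns with the same
configuration and seed reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import build_prompt_regions, parse_gtf, write_modified_gtf, write_regions
from .cross_species import OrthologMap, best_match, build_signatures, correlate_with_panel
from .diffexpr import COMPARISONS, partition_subtypes, summarize_degs, test_differential
from .multivariate import hcluster, pca, spearman_pairs, zscore_rows
from .prompt_corr import classify_pairs, prompt_fold_changes
from .quantify import ExpressionMatrix, count_fragments, features_from_regions, read_fragments
from .simulate import SimulationConfig, simulate_all
from .validation import validate_genes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "regions", "quantify", "deg", "multivariate",
          "xspecies", "promptcorr", "validate")

STAGE_DEPS = {
    "regions": ("simulate",),
    "quantify": ("simulate", "regions"),
    "deg": ("simulate",),
    "multivariate": ("simulate", "deg"),
    "xspecies": ("simulate", "deg"),
    "promptcorr": ("simulate", "regions", "quantify", "deg"),
    "validate": ("simulate",),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Thresholds, toggles, and paths of one pipeline run.

    Threshold defaults are the emulated study's analysis constants:
    2-fold gate, p < 0.01, 1500 bp window, 2-fold PROMPT gate.
    """

    outdir: str = "mgt_run"
    seed: int = 0
    fc: float = 2.0
    alpha: float = 0.01
    prompt_fc: float = 2.0
    window: int = 1500
    min_mean_count: float = 5.0
    eps: float = 0.1
    test: str = "moderated"
    exclusion: str = "both-strands"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        for v, name in ((self.fc, "fc"), (self.alpha, "alpha"), (self.prompt_fc, "prompt_fc"),
                        (self.window, "window"), (self.min_mean_count, "min_mean_count")):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        self.sim = self.sim.with_seed(self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` text file; unknown keys are errors.

        Keys matching a SimulationConfig field are routed there; stage
        toggles are ``stage.<name> = true|false``.
        """
        run_kwargs: dict = {}
        sim_kwargs: dict = {}
        stages = {s: True for s in STAGES}
        run_fields = {f.name: f for f in fields(cls) if f.name not in ("stages", "sim")}
        sim_fields = {f.name: f for f in fields(SimulationConfig)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (t.strip() for t in line.split("=", 1))
                if key.startswith("stage."):
                    name = key[len("stage."):]
                    if name not in STAGES:
                        raise ValueError(f"{path}:{lineno}: unknown stage {name!r}")
                    stages[name] = value.lower() in ("1", "true", "yes", "on")
                elif key in run_fields:
                    run_kwargs[key] = _coerce(value, run_fields[key].type)
                elif key in sim_fields:
                    sim_kwargs[key] = _coerce(value, sim_fields[key].type)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(stages=stages, sim=SimulationConfig(**sim_kwargs), **run_kwargs)


def _coerce(value: str, annot) -> object:
    annot = str(annot)
    if "int" in annot and "tuple" not in annot:
        return int(value)
    if "float" in annot:
        return float(value)
    if "tuple" in annot:
        parts = [p.strip() for p in value.split(",")]
        return tuple(float(p) if "." in p else int(p) for p in parts)
    return value


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rows(path: Path) -> int:
    try:
        with open(path) as fh:
            return sum(1 for _ in fh)
    except UnicodeDecodeError:
        return -1


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    A disabled prerequisite raises :class:`PipelineError` before any work;
    a stage failure writes a ``FAILED`` marker naming the stage and
    re-raises, keeping partial outputs on disk for inspection.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s\t%(name)s\t%(message)s"))
    root = logging.getLogger("mgtkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    enabled = [s for s in STAGES if config.stages.get(s, True)]
    for s in enabled:
        missing = [d for d in STAGE_DEPS.get(s, ()) if d not in enabled]
        if missing:
            raise PipelineError(f"stage {s!r} requires disabled stage(s): {missing}")

    manifest: dict = {"seed": config.seed, "mgtkit_version": __version__,
                      "stages": enabled, "outputs": {}}
    outputs = manifest["outputs"]
    state: dict = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = {"path": path.name, "sha256": _sha256(path), "rows": _rows(path)}

    current = "setup"
    try:
        if "simulate" in enabled:
            current = "simulate"
            paths = simulate_all(config.sim, outdir)
            for name, p in paths.items():
                record(name, p)
            state["paths"] = paths

        if "regions" in enabled:
            current = "regions"
            genes = parse_gtf(state["paths"]["annotation_gtf"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                regions = build_prompt_regions(genes, window=config.window, exclusion=config.exclusion)
            bed = outdir / "prompt_regions.bed"
            gtf = outdir / "prompt_regions.gtf"
            write_regions(regions, bed)
            write_modified_gtf(regions, gtf)
            record("prompt_regions_bed", bed)
            record("prompt_regions_gtf", gtf)
            state["regions"] = regions

        if "quantify" in enabled:
            current = "quantify"
            fragments = read_fragments(state["paths"]["fragments_bed"])
            meta = pd.read_csv(state["paths"]["meta_tsv"], sep="\t", index_col=0)
            counts = count_fragments(features_from_regions(state["regions"]), fragments,
                                     strand_mode="ignore", samples=list(meta.index))
            p = outdir / "prompt_counts.tsv"
            counts.rename_axis("gene_id").to_csv(p, sep="\t")
            record("prompt_counts_tsv", p)
            state["prompt_counts"] = counts
            state["meta"] = meta

        if "deg" in enabled:
            current = "deg"
            matrix = ExpressionMatrix.read(state["paths"]["fpkm_tsv"], state["paths"]["meta_tsv"])
            state["matrix"] = matrix
            records = {}
            for comp in COMPARISONS:
                rec = test_differential(matrix, comp, test=config.test, eps=config.eps,
                                        fc=config.fc, alpha=config.alpha, seed=config.seed)
                records[comp] = rec
                p = outdir / f"deg_{comp}.tsv"
                rec.to_csv(p, sep="\t", index=False)
                record(f"deg_{comp}_tsv", p)
            partition = partition_subtypes({c: records[c] for c in COMPARISONS if c != "overall"})
            venn = outdir / "venn_cells.tsv"
            partition.to_frame().to_csv(venn, sep="\t", index=False)
            record("venn_cells_tsv", venn)
            top = outdir / "top_degs.tsv"
            summarize_degs(pd.concat(records.values(), ignore_index=True)).to_csv(top, sep="\t", index=False)
            record("top_degs_tsv", top)
            state["deg"] = records
            state["partition"] = partition

        if "multivariate" in enabled:
            current = "multivariate"
            matrix = state["matrix"]
            import numpy as np
            logx = np.log2(matrix.values + config.eps)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tree = hcluster(logx)
                pc = pca(logx)
            nwk = outdir / "sample_tree.newick"
            nwk.write_text(tree.to_newick() + "\n")
            record("sample_tree_newick", nwk)
            p = outdir / "pca_scores.tsv"
            pc.scores.join(matrix.meta).rename_axis("sample_id").to_csv(p, sep="\t")
            record("pca_scores_tsv", p)
            pv = outdir / "pca_variance.tsv"
            pc.summary().to_csv(pv, sep="\t", index=False)
            record("pca_variance_tsv", pv)
            # per-subtype mean log2 profiles over genes passing anywhere
            union = sorted(set().union(*(set(r.loc[r["passes"], "gene_id"]) for r in state["deg"].values())))
            if len(union) >= 3:
                profiles = pd.DataFrame({
                    st: logx.loc[union, matrix.samples(condition="tumor", subtype=st)].mean(axis=1)
                    for st in sorted(config.sim.n_animals_per_subtype)})
                rho, _ = spearman_pairs(profiles)
                ps = outdir / "subtype_spearman.tsv"
                rho.rename_axis("subtype").to_csv(ps, sep="\t")
                record("subtype_spearman_tsv", ps)

        if "xspecies" in enabled:
            current = "xspecies"
            orthologs = OrthologMap.read(state["paths"]["orthologs_tsv"])
            panel = pd.read_csv(state["paths"]["human_panel_tsv"], sep="\t", index_col=0)
            signatures = build_signatures(state["partition"], state["matrix"], eps=config.eps)
            frames = []
            for st, sig in signatures.items():
                if sig.size >= 3:
                    out = correlate_with_panel(sig, orthologs, panel, eps=config.eps)
                    if not out.empty:
                        frames.append(out)
            xs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
                columns=["canine_subtype", "human_subtype", "r", "p", "n"])
            p = outdir / "cross_species.tsv"
            xs.to_csv(p, sep="\t", index=False)
            record("cross_species_tsv", p)
            state["xspecies"] = xs

        if "promptcorr" in enabled:
            current = "promptcorr"
            fcs = prompt_fold_changes(state["prompt_counts"], state["meta"], eps=config.eps)
            pairs, summary = classify_pairs(
                state["deg"]["overall"], fcs, min_mean_count=config.min_mean_count,
                fc=config.fc, alpha=config.alpha, prompt_fc=config.prompt_fc)
            pp = outdir / "prompt_pairs.tsv"
            pairs.to_csv(pp, sep="\t", index=False)
            record("prompt_pairs_tsv", pp)
            ps = outdir / "prompt_summary.json"
            ps.write_text(json.dumps(summary, indent=1, allow_nan=True) + "\n")
            record("prompt_summary_json", ps)
            state["prompt_summary"] = summary

        if "validate" in enabled:
            current = "validate"
            qpcr = pd.read_csv(state["paths"]["qpcr_tsv"], sep="\t")
            res = validate_genes(qpcr, seed=config.seed)
            p = outdir / "validation.tsv"
            res.to_csv(p, sep="\t", index=False)
            record("validation_tsv", p)
            state["validation"] = res
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    root.removeHandler(handler)
    handler.close()
    record("run_log", log_path)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
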