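"""End-to-end orchestration of the serial-biopsy analysis workflow.

One configuration drives the whole study graph: (simulate or load inputs)
-> probe collapse + print-batch residualization -> paired time-point
contrasts (T1 vs T2; T1 vs TS in residual disease) -> responder contrasts
(T1, T2, T2-T1) -> subtype calls and paired concordance -> RFS screens
(T1, TS, TS-T1) -> gene-set overrepresentation per significant set -> a
JSON summary holding every cohort-level count (significant features per
contrast with up/down split, concordance rates, transition tables, overlap
of outcome gene sets), plus per-stage TSV tables.

Every number in the summary is computed by the stage functions themselves;
re-running with the same configuration and seed reproduces the outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .datamodel import CentroidPanel, ExpressionMatrix, GeneSetCollection
from .enrich import enrich_all
from .normalize import collapse_probes, residualize_batch
from .permtest import DEResult, run_contrast
from .simulate import CohortTruth, SimConfig, simulate_cohort, truth_eval
from .subtype import assign_subtypes, concordance, paired_calls
from .survival import rfs_screen_matrix, screen_rfs

DE_CONTRASTS = ("t1_vs_t2", "t1_vs_ts", "rcb_t1", "rcb_t2", "rcb_delta_t2")
RFS_MODES = ("t1", "ts", "delta_ts")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one full run.

    Either ``sim`` (a :class:`SimConfig`) or the four input paths must be
    given.  Thresholds default to the study's: adjusted p < 0.05 for
    time-point contrasts, raw p < 0.005 for outcome contrasts, enrichment
    p < 0.05.
    """

    sim: SimConfig | None = None
    expr_path: str | None = None
    meta_path: str | None = None
    centroids_path: str | None = None
    gmt_path: str | None = None
    probe_map_path: str | None = None
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    raw_alpha: float = 0.005
    enrich_alpha: float = 0.05
    metric: str = "spearman"
    min_genes: int = 30
    adjust_hr: bool = False
    collapse_first: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            for key in ("prolif_genes", "immune_genes", "response_genes", "hazard_genes",
                        "subtype_labels", "subtype_proportions"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = SimConfig(**sim_raw)
        return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Index):
        return [str(v) for v in obj]
    return obj


def _write_de_tsv(result: DEResult, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# contrast: {result.contrast}\n")
        fh.write(f"# threshold_rule: {result.threshold_rule}\n")
        fh.write(f"# alpha: {result.alpha}\n")
        fh.write(f"# n_perm: {result.n_perm}\n")
        fh.write(f"# exhaustive: {result.exhaustive}\n")
        fh.write(f"# seed: {result.seed}\n")
        table = result.table.copy()
        table.index.name = "feature_id"
        table.to_csv(fh, sep="\t", na_rep="NA")


def _load_inputs(config: PipelineConfig, out_dir: Path | None):
    if config.sim is not None:
        expr, meta, truth = simulate_cohort(config.sim)
        panel = truth.centroid_panel
        gmt = GeneSetCollection(
            {
                "PROLIFERATION": truth.prolif_genes,
                "IMMUNE": truth.immune_genes,
                "RESPONSE": truth.response_genes,
                "HAZARD": truth.hazard_genes,
            },
            {
                "PROLIFERATION": "planted proliferation genes (synthetic)",
                "IMMUNE": "planted immune genes (synthetic)",
                "RESPONSE": "planted response-delta genes (synthetic)",
                "HAZARD": "planted recurrence-hazard genes (synthetic)",
            },
        )
        probe_map = truth.probe_to_gene
        if config.gmt_path:
            gmt = sio.read_gmt(config.gmt_path)
        if config.centroids_path:
            panel = sio.read_centroids(config.centroids_path)
        if out_dir is not None:
            sio.write_expression(expr, out_dir / "expression.tsv")
            sio.write_sample_meta(meta, out_dir / "samples.tsv")
            sio.write_centroids(panel, out_dir / "centroids.tsv")
            sio.write_gmt(gmt, out_dir / "genesets.gmt")
            if probe_map:
                sio.write_probe_map(probe_map, out_dir / "probe_map.tsv")
            with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(_jsonable(truth.to_dict()), fh, indent=1, sort_keys=True)
        return expr, meta, panel, gmt, probe_map, truth
    for name in ("expr_path", "meta_path", "centroids_path", "gmt_path"):
        if getattr(config, name) is None:
            raise ValueError(f"config needs either sim or all input paths; {name} is missing")
    expr = sio.read_expression(config.expr_path, level="probe" if config.probe_map_path else "gene")
    meta = sio.read_sample_meta(config.meta_path)
    panel = sio.read_centroids(config.centroids_path)
    gmt = sio.read_gmt(config.gmt_path)
    probe_map = sio.read_probe_map(config.probe_map_path) if config.probe_map_path else None
    return expr, meta, panel, gmt, probe_map, None


def run_all(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full workflow; returns (and optionally writes) the summary.

    On a stage failure a :class:`PipelineError` naming the stage is raised;
    outputs of completed stages are retained and the manifest marks the run
    incomplete.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"complete": False, "stages": [], "outputs": []}
    summary: dict[str, Any] = {
        "thresholds": {
            "timepoint_adjusted_alpha": config.alpha,
            "outcome_raw_alpha": config.raw_alpha,
            "enrichment_alpha": config.enrich_alpha,
        },
        "n_perm": config.n_perm,
        "seed": config.seed,
    }

    def done(stage: str, *files: str) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(files)
        if out_path is not None:
            with open(out_path / "manifest.json", "w", encoding="utf-8") as fh:
                json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)

    # ---- inputs -----------------------------------------------------------
    try:
        expr, meta, panel, gmt, probe_map, truth = _load_inputs(config, out_path)
    except Exception as exc:
        raise PipelineError("inputs", exc) from exc
    summary["cohort"] = {
        "n_samples": int(len(meta)),
        "n_patients": int(meta["patient_id"].nunique()),
        "samples_per_timepoint": meta["timepoint"].value_counts().to_dict(),
        "synthetic": truth is not None,
    }
    done("inputs")

    # ---- normalization ----------------------------------------------------
    try:
        norm = expr
        if probe_map is not None and norm.level == "probe":
            if config.collapse_first:
                norm = residualize_batch(collapse_probes(norm, probe_map), meta)
            else:
                norm = collapse_probes(residualize_batch(norm, meta), probe_map)
        else:
            norm = residualize_batch(norm, meta)
        if out_path is not None:
            sio.write_expression(norm, out_path / "normalized_expression.tsv")
    except Exception as exc:
        raise PipelineError("normalization", exc) from exc
    done("normalization", "normalized_expression.tsv")

    # ---- differential expression ------------------------------------------
    contrasts: dict[str, DEResult] = {}
    summary["contrasts"] = {}
    for name in DE_CONTRASTS:
        try:
            res = run_contrast(
                norm, meta, name,
                n_perm=config.n_perm, seed=config.seed,
                alpha=config.alpha, raw_alpha=config.raw_alpha,
            )
        except Exception as exc:
            raise PipelineError(f"de:{name}", exc) from exc
        contrasts[name] = res
        summary["contrasts"][name] = res.summary()
        if out_path is not None:
            _write_de_tsv(res, out_path / f"de_{name}.tsv")
        done(f"de:{name}", f"de_{name}.tsv")

    # ---- subtyping --------------------------------------------------------
    try:
        calls = assign_subtypes(norm, panel, metric=config.metric, min_genes=min(config.min_genes, len(panel.gene_ids)))
        summary["concordance"] = {}
        for tp_a, tp_b in (("T1", "T2"), ("T1", "TS")):
            ca, cb = paired_calls(calls, meta, tp_a, tp_b)
            conc = concordance(ca, cb)
            summary["concordance"][f"{tp_a}_{tp_b}"] = conc.summary()
            if out_path is not None:
                conc.transitions.to_csv(out_path / f"transitions_{tp_a}_{tp_b}.tsv", sep="\t")
        if out_path is not None:
            calls.to_csv(out_path / "subtype_calls.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError("subtyping", exc) from exc
    done("subtyping", "subtype_calls.tsv")

    # ---- survival screens -------------------------------------------------
    screens: dict[str, pd.DataFrame] = {}
    summary["rfs_screens"] = {}
    for mode in RFS_MODES:
        try:
            values, t, e, hr = rfs_screen_matrix(norm, meta, mode)
            adj = hr if config.adjust_hr else None
            res = screen_rfs(values, t, e, adjust=adj, threshold=config.raw_alpha)
        except Exception as exc:
            raise PipelineError(f"rfs:{mode}", exc) from exc
        screens[mode] = res
        sig = res.index[res["significant"].fillna(False)]
        summary["rfs_screens"][mode] = {
            "n_features": int(len(res)),
            "n_patients": int(res["n"].max()) if len(res) else 0,
            "n_significant": int(len(sig)),
            "n_reduced_rfs": int((res.loc[sig, "direction"] == "reduced_rfs").sum()),
            "n_improved_rfs": int((res.loc[sig, "direction"] == "improved_rfs").sum()),
            "threshold_rule": f"lr_p<{config.raw_alpha} (no multiplicity correction)",
            "adjusted_for_hr": bool(config.adjust_hr),
        }
        if out_path is not None:
            res.to_csv(out_path / f"rfs_{mode}.tsv", sep="\t", na_rep="NA")
        done(f"rfs:{mode}", f"rfs_{mode}.tsv")

    # ---- enrichment -------------------------------------------------------
    summary["enrichment"] = {}
    for name, res in contrasts.items():
        sig = list(res.significant)
        universe = list(res.table.index[~res.table["raw_p"].isna()])
        block: dict[str, Any] = {"n_significant": len(sig)}
        if sig:
            try:
                table = enrich_all(sig, universe, gmt, alpha=config.enrich_alpha)
            except Exception as exc:
                raise PipelineError(f"enrichment:{name}", exc) from exc
            block["sets"] = {
                s: {"p": float(r["p"]), "n_overlap": int(r["n_overlap"]), "significant": bool(r["significant"])}
                for s, r in table.iterrows()
            }
            if out_path is not None:
                table.to_csv(out_path / f"enrichment_{name}.tsv", sep="\t", na_rep="NA")
        summary["enrichment"][name] = block
    done("enrichment")

    # ---- overlap reports --------------------------------------------------
    rcb_sets = {n: set(contrasts[n].significant) for n in ("rcb_t1", "rcb_t2", "rcb_delta_t2")}
    rfs_sets = {
        m: set(screens[m].index[screens[m]["significant"].fillna(False)]) for m in RFS_MODES
    }
    def _pairwise(sets: dict[str, set]) -> dict:
        names = list(sets)
        out = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                out[f"{a}&{b}"] = sorted(sets[a] & sets[b])
        out["&".join(names)] = sorted(set.intersection(*sets.values())) if names else []
        return out
    summary["overlaps"] = {"rcb_contrasts": _pairwise(rcb_sets), "rfs_screens": _pairwise(rfs_sets)}
    done("overlaps")

    # ---- truth evaluation (synthetic runs only) ---------------------------
    if truth is not None:
        universe = list(norm.feature_ids)
        evals = {}
        for name, planted in (
            ("t1_vs_t2", truth.t2_marginal_shift_genes),
            ("rcb_delta_t2", truth.response_genes),
        ):
            if planted:
                sens, fdr = truth_eval(set(contrasts[name].significant), planted, universe)
                evals[name] = {"sensitivity": sens, "observed_fdr": fdr}
        if truth.hazard_genes:
            sens, fdr = truth_eval(rfs_sets["ts"], truth.hazard_genes, universe)
            evals["rfs_ts"] = {"sensitivity": sens, "observed_fdr": fdr}
        summary["truth_eval"] = evals
    manifest["complete"] = True
    done("summary", "summary.json")
    if out_path is not None:
        with open(out_path / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
    return summary
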