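"""End-to-end orchestration: simulate -> assoc -> network -> c3net -> enrich.

Stages communicate through files (GCT / TSV / SIF) so that every CLI
subcommand is independently usable; :func:`run_all` wires them together
from a single config mapping and writes a machine-parseable JSON run
report (stage timings, row counts, config echo).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from . import simulate as sim
from .association import CriteriaConfig, call_associations, tissue_zscore
from .enrichment import EnrichmentConfig, hypergeom_enrich
from .errors import EmptyResultError, ValidationError
from .minet import C3Net
from .wgcna import (
    CoexpressionNetwork,
    PreprocessConfig,
    UNASSIGNED,
    ModulePartition,
    preprocess,
    tissue_fold_profile,
    write_sif,
)

logger = logging.getLogger(__name__)

__all__ = ["focal_module", "run_all", "demo_config", "demo_annotation_gmt",
           "marker_recovery"]


def focal_module(partition: ModulePartition, focal_genes: Sequence[str]) -> str:
    """Module label holding the plurality of the focal genes.

    Unassigned genes do not vote; an exact tie raises with the candidate
    labels listed, as does a focal set that is entirely unassigned.
    """
    labels = partition.labels
    missing = [g for g in focal_genes if g not in labels.index]
    if missing:
        raise ValidationError(f"focal genes not in partition: {missing[:5]}")
    votes = labels.loc[list(focal_genes)]
    votes = votes[votes != UNASSIGNED]
    if votes.empty:
        raise ValidationError("all focal genes are unassigned")
    counts = votes.value_counts()
    top = counts[counts == counts.iloc[0]]
    if len(top) > 1:
        raise ValidationError(f"focal-module tie between {sorted(top.index)}")
    return str(top.index[0])


def marker_recovery(
    assoc: pd.DataFrame, truth: sim.TruthTable
) -> dict[str, float]:
    """Sensitivity / specificity of the screen against planted markers."""
    truth_pairs = truth.marker_pairs()
    called = set(zip(assoc.loc[assoc["passes"], "gene"], assoc.loc[assoc["passes"], "tissue"]))
    universe = set(zip(assoc["gene"], assoc["tissue"]))
    tp = len(called & truth_pairs)
    fp = len(called - truth_pairs)
    fn = len((truth_pairs & universe) - called)
    tn = len(universe) - tp - fp - fn
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "true_positives": tp,
        "false_positives": fp,
    }


def demo_annotation_gmt(truth: sim.TruthTable, all_genes: Sequence[str],
                        seed: int = 0, n_random_terms: int = 20) -> dict[str, list[str]]:
    """Synthetic term annotation for the bundled demo.

    One term per planted module (its genes plus a few random extras, so the
    planted signal is recoverable but not trivially identical) and
    ``n_random_terms`` random 15-40 gene terms as a null background.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(list(all_genes), dtype=object)
    sets: dict[str, list[str]] = {}
    modules: dict[str, list[str]] = {}
    for gene, module in truth.modules.items():
        modules.setdefault(module, []).append(gene)
    for module, genes in sorted(modules.items()):
        extras = rng.choice(pool, size=min(10, len(pool)), replace=False)
        sets[f"TERM:{module}"] = sorted(set(genes) | set(extras))
    for t in range(n_random_terms):
        size = int(rng.integers(15, 41))
        sets[f"TERM:random_{t:02d}"] = sorted(rng.choice(pool, size=size, replace=False))
    return sets


def demo_config(seed: int = 42) -> dict:
    """The bundled self-contained study conditions for ``run_all``."""
    spec = sim.pipeline_demo_spec(seed)
    return {
        "seed": seed,
        "synthetic": {"bundled": "pipeline"},
        "criteria": {},
        "gene_rule": {"required_prefix": "OR", "forbidden_suffix": "P"},
        "preprocess": {"min_detected_samples": 0.5},
        "network": {"min_module_size": 30, "tom_edge_cutoff": 0.025},
        "mi": {"alpha": 0.01, "n_permutations": 100},
        "enrichment": {"q_max": 0.05, "min_overlap": 10},
        "focal_tissue": spec.tissue_names[0],
        "focal_genes": [g for g, t, _ in spec.markers if t == spec.tissue_names[0]],
        "demo_gmt": True,
    }


def _load_inputs(config: Mapping, out_dir: Path, report: dict):
    """Simulate or read the expression matrix, annotation and truth."""
    synthetic = config.get("synthetic")
    truth = None
    if synthetic:
        seed = int(config.get("seed", 0))
        if synthetic.get("bundled") == "pipeline":
            spec = sim.pipeline_demo_spec(seed)
        elif synthetic.get("bundled") == "marker":
            spec = sim.marker_demo_spec(seed)
        else:
            spec = sim.SyntheticSpec(**{k: v for k, v in synthetic.items() if k != "bundled"},
                                     seed=seed)
        expr, annot, truth = sim.generate(spec)
        tio.write_gct(expr, out_dir / "expression.gct")
        tio.write_metadata(annot, out_dir / "metadata.tsv")
        sim.write_truth(truth, out_dir / "truth.tsv")
    else:
        paths = config["paths"]
        expr = tio.read_gct(paths["expr"])
        annot = tio.read_metadata(paths["meta"],
                                  config.get("sample_col", "sample_id"),
                                  config.get("tissue_col", "tissue"))
        if paths.get("truth"):
            truth = sim.read_truth(paths["truth"])
    report["n_genes"], report["n_samples"] = expr.shape
    return expr, annot, truth


def run_all(config: Mapping, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns (and writes) the run report.

    Any stage error aborts with a stage-tagged message; outputs of earlier
    stages are retained on disk. A missing term-annotation file only skips
    the enrichment stage (with a logged warning).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(config), "stages": {}}
    t_all = time.perf_counter()

    def stage(name):
        report["stages"][name] = {"seconds": None}
        return time.perf_counter()

    # ---- inputs / simulation ----
    t0 = stage("inputs")
    try:
        expr, annot, truth = _load_inputs(config, out_dir, report)
    except Exception as exc:
        raise type(exc)(f"[inputs] {exc}") from exc
    report["stages"]["inputs"]["seconds"] = round(time.perf_counter() - t0, 3)

    # ---- tissue filtering ----
    tf = config.get("tissue_filter")
    if tf:
        cfg = tio.TissueFilterConfig(**tf)
        annot = tio.recategorize_samples(annot, cfg)
        annot = tio.filter_tissues(annot, cfg)
        expr = expr[annot.index]

    # ---- association screen ----
    t0 = stage("assoc")
    rule = tio.GeneSymbolRule(**config.get("gene_rule", {}))
    screen_genes = tio.select_genes_by_rule(list(expr.index), rule)
    if not screen_genes:
        screen_genes = list(expr.index)
    crit = CriteriaConfig(**config.get("criteria", {}))
    assoc = call_associations(expr, annot, screen_genes, crit)
    tio.write_table(assoc, out_dir / "associations.tsv")
    passing = assoc[assoc["passes"]]
    summary = (passing.groupby("tissue")["gene"]
               .agg(["count", lambda g: ",".join(sorted(g))])
               .rename(columns={"count": "n_genes", "<lambda_0>": "genes"}))
    tio.write_table(summary.reset_index(), out_dir / "association_summary.tsv")
    z = tissue_zscore(expr, annot, screen_genes)
    tio.write_table(z.reset_index(), out_dir / "tissue_zscores.tsv")
    report["stages"]["assoc"].update({
        "seconds": round(time.perf_counter() - t0, 3),
        "n_genes_screened": len(screen_genes),
        "n_marker_genes": int(passing["gene"].nunique()),
        "n_marker_tissues": int(passing["tissue"].nunique()),
    })
    if truth is not None and truth.markers:
        report["stages"]["assoc"]["recovery"] = marker_recovery(assoc, truth)

    # ---- co-expression network on the focal tissue ----
    t0 = stage("network")
    focal_tissue = config.get("focal_tissue") or annot["tissue"].iloc[0]
    pre = PreprocessConfig(**config.get("preprocess", {}))
    try:
        logexpr = preprocess(expr, pre, annot, [focal_tissue])
    except EmptyResultError as exc:
        raise EmptyResultError(f"[network] {exc}") from exc
    net_params = dict(config.get("network", {}))
    net = CoexpressionNetwork(**net_params)
    net.fit(logexpr.T)
    modules_tbl = net.partition_.labels.rename("module").reset_index()
    modules_tbl.columns = ["gene", "module"]
    tio.write_table(modules_tbl, out_dir / "modules.tsv")
    tio.write_table(net.eigengenes_.reset_index(names="module"), out_dir / "eigengenes.tsv")
    edges = net.edges()
    tio.write_table(edges, out_dir / "tom_edges.tsv")
    write_sif(edges, out_dir / "tom_edges.sif")
    fold = tissue_fold_profile(expr, annot, list(logexpr.index))
    tio.write_table(fold.reset_index(), out_dir / "tissue_fold_profile.tsv")
    report["stages"]["network"].update({
        "seconds": round(time.perf_counter() - t0, 3),
        "soft_power": net.power_,
        "n_genes": int(logexpr.shape[0]),
        "n_modules": len(net.partition_.modules()),
        "n_tom_edges": int(len(edges)),
    })

    # ---- focal module + c3net segmentation ----
    t0 = stage("c3net")
    focal_genes = config.get("focal_genes")
    if focal_genes:
        module = focal_module(net.partition_, focal_genes)
    elif net.partition_.modules():
        module = net.partition_.modules()[0]
    else:
        raise EmptyResultError("[c3net] no module detected to segment")
    members = net.partition_.members(module)
    mi_params = dict(config.get("mi", {}))
    mi_params.setdefault("random_state", int(config.get("seed", 0)))
    c3 = C3Net(**mi_params)
    c3.fit(logexpr.loc[members].T)
    tio.write_table(c3.edges_, out_dir / "c3net_edges.tsv")
    comps = c3.network_.components.reset_index()
    tio.write_table(comps, out_dir / "c3net_components.tsv")
    write_sif(c3.edges_, out_dir / "c3net_edges.sif", relation="mi")
    report["stages"]["c3net"].update({
        "seconds": round(time.perf_counter() - t0, 3),
        "focal_module": module,
        "n_module_genes": len(members),
        "n_edges": int(len(c3.edges_)),
        "n_components": int(c3.network_.components.nunique()),
        "mi_threshold": c3.threshold_,
    })

    # ---- enrichment of the focal module ----
    t0 = stage("enrich")
    gmt_path = (config.get("paths") or {}).get("gmt")
    annotation = None
    if config.get("demo_gmt") and truth is not None:
        annotation = demo_annotation_gmt(truth, list(logexpr.index),
                                         seed=int(config.get("seed", 0)))
        tio.write_gmt(annotation, out_dir / "demo_annotation.gmt")
    elif gmt_path:
        if Path(gmt_path).exists():
            annotation = tio.read_gmt(gmt_path)
        else:
            logger.warning("GMT file %s not found: enrichment skipped", gmt_path)
    if annotation is None:
        logger.warning("no term annotation supplied: enrichment skipped")
        report["stages"]["enrich"].update({"seconds": 0.0, "skipped": True})
    else:
        ecfg = EnrichmentConfig(**config.get("enrichment", {}))
        records = hypergeom_enrich(members, annotation, list(logexpr.index), ecfg)
        tio.write_table(records, out_dir / "enrichment.tsv")
        report["stages"]["enrich"].update({
            "seconds": round(time.perf_counter() - t0, 3),
            "n_terms_tested": int(len(records)),
            "n_terms_passing": int(records["passes"].sum()),
        })

    report["total_seconds"] = round(time.perf_counter() - t_all, 3)
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
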