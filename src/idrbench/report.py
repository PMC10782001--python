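"""Pipeline orchestration: run the full comparative benchmark and emit
report tables.

:func:`run_benchmark` takes parsed reference entries plus per-method
score profiles and produces:

* a dataset summary (protein/IDR/residue counts per stratum);
* a residue-level table (calibrated threshold, coverage, AUC, AUPRC,
  MCC, F1) with significance verdicts against reference methods;
* a per-IDR-type AUC table over the shortIDR/longIDR/bindingIDR/
  non-terminusIDR strata;
* a protein-level disorder-content table (MAE, SCC);
* a fully-disordered-protein table (F1, sensitivity at content cut-offs
  0.99/0.90/0.80);
* optionally the marker analysis (competitive split, marker p-values,
  below-median selection).

Verdict cells use the 'value x|y|z' notation: one '+'/'-'/'=' symbol per
reference method, read from the reference method's perspective.

Every table is emitted as a TSV plus a machine-readable JSON twin; the
run is deterministic under a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import markers as markers_mod
from . import metrics, significance, stratify
from .errors import ParameterError, UndefinedMetricError
from .types import MarkerVector, ReferenceEntry, ScoreProfile

logger = logging.getLogger(__name__)

IDR_TYPE_DATASETS = ("longIDR", "shortIDR", "bindingIDR", "non-terminusIDR")
FDP_DATASETS = {"FDP99": 0.99, "FDP90": 0.90, "FDP80": 0.80}


@dataclass
class RunConfig:
    """In-memory run configuration for :func:`run_benchmark`."""

    entries: Sequence[ReferenceEntry]
    methods: Mapping[str, Mapping[str, ScoreProfile]]  # method -> id -> profile
    reference_methods: Sequence[str] = ()
    seed: int = 0
    compute_verdicts: bool = True
    marker_method: Optional[str] = None      # AF2-style method for the split
    marker_floor_method: Optional[str] = None  # floor = its dataset AUC
    binding_profiles: Optional[Mapping[str, ScoreProfile]] = None
    coil_profiles: Optional[Mapping[str, ScoreProfile]] = None


def _pooled_evaluator(profiles, references, threshold, stat: str):
    """Subset evaluator: pooled residue-level metric over subset ids."""

    def evaluate(ids: List[str]) -> float:
        result = metrics.pooled_residue_eval(profiles, references, threshold, ids)
        return result[stat]

    return evaluate


def _content_evaluator(pred_content: Mapping[str, float],
                       native_content: Mapping[str, float], stat: str):
    def evaluate(ids: List[str]) -> float:
        ids = [i for i in ids if i in pred_content]
        if len(ids) < 2:
            raise UndefinedMetricError("too few covered proteins")
        pred = [pred_content[i] for i in ids]
        native = [native_content[i] for i in ids]
        if stat == "mae":
            return metrics.content_mae(pred, native)
        return metrics.content_scc(pred, native)

    return evaluate


def _fdp_evaluator(pred_content, native_content, cutoff: float, stat: str):
    def evaluate(ids: List[str]) -> float:
        ids = [i for i in ids if i in pred_content]
        if not ids:
            raise UndefinedMetricError("no covered proteins")
        f1, sens = metrics.fdp_eval(
            [pred_content[i] for i in ids],
            [native_content[i] for i in ids], cutoff,
        )
        return f1 if stat == "f1" else sens

    return evaluate


def _verdict_cell(value: float, verdicts: Optional[Mapping[str, object]],
                  reference_methods: Sequence[str], method: str) -> str:
    if not reference_methods or verdicts is None:
        return f"{value:.3f}"
    symbols = []
    for ref in reference_methods:
        if ref == method:
            symbols.append(" ")
        elif ref in verdicts:
            symbols.append(verdicts[ref].symbol)
        else:
            symbols.append(".")  # not testable: too few valid subsets
    return f"{value:.3f} " + "|".join(symbols)


def run_benchmark(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Run the full comparative evaluation; returns named tables."""
    entries = list(config.entries)
    references = {e.id: e for e in entries}
    membership = stratify.build_datasets(entries)
    tables: Dict[str, pd.DataFrame] = {}
    tables["dataset_summary"] = stratify.dataset_summary(membership, entries)

    all_ids = sorted(references)
    thresholds = {}
    binarized: Dict[str, Dict[str, ScoreProfile]] = {}
    for method, profiles in config.methods.items():
        matched = [p for p in profiles.values() if p.id in references]
        if not matched:
            raise ParameterError(f"method {method}: no profiles match the reference")
        t = metrics.calibrate_threshold(matched, references, method=method)
        thresholds[method] = t
        binarized[method] = {p.id: metrics.binarize(p, t) for p in matched}

    # ---- residue-level table (whole-benchmark dataset) ----
    residue_rows = []
    caid_eval = {}
    for method, profiles in config.methods.items():
        caid_eval[method] = metrics.pooled_residue_eval(
            profiles, references, thresholds[method], all_ids
        )
    reference_methods = list(config.reference_methods)
    if not reference_methods:
        reference_methods = [max(caid_eval, key=lambda m: caid_eval[m]["auc"])]

    residue_verdicts = {}
    if config.compute_verdicts and len(config.methods) > 1:
        plan = significance.make_subsets(all_ids, "disjoint_5pct", config.seed)
        for stat in ("auc", "auprc", "mcc", "f1"):
            evaluators = {
                m: _pooled_evaluator(config.methods[m], references, thresholds[m], stat)
                for m in config.methods
            }
            residue_verdicts[stat] = significance.compare_methods(
                plan, evaluators, reference_methods, metric=stat
            )
    for method in sorted(config.methods, key=lambda m: -caid_eval[m]["auc"]):
        ev = caid_eval[method]
        row = {
            "method": method,
            "threshold": round(thresholds[method].threshold, 3),
            "coverage_pct": round(100 * ev["coverage"]),
        }
        for stat in ("auc", "auprc", "mcc", "f1"):
            row[stat] = _verdict_cell(
                ev[stat],
                residue_verdicts.get(stat, {}).get(method),
                reference_methods, method,
            )
        residue_rows.append(row)
    tables["residue_level"] = pd.DataFrame(residue_rows)

    # ---- per-IDR-type AUC table ----
    type_rows = []
    for method in sorted(config.methods, key=lambda m: -caid_eval[m]["auc"]):
        row = {"method": method}
        for dataset in IDR_TYPE_DATASETS:
            ids = sorted(stratify.dataset_members(membership, dataset))
            if not ids:
                row[dataset] = ""
                continue
            try:
                ev = metrics.pooled_residue_eval(
                    config.methods[method], references, thresholds[method], ids
                )
                cell = f"{ev['auc']:.3f}"
            except UndefinedMetricError:
                cell = ""
            if (config.compute_verdicts and len(config.methods) > 1
                    and len(ids) >= 20 and cell):
                plan = significance.make_subsets(ids, "disjoint_5pct", config.seed)
                evaluators = {
                    m: _pooled_evaluator(config.methods[m], references,
                                         thresholds[m], "auc")
                    for m in config.methods
                }
                verdicts = significance.compare_methods(
                    plan, evaluators, reference_methods, metric="auc"
                )
                cell = _verdict_cell(ev["auc"], verdicts[method],
                                     reference_methods, method)
            row[dataset] = cell
        type_rows.append(row)
    tables["idr_type_auc"] = pd.DataFrame(type_rows)

    # ---- protein-level disorder content ----
    native_content = {pid: references[pid].disorder_content for pid in all_ids}
    pred_content: Dict[str, Dict[str, float]] = {}
    for method in config.methods:
        pred_content[method] = {
            pid: metrics.disorder_content(p.binary)
            for pid, p in binarized[method].items()
        }
    content_rows = []
    content_verdicts = {}
    if config.compute_verdicts and len(config.methods) > 1:
        plan = significance.make_subsets(all_ids, "disjoint_5pct", config.seed)
        for stat in ("mae", "scc"):
            evaluators = {
                m: _content_evaluator(pred_content[m], native_content, stat)
                for m in config.methods
            }
            content_verdicts[stat] = significance.compare_methods(
                plan, evaluators, reference_methods, metric=stat
            )
    for method in sorted(config.methods, key=lambda m: -caid_eval[m]["auc"]):
        ids = sorted(pred_content[method])
        mae = metrics.content_mae([pred_content[method][i] for i in ids],
                                  [native_content[i] for i in ids])
        try:
            scc = metrics.content_scc([pred_content[method][i] for i in ids],
                                      [native_content[i] for i in ids])
        except UndefinedMetricError:
            scc = float("nan")
        content_rows.append({
            "method": method,
            "mae": _verdict_cell(mae, content_verdicts.get("mae", {}).get(method),
                                 reference_methods, method),
            "scc": _verdict_cell(scc, content_verdicts.get("scc", {}).get(method),
                                 reference_methods, method),
        })
    tables["content"] = pd.DataFrame(content_rows)

    # ---- fully disordered proteins ----
    fdp_rows = []
    fdp_verdicts: Dict[str, dict] = {}
    if config.compute_verdicts and len(config.methods) > 1:
        plan20 = significance.make_subsets(all_ids, "sampled_20pct", config.seed)
        for name, cutoff in FDP_DATASETS.items():
            for stat in ("f1", "sensitivity"):
                evaluators = {
                    m: _fdp_evaluator(pred_content[m], native_content, cutoff, stat)
                    for m in config.methods
                }
                try:
                    fdp_verdicts[(name, stat)] = significance.compare_methods(
                        plan20, evaluators, reference_methods, metric=stat
                    )
                except UndefinedMetricError:
                    continue
    for method in sorted(config.methods, key=lambda m: -caid_eval[m]["auc"]):
        row = {"method": method}
        ids = sorted(pred_content[method])
        for name, cutoff in FDP_DATASETS.items():
            try:
                f1, sens = metrics.fdp_eval(
                    [pred_content[method][i] for i in ids],
                    [native_content[i] for i in ids], cutoff,
                )
            except UndefinedMetricError:
                row[f"{name}_f1"] = ""
                row[f"{name}_sensitivity"] = ""
                continue
            row[f"{name}_f1"] = _verdict_cell(
                f1, fdp_verdicts.get((name, "f1"), {}).get(method),
                reference_methods, method)
            row[f"{name}_sensitivity"] = _verdict_cell(
                sens, fdp_verdicts.get((name, "sensitivity"), {}).get(method),
                reference_methods, method)
        fdp_rows.append(row)
    tables["fdp"] = pd.DataFrame(fdp_rows)

    # ---- marker analysis (optional) ----
    if config.marker_method is not None:
        tables.update(_marker_analysis(config, references, caid_eval, binarized))
    return tables


def _marker_analysis(config: RunConfig, references, caid_eval, binarized):
    af2_method = config.marker_method
    floor_method = config.marker_floor_method or max(
        caid_eval, key=lambda m: caid_eval[m]["auc"]
    )
    auc_floor = caid_eval[floor_method]["auc"]
    others = [m for m in config.methods if m != af2_method]
    af2_auc = metrics.per_protein_auc(config.methods[af2_method], references)
    per_method_auc = {
        m: metrics.per_protein_auc(config.methods[m], references) for m in others
    }
    predictor_aucs = {}
    for pid in references:
        aucs = [per_method_auc[m][pid] for m in others if pid in per_method_auc[m]]
        if len(aucs) >= 2:
            predictor_aucs[pid] = aucs
    if not predictor_aucs:
        # the confidence interval needs >= 2 non-AF2 predictors per protein
        logger.warning("marker analysis skipped: fewer than 2 comparator methods")
        return {}
    split = markers_mod.competitive_split(af2_auc, auc_floor, predictor_aucs)

    marker_vectors: Dict[str, MarkerVector] = {}
    disorder_binary = binarized[af2_method]
    for pid in set(split.competitive) | set(split.rest):
        if pid not in disorder_binary:
            continue
        binding = (config.binding_profiles or {}).get(pid)
        coil = (config.coil_profiles or {}).get(pid)
        marker_vectors[pid] = markers_mod.compute_markers(
            disorder_binary[pid], binding, coil
        )
    if split.competitive and split.rest:
        p_values = markers_mod.compare_marker_distributions(split, marker_vectors)
        medians = markers_mod.group_medians(marker_vectors, split.competitive)
        active = [m for m in markers_mod.DEFAULT_ACTIVE_MARKERS if p_values[m] < 0.05]
        selected = markers_mod.marker_select(
            marker_vectors, medians, active or markers_mod.DEFAULT_ACTIVE_MARKERS
        )
    else:
        # degenerate split (every protein on one side): distribution
        # comparison and below-median selection are not meaningful
        logger.warning("competitive split is one-sided; skipping marker tests")
        p_values = {name: float("nan") for name in MarkerVector.FIELDS}
        medians = markers_mod.group_medians(marker_vectors, marker_vectors)
        selected = set()
    marker_table = pd.DataFrame([
        {"protein_id": pid, "competitive": pid in split.competitive,
         "selected": pid in selected,
         **{name: getattr(vec, name) for name in MarkerVector.FIELDS}}
        for pid, vec in sorted(marker_vectors.items())
    ])
    pvalue_table = pd.DataFrame([
        {"marker": name, "p_value": p_values[name],
         "significant": p_values[name] < 0.05,
         "competitive_median": medians[name]}
        for name in MarkerVector.FIELDS
    ])
    return {"markers": marker_table, "marker_pvalues": pvalue_table}


def emit_tables(tables: Mapping[str, pd.DataFrame], out_dir) -> List[Path]:
    """Write each table as TSV plus a JSON twin; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        tsv_path = out_dir / f"{name}.tsv"
        json_path = out_dir / f"{name}.json"
        table.to_csv(tsv_path, sep="\t", index=False)
        records = json.loads(table.to_json(orient="records"))
        json_path.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")
        written.extend([tsv_path, json_path])
    return written


def load_tables(out_dir) -> Dict[str, pd.DataFrame]:
    """Re-load emitted JSON twins into DataFrames."""
    out_dir = Path(out_dir)
    tables = {}
    for json_path in sorted(out_dir.glob("*.json")):
        tables[json_path.stem] = pd.DataFrame(json.loads(json_path.read_text()))
    return tables
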