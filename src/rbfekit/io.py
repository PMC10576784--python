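"""Readers and writers for the package's plain-text formats.

Assay CSV
    Leading ``# key: value`` comment lines hold assay metadata (assay_id,
    category, units, source), followed by columns
    ``compound_id,measure_type,value,qualifier,std_err``.  The ``units``
    dialect is one of ``molar``, ``nanomolar`` or ``pKi``; values are
    normalized to molar concentrations on ingest (pKi p -> 10**-p M).

Graph edge-list CSV
    Columns ``ligand_a,ligand_b,ddg_pred,ddg_se`` (ddg_se optional/blank);
    experimental dGs can be joined from an assay CSV by compound id.

Survey manifest YAML
    ``groups`` of assay CSV paths measured on the same series (all
    unordered pairs within a group become comparisons), plus censoring and
    bootstrap settings and an output directory.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import yaml

from .affinity import DEFAULT_THERMO, AffinityMeasurement, MeasureType, Qualifier
from .exceptions import InsufficientOverlapError, ParseError, RbfeError
from .graph import Edge, PerturbationGraph
from .metrics import AggregateResult
from .survey import (
    AssayComparison,
    AssaySeries,
    compare_assays,
    pooled_pairwise_errors,
    survey_aggregate,
)

ASSAY_COLUMNS = ["compound_id", "measure_type", "value", "qualifier", "std_err"]
GRAPH_COLUMNS = ["ligand_a", "ligand_b", "ddg_pred", "ddg_se"]
UNITS = ("molar", "nanomolar", "pKi")


def _read_metadata(path: Path) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def _to_molar(value: float, units: str, row: int, path: Path) -> float:
    if units == "molar":
        molar = value
    elif units == "nanomolar":
        molar = value * 1e-9
    else:  # pKi
        molar = 10.0 ** (-value)
    if not (molar > 0 and math.isfinite(molar)):
        raise ParseError(f"{path}, row {row}: non-positive concentration {value!r}")
    return molar


def read_assay_csv(path) -> AssaySeries:
    """Read one assay series, normalizing all values to molar units."""
    path = Path(path)
    meta = _read_metadata(path)
    units = meta.get("units", "molar")
    if units not in UNITS:
        raise ParseError(f"{path}: unknown units dialect {units!r}")
    df = pd.read_csv(path, comment="#", dtype={"compound_id": str})
    required = [c for c in ASSAY_COLUMNS if c != "std_err"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    measurements: List[AffinityMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mtype = MeasureType(row.measure_type)
        except ValueError:
            raise ParseError(
                f"{path}, row {i}: unknown measure_type {row.measure_type!r}"
            ) from None
        qual = getattr(row, "qualifier", "eq")
        if pd.isna(qual) or qual == "":
            qual = "eq"
        try:
            qual = Qualifier(qual)
        except ValueError:
            raise ParseError(f"{path}, row {i}: bad qualifier {qual!r}") from None
        value = row.value
        if pd.isna(value):
            raise ParseError(f"{path}, row {i}: missing value")
        molar = _to_molar(float(value), units, i, path)
        se = getattr(row, "std_err", None)
        se = None if se is None or pd.isna(se) else float(se)
        try:
            measurements.append(
                AffinityMeasurement(str(row.compound_id), mtype, molar, qual, se)
            )
        except RbfeError as exc:
            raise ParseError(f"{path}, row {i}: {exc}") from None

    try:
        return AssaySeries(
            assay_id=meta.get("assay_id", path.stem),
            category=meta.get("category", "binding"),
            measurements=measurements,
            source_tag=meta.get("source", "public"),
        )
    except RbfeError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_assay_csv(series: AssaySeries, path, units: str = "molar") -> None:
    """Write an assay series in any of the three units dialects."""
    if units not in UNITS:
        raise RbfeError(f"unknown units dialect {units!r}")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# assay_id: {series.assay_id}\n")
        fh.write(f"# category: {series.category}\n")
        fh.write(f"# units: {units}\n")
        fh.write(f"# source: {series.source_tag}\n")
        writer = csv.writer(fh)
        writer.writerow(ASSAY_COLUMNS)
        for m in series.measurements:
            if units == "molar":
                value = repr(m.value)
            elif units == "nanomolar":
                value = repr(m.value / 1e-9)
            else:
                value = repr(-math.log10(m.value))
            writer.writerow(
                [
                    m.compound_id,
                    m.measure_type.value,
                    value,
                    m.qualifier.value,
                    "" if m.std_err is None else repr(m.std_err),
                ]
            )


def read_graph_csv(path, assay_path=None) -> PerturbationGraph:
    """Read a perturbation-graph edge list; optionally join experimental dGs."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"ligand_a": str, "ligand_b": str})
    missing = [c for c in GRAPH_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    edges: List[Edge] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.ddg_pred):
            raise ParseError(f"{path}, row {i}: missing ddg_pred")
        se = getattr(row, "ddg_se", None)
        se = None if se is None or pd.isna(se) else float(se)
        try:
            edges.append(Edge(str(row.ligand_a), str(row.ligand_b), float(row.ddg_pred), se))
        except RbfeError as exc:
            raise ParseError(f"{path}, row {i}: {exc}") from None

    exp_dg: Dict[str, float] = {}
    if assay_path is not None:
        from .affinity import abs_dg

        series = read_assay_csv(assay_path)
        exp_dg = {m.compound_id: abs_dg(m, DEFAULT_THERMO) for m in series.measurements}
    try:
        return PerturbationGraph(edges=edges, exp_dg=exp_dg)
    except RbfeError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_graph_csv(g: PerturbationGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GRAPH_COLUMNS)
        for e in g.edges:
            writer.writerow([e.a, e.b, repr(e.ddg), "" if e.se is None else repr(e.se)])


def read_manifest(path) -> Dict[str, object]:
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "groups" not in manifest:
        raise ParseError(f"{path}: manifest must be a mapping with a 'groups' list")
    return manifest


def sha256_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, AggregateResult):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def collect_comparisons(
    manifest: Dict[str, object], base_dir=None
) -> Tuple[List[AssayComparison], List[Dict[str, str]]]:
    """Read a manifest's assay groups and score all within-group pairs.

    Every unordered pair of assays inside one group becomes a comparison;
    pairs that share too few compounds are recorded as skipped rather than
    failing the whole survey.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    censoring = manifest.get("censoring", {}) or {}
    policy = censoring.get("policy", "qualifier_only")
    plateau_k = int(censoring.get("plateau_k", 3))

    comparisons: List[AssayComparison] = []
    skipped: List[Dict[str, str]] = []
    for group in manifest["groups"]:
        name = group.get("name", "group")
        paths = [base / p for p in group["assays"]]
        series = [read_assay_csv(p) for p in paths]
        for i in range(len(series)):
            for j in range(i + 1, len(series)):
                try:
                    comparisons.append(
                        compare_assays(series[i], series[j], policy=policy,
                                       plateau_k=plateau_k)
                    )
                except InsufficientOverlapError as exc:
                    skipped.append({"group": name, "reason": str(exc)})
    if not comparisons:
        raise InsufficientOverlapError("no assay pair in the manifest is comparable")
    return comparisons, skipped


def run_survey(manifest: Dict[str, object], base_dir=None) -> Dict[str, object]:
    """Run the reproducibility survey described by a manifest.

    Scores every within-group assay pair (see :func:`collect_comparisons`)
    and aggregates overall and per category.  Returns a JSON-serializable
    result with the per-comparison metrics, the aggregates, and the
    censoring removal log.
    """
    boot = manifest.get("bootstrap", {}) or {}
    n_boot = int(boot.get("n_boot", 10_000))
    seed = boot.get("seed")
    seed = None if seed is None else int(seed)

    comparisons, skipped = collect_comparisons(manifest, base_dir=base_dir)
    aggregates = survey_aggregate(comparisons, n_boot=n_boot, seed=seed)
    pooled = pooled_pairwise_errors(comparisons)
    return {
        "comparisons": [
            {
                "comparison_category": c.comparison_category,
                "shared_compounds": c.shared_compounds,
                **c.metrics.to_dict(),
            }
            for c in comparisons
        ],
        "aggregates": aggregates,
        "removal_log": [
            {"comparison": c.metrics.label, **entry}
            for c in comparisons
            for entry in c.removal_log
        ],
        "skipped": skipped,
        "n_pooled_pair_errors": int(pooled.size),
    }
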