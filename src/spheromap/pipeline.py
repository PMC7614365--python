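"""End-to-end orchestration: simulate -> preprocess -> lineage space ->
spatial map -> dynamic map -> ternary -> report.

A single YAML config drives a reproducible run: one master seed feeds a
fixed-order per-stage seed derivation, every stage writes under the output
directory, and re-running an identical config reproduces an identical
report (``--resume`` skips recomputation when the config hash matches).

QC thresholds are data-scale dependent: the defaults here suit the
synthetic Smart-seq-like depth (~10k counts/cell); deeper real full-length
data would use the stricter expr_io defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__, expr_io, lineage_space, simdata, spatial_map
from .experiments import derive_seed
from .mesh import REGIONS, STAGES
from .simdata import SimConfig

REPORT_SCHEMA_VERSION = 1


@dataclass
class ConditionSpec:
    """One culture condition: a lambda-mixture of two region archetypes."""

    name: str
    source: str
    target: str
    lam: float = 0.0
    control: str | None = None  # name of the control condition, if perturbed
    cells: int = 200


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_vertices: int = 400
    radius_um: float = 100.0
    gene_set_mode: str = "cca"  # cca | hvg
    n_genes: int = 300
    min_genes_detected: int = 500
    min_total_counts: int = 4000
    gp_optimize: bool = True
    gp_starts: int = 5
    ternary_markers: tuple = ("SOX2", "TFAP2A", "VTCN1")
    conditions: list = field(default_factory=list)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["conditions"] = [asdict(c) for c in self.conditions]
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


DEFAULT_CONDITIONS = [
    # controls mirror Epi-spheroids (with feeders) and Am-spheroids (without)
    ConditionSpec("Epi_control", "EmDisc_anterior", "EmDisc_anterior", 0.0),
    ConditionSpec("Am_control", "Am_distal", "Am_distal", 0.0),
    # BMP activation converts Epi- toward Am-spheroids
    ConditionSpec("BMP4", "EmDisc_anterior", "Am_distal", 0.8, control="Epi_control"),
    # ACTIVIN/NODAL inhibition reverses disc fate toward amnion
    ConditionSpec("SB43", "EmDisc_anterior", "Am_distal", 0.9, control="Epi_control"),
    # ACTIVIN stimulation rescues disc identity without feeders
    ConditionSpec("ActA_noMEF", "Am_distal", "EmDisc_anterior", 0.8, control="Am_control"),
    # FGF blocks amnion acquisition only partially
    ConditionSpec("FGF2_noMEF", "Am_distal", "EmDisc_anterior", 0.5, control="Am_control"),
]


def validate_config(source) -> tuple:
    """Parse a YAML config into a RunConfig, collecting every violation.

    Returns (config_or_None, list_of_violations).
    """
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    errors = []
    if not isinstance(doc, dict):
        return None, ["config must be a YAML mapping"]
    if "out_dir" not in doc:
        errors.append("out_dir is required")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a non-negative integer (got {seed!r})")
    for key in ("min_genes_detected", "min_total_counts"):
        v = doc.get(key, 0)
        if not isinstance(v, int) or v < 0:
            errors.append(f"{key} must be a non-negative integer (got {v!r})")
    mode = doc.get("gene_set_mode", "cca")
    if mode not in ("cca", "hvg"):
        errors.append(f"gene_set_mode must be 'cca' or 'hvg' (got {mode!r})")
    raw_conditions = doc.get("conditions")
    conditions = []
    if raw_conditions is not None:
        names = [c.get("name") for c in raw_conditions if isinstance(c, dict)]
        for c in raw_conditions:
            if not isinstance(c, dict) or "name" not in c:
                errors.append(f"condition entries need a name: {c!r}")
                continue
            lam = c.get("lam", 0.0)
            if not (0.0 <= float(lam) <= 1.0):
                errors.append(f"condition {c['name']}: lam must be in [0, 1]")
            for key in ("source", "target"):
                region = c.get(key)
                if region not in REGIONS:
                    errors.append(
                        f"condition {c['name']}: unknown {key} region {region!r}"
                    )
            control = c.get("control")
            if control is not None and control not in names:
                errors.append(
                    f"condition {c['name']}: control {control!r} is not a "
                    "configured condition"
                )
            conditions.append(
                ConditionSpec(
                    name=str(c["name"]),
                    source=c.get("source", REGIONS[0]),
                    target=c.get("target", REGIONS[0]),
                    lam=float(lam),
                    control=control,
                    cells=int(c.get("cells", 200)),
                )
            )
    if errors:
        return None, errors
    cfg = RunConfig(
        out_dir=str(doc["out_dir"]),
        seed=seed,
        n_vertices=int(doc.get("n_vertices", 400)),
        radius_um=float(doc.get("radius_um", 100.0)),
        gene_set_mode=mode,
        n_genes=int(doc.get("n_genes", 300)),
        min_genes_detected=int(doc.get("min_genes_detected", 500)),
        min_total_counts=int(doc.get("min_total_counts", 4000)),
        gp_optimize=bool(doc.get("gp_optimize", True)),
        gp_starts=int(doc.get("gp_starts", 5)),
        ternary_markers=tuple(doc.get("ternary_markers", ("SOX2", "TFAP2A", "VTCN1"))),
        conditions=conditions or list(DEFAULT_CONDITIONS),
    )
    return cfg, []


def _stage_fail(stage: str, exc: Exception):
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute every stage and write the report; deterministic in the config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    report_path = out / "report.json"
    if resume and manifest_path.exists() and report_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash:
            return json.loads(report_path.read_text())

    master = config.seed
    # --- simulate -------------------------------------------------------
    try:
        mesh = simdata.make_embryo_mesh(
            config.n_vertices, config.radius_um, seed=derive_seed(master, "mesh")
        )
        fields = simdata.make_expression_fields(
            mesh, seed=derive_seed(master, "fields")
        )
        ref = simdata.sample_reference_profiles(
            fields, mesh, cfg=SimConfig(seed=derive_seed(master, "reference"))
        )
        series = simdata.make_stage_series(
            mesh, SimConfig(seed=derive_seed(master, "stages"))
        )
        (out / "simulate").mkdir(exist_ok=True)
        mesh.save_ply(out / "simulate" / "mesh.ply")
    except Exception as exc:  # noqa: BLE001
        _stage_fail("simulate", exc)

    # --- preprocess -----------------------------------------------------
    try:
        pseudobulks = {}
        raw = {}
        for cond in config.conditions:
            cfg = SimConfig(
                seed=derive_seed(master, f"cells:{cond.name}"),
                cells_per_spheroid=cond.cells,
            )
            cells = simdata.sample_spheroid_cells(
                fields, mesh, cond.source, cond.target, cond.lam, cfg,
                condition=cond.name,
            )
            cells = expr_io.qc_filter(
                cells, config.min_genes_detected, config.min_total_counts
            )
            cells = expr_io.normalize(cells)
            raw[cond.name] = cells
            pseudobulks[cond.name] = expr_io.pseudo_bulk(cells, "condition")[0]
    except Exception as exc:  # noqa: BLE001
        _stage_fail("preprocess", exc)

    # --- gene set -------------------------------------------------------
    try:
        vitro = list(pseudobulks.values())
        if config.gene_set_mode == "cca" and len(vitro) >= 4:
            genes, _ = lineage_space.cca_select_genes(
                ref.profiles, vitro, n_components=2, top_k=config.n_genes
            )
        else:
            genes = expr_io.select_hvg(
                expr_io.normalize(ref.counts), config.n_genes
            )
    except Exception as exc:  # noqa: BLE001
        _stage_fail("gene_set", exc)

    # --- lineage space --------------------------------------------------
    try:
        labels = [
            lineage_space.EMDISC if l.startswith("EmDisc") else lineage_space.AM
            for l in ref.lineage
        ]
        adj = lineage_space.adjust_profiles({"vivo": ref.profiles, "vitro": vitro})
        model = lineage_space.fit_pca(adj["vivo"] + adj["vitro"], genes, n_pcs=2)
        scores = np.array([lineage_space.project(p, model) for p in adj["vivo"]])
        lineage_space.attach_boundary(model, scores, labels)
        (out / "lineage").mkdir(exist_ok=True)
        model.to_json(out / "lineage" / "model.json")
        adj_vitro = {p.name: p for p in adj["vitro"]}

        stage_refs = []
        for stage in STAGES:
            cfg = SimConfig(
                seed=derive_seed(master, f"stageref:{stage}"), cells_per_spheroid=100
            )
            cells = simdata.sample_spheroid_cells(
                series[stage], mesh, "EmDisc_anterior", "EmDisc_anterior", 0.0, cfg,
                condition=stage,
            )
            stage_refs.append(expr_io.pseudo_bulk(expr_io.normalize(cells), "condition")[0])
    except Exception as exc:  # noqa: BLE001
        _stage_fail("lineage", exc)

    # --- spatial maps ---------------------------------------------------
    try:
        (out / "map").mkdir(exist_ok=True)
        static_fields = {}
        for name, pb in pseudobulks.items():
            fld = spatial_map.static_map(
                pb, ref, genes,
                optimize_hyper=config.gp_optimize,
                seed=derive_seed(master, "gp"),
            )
            static_fields[name] = fld
            spatial_map.field_to_csv(fld, out / "map" / f"static_{name}.csv")
            spatial_map.field_to_ply(fld, mesh, out / "map" / f"static_{name}.ply")
    except Exception as exc:  # noqa: BLE001
        _stage_fail("map", exc)

    # --- dynamic maps + ternary + report -------------------------------
    try:
        (out / "dynamic").mkdir(exist_ok=True)
        report_conditions = {}
        for cond in config.conditions:
            pb = pseudobulks[cond.name]
            fld = static_fields[cond.name]
            label, dval = lineage_space.classify(adj_vitro[cond.name], model)
            stage_call, stage_corr = lineage_space.assign_stage(pb, stage_refs)
            argmax = fld.argmax_vertex()
            entry = {
                "lineage_call": label,
                "decision_value": round(dval, 6),
                "stage_call": stage_call,
                "stage_correlations": {
                    k: round(v, 6) for k, v in stage_corr.items()
                },
                "static_argmax_vertex": argmax,
                "static_argmax_region": str(mesh.region_labels[argmax]),
                "static_region_means": {
                    k: round(v, 6) for k, v in fld.region_means(mesh).items()
                },
            }
            marker_means = [
                max(float(pb.values.get(g, 0.0)), 0.0) for g in config.ternary_markers
            ]
            tp = spatial_map.ternary_coords(marker_means, config.ternary_markers)
            entry["ternary"] = [round(v, 6) for v in tp.p]
            if cond.control is not None:
                dyn = spatial_map.dynamic_map(fld, static_fields[cond.control])
                spatial_map.field_to_csv(dyn, out / "dynamic" / f"dynamic_{cond.name}.csv")
                entry["dynamic_region_mean_delta"] = {
                    k: round(v, 6) for k, v in dyn.region_means(mesh).items()
                }
                ctrl_pb = pseudobulks[cond.control]
                ctrl_means = [
                    max(float(ctrl_pb.values.get(g, 0.0)), 0.0)
                    for g in config.ternary_markers
                ]
                origin, endpoint = spatial_map.ternary_arrow(
                    ctrl_means, marker_means, config.ternary_markers
                )
                entry["ternary_arrow"] = {
                    "origin": [round(v, 6) for v in origin.p],
                    "endpoint": [round(v, 6) for v in endpoint.p],
                }
            report_conditions[cond.name] = entry
    except Exception as exc:  # noqa: BLE001
        _stage_fail("report", exc)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "config_hash": chash,
        "seed": master,
        "gene_set_mode": config.gene_set_mode,
        "n_genes_used": len(genes),
        "conditions": report_conditions,
    }
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": chash,
        "files": {
            f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _write_summary(out / "summary.txt", report)
    return report


def _write_summary(path: Path, report: dict) -> None:
    lines = [
        f"spheromap run (schema v{report['schema_version']}, "
        f"software {report['software_version']})",
        f"seed {report['seed']}, gene set {report['gene_set_mode']} "
        f"({report['n_genes_used']} genes)",
        "",
    ]
    for name, entry in report["conditions"].items():
        lines.append(
            f"{name}: {entry['lineage_call']} (d={entry['decision_value']:+.3f}), "
            f"stage {entry['stage_call']}, "
            f"static argmax in {entry['static_argmax_region']}"
        )
        if "dynamic_region_mean_delta" in entry:
            deltas = entry["dynamic_region_mean_delta"]
            lines.append(
                "    dynamic mean delta: "
                + ", ".join(f"{k}={v:+.3f}" for k, v in deltas.items())
            )
    path.write_text("\n".join(lines) + "\n")
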