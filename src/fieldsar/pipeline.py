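"""End-to-end orchestration: pose RMSD → IFP → 3D-QSAR from one config.

The stages mirror the post-docking analysis order for a congeneric series:
select/check poses against the essential salt bridge, measure pose
similarity to a reference compound over common graphs, fingerprint the
complexes, then build the field-based QSAR model.  Every run writes a
``run_report.json`` with the fully resolved configuration so results are
auditable, and all tabular outputs are plain CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fields as field_mod
from .ifp import ComplexPose, IfpConfig, compute_ifp, detect_salt_bridge, occurrence_profile
from .io_dataset import ActivityTable, load_poses, load_protein
from .mcs import rmsd_table
from .pls import export_contours, select_model

log = logging.getLogger("fieldsar")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    poses: str
    activities: str | None = None
    protein: str | None = None
    output_dir: str = "fieldsar_out"
    seed: int = 0
    reference: str | None = None  # compound id for the RMSD stage
    stages: dict = field(default_factory=lambda: {"rmsd": True, "ifp": True, "qsar": True})
    rmsd: dict = field(default_factory=lambda: {"ring_relaxed": False})
    ifp: dict = field(default_factory=dict)  # IfpConfig keys + essential_residue
    fields: dict = field(default_factory=lambda: {
        "spacing": 1.0, "padding": 5.0, "cap": 30.0,
        "zero_threshold": 0.05, "nlevel_max": 4})
    srd: dict = field(default_factory=lambda: {
        "enabled": False, "n_seeds": None,
        "critical_distance": 2.0, "collinearity_cutoff": 0.8})
    pls: dict = field(default_factory=lambda: {
        "nc_max": 8, "field_sets": ["S", "E", "SE"], "contour_percentile": 85.0})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "poses" not in raw:
            raise ConfigError("config must name a 'poses' SDF file")
        cfg = cls(**raw)
        for key in ("poses", "activities", "protein"):
            path = getattr(cfg, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key} file not found: {path}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        return cls.from_dict(raw)


_FIELD_NAMES = {"S": ("steric",), "E": ("electrostatic",),
                "SE": ("steric", "electrostatic")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    report: dict = {"config": asdict(config), "outputs": {}}
    try:
        log.info("config: %s", json.dumps(asdict(config), sort_keys=True))
        mols = load_poses(config.poses)
        log.info("loaded %d poses from %s", len(mols), config.poses)
        table = (ActivityTable.read_csv(config.activities)
                 if config.activities else None)
        protein = load_protein(config.protein) if config.protein else None

        if config.stages.get("rmsd", True):
            _stage_rmsd(config, mols, out, report)
        if config.stages.get("ifp", True) and protein is not None:
            _stage_ifp(config, protein, mols, out, report)
        if config.stages.get("qsar", True) and table is not None:
            _stage_qsar(config, mols, table, out, report)
        (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage_rmsd(config, mols, out, report):
    try:
        ref = mols[0]
        if config.reference is not None:
            match = [m for m in mols if m.id == config.reference]
            if not match:
                raise ValueError(f"reference compound {config.reference!r} not in poses")
            ref = match[0]
        tab = rmsd_table(ref, mols, ring_relaxed=bool(config.rmsd.get("ring_relaxed")))
        path = out / "rmsd.csv"
        tab.to_csv(path, index=False)
        report["outputs"]["rmsd"] = str(path)
        log.info("rmsd stage: reference %s, %d probes", ref.id, len(mols))
    except Exception as exc:
        raise StageError("rmsd", exc) from exc


def _stage_ifp(config, protein, mols, out, report):
    try:
        opts = dict(config.ifp)
        essential = opts.pop("essential_residue", None)
        cfg = IfpConfig.from_dict(opts)
        complexes = [ComplexPose(protein, m) for m in mols]
        ifps = [compute_ifp(c, cfg) for c in complexes]
        long_rows = []
        for c, bits in zip(complexes, ifps):
            for res, b in bits.items():
                for bit, val in b.as_dict().items():
                    if val:
                        long_rows.append({"complex_id": c.ligand.id,
                                          "residue": res, "bit": bit, "value": 1})
        pd.DataFrame(long_rows).to_csv(out / "ifp.csv", index=False)
        occ = occurrence_profile(ifps)
        occ.rename_axis("residue").to_csv(out / "ifp_occurrence.csv")
        report["outputs"]["ifp"] = str(out / "ifp.csv")
        report["outputs"]["ifp_occurrence"] = str(out / "ifp_occurrence.csv")
        if essential:
            flags = {c.ligand.id: bool(detect_salt_bridge(
                c, essential, protonate_amines=cfg.protonate_amines))
                for c in complexes}
            report["outputs"]["essential_interaction"] = flags
            log.info("essential %s satisfied by %d/%d complexes", essential,
                     sum(flags.values()), len(flags))
    except Exception as exc:
        raise StageError("ifp", exc) from exc


def _stage_qsar(config, mols, table, out, report):
    try:
        fc = config.fields
        fm = field_mod.compute_field_matrix(
            mols, spacing=float(fc.get("spacing", 1.0)),
            padding=float(fc.get("padding", 5.0)))
        fm = field_mod.pretreat(fm, cap=float(fc.get("cap", 30.0)),
                                zero_threshold=float(fc.get("zero_threshold", 0.05)),
                                nlevel_max=int(fc.get("nlevel_max", 4)))
        fm = field_mod.buw_scale(fm)
        if config.srd.get("enabled"):
            from .pls import fit_pls
            train = table.subset("train")
            ids = [str(i) for i in (train["id"] if len(train) else table.frame["id"])]
            idx = {cid: k for k, cid in enumerate(fm.compound_ids)}
            rows = [idx[i] for i in ids]
            y = table.frame.set_index("id").loc[ids, "pKi"].to_numpy(dtype=float)
            pre = fit_pls(fm.modeling_matrix()[rows], y, min(3, len(rows) - 1))
            fm = field_mod.srd_group(
                fm, np.abs(pre.coef), n_seeds=config.srd.get("n_seeds"),
                critical_distance=float(config.srd.get("critical_distance", 2.0)),
                collinearity_cutoff=float(config.srd.get("collinearity_cutoff", 0.8)))
        nc_max = int(config.pls.get("nc_max", 8))
        sets = tuple(_FIELD_NAMES[s] for s in config.pls.get("field_sets", ["S", "E", "SE"]))
        best = select_model(fm, table, nc_range=range(1, nc_max + 1), field_sets=sets)
        best.predictions.to_csv(out / "predictions.csv", index=False,
                                float_format="%.4f")
        model_info = best.summary_row()
        model_info["contributions"] = best.contributions
        (out / "model.json").write_text(json.dumps(model_info, indent=1))
        contours = export_contours(best, out / "contours",
                                   percentile=float(config.pls.get("contour_percentile", 85.0)))
        report["outputs"]["model"] = str(out / "model.json")
        report["outputs"]["predictions"] = str(out / "predictions.csv")
        report["outputs"]["contours"] = contours
        report["model"] = model_info
        log.info("qsar stage: best model %s NC=%d Q2=%.3f", best.label,
                 best.n_components, best.q2)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("qsar", exc) from exc


def report_table1_stats(predictions: pd.DataFrame | str | Path) -> dict[str, float]:
    """Training/external statistics from an experimental-vs-predicted table.

    Needs columns experimental_pKi, predicted_pKi and split; returns
    R²_train = 1 − SSres/SStot over training rows, plus Rtest² (squared
    Pearson correlation) and S_test = sqrt(SSE/n) over test rows.
    """
    df = predictions if isinstance(predictions, pd.DataFrame) \
        else pd.read_csv(predictions)
    required = {"experimental_pKi", "predicted_pKi", "split"}
    if not required.issubset(df.columns):
        raise ValueError(f"predictions table needs columns {sorted(required)}")
    out: dict[str, float] = {}
    train = df[df["split"] == "train"]
    if len(train):
        e = train["experimental_pKi"].to_numpy(dtype=float)
        p = train["predicted_pKi"].to_numpy(dtype=float)
        out["r2_train"] = float(1.0 - np.sum((e - p) ** 2) / np.sum((e - e.mean()) ** 2))
    test = df[df["split"] == "test"]
    if len(test) >= 2:
        e = test["experimental_pKi"].to_numpy(dtype=float)
        p = test["predicted_pKi"].to_numpy(dtype=float)
        r = float(np.corrcoef(p, e)[0, 1])
        out["rtest2"] = r * r
        out["s_test"] = float(np.sqrt(np.mean((p - e) ** 2)))
    if not out:
        raise ValueError("no train or test rows found (check the split column)")
    return out
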