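"""CSV patient tables, YAML configuration, and the JSON model archive.

The patient table is a plain CSV with header
``patient_id, psa, psma, tpsa, rbc, hb, pap`` plus optional ``label, diet,
family_history, year, em`` columns.  Rows with missing, non-numeric,
negative or non-finite marker values are dropped and counted, mirroring the
"drop samples with missing or abnormal value" preprocessing step.

Trained systems persist as a single JSON document (format version string
included) holding the config, the shared standardization statistics and
every learner's parameters.  Serialization is canonical (sorted keys,
repr-faithful floats), so two identical training runs write byte-identical
archives.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec
from .core import (
    MARKER_NAMES,
    LabeledSample,
    MarkerProfile,
    StageLabel,
    Standardizer,
    SystemConfig,
)
from .nets import MLPModel, RBFModel
from .pipeline import TrainedSystem, TrainingReport
from .stacking import ELRModel
from .svm import STAGE_PAIRS, BinarySVMModel, KernelSpec, OvOGroup

logger = logging.getLogger("prostate_dss")

ARCHIVE_FORMAT_VERSION = "prostate-dss-archive-1"

MARKER_COLUMNS = list(MARKER_NAMES)
OPTIONAL_COLUMNS = ["patient_id", "label", "diet", "family_history", "year", "em"]


@dataclasses.dataclass
class DropReport:
    n_read: int
    n_kept: int
    n_dropped: int
    reasons: dict[str, int]


def read_patient_table(path: str | Path) -> tuple[list[LabeledSample], DropReport]:
    """Read a patient CSV; validate markers; drop and count bad rows.

    A missing marker column is a hard error naming the column.  Headers are
    case-insensitive and canonicalized to lower case.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in MARKER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    samples: list[LabeledSample] = []
    reasons: dict[str, int] = {}
    for _, row in df.iterrows():
        values = {}
        bad = None
        for col in MARKER_COLUMNS:
            raw = row[col]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or (
                isinstance(raw, str) and not raw.strip()
            ):
                bad = f"missing {col}"
                break
            try:
                v = float(raw)
            except (TypeError, ValueError):
                bad = f"non-numeric {col}"
                break
            if not np.isfinite(v):
                bad = f"non-finite {col}"
                break
            if v < 0:
                bad = f"negative {col}"
                break
            values[col] = v
        if bad is not None:
            reasons[bad] = reasons.get(bad, 0) + 1
            continue
        label = None
        if "label" in df.columns and isinstance(row.get("label"), str) and row["label"].strip():
            label = StageLabel.from_string(row["label"])
        def _str(col: str) -> str | None:
            v = row.get(col)
            return v.strip() if isinstance(v, str) and v.strip() else None

        fam = _str("family_history")
        year = _str("year")
        samples.append(
            LabeledSample(
                profile=MarkerProfile(**values),
                label=label,
                diet=_str("diet"),
                family_history=(int(float(fam)) if fam else None),
                year=(int(float(year)) if year else None),
                patient_id=_str("patient_id"),
            )
        )
    n_read = len(df)
    report = DropReport(
        n_read=n_read,
        n_kept=len(samples),
        n_dropped=n_read - len(samples),
        reasons=reasons,
    )
    if report.n_dropped:
        logger.info(
            "dropped %d of %d rows with missing or abnormal values: %s",
            report.n_dropped, n_read, report.reasons,
        )
    return samples, report


def write_patient_table(samples: list[LabeledSample], path: str | Path) -> None:
    """Write samples as CSV with repr-faithful floats (round-trip exact)."""
    rows = []
    for s in samples:
        row = {"patient_id": s.patient_id or ""}
        for m in MARKER_COLUMNS:
            row[m] = repr(float(getattr(s.profile, m)))
        row["label"] = str(s.label) if s.label is not None else ""
        row["diet"] = s.diet or ""
        row["family_history"] = "" if s.family_history is None else str(s.family_history)
        row["year"] = "" if s.year is None else str(s.year)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration files (flat YAML mirroring SystemConfig / CohortSpec fields)
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[SystemConfig, CohortSpec]:
    """Split a flat YAML mapping into SystemConfig and CohortSpec overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> tuple[SystemConfig, CohortSpec]:
    sys_fields = {f.name for f in dataclasses.fields(SystemConfig)}
    coh_fields = {f.name for f in dataclasses.fields(CohortSpec)}
    sys_kwargs, coh_kwargs = {}, {}
    for key, value in raw.items():
        known = False
        if key in sys_fields:
            sys_kwargs[key] = _parse_config_value(key, value)
            known = True
        if key in coh_fields:
            coh_kwargs[key] = _parse_cohort_value(key, value)
            known = True
        if not known:
            raise ValueError(f"unknown configuration key: {key}")
    return SystemConfig(**sys_kwargs), CohortSpec(**coh_kwargs)


def _parse_config_value(key: str, value):
    if key == "supervising_values":
        return {StageLabel.from_string(k): float(v) for k, v in value.items()}
    if key in ("stage_thresholds", "c_grid", "gauss_sigma_grid", "group_kernels"):
        return tuple(value)
    if key == "poly_degree_grid":
        return tuple(int(v) for v in value)
    if key == "rbf_hidden_units":
        return tuple(int(v) for v in value)
    if key == "mlp_architectures":
        return tuple(tuple(int(u) for u in arch) for arch in value)
    return value


def _parse_cohort_value(key: str, value):
    if key in ("n_per_class", "severity_location"):
        return {StageLabel.from_string(k): v for k, v in value.items()}
    return value


def save_config(config: SystemConfig, spec: CohortSpec, path: str | Path) -> None:
    doc: dict = {}
    for f in dataclasses.fields(SystemConfig):
        v = getattr(config, f.name)
        if f.name == "supervising_values":
            v = {str(k): float(val) for k, val in v.items()}
        elif isinstance(v, tuple):
            v = [list(x) if isinstance(x, tuple) else x for x in v]
        doc[f.name] = v
    for f in dataclasses.fields(CohortSpec):
        if f.name == "seed":  # SystemConfig.seed wins in the flat document
            continue
        v = getattr(spec, f.name)
        if f.name in ("n_per_class", "severity_location"):
            v = {str(k): val for k, val in v.items()}
        doc[f.name] = v
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Model archive (JSON)
# ---------------------------------------------------------------------------

def _arr(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def _enc_scaler(s: Standardizer | None) -> dict | None:
    if s is None:
        return None
    return {"mean": _arr(s.mean), "scale": _arr(s.scale)}


def _dec_scaler(d: dict | None) -> Standardizer | None:
    if d is None:
        return None
    return Standardizer(np.array(d["mean"]), np.array(d["scale"]))


def _enc_kernel(k: KernelSpec) -> dict:
    return {
        "kind": k.kind, "degree": k.degree, "sigma": k.sigma,
        "beta": k.beta, "theta": k.theta,
    }


def _dec_kernel(d: dict) -> KernelSpec:
    return KernelSpec(**d)


def _enc_svm(m: BinarySVMModel, with_scaler: bool = False) -> dict:
    return {
        "sv_x": _arr(m.sv_x),
        "sv_y": _arr(m.sv_y),
        "alpha": _arr(m.alpha),
        "b": m.b,
        "C": m.C,
        "kernel": _enc_kernel(m.kernel),
        "scaler": _enc_scaler(m.scaler) if with_scaler else None,
        "diagnostics": m.diagnostics,
    }


def _dec_svm(d: dict) -> BinarySVMModel:
    return BinarySVMModel(
        sv_x=np.array(d["sv_x"]),
        sv_y=np.array(d["sv_y"]),
        alpha=np.array(d["alpha"]),
        b=d["b"],
        C=d["C"],
        kernel=_dec_kernel(d["kernel"]),
        scaler=_dec_scaler(d.get("scaler")),
        diagnostics=d.get("diagnostics", {}),
    )


def _enc_group(g: OvOGroup) -> dict:
    return {
        "kernel_kind": g.kernel_kind,
        "models": {f"{a}|{b}": _enc_svm(m) for (a, b), m in g.models.items()},
        "diagnostics": g.diagnostics,
    }


def _dec_group(d: dict, scaler: Standardizer) -> OvOGroup:
    models = {}
    for key, enc in d["models"].items():
        a, b = key.split("|")
        models[(StageLabel.from_string(a), StageLabel.from_string(b))] = _dec_svm(enc)
    return OvOGroup(
        models=models,
        kernel_kind=d["kernel_kind"],
        scaler=scaler,
        diagnostics=d.get("diagnostics", {}),
    )


def _enc_mlp(m: MLPModel) -> dict:
    return {
        "sizes": list(m.sizes),
        "weights": [_arr(W) for W in m.weights],
        "biases": [_arr(b) for b in m.biases],
        "diagnostics": m.diagnostics,
    }


def _dec_mlp(d: dict, scaler: Standardizer) -> MLPModel:
    return MLPModel(
        sizes=tuple(d["sizes"]),
        weights=[np.array(W) for W in d["weights"]],
        biases=[np.array(b) for b in d["biases"]],
        scaler=scaler,
        diagnostics=d.get("diagnostics", {}),
    )


def _enc_rbf(m: RBFModel) -> dict:
    return {
        "centers": _arr(m.centers),
        "betas": _arr(m.betas),
        "W": _arr(m.W),
        "b": _arr(m.b),
        "diagnostics": m.diagnostics,
    }


def _dec_rbf(d: dict, scaler: Standardizer) -> RBFModel:
    return RBFModel(
        centers=np.array(d["centers"]),
        betas=np.array(d["betas"]),
        W=np.array(d["W"]),
        b=np.array(d["b"]),
        scaler=scaler,
        diagnostics=d.get("diagnostics", {}),
    )


def _enc_config(c: SystemConfig) -> dict:
    d = dataclasses.asdict(c)
    d["supervising_values"] = {str(k): float(v) for k, v in c.supervising_values.items()}
    return d


def _dec_config(d: dict) -> SystemConfig:
    d = dict(d)
    d["supervising_values"] = {
        StageLabel.from_string(k): float(v) for k, v in d["supervising_values"].items()
    }
    for key in ("stage_thresholds", "group_kernels", "c_grid", "gauss_sigma_grid",
                "poly_degree_grid", "rbf_hidden_units"):
        d[key] = tuple(d[key])
    d["mlp_architectures"] = tuple(tuple(a) for a in d["mlp_architectures"])
    return SystemConfig(**d)


def save_system(system: TrainedSystem, path: str | Path) -> None:
    """Persist a trained system as one canonical JSON archive."""
    doc = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "config": _enc_config(system.config),
        "scaler": _enc_scaler(system.scaler),
        "gate": _enc_svm(system.gate),
        "groups": [_enc_group(g) for g in system.groups],
        "mlps": [_enc_mlp(m) for m in system.mlps],
        "rbfs": [_enc_rbf(r) for r in system.rbfs],
        "elr": {
            "w": _arr(system.elr.w),
            "b": system.elr.b,
            "target_scale": system.elr.target_scale,
            "training_loss": system.elr.training_loss,
        },
        "report": {
            "learner_errors": system.report.learner_errors,
            "epsilon_ok": system.report.epsilon_ok,
            "train_indices": system.report.train_indices,
            "test_indices": system.report.test_indices,
        },
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def load_system(path: str | Path) -> TrainedSystem:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"unsupported archive format: {version!r}")
    scaler = _dec_scaler(doc["scaler"])
    gate = _dec_svm(doc["gate"])
    gate.scaler = scaler
    elr = ELRModel(
        w=np.array(doc["elr"]["w"]),
        b=doc["elr"]["b"],
        target_scale=doc["elr"]["target_scale"],
        training_loss=doc["elr"]["training_loss"],
    )
    report = TrainingReport(
        learner_errors=doc["report"]["learner_errors"],
        epsilon_ok=doc["report"]["epsilon_ok"],
        train_indices=doc["report"]["train_indices"],
        test_indices=doc["report"]["test_indices"],
    )
    return TrainedSystem(
        scaler=scaler,
        gate=gate,
        groups=[_dec_group(g, scaler) for g in doc["groups"]],
        mlps=[_dec_mlp(m, scaler) for m in doc["mlps"]],
        rbfs=[_dec_rbf(r, scaler) for r in doc["rbfs"]],
        elr=elr,
        config=_dec_config(doc["config"]),
        report=report,
    )
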