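"""Readers/writers for profile TSVs, sidecar metadata and result JSON.

Profiles travel as TSV (columns ``residue_id  nucleus  x  y  y_err``; x is
the irradiation offset in ppm for CEST and nu_CPMG in Hz for CPMG) with a
YAML sidecar of ``key: value`` metadata carrying the experiment and sample
condition.  Results serialize to JSON with stable key order, full float
precision and provenance (config hash, seed).  '#'-prefixed comment lines
are permitted in TSVs; the encoding is UTF-8 throughout.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exchange import (
    CESTExperiment,
    CESTProfile,
    Condition,
    CPMGExperiment,
    DispersionProfile,
)

__all__ = [
    "RunConfig",
    "read_profiles",
    "write_profiles",
    "write_results",
    "read_results",
    "config_hash",
]

PROFILE_COLUMNS = ["residue_id", "nucleus", "x", "y", "y_err"]

_REQUIRED_META = {
    "cest": ["kind", "b1_field", "t_cest", "nucleus_freq"],
    "cpmg": ["kind", "t_cpmg", "nucleus_freq"],
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration.

    Unknown keys in a config file are rejected with an error naming the
    offending key, so typos never silently fall back to defaults.
    """

    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1
    thresholds: dict = dataclasses.field(default_factory=dict)
    optimizer: dict = dataclasses.field(
        default_factory=lambda: {"n_starts": 5, "ftol": 1e-10, "xtol": 1e-8}
    )
    experiment: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# profile TSV + sidecar


def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(".meta.yaml")


def write_profiles(profiles, tsv_path) -> Path:
    """Write a homogeneous profile collection to TSV plus a YAML sidecar.

    All profiles must share one experiment and condition (one acquisition).
    Returns the sidecar path.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("nothing to write")
    first = profiles[0]
    is_cest = isinstance(first, CESTProfile)
    for p in profiles:
        if isinstance(p, CESTProfile) != is_cest or p.experiment != first.experiment:
            raise ValueError("profiles in one file must share an experiment")
    tsv_path = Path(tsv_path)
    rows = []
    for p in profiles:
        x = p.offsets if is_cest else p.nu_cpmg
        y = p.intensity_ratio if is_cest else p.r2_eff
        for xi, yi, ei in zip(x, y, p.errors):
            rows.append((p.residue_id, p.nucleus, xi, yi, ei))
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("# x: ppm offset (CEST) or nu_CPMG Hz (CPMG); y: I/I0 or R2eff\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    exp = first.experiment
    meta = {"kind": "cest" if is_cest else "cpmg",
            "nucleus_freq": float(exp.nucleus_freq)}
    if is_cest:
        meta.update(b1_field=float(exp.b1_field), t_cest=float(exp.t_cest))
    else:
        meta.update(t_cpmg=float(exp.t_cpmg))
    if first.condition is not None:
        meta.update(
            concentration_mM=float(first.condition.concentration),
            temperature_C=float(first.condition.temperature),
            b0_label=float(first.condition.b0_label),
        )
    side = _sidecar_path(tsv_path)
    with open(side, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return side


def _read_one(tsv_path: Path):
    side = _sidecar_path(tsv_path)
    if not side.exists():
        raise FileNotFoundError(f"{tsv_path}: missing sidecar {side.name}")
    with open(side, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    kind = meta.get("kind")
    if kind not in ("cest", "cpmg"):
        raise ValueError(f"{side}: 'kind' must be 'cest' or 'cpmg', got {kind!r}")
    missing = [k for k in _REQUIRED_META[kind] if k not in meta]
    if missing:
        raise ValueError(f"{side}: missing sidecar field(s): {', '.join(missing)}")

    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != PROFILE_COLUMNS:
        bad = [c for c in df.columns if c not in PROFILE_COLUMNS]
        want = [c for c in PROFILE_COLUMNS if c not in df.columns]
        raise ValueError(
            f"{tsv_path}: header mismatch: unexpected column(s) "
            f"{bad or '[]'}, missing {want or '[]'}"
        )
    for col in ("x", "y", "y_err"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[converted.isna() & df[col].notna()]
        if len(bad_rows):
            # +2: header line plus 1-based numbering (comment lines are
            # stripped by the reader before indexing, as documented)
            lines = ", ".join(str(i + 2) for i in bad_rows[:5])
            raise ValueError(
                f"{tsv_path}: non-numeric value(s) in column '{col}' "
                f"(data line(s) {lines})"
            )
        df[col] = converted
    if df[["x", "y", "y_err"]].isna().any().any():
        raise ValueError(f"{tsv_path}: empty numeric cells")

    condition = None
    if "concentration_mM" in meta:
        condition = Condition(
            concentration=float(meta["concentration_mM"]),
            temperature=float(meta.get("temperature_C", 25.0)),
            b0_label=float(meta.get("b0_label", 0.0) or meta["nucleus_freq"]),
        )
    out = []
    for (rid, nuc), grp in df.groupby(["residue_id", "nucleus"], sort=False):
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        e = grp["y_err"].to_numpy()
        if kind == "cest":
            exp = CESTExperiment(
                b1_field=float(meta["b1_field"]), t_cest=float(meta["t_cest"]),
                offsets=x, nucleus_freq=float(meta["nucleus_freq"]),
            )
            out.append(CESTProfile(str(rid), str(nuc), y, e, exp, condition))
        else:
            exp = CPMGExperiment(
                nu_cpmg=x, t_cpmg=float(meta["t_cpmg"]),
                nucleus_freq=float(meta["nucleus_freq"]),
            )
            out.append(DispersionProfile(str(rid), str(nuc), y, e, exp, condition))
    return out


def read_profiles(pattern) -> list:
    """Read all profile TSVs matching a path or glob into typed objects.

    Objects are typed CEST/CPMG by the sidecar ``kind``; every validation
    failure is fatal with a message naming the file, column or line.
    """
    paths = sorted(globmod.glob(str(pattern)))
    if not paths:
        p = Path(str(pattern))
        if p.exists():
            paths = [str(p)]
        else:
            raise FileNotFoundError(f"no profile files match {pattern!r}")
    out = []
    for path in paths:
        out.extend(_read_one(Path(path)))
    return out


# ---------------------------------------------------------------------------
# results JSON


def _jsonify(obj):
    if hasattr(obj, "as_dict"):
        return _jsonify(obj.as_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            raise ValueError("refusing to serialize NaN (diagnose the fit first)")
        return v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_results(results, path, seed=None, config=None) -> None:
    """Serialize results to JSON with stable ordering and provenance.

    Floats keep full precision; NaN values are refused with a diagnostic.
    ``seed`` and a hash of ``config`` are embedded so identical runs yield
    identical files.
    """
    payload = {"results": _jsonify(results)}
    if seed is not None:
        payload["seed"] = int(seed)
    if config is not None:
        payload["config_hash"] = config_hash(_jsonify(config))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
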