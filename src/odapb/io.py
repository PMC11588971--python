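"""Readers/writers for site tables, protocol records and scenario configs.

Protocol artifacts are JSON, one file per site per step, with every float
serialized through Python's ``repr`` (the shortest decimal that round-trips
the double exactly, at most 17 significant digits).  Two sites that received
the same broadcast initial value therefore serialize it to byte-identical
text, which is how the solve step verifies payload compatibility.

A ``manifest.json`` in the protocol workdir records a SHA-256 checksum per
artifact so that tampering between steps is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FitResult, GradientPayload, LocalFit, MetaEstimate, SiteData
from .errors import ProtocolError, ValidationError
from .simulate import ScenarioConfig

SCHEMA_VERSION = 1

__all__ = [
    "read_site_table",
    "write_record",
    "read_record",
    "local_fit_to_record",
    "record_to_local_fit",
    "payload_to_record",
    "record_to_payload",
    "meta_to_record",
    "record_to_meta",
    "result_to_record",
    "update_manifest",
    "verify_manifest",
    "read_scenario_config",
    "result_table",
]


# ---------------------------------------------------------------------------
# Site tables


def read_site_table(
    path,
    outcome: str,
    exposure: str,
    covariates: list[str] | None = None,
    categorical: list[str] | None = None,
    site_id: str | None = None,
    delimiter: str = ",",
) -> SiteData:
    """Read one site's delimited table into a :class:`SiteData`.

    The design matrix is assembled as (intercept, exposure, covariates...),
    with each declared categorical covariate expanded into indicator columns
    (first-observed level is the dropped reference; the level order is
    recorded in ``column_names`` as ``col=level``).  Outcomes must be
    strictly 0/1 and no cell may be missing — validation failures name the
    offending rows rather than imputing.
    """
    covariates = list(covariates or [])
    categorical = set(categorical or [])
    path = Path(path)
    # round_trip: the default C float parser can be 1 ulp off, which breaks
    # the bitwise protocol-fidelity contract between file and in-memory runs
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    needed = [outcome, exposure, *covariates]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path.name}: missing columns {missing_cols}")
    sub = df[needed]
    na_rows = sub.index[sub.isna().any(axis=1)]
    if len(na_rows):
        raise ValidationError(
            f"{path.name}: missing values in rows {na_rows[:10].tolist()}"
        )
    y_raw = df[outcome]
    bad = y_raw.index[~y_raw.isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"{path.name}: outcome column {outcome!r} has non-binary values "
            f"in rows {bad[:10].tolist()}"
        )
    n = len(df)
    columns = [np.ones(n)]
    names = ["(intercept)"]
    columns.append(df[exposure].to_numpy(dtype=float))
    names.append(exposure)
    for c in covariates:
        if c in categorical:
            levels = list(dict.fromkeys(df[c].tolist()))  # first-observed order
            for level in levels[1:]:
                columns.append((df[c] == level).to_numpy(dtype=float))
                names.append(f"{c}={level}")
        else:
            columns.append(df[c].to_numpy(dtype=float))
            names.append(c)
    return SiteData(
        outcomes=y_raw.to_numpy(dtype=int),
        design=np.column_stack(columns),
        site_id=site_id or path.stem,
        column_names=names,
    )


# ---------------------------------------------------------------------------
# JSON records (full-precision floats)


def _num(x) -> float:
    return float(x)


def _vec(v) -> list[float]:
    return [float(x) for x in np.asarray(v, dtype=float).ravel()]


def write_record(record: dict, path) -> str:
    """Serialize a record dict to JSON text (floats via exact repr), write
    it, and return the text."""
    text = json.dumps(record, indent=1, sort_keys=True)
    Path(path).write_text(text)
    return text


def read_record(path) -> dict:
    return json.loads(Path(path).read_text())


def local_fit_to_record(fit: LocalFit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "record_type": "local_fit",
        "site_id": fit.site_id,
        "estimate": _vec(fit.estimate),
        "covariance": _vec(fit.covariance),
        "p": int(fit.estimate.shape[0]),
        "n": int(fit.n),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "gradient_norm": _num(fit.gradient_norm),
    }


def record_to_local_fit(rec: dict) -> LocalFit:
    p = rec["p"]
    return LocalFit(
        estimate=np.array(rec["estimate"], dtype=float),
        covariance=np.array(rec["covariance"], dtype=float).reshape(p, p),
        n=rec["n"],
        converged=rec["converged"],
        n_iter=rec["n_iter"],
        gradient_norm=rec["gradient_norm"],
        site_id=rec["site_id"],
    )


def payload_to_record(payload: GradientPayload) -> dict:
    p = payload.theta_bar.shape[0]
    return {
        "schema_version": SCHEMA_VERSION,
        "record_type": "gradient_payload",
        "site_id": payload.site_id,
        "theta_bar": _vec(payload.theta_bar),
        "grad1": _vec(payload.grad1),
        "grad2": _vec(payload.grad2),  # row-major
        "p": int(p),
        "n": int(payload.n),
    }


def record_to_payload(rec: dict) -> GradientPayload:
    p = rec["p"]
    return GradientPayload(
        site_id=rec["site_id"],
        theta_bar=np.array(rec["theta_bar"], dtype=float),
        grad1=np.array(rec["grad1"], dtype=float),
        grad2=np.array(rec["grad2"], dtype=float).reshape(p, p),
        n=rec["n"],
    )


def meta_to_record(me: MetaEstimate) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "record_type": "meta_estimate",
        "estimate": _vec(me.estimate),
        "per_component_variance": _vec(me.per_component_variance),
        "sites_used": list(me.sites_used),
        "sites_dropped": [list(t) for t in me.sites_dropped],
    }


def record_to_meta(rec: dict) -> MetaEstimate:
    return MetaEstimate(
        estimate=np.array(rec["estimate"], dtype=float),
        per_component_variance=np.array(
            rec["per_component_variance"], dtype=float
        ),
        sites_used=list(rec["sites_used"]),
        sites_dropped=[tuple(t) for t in rec["sites_dropped"]],
    )


def result_to_record(result: FitResult) -> dict:
    p = result.estimate.shape[0]
    return {
        "schema_version": SCHEMA_VERSION,
        "record_type": "fit_result",
        "method": result.method,
        "estimate": _vec(result.estimate),
        "covariance": _vec(result.covariance),
        "rr": _vec(result.rr),
        "rr_ci_low": _vec(result.rr_ci_low),
        "rr_ci_high": _vec(result.rr_ci_high),
        "p": int(p),
        "N": int(result.N),
        "K": int(result.K),
        "lead_site": result.lead_site,
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
    }


def result_table(result: FitResult, column_names: list[str] | None = None):
    """Coefficient table (one row per parameter) as a DataFrame."""
    p = result.estimate.shape[0]
    names = column_names or ["(intercept)"] + [f"x{i}" for i in range(1, p)]
    se = result.se
    rows = []
    for i in range(p):
        row = {
            "term": names[i],
            "coef": result.estimate[i],
            "se": se[i],
        }
        if i == 0:
            row.update(rr=np.nan, rr_ci_low=np.nan, rr_ci_high=np.nan)
        else:
            row.update(
                rr=result.rr[i - 1],
                rr_ci_low=result.rr_ci_low[i - 1],
                rr_ci_high=result.rr_ci_high[i - 1],
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manifest / checksums


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def update_manifest(workdir, path, step: str) -> None:
    """Record (or refresh) the checksum of a protocol artifact."""
    workdir = Path(workdir)
    manifest_path = workdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    rel = Path(path).name
    manifest[rel] = {"step": step, "sha256": _sha256(path)}
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def verify_manifest(workdir, paths) -> None:
    """Check each artifact against the manifest; raise on any mismatch."""
    workdir = Path(workdir)
    manifest_path = workdir / "manifest.json"
    if not manifest_path.exists():
        raise ProtocolError("no manifest.json in workdir; cannot verify")
    manifest = json.loads(manifest_path.read_text())
    for path in paths:
        rel = Path(path).name
        if rel not in manifest:
            raise ProtocolError(f"artifact {rel} is not listed in the manifest")
        if manifest[rel]["sha256"] != _sha256(path):
            raise ProtocolError(
                f"artifact {rel} does not match its manifest checksum "
                "(tampered or regenerated out of protocol order)"
            )


# ---------------------------------------------------------------------------
# Scenario configs (key = value text)

_SCALARS = {
    "K": int,
    "n_per_site": int,
    "alpha": float,
    "beta1": float,
    "p_x1": float,
    "p_z1": float,
    "p_z2": float,
    "n_reps": int,
    "base_seed": int,
}


def read_scenario_config(path) -> ScenarioConfig:
    """Parse a ``key = value`` scenario file into a :class:`ScenarioConfig`.

    ``gamma`` takes three comma-separated values; ``age_dist`` takes
    ``normal,MEAN,SD`` or ``uniform,LO,HI``.
    """
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (t.strip() for t in line.split("=", 1))
        if key in _SCALARS:
            kwargs[key] = _SCALARS[key](value)
        elif key == "gamma":
            kwargs["gamma"] = tuple(float(t) for t in value.split(","))
        elif key == "age_dist":
            parts = [t.strip() for t in value.split(",")]
            kwargs["age_dist"] = (parts[0], *(float(t) for t in parts[1:]))
        else:
            raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
    return ScenarioConfig(**kwargs)


def dataclass_asdict(obj) -> dict:
    return dataclasses.asdict(obj)
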