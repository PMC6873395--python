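"""File formats: count tables, metadata, parameters, scenarios, reports.

Canonical formats are plain text: TSV for matrices (features on rows, first
column feature IDs, header row sample IDs; CSV accepted by extension),
a versioned JSON schema for simulation parameters, YAML for scenarios.
MatrixMarket ``.mtx`` ingestion is supported behind the same reader contract
via ``<stem>_features.tsv`` / ``<stem>_samples.tsv`` sidecar files.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidParameterError, TableFormatError
from .estimation import GroupedCountTable
from .evaluation import EvalReport
from .model import GroupParams, SimulationParams, SimulationResult
from .presets import PresetScenario

PARAMS_SCHEMA_VERSION = 1

__all__ = [
    "read_metadata",
    "read_count_table",
    "write_count_table",
    "read_params",
    "write_params",
    "write_simulation",
    "read_scenario",
    "write_scenario",
    "write_eval_report",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a sample metadata table with ``sample_id`` and ``group`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: metadata is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise TableFormatError(f"{path}: duplicate sample ids in metadata: {dups}")
    return dict(zip(df["sample_id"], df["group"]))


def _read_matrix(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        features = Path(f"{path.with_suffix('')}_features.tsv")
        samples = Path(f"{path.with_suffix('')}_samples.tsv")
        for sidecar in (features, samples):
            if not sidecar.exists():
                raise TableFormatError(
                    f"{path}: MatrixMarket input needs sidecar file {sidecar}"
                )
        mat = np.asarray(mmread(str(path)).todense())
        rows = features.read_text().split()
        cols = samples.read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: no sample columns found")
    return df


def read_count_table(
    path: str | Path, metadata_path: str | Path | None = None,
    group_of: Mapping[str, str] | None = None,
) -> GroupedCountTable:
    """Load and validate a features x samples count table plus group labels.

    Group labels come either from a metadata file (``sample_id``/``group``
    TSV or CSV) or from an in-memory mapping. Samples present in the counts
    but absent from the metadata are an error; extra metadata rows are
    ignored.
    """
    path = Path(path)
    df = _read_matrix(path)
    if df.empty:
        raise TableFormatError(f"{path}: empty count table")
    values = df.to_numpy()
    numeric = pd.to_numeric(df.stack(), errors="coerce").unstack()
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {values[i, j]!r}"
        )
    arr = numeric.to_numpy(dtype=float)
    frac = arr != np.floor(arr)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise TableFormatError(
            f"{path}: non-integer count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {arr[i, j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise TableFormatError(
            f"{path}: negative count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )

    if metadata_path is not None:
        group_of = read_metadata(metadata_path)
    if group_of is None:
        raise InvalidParameterError("either metadata_path or group_of is required")
    missing = [s for s in df.columns if s not in group_of]
    if missing:
        raise TableFormatError(
            f"{path}: samples missing from metadata: {sorted(map(str, missing))}"
        )
    return GroupedCountTable(
        counts=arr.astype(np.int64),
        feature_ids=tuple(map(str, df.index)),
        sample_ids=tuple(map(str, df.columns)),
        group_of={str(s): str(group_of[s]) for s in df.columns},
    )


def write_count_table(
    matrix: np.ndarray,
    feature_ids,
    sample_ids,
    path: str | Path,
    float_format: str | None = None,
) -> Path:
    path = Path(path)
    df = pd.DataFrame(matrix, index=list(feature_ids), columns=list(sample_ids))
    df.index.name = "feature_id"
    df.to_csv(path, sep=_sep_for(path), float_format=float_format)
    return path


def write_params(params: SimulationParams, path: str | Path) -> Path:
    """Serialize parameters to the versioned JSON schema (hand-editable)."""
    doc = {
        "schema_version": PARAMS_SCHEMA_VERSION,
        "feature_ids": list(params.feature_ids),
        "groups": [
            {
                "name": g.name,
                "mu": [float(x) for x in g.mu],
                "phi": [float(x) for x in g.phi],
                "lib_sizes": [int(x) for x in g.lib_sizes],
            }
            for g in params.groups
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1) + "\n")
    return path


def read_params(path: str | Path) -> SimulationParams:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise TableFormatError(f"{path}: invalid JSON: {err}") from err
    version = doc.get("schema_version")
    if version != PARAMS_SCHEMA_VERSION:
        raise TableFormatError(
            f"{path}: unsupported params schema_version {version!r} "
            f"(expected {PARAMS_SCHEMA_VERSION})"
        )
    try:
        groups = tuple(
            GroupParams(
                name=g["name"],
                mu=np.asarray(g["mu"], dtype=float),
                phi=np.asarray(g["phi"], dtype=float),
                lib_sizes=np.asarray(g["lib_sizes"], dtype=np.int64),
            )
            for g in doc["groups"]
        )
        return SimulationParams(feature_ids=tuple(doc["feature_ids"]), groups=groups)
    except KeyError as err:
        raise TableFormatError(f"{path}: missing field {err} in params file") from err


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write a simulation to ``outdir``.

    Emits ``counts.tsv`` (the synthetic OTU table), ``relative_abundances.tsv``
    (pre-sequencing ground-truth composition, columns sum to 1),
    ``metadata.tsv`` (sample to group map), ``params.json`` and
    ``manifest.json`` recording the seed needed to reproduce the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": write_count_table(
            result.counts, result.feature_ids, result.sample_ids,
            outdir / "counts.tsv",
        ),
        "rel_abundance": write_count_table(
            result.rel_abundance, result.feature_ids, result.sample_ids,
            outdir / "relative_abundances.tsv", float_format="%.17g",
        ),
        "params": write_params(result.params_used, outdir / "params.json"),
    }
    meta = pd.DataFrame(
        {"sample_id": list(result.sample_ids), "group": list(result.sample_groups)}
    )
    meta_path = outdir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    manifest = {
        "tool": "otusim",
        "version": __version__,
        "seed": result.seed,
        "population_scale": result.population_scale,
        "n_features": result.params_used.n_features,
        "n_samples": result.params_used.n_samples,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    paths["manifest"] = manifest_path
    return paths


def read_scenario(path: str | Path) -> PresetScenario:
    """Load a scenario recipe from a YAML file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise TableFormatError(f"{path}: scenario file must be a YAML mapping")
    if "depth_range" in doc:
        doc["depth_range"] = tuple(doc["depth_range"])
    doc.setdefault("name", path.stem)
    try:
        return PresetScenario(**doc)
    except TypeError as err:
        raise TableFormatError(f"{path}: bad scenario field: {err}") from err


def write_scenario(scenario: PresetScenario, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))
    return path


def write_eval_report(report: EvalReport, outdir: str | Path) -> dict[str, Path]:
    """Serialize an :class:`EvalReport` as tidy TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tests_path = outdir / "comparison_tests.tsv"
    report.tests.to_csv(tests_path, sep="\t", index=False)
    paths["tests"] = tests_path

    sp_rows = [
        {"scope": "total", "name": which, "sparsity_pct": value}
        for which, value in report.total_sparsity.items()
    ]
    for g in report.group_sparsity.index:
        for which in ("real", "sim"):
            sp_rows.append(
                {
                    "scope": "group",
                    "name": f"{g}:{which}",
                    "sparsity_pct": report.group_sparsity.loc[g, which],
                }
            )
    sp_path = outdir / "sparsity_summary.tsv"
    pd.DataFrame(sp_rows).to_csv(sp_path, sep="\t", index=False)
    paths["sparsity"] = sp_path

    r2_path = outdir / "r_squared.tsv"
    pd.DataFrame(
        [{"comparison": k, "r_squared": v} for k, v in report.r_squared.items()]
    ).to_csv(r2_path, sep="\t", index=False)
    paths["r_squared"] = r2_path

    for which in ("real", "sim"):
        frames = {
            "mean_intensity": report.group_mean_intensity[which],
            "variance": report.group_variance[which],
            "relative_variance": report.group_rv[which],
        }
        tidy = []
        for metric, frame in frames.items():
            melted = frame.reset_index(names="feature_id").melt(
                id_vars="feature_id", var_name="group", value_name="value"
            )
            melted.insert(1, "metric", metric)
            tidy.append(melted)
        path = outdir / f"group_metrics_{which}.tsv"
        pd.concat(tidy, ignore_index=True).to_csv(path, sep="\t", index=False)
        paths[f"metrics_{which}"] = path
    return paths
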