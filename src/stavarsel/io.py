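"""Reading expression matrices and metadata; writing result bundles.

Expression tables are delimited text (TSV or CSV, auto-detected by
extension) with one header row and the IDs in the first column.  The
common layout for expression matrices puts features in rows and samples in
columns, so that is the default orientation; it is a flag, not an
inference, because published tables use both layouts.

Result bundles serialize to JSON (summaries, config provenance) and TSV
(per-sample records, frequency tables) with deterministic field ordering:
two runs with the same configuration and seed produce byte-identical
files.  Wall-clock timestamps go to the run log only, never into the
serialized artifacts, precisely so that reruns can be diffed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .nested_cv import ClassificationSummary

logger = logging.getLogger(__name__)


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    return df


def read_expression_matrix(path, orientation: str = "rows-are-features") -> pd.DataFrame:
    """Load and validate a CPM expression matrix as samples x features.

    ``orientation`` says what the file's rows are; the returned frame is
    always samples x features.
    """
    if orientation not in ("rows-are-features", "rows-are-samples"):
        raise ValueError("orientation must be 'rows-are-features' or 'rows-are-samples'")
    df = _read_delimited(path)
    if orientation == "rows-are-features":
        df = df.T
    validate_expression_matrix(df, source=str(path))
    return df


def validate_expression_matrix(df: pd.DataFrame, source: str = "matrix") -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{source}: duplicate sample IDs {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{source}: duplicate feature IDs {dups}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.any().any():
        r = df.index[bad.any(axis=1)][0]
        c = df.columns[bad.any(axis=0)][0]
        raise ValueError(f"{source}: non-numeric value at sample {r!r}, feature {c!r}")
    neg = values < 0
    if neg.any().any():
        r = df.index[neg.any(axis=1)][0]
        c = df.columns[neg.any(axis=0)][0]
        raise ValueError(f"{source}: negative value at sample {r!r}, feature {c!r}")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError(f"{source}: non-finite value present")


def write_expression_matrix(df: pd.DataFrame, path, orientation: str = "rows-are-features"):
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = df.T if orientation == "rows-are-features" else df
    out.to_csv(path, sep=sep)


def read_metadata(path, comparison: tuple[str, str]) -> pd.DataFrame:
    """Load sample metadata restricted to the two requested group labels.

    The first label of ``comparison`` is the negative class, the second
    the positive class.  Returns a DataFrame indexed by sample_id with a
    ``group`` column, file order preserved.
    """
    neg, pos = comparison
    if neg == pos:
        raise ValueError("comparison labels must differ")
    df = _read_delimited(path)
    df.index.name = "sample_id"
    if "group" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'group' column")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in metadata")
    present = set(df["group"])
    missing = {neg, pos} - present
    if missing:
        raise ValueError(f"{path}: requested group(s) {sorted(missing)} not in metadata")
    return df[df["group"].isin([neg, pos])]


def align_matrix_metadata(matrix: pd.DataFrame, meta: pd.DataFrame):
    """Restrict the matrix to metadata samples; error on samples missing
    from the metadata."""
    missing = [s for s in matrix.index if s not in meta.index]
    overlap = [s for s in matrix.index if s in meta.index]
    if not overlap:
        raise ValueError("no metadata entry for any matrix sample")
    if len(overlap) < len(meta):
        absent = [s for s in meta.index if s not in matrix.index]
        raise ValueError(f"samples in metadata but absent from matrix: {absent}")
    if missing:
        logger.info("samples without metadata dropped from matrix: %s", missing)
    sub = matrix.loc[[s for s in matrix.index if s in meta.index]]
    return sub, meta.loc[sub.index]


@dataclass
class ResultBundle:
    """Everything one analysis produces, ready for serialization."""

    records: pd.DataFrame
    summaries: dict[str, ClassificationSummary]
    selected_features: list[str] = field(default_factory=list)
    frequency_table: pd.DataFrame | None = None
    step_forward_curve: pd.DataFrame | None = None
    config: RunConfig | None = None
    seed: int = 0

    def provenance(self) -> dict:
        cfg_yaml = self.config.to_yaml() if self.config else ""
        return {
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "seed": self.seed,
            "n_samples": int(len(self.records)),
        }


def _float_fmt(x):
    if isinstance(x, float):
        return round(x, 10)
    return x


def write_result_bundle(bundle: ResultBundle, out_dir) -> dict:
    """Write the bundle; returns a manifest {artifact: path}.

    JSON keys are sorted and floats rounded to 10 decimals so equal-seed
    reruns serialize byte-identically.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out}: {exc}") from exc
    manifest = {}

    records_path = out / "prediction_records.tsv"
    bundle.records.to_csv(records_path, sep="\t", index=False, float_format="%.10g")
    manifest["records"] = str(records_path)

    summary = {
        "summaries": {k: {kk: _float_fmt(vv) for kk, vv in s.to_dict().items()} for k, s in sorted(bundle.summaries.items())},
        "selected_features": list(bundle.selected_features),
        "provenance": bundle.provenance(),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["summary"] = str(summary_path)

    if bundle.config is not None:
        cfg_path = out / "config.yaml"
        cfg_path.write_text(bundle.config.to_yaml())
        manifest["config"] = str(cfg_path)

    if bundle.frequency_table is not None:
        freq_path = out / "selection_frequencies.tsv"
        bundle.frequency_table.to_csv(freq_path, sep="\t", index=False, float_format="%.10g")
        manifest["frequency_table"] = str(freq_path)
    if bundle.step_forward_curve is not None:
        curve_path = out / "step_forward_curve.tsv"
        bundle.step_forward_curve.to_csv(curve_path, sep="\t", index=False, float_format="%.10g")
        manifest["step_forward_curve"] = str(curve_path)
    return manifest
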