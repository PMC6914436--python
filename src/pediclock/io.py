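"""Containers and file formats for methylation clock data.

The central object is :class:`BetaMatrix`, a probes x samples array of
methylation beta values (fraction methylated, in [0, 1]) with NaN marking
missing measurements.  Beta matrices travel as delimited text with probe ids
in the first column and sample ids in the header row, the layout of a typical
GEO series-matrix export.  Clock models are stored as versioned JSON.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "RangeError",
    "BetaMatrix",
    "ClockModel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_metadata",
    "read_annotation",
    "intersect_platforms",
    "save_model",
    "load_model",
    "atomic_write_text",
]

#: Tokens treated as missing in delimited input (case-insensitive).
NA_TOKENS = ["", "NA", "Na", "na", "nA", "NaN", "NAN", "nan"]

MODEL_SCHEMA_VERSION = 1
_MODEL_KEYS = {
    "schema_version",
    "intercept",
    "coefficients",
    "toddler_age",
    "alpha",
    "lambda",
    "training_summary",
}


class FormatError(ValueError):
    """Malformed file: bad header, truncated JSON, wrong keys."""


class ValidationError(ValueError):
    """Structurally valid input that violates a contract (duplicates, etc.)."""


class RangeError(ValueError):
    """A beta value outside [0, 1]."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values with NaN as the missing marker.

    Parameters
    ----------
    probe_ids
        Row labels; unique, order defines row order of ``values``.
    sample_ids
        Column labels; unique.
    values
        Float array of shape ``(len(probe_ids), len(sample_ids))``.  Every
        non-NaN entry must lie in [0, 1].
    platform_of_sample
        Optional map sample id -> platform label (e.g. ``"27K"``/``"450K"``).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = finite[(finite < 0.0) | (finite > 1.0)][0]
            raise RangeError(f"beta value {bad} outside [0, 1]")

    # -- basic queries -----------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    # -- conversions and subsetting ---------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, platform_of_sample: Mapping[str, str] | None = None
    ) -> "BetaMatrix":
        return cls(
            probe_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            platform_of_sample=dict(platform_of_sample or {}),
        )

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        idx = self.probe_index()
        rows = [idx[p] for p in probes]
        return BetaMatrix(
            list(probes),
            list(self.sample_ids),
            self.values[rows, :].copy(),
            dict(self.platform_of_sample),
        )

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return BetaMatrix(
            list(self.probe_ids),
            list(samples),
            self.values[:, cols].copy(),
            {s: self.platform_of_sample[s] for s in samples if s in self.platform_of_sample},
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            list(self.probe_ids),
            list(self.sample_ids),
            self.values.copy(),
            dict(self.platform_of_sample),
        )


@dataclass
class ClockModel:
    """A sparse linear clock on the transformed-age scale.

    ``predict = F_inverse(intercept + sum_j coefficients[j] * beta[j])`` with
    the piecewise log/linear age transform F parameterized by ``toddler_age``
    (months).  ``alpha`` and ``lam`` record the elastic-net mixing and penalty
    strength used in training.
    """

    intercept: float
    coefficients: dict[str, float]
    toddler_age: float = 48.0
    alpha: float = 0.48
    lam: float = 0.000954
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intercept = float(self.intercept)
        self.coefficients = {str(k): float(v) for k, v in self.coefficients.items()}
        if not all(math.isfinite(v) for v in self.coefficients.values()):
            raise ValidationError("non-finite clock coefficient")
        if not math.isfinite(self.intercept):
            raise ValidationError("non-finite intercept")
        if not self.toddler_age > 0:
            raise ValidationError("toddler_age must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValidationError("lambda must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)


# ---------------------------------------------------------------------------
# delimited beta matrices
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if dialect not in {"csv", "tsv"}:
        raise FormatError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes x samples beta matrix from CSV/TSV.

    First column holds probe ids, header row holds sample ids.  Empty cells
    and NA/NaN tokens (any case) become missing.  Lines starting with ``#``
    are treated as provenance comments and skipped.
    """
    sep = _sep_for(path, dialect)
    try:
        frame = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=NA_TOKENS,
            keep_default_na=False,
            comment="#",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if frame.index.name is None and frame.index.size and frame.columns.size == 0:
        raise FormatError(f"{path}: no sample columns found")
    if frame.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in header")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate probe id {dup!r}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric beta value: {exc}") from exc
    finite = values[~np.isnan(values)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise RangeError(f"{path}: beta value outside [0, 1]")
    return BetaMatrix(
        [str(i) for i in frame.index], [str(c) for c in frame.columns], values
    )


def write_beta_matrix(
    m: BetaMatrix,
    path: str | Path,
    dialect: str | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a beta matrix as delimited text (NaN -> empty cell)."""
    sep = _sep_for(path, dialect)
    text = m.to_frame().to_csv(sep=sep, na_rep="", index_label="probe_id")
    if header_comment:
        text = f"# {header_comment}\n{text}"
    atomic_write_text(path, text)


# ---------------------------------------------------------------------------
# sample metadata and probe annotation
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (CSV).

    Requires columns ``sample_id`` and ``age_months`` (or ``age_years``,
    converted by x12).  Optional columns ``sex`` (M/F/unknown), ``group``,
    ``dataset_id`` are filled with defaults when absent; extra columns pass
    through untouched.
    """
    meta = pd.read_csv(path, comment="#")
    if "sample_id" not in meta.columns:
        raise FormatError(f"{path}: missing required column sample_id")
    if "age_months" not in meta.columns:
        if "age_years" in meta.columns:
            meta["age_months"] = meta["age_years"].astype(float) * 12.0
        else:
            raise FormatError(f"{path}: missing required column age_months")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["age_months"] = meta["age_months"].astype(float)
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    if (meta["age_months"] <= 0).any():
        raise ValidationError(f"{path}: age_months must be positive")
    for col, default in (("sex", "unknown"), ("group", ""), ("dataset_id", "")):
        if col not in meta.columns:
            meta[col] = default
        meta[col] = meta[col].fillna(default).astype(str)
    return meta


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read probe annotation (CSV): probe_id, chromosome, gene, on_27k, on_450k."""
    ann = pd.read_csv(path, comment="#")
    required = {"probe_id", "chromosome", "on_27k", "on_450k"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    ann["probe_id"] = ann["probe_id"].astype(str)
    if ann["probe_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate probe_id in annotation")
    for col in ("on_27k", "on_450k"):
        ann[col] = ann[col].astype(bool)
    if "gene" not in ann.columns:
        ann["gene"] = ""
    return ann


def _norm_chrom(c: str) -> str:
    c = str(c).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def intersect_platforms(
    matrices: Sequence[BetaMatrix], annotation: pd.DataFrame
) -> BetaMatrix:
    """Merge per-dataset matrices onto the cross-platform autosomal probe set.

    Keeps probes flagged on both the 27K and 450K arrays whose chromosome is
    not X or Y, concatenates samples in input order, and marks probes absent
    from a source matrix as missing for that matrix's samples.  Probe order
    in the output is lexicographic for determinism.
    """
    if not matrices:
        raise ValidationError("need at least one beta matrix")
    ann = annotation.set_index("probe_id")
    all_probes: set[str] = set()
    for m in matrices:
        all_probes.update(m.probe_ids)
    unknown = all_probes - set(ann.index)
    if unknown:
        raise ValidationError(
            f"annotation does not cover {len(unknown)} probes, "
            f"e.g. {sorted(unknown)[:3]}"
        )
    chrom = ann["chromosome"].map(_norm_chrom)
    eligible = set(
        ann.index[ann["on_27k"] & ann["on_450k"] & ~chrom.isin(["X", "Y"])]
    )
    probes = sorted(all_probes & eligible)

    sample_ids: list[str] = []
    for m in matrices:
        sample_ids.extend(m.sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample id across input matrices")

    values = np.full((len(probes), len(sample_ids)), np.nan)
    platform: dict[str, str] = {}
    row_of = {p: i for i, p in enumerate(probes)}
    col = 0
    for m in matrices:
        keep = [(row_of[p], i) for i, p in enumerate(m.probe_ids) if p in row_of]
        if keep:
            rows, src = zip(*keep)
            values[list(rows), col : col + m.n_samples] = m.values[list(src), :]
        platform.update(m.platform_of_sample)
        col += m.n_samples
    return BetaMatrix(probes, sample_ids, values, platform)


# ---------------------------------------------------------------------------
# clock model JSON
# ---------------------------------------------------------------------------

def save_model(model: ClockModel, path: str | Path) -> None:
    """Serialize a clock model to versioned JSON (lossless float round-trip)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "toddler_age": model.toddler_age,
        "alpha": model.alpha,
        "lambda": model.lam,
        "training_summary": model.training_summary,
    }
    atomic_write_text(path, json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_model(path: str | Path) -> ClockModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not valid clock-model JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: expected a JSON object")
    keys = set(payload)
    if keys != _MODEL_KEYS:
        missing, extra = _MODEL_KEYS - keys, keys - _MODEL_KEYS
        raise FormatError(
            f"{path}: bad model keys (missing {sorted(missing)}, extra {sorted(extra)})"
        )
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema_version {payload['schema_version']!r}"
        )
    return ClockModel(
        intercept=payload["intercept"],
        coefficients=payload["coefficients"],
        toddler_age=payload["toddler_age"],
        alpha=payload["alpha"],
        lam=payload["lambda"],
        training_summary=payload["training_summary"],
    )


# ---------------------------------------------------------------------------
# atomic writes (no partial output files)
# ---------------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename, never leaving partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
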