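"""Readers and writers for on-disk artifacts.

Expression matrices travel as tab-separated text (probes x samples,
linear-scale intensities), gene sets as GMT, clinical and score tables as
CSV, and fitted models as JSON with a schema version field.  Every
reader validates the invariants of the in-memory type it produces and
every reader/writer pair is a lossless round trip to 12 significant
digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "CANONICAL_FEATURES",
    "PBT_FEATURES",
    "CLASSIFIER_FEATURES",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_scores",
    "write_scores",
    "write_model",
    "read_model",
    "model_roundtrip",
]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed data violates a domain-type invariant."""


#: Canonical 12-feature ordering of the injury score matrix: eight PBT
#: fold-change scores followed by the four molecular classifier
#: probabilities.
PBT_FEATURES = ["DAMP", "IRRAT", "IRITD3", "IRITD5", "IGT", "MCAT", "KT1", "KT2"]
CLASSIFIER_FEATURES = ["ciProb", "ctProb", "lowGFRProb", "ProtProb"]
CANONICAL_FEATURES = PBT_FEATURES + CLASSIFIER_FEATURES


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of positive linear-scale intensities.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    control_sample_ids
        Samples designated as the control (nephrectomy) population used
        as the fold-change baseline.
    """

    values: pd.DataFrame
    control_sample_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.control_sample_ids = [str(c) for c in self.control_sample_ids]
        self.validate()

    # -- convenience views ---------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def biopsy_ids(self) -> list[str]:
        """Sample ids that are not controls."""
        ctrl = set(self.control_sample_ids)
        return [s for s in self.values.columns if s not in ctrl]

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite intensity at probe {idx[r]!r}, sample {cols[c]!r}"
            )
        if (vals <= 0).any():
            r, c = np.argwhere(vals <= 0)[0]
            raise ValidationError(
                f"non-positive intensity {vals[r, c]!r} at probe "
                f"{idx[r]!r}, sample {cols[c]!r}; intensities must be "
                "positive linear-scale values"
            )
        missing = set(self.control_sample_ids) - set(map(str, cols))
        if missing:
            raise ValidationError(
                f"control sample ids not present in matrix: {sorted(missing)}"
            )


def read_expression(path: str | Path, control_ids: Sequence[str] = ()) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column holds probe ids, the header row holds sample ids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), list(control_ids))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    probe_ids: tuple[str, ...]
    annotation: str = ""


@dataclasses.dataclass
class GeneSetCollection:
    """Ordered collection of named, non-empty gene (probe) sets."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene-set names: {dup}")
        for s in self.sets:
            if len(s.probe_ids) == 0:
                raise ValidationError(f"gene set {s.name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: list[GeneSet] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected name, description, members")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name, tuple(members), desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.annotation, *s.probe_ids]) for s in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------

#: column -> (dtype kind, required)
CLINICAL_SCHEMA: dict[str, tuple[str, bool]] = {
    "sample_id": ("str", True),
    "patient_id": ("str", True),
    "days_post_transplant": ("int", True),
    "egfr": ("float", False),
    "proteinuria_positive": ("bool", False),
    "donor_age": ("float", False),
    "deceased_donor": ("bool", False),
    "dgf": ("bool", False),
    "ci_score": ("int", False),
    "ct_score": ("int", False),
    "i_score": ("int", False),
    "ti_score": ("int", False),
    "histology_dx": ("str", False),
    "rejection_group": ("str", False),
    "pct_cortex_estimate": ("float", False),
    "followup_days": ("int", False),
    "graft_failed": ("bool", False),
    "died_with_function": ("bool", False),
}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    out = []
    for i, v in col.items():
        if pd.isna(v) or (isinstance(v, str) and not v.strip()):
            out.append(pd.NA)
        elif isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key not in _BOOL_MAP:
                raise FormatError(
                    f"row {i}, column {name!r}: cannot parse {v!r} as boolean"
                )
            out.append(_BOOL_MAP[key])
    return pd.array(out, dtype="boolean")


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a clinical table in place; returns the typed frame."""
    for col, (kind, required) in CLINICAL_SCHEMA.items():
        if col not in df.columns:
            if required:
                raise FormatError(f"clinical table missing required column {col!r}")
            df[col] = pd.NA
    for col, (kind, required) in CLINICAL_SCHEMA.items():
        s = df[col]
        try:
            if kind == "str":
                df[col] = s.astype("string") if not required else s.astype(str)
            elif kind == "int":
                as_float = pd.array(s, dtype="Float64")
                frac = as_float.to_numpy(dtype=float, na_value=0.0) % 1
                if (frac != 0).any():
                    raise ValueError(f"non-integer value in integer column {col!r}")
                df[col] = as_float.astype("Int64")
            elif kind == "float":
                df[col] = pd.array(s, dtype="Float64")
            elif kind == "bool":
                df[col] = _parse_bool_column(s, col)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"column {col!r}: {exc}") from exc
        if required and df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise ValidationError(f"row {row}: required column {col!r} is missing")

    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate sample_id values: {dup}")
    if (df["days_post_transplant"] < 0).any():
        row = df.index[df["days_post_transplant"] < 0][0]
        raise ValidationError(f"row {row}: negative days_post_transplant")
    bad = df["followup_days"].notna() & (df["followup_days"] < 0)
    if bad.any():
        row = df.index[bad][0]
        raise ValidationError(f"row {row}: negative followup_days")
    both = (df["graft_failed"].fillna(False) & df["died_with_function"].fillna(False))
    if both.any():
        row = df.index[both][0]
        raise ValidationError(
            f"row {row}: graft_failed and died_with_function cannot both be true"
        )
    for col, hi in [("ci_score", 3), ("ct_score", 3), ("i_score", 3), ("ti_score", 3)]:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > hi)).any():
            raise ValidationError(f"column {col!r}: lesion scores must be in 0..{hi}")
    return df.reset_index(drop=True)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-biopsy clinical CSV (comma, UTF-8, header)."""
    try:
        df = pd.read_csv(path, dtype="object")
    except Exception as exc:
        raise FormatError(f"cannot parse clinical CSV {path}: {exc}") from exc
    # numeric columns get a targeted error with row/column position
    for col, (kind, _) in CLINICAL_SCHEMA.items():
        if col not in df.columns or kind not in ("int", "float"):
            continue
        for i, v in df[col].items():
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                continue
            try:
                float(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {i}, column {col!r}: unparseable numeric {v!r}"
                ) from None
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ScoreTable
# ---------------------------------------------------------------------------

def validate_scores(df: pd.DataFrame, require_canonical: bool = False) -> pd.DataFrame:
    if df.index.duplicated().any():
        raise ValidationError("duplicate sample ids in score table")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValidationError(f"score table has missing values in column {col!r}")
    if require_canonical and list(df.columns) != CANONICAL_FEATURES:
        raise ValidationError(
            f"expected canonical 12-feature columns {CANONICAL_FEATURES}, "
            f"got {list(df.columns)}"
        )
    for col in df.columns:
        if col in PBT_FEATURES and (df[col] <= 0).any():
            raise ValidationError(f"PBT column {col!r} must be strictly positive")
        if col in CLASSIFIER_FEATURES and ((df[col] < 0) | (df[col] > 1)).any():
            raise ValidationError(f"classifier column {col!r} must lie in [0, 1]")
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return validate_scores(df.astype(float))


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# Model serialization (JSON)
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def write_model(model, path: str | Path) -> None:
    """Serialize an ArchetypeModel (or any object with ``to_dict``) to JSON."""
    payload = model.to_dict()
    payload["schema_version"] = MODEL_SCHEMA_VERSION
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: str | Path):
    from .injury_space import ArchetypeModel

    payload = json.loads(Path(path).read_text())
    version = payload.pop("schema_version", None)
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(f"unsupported model schema version: {version!r}")
    return ArchetypeModel.from_dict(payload)


def model_roundtrip(model):
    """Round-trip a model through its JSON representation (lossless to 1e-9)."""
    import tempfile

    with tempfile.NamedTemporaryFile("w+", suffix=".json", delete=True) as fh:
        write_model(model, fh.name)
        return read_model(fh.name)
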