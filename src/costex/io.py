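"""Table and configuration I/O.

All interchange files are tab-separated UTF-8 text with '.' decimals.
Files written by this package carry provenance comment lines
(``# key=value``) before the header row; :func:`read_table` skips them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

logger = logging.getLogger("costex")

__all__ = [
    "TableSchema",
    "SchemaError",
    "read_table",
    "write_table",
    "config_hash",
    "load_config",
    "dump_config",
]

_KINDS = {
    "str": str,
    "int": "int64",
    "float": float,
    "bool": "bool",
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Declared columns (name -> kind in {str,int,float,bool}) plus an
    optional column required to be unique (e.g. a gene ID)."""

    columns: Dict[str, str]
    key: Optional[str] = None


def read_table(path, schema: Optional[TableSchema] = None) -> pd.DataFrame:
    """Read a TSV, validating against ``schema`` when given.

    Missing columns raise :class:`SchemaError` naming the column;
    duplicated values in the schema's key column are likewise rejected.
    Extra columns are kept as-is.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if schema is not None:
        for name, kind in schema.columns.items():
            if name not in df.columns:
                raise SchemaError(f"{path.name}: missing required column '{name}'")
            try:
                if kind == "bool":
                    df[name] = df[name].map(
                        {"0": False, "1": True, "False": False, "True": True}
                    )
                    if df[name].isna().any():
                        raise ValueError("unparseable boolean")
                else:
                    df[name] = df[name].astype(_KINDS[kind])
            except (ValueError, KeyError) as exc:
                raise SchemaError(
                    f"{path.name}: column '{name}' is not of kind '{kind}': {exc}"
                ) from exc
        if schema.key is not None and df[schema.key].duplicated().any():
            dupes = df[schema.key][df[schema.key].duplicated()].iloc[0]
            raise SchemaError(
                f"{path.name}: duplicate values in key column "
                f"'{schema.key}' (e.g. {dupes!r})"
            )
    else:
        # best-effort numeric conversion when no schema is declared
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    logger.info("read %d rows from %s", len(df), path)
    return df


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a TSV with provenance comment lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    logger.info("wrote %d rows to %s", len(df), path)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def config_hash(cfg) -> str:
    """Short stable digest of a config dataclass, for provenance headers."""
    plain = yaml.safe_dump(_to_plain(cfg), sort_keys=True)
    return hashlib.sha1(plain.encode("utf-8")).hexdigest()[:12]


def dump_config(cfg, path) -> None:
    """Write a dataclass config as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_config(path, cls, **overrides):
    """Load a YAML mapping into dataclass ``cls``, rejecting unknown keys.

    Nested dataclass fields declared as tuples of dataclasses are rebuilt
    when the class exposes ``_nested`` mapping field name -> element type.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    raw.update(overrides)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    nested = getattr(cls, "_nested", {})
    for key, elem_cls in nested.items():
        if key in raw and raw[key] is not None:
            raw[key] = tuple(
                elem_cls(**v) if isinstance(v, dict) else v for v in raw[key]
            )
    for key, value in list(raw.items()):
        if isinstance(value, list):
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return cls(**raw)
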