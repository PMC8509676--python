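"""CSV/config input validation and structured JSON fit reports."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["read_table", "FitReport", "write_report", "read_report", "file_digest"]


def read_table(path, columns: dict[str, str] | list[str]) -> pd.DataFrame:
    """Read a CSV table and validate the expected numeric columns.

    ``columns`` maps required column names to unit strings (or is a plain
    list of names); the unit convention is carried in suffixes such as
    ``_uM``, ``_percent_vv``, ``_ucal``, ``_T_per_cm``.  Decimal commas
    are rejected with a locale hint; RFC-4180 dot-decimal CSV is expected.
    """
    path = Path(path)
    names = list(columns)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if df.shape[0] == 0:
        raise ValueError(f"{path.name}: empty data (header only)")
    out = {}
    for col in names:
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if raw.isna().any():
            row = int(raw.index[raw.isna()][0]) + 2  # header is line 1
            raise ValueError(f"{path.name}: missing value in column {col!r} at line {row}")
        if bad.any():
            row = int(bad.index[bad][0])
            cell = raw.iloc[row]
            hint = ""
            if "," in str(cell):
                hint = " (decimal commas are not supported; use dot-decimal CSV)"
            raise ValueError(
                f"{path.name}: non-numeric value {cell!r} in column {col!r} "
                f"at line {row + 2}{hint}"
            )
        out[col] = vals.astype(float)
    return pd.DataFrame(out)


def file_digest(path) -> str:
    """sha256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class FitReport:
    """Serializable record of one analysis: estimates, flags, provenance.

    ``estimates`` maps parameter names to ``{"value", "stderr", "unit"}``
    dicts; estimates of flagged (unmeasurable) parameters are omitted
    rather than reported as numbers.  ``derived`` holds quantities
    computed from the estimates (populations, radii, c-values, ...).
    """

    kind: str
    estimates: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    input_digest: str | None = None
    seed: int | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "estimates": self.estimates,
            "derived": self.derived,
            "flags": self.flags,
            "input_digest": self.input_digest,
            "seed": self.seed,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitReport":
        return cls(
            kind=d["kind"],
            estimates=d.get("estimates", {}),
            derived=d.get("derived", {}),
            flags=d.get("flags", {}),
            input_digest=d.get("input_digest"),
            seed=d.get("seed"),
            version=d.get("version", __version__),
        )


def _round_floats(obj):
    """Round floats to 6 significant digits for stable serialization."""
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(report: FitReport, path=None) -> str:
    """Serialize a report to deterministic JSON; write it when ``path``
    is given and return the JSON text either way."""
    text = json.dumps(_round_floats(report.to_dict()), sort_keys=True, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_report(path) -> FitReport:
    return FitReport.from_dict(json.loads(Path(path).read_text()))
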