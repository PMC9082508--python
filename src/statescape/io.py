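"""Matrix exchange formats and reproducible table export.

Hamiltonians travel either as JSON objects ``{basis_order, bond_length,
matrix}`` (matrix row-major) or as plain whitespace-delimited text (one row
per line); both round-trip at full double precision.  Record tables are
exported as JSON or CSV with a comment header carrying the package version,
the seed and a hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "write_hamiltonian",
    "read_hamiltonian",
    "export_table",
    "read_table",
]


def write_hamiltonian(path, matrix, bond_length: float | None = None,
                      basis_order=None, fmt: str | None = None) -> None:
    """Write a symmetric matrix as JSON or delimited text (inferred from suffix)."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "text")
    if fmt == "json":
        payload = {
            "basis_order": list(basis_order) if basis_order is not None else None,
            "bond_length": bond_length,
            "matrix": [[float(x) for x in row] for row in matrix],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        lines = [" ".join(repr(float(x)) for x in row) for row in matrix]
        path.write_text("\n".join(lines) + "\n")


def read_hamiltonian(path) -> np.ndarray:
    """Read a matrix written by :func:`write_hamiltonian` (JSON or text)."""
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith("{"):
        payload = json.loads(text)
        return np.asarray(payload["matrix"], dtype=float)
    rows = [[float(x) for x in line.replace(",", " ").split()]
            for line in text.splitlines() if line.strip() and not line.startswith("#")]
    return np.asarray(rows, dtype=float)


def _config_hash(config: dict | None) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("statescape")
    except PackageNotFoundError:  # pragma: no cover - source tree use
        return "unknown"


def export_table(records, path, fmt: str = "csv", seed=None,
                 config: dict | None = None) -> None:
    """Write a record table with a reproducibility header.

    ``records`` is a DataFrame or a list of dicts/dataclasses; every numeric
    field round-trips at full double precision.
    """
    if fmt not in ("csv", "json"):
        raise ConfigError(f"unsupported export format {fmt!r}")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__
                             if np.isscalar(getattr(r, k)) or
                             isinstance(getattr(r, k), (tuple, str))})
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    header = {"version": _version(), "seed": seed, "config_hash": _config_hash(config)}
    path = Path(path)
    if fmt == "json":
        def _plain(o):
            return o.item() if hasattr(o, "item") else str(o)
        payload = {"header": header, "records": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1, default=_plain) + "\n")
    else:
        buf = _io.StringIO()
        for k, v in header.items():
            buf.write(f"# {k}={v}\n")
        # shortest round-trip representation keeps numeric fields bit-exact
        df.to_csv(buf, index=False, float_format=lambda v: repr(float(v)))
        path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`export_table` (either format)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        payload = json.loads(text)
        return pd.DataFrame(payload["records"])
    return pd.read_csv(_io.StringIO(text), comment="#",
                       float_precision="round_trip")
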