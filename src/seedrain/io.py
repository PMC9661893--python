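"""Readers and writers for the study tables and posterior draws.

All tables are UTF-8 CSV with a header row. Unknown columns are ignored
with a logged warning; missing required columns raise :class:`SchemaError`;
rows violating type invariants raise :class:`ValidationError` listing the
offending zero-based row indices.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import (
    PatchInfo,
    PosteriorDraws,
    SchemaError,
    SiteWind,
    TransectInfo,
    TrapObservation,
    ValidationError,
)

log = logging.getLogger("seedrain")

PathLike = Union[str, Path]

_SCHEMAS: Dict[str, Dict[str, type]] = {
    "traps": {
        "site_id": str, "patch_id": str, "transect_id": str, "trap_id": str,
        "trap_kind": str, "dist_trap": float, "capture_height": float,
        "area": float, "days_deployed": float, "n_seeds": int,
    },
    "patches": {
        "patch_id": str, "site_id": str, "n_reproductive": int,
        "seeds_per_plant": float, "total_available_seed": float,
        "canopy_height_class": float,
    },
    "transects": {
        "transect_id": str, "patch_id": str, "azimuth": float,
        "wind_orient": float, "wind_face": bool,
    },
    "wind": {
        "site_id": str, "gust_headings": str, "U": float,
    },
}

_RECORD_TYPES = {
    "traps": TrapObservation,
    "patches": PatchInfo,
    "transects": TransectInfo,
    "wind": SiteWind,
}


def format_headings(headings: Sequence[Tuple[float, float]]) -> str:
    """Serialize gust-heading intervals as ``'lo-hi;lo-hi'`` (degrees)."""
    return ";".join(f"{float(lo)!r}-{float(hi)!r}" for lo, hi in headings)


_FLOAT_RE = re.compile(r"[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?")


def parse_headings(text: str) -> Tuple[Tuple[float, float], ...]:
    out = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        nums = _FLOAT_RE.findall(part)
        if not nums:
            raise ValueError(f"cannot parse gust heading {part!r}")
        lo_f = float(nums[0])
        hi_f = float(nums[-1]) if len(nums) > 1 else lo_f
        out.append((lo_f, hi_f))
    return tuple(out)


def _coerce(value, typ, col: str, row: int):
    try:
        if typ is bool:
            if isinstance(value, (bool, np.bool_)):
                return bool(value)
            s = str(value).strip().lower()
            if s in ("true", "1", "yes"):
                return True
            if s in ("false", "0", "no"):
                return False
            raise ValueError(s)
        if typ is int:
            f = float(value)
            if not f.is_integer():
                raise ValueError(value)
            return int(f)
        return typ(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row}: column {col!r} has non-{typ.__name__} value {value!r}", rows=[row]
        ) from exc


def read_table(path: PathLike, schema: str):
    """Read and validate one of the study tables.

    Parameters
    ----------
    path : path to a delimited text file with a header row.
    schema : one of ``'traps'``, ``'patches'``, ``'transects'``, ``'wind'``.

    Returns
    -------
    list of the matching record dataclass, in file row order.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing} for schema {schema!r}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path.name, extra)

    records = []
    bad_rows: List[int] = []
    messages: List[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        kwargs = {}
        try:
            for col, typ in cols.items():
                raw = getattr(row, col)
                if schema == "wind" and col == "gust_headings":
                    kwargs[col] = parse_headings(raw)
                else:
                    kwargs[col] = _coerce(raw, typ, col, i)
            rec = _RECORD_TYPES[schema](**kwargs)
            rec.validate()
        except ValidationError as exc:
            bad_rows.append(i)
            messages.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    if bad_rows:
        raise ValidationError(
            f"{path.name} ({schema}): {len(bad_rows)} invalid row(s):\n  " + "\n  ".join(messages),
            rows=bad_rows,
        )
    return records


def write_table(records: Sequence, path: PathLike) -> None:
    """Write records (a uniform sequence of study dataclasses) as CSV."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty table")
    rows = []
    for rec in records:
        d = rec.__dict__.copy()
        if isinstance(rec, SiteWind):
            d["gust_headings"] = format_headings(rec.gust_headings)
        rows.append(d)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_posterior(draws: PosteriorDraws, path: PathLike) -> None:
    """Write posterior draws as a long-format CSV (chain, iteration, parameter, value).

    The write/read round trip is exact: values are serialized with ``repr``
    so every float64 survives bit-identically.
    """
    if not draws.draws:
        raise ValueError("posterior is empty; nothing to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chain,iteration,parameter,value\n")
        for name, arr in draws.draws.items():
            a = arr if arr.ndim == 3 else arr[:, :, None]
            n_chain, n_draw, k = a.shape
            for c in range(n_chain):
                for d in range(n_draw):
                    for j in range(k):
                        pname = name if arr.ndim == 2 else f"{name}[{j}]"
                        fh.write(f"{c},{d},{pname},{float(a[c, d, j])!r}\n")


def read_posterior(path: PathLike) -> PosteriorDraws:
    """Read a long-format posterior CSV back into :class:`PosteriorDraws`.

    Convergence metadata (r-hat) is not stored in the CSV; the returned
    object carries empty diagnostics with ``converged=True`` as a marker
    that no diagnostic contradicts it.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"chain", "iteration", "parameter", "value"}
    if not need.issubset(df.columns):
        raise SchemaError(f"posterior file missing columns {sorted(need - set(df.columns))}")
    n_chain = int(df["chain"].max()) + 1
    n_draw = int(df["iteration"].max()) + 1
    base_names: Dict[str, int] = {}
    for p in df["parameter"].unique():
        if p.endswith("]"):
            base, idx = p[:-1].rsplit("[", 1)
            base_names[base] = max(base_names.get(base, 0), int(idx) + 1)
        else:
            base_names[p] = 0
    out: Dict[str, np.ndarray] = {}
    for base, k in base_names.items():
        shape = (n_chain, n_draw) if k == 0 else (n_chain, n_draw, k)
        out[base] = np.full(shape, np.nan)
    for chain, it, p, v in df[["chain", "iteration", "parameter", "value"]].itertuples(index=False):
        if p.endswith("]"):
            base, idx = p[:-1].rsplit("[", 1)
            out[base][int(chain), int(it), int(idx)] = v
        else:
            out[p][int(chain), int(it)] = v
    return PosteriorDraws(draws=out, rhat={}, converged=True)
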