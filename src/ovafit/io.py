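"""CSV readers/writers with schema validation and report formatting.

CSV dialect: UTF-8, comma-separated, mandatory header, "." decimal point.
Malformed rows are rejected individually with their line numbers logged;
structurally broken files (missing columns, empty) raise :class:`DataError`.

Reports mirror the published table conventions: curve parameters to three
significant figures with the 95% CI in parentheses, e.g. ``40.1(39.9–40.2)``,
regression coefficients to three decimals. The CI dash is an en-dash by
default, switchable to an ASCII hyphen for portability.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from .birth import KNOWN_GRADES
from .errors import DataError

logger = logging.getLogger("ovafit")

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_report",
    "format_estimate_ci",
    "write_run_log",
]


def _is_01(v) -> bool:
    return v in (0, 1)


def _nonneg(v) -> bool:
    return v >= 0


#: schema id -> {column: (converter, validator or None)}; None validator
#: means any converted value is accepted. Optional columns are suffixed "?".
SCHEMAS: Dict[str, Dict[str, tuple]] = {
    "weighted_series": {
        "x": (float, None),
        "y": (float, lambda v: 0 <= v <= 100),
        "n": (int, lambda v: v >= 1),
    },
    "events": {"x": (float, None), "outcome": (int, _is_01)},
    "quant": {"age": (int, None), "value": (float, _nonneg)},
    "svbt": {
        "age": (float, None),
        "gardner": (lambda s: str(s).strip().upper(), lambda v: v in KNOWN_GRADES),
        "culture_day": (int, lambda v: v in (5, 6)),
        "live_birth": (int, _is_01),
    },
    "opu": {
        "age": (float, None),
        "cycle_index": (int, lambda v: v >= 1),
        "factor_value": (float, _nonneg),
        "live_birth": (int, _is_01),
        "censored_reason?": (str, None),
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Returns typed rows; each malformed row is dropped with its (1-based,
    header included) line number logged. Missing required columns or an
    empty/headerless file raise :class:`DataError`.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty file: {path}") from None
    spec = SCHEMAS[schema]
    required = [c for c in spec if not c.endswith("?")]
    optional = {c[:-1]: spec[c] for c in spec if c.endswith("?")}
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing} for schema {schema!r}")
    if len(raw) == 0:
        logger.warning("read_table: %s contains a header but no rows", path)
        cols = required + [c for c in optional if c in raw.columns]
        return pd.DataFrame(columns=cols)

    cols = {c: spec[c] for c in required}
    cols.update({c: conv for c, conv in optional.items() if c in raw.columns})
    out_rows, bad = [], []
    for i, row in raw.iterrows():
        line_no = i + 2  # 1-based, after the header line
        parsed = {}
        try:
            for col, (conv, check) in cols.items():
                val = conv(row[col])
                if check is not None and not check(val):
                    raise ValueError(f"invalid {col}={row[col]!r}")
                parsed[col] = val
        except (ValueError, TypeError) as exc:
            bad.append((line_no, str(exc)))
            continue
        out_rows.append(parsed)
    for line_no, msg in bad:
        logger.warning("read_table: %s line %d rejected: %s", path, line_no, msg)
    logger.info(
        "read_table: %s -> %d rows accepted, %d rejected", path, len(out_rows), len(bad)
    )
    return pd.DataFrame(out_rows, columns=list(cols))


def _sig3(v: float) -> str:
    return f"{float(v):.3g}"


def format_estimate_ci(
    estimate: float, lo: float, hi: float, fmt: Callable[[float], str] = _sig3,
    en_dash: bool = True,
) -> str:
    """``40.1(39.9–40.2)``-style display string."""
    dash = "–" if en_dash else "-"
    return f"{fmt(estimate)}({fmt(lo)}{dash}{fmt(hi)})"


def write_report(
    fits: dict,
    path,
    en_dash: bool = True,
) -> Optional[pd.DataFrame]:
    """Write fitted parameter tables to one tidy CSV.

    ``fits`` maps a label to an object exposing ``to_frame()`` with columns
    ``param``/``variable``, ``estimate``/``coef``, ``ci_low``, ``ci_high``
    (curve fits and logit models both qualify). Curve parameters are shown to
    3 significant figures, coefficients to 3 decimals, each with its CI in
    parentheses in a ``display`` column. An empty ``fits`` is a warning
    no-op.
    """
    if not fits:
        logger.warning("write_report: nothing to write")
        return None
    frames = []
    for label, fit in fits.items():
        df = fit.to_frame().copy()
        if "param" in df.columns:  # curve fit: 3 significant figures
            value_col, name_col, fmt = "estimate", "param", _sig3
        else:  # regression: 3 decimals
            value_col, name_col, fmt = "coef", "variable", lambda v: f"{float(v):.3f}"
        df.insert(0, "fit", label)
        df["display"] = [
            format_estimate_ci(e, lo, hi, fmt=fmt, en_dash=en_dash)
            for e, lo, hi in zip(df[value_col], df["ci_low"], df["ci_high"])
        ]
        extras = {}
        for attr in ("r2_adj", "auc", "threshold", "accuracy"):
            v = getattr(fit, attr, None)
            if v is not None:
                extras[attr] = float(v)
        for k, v in extras.items():
            df[k] = v
        df = df.rename(columns={name_col: "term", value_col: "estimate"})
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    logger.info("write_report: wrote %d rows to %s", len(out), path)
    return out


def write_run_log(path, seed: int, config: dict, extra: Optional[dict] = None) -> dict:
    """Machine-readable reproducibility log: seed, config hash, versions."""
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    record = {
        "seed": int(seed),
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
    return record
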