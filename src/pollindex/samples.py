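"""Sample tables: schema, CSV I/O, validation and replicate aggregation.

A concentration matrix is a plain pandas DataFrame: one row per sample (or
per site after replicate aggregation), one column per element (mg/kg dry
soil) plus the transect metadata columns below.  Missing concentrations are
NaN, never silently zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import ELEMENTS, normalize_symbol, ReferenceError

#: Metadata columns recognised by the transect layout.
METADATA_COLUMNS: tuple[str, ...] = ("site_id", "side", "distance_m", "along_m", "replicate")
OPTIONAL_COLUMNS: tuple[str, ...] = ("pH_KCl", "EC")

#: Perpendicular sampling distances of the study layout (negative = left/west
#: of the barrier; the left side has one extra station at -5 m).
STUDY_DISTANCES_LEFT: tuple[float, ...] = (-0.5, -2.5, -5.0, -10.0, -20.0, -50.0)
STUDY_DISTANCES_RIGHT: tuple[float, ...] = (0.5, 2.5, 10.0, 20.0, 50.0)

#: Maximum replicate coefficient of variation accepted by the field QC rule.
REPLICATE_CV_LIMIT = 0.10


class SchemaError(ValueError):
    """The table is missing a mandatory column or has an unusable layout."""


class ValidationError(ValueError):
    """A cell violates a validity rule (negative or unparseable concentration)."""


def element_columns(df: pd.DataFrame, registry: Sequence[str] | None = None) -> list[str]:
    """Columns of ``df`` holding element concentrations.

    Elements are recognised by symbol against ``registry`` (default: the
    built-in six-element panel), preserving the DataFrame's column order.
    """
    known = {normalize_symbol(s) for s in (registry or ELEMENTS)}
    out = []
    for col in df.columns:
        try:
            sym = normalize_symbol(col)
        except ReferenceError:
            continue
        if sym in known:
            out.append(col)
    return out


def validate_samples(df: pd.DataFrame, elements: Sequence[str] | None = None) -> pd.DataFrame:
    """Check concentration validity; returns ``df`` with float element columns.

    Raises :class:`ValidationError` naming the offending row for negative or
    unparseable concentrations.
    """
    df = df.copy()
    cols = list(elements) if elements else element_columns(df)
    for col in cols:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"unparseable concentration in column {col!r}: {exc}") from exc
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValidationError(
                f"negative concentration for {col!r} in row(s) {list(neg[:5])}"
            )
    if "replicate" in df.columns and "site_id" in df.columns:
        counts = df.groupby("site_id", sort=False)["replicate"].size()
        too_many = counts[counts > 6]
        if len(too_many):
            raise ValidationError(
                f"more than 6 replicates for site(s) {list(too_many.index[:5])}"
            )
    return df


def read_samples(
    path: str | Path,
    sep: str = ",",
    registry: Sequence[str] | None = None,
    require: Iterable[str] = (),
) -> pd.DataFrame:
    """Read a wide-format sample CSV into a validated concentration matrix.

    Parameters
    ----------
    path:
        CSV file with a header naming metadata and element columns.
    sep:
        Field separator (comma-separated, dot-decimal, UTF-8 by default).
    registry:
        Element symbols to recognise; defaults to the Zn/Cu/Pb/Cr/Ni/Cd panel.
    require:
        Metadata column names that must be present.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    cols = element_columns(df, registry)
    if not cols:
        raise SchemaError("no element concentration columns found in header")
    return validate_samples(df, cols)


def write_samples(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a concentration matrix with round-trip-exact floats."""
    df.to_csv(path, sep=sep, index=False)


def aggregate_replicates(
    df: pd.DataFrame,
    elements: Sequence[str] | None = None,
    cv_limit: float = REPLICATE_CV_LIMIT,
) -> pd.DataFrame:
    """Collapse field replicates to one row per site.

    Per element, the site value is the arithmetic mean over replicates and a
    ``cv_<element>`` column reports the replicate coefficient of variation
    (population SD over mean, 0 for a single replicate).  ``cv_ok`` flags
    whether every element's replicate CV is within ``cv_limit`` — the usual
    field quality-control rule.  No exclusion is performed on that basis.

    Idempotent: input without a ``replicate`` column (or with one row per
    site) passes through with zero CVs.
    """
    if df.empty:
        raise ValidationError("cannot aggregate an empty sample table")
    cols = list(elements) if elements else element_columns(df)
    if "site_id" not in df.columns or "replicate" not in df.columns:
        out = df.copy()
        for col in cols:
            out[f"cv_{col}"] = 0.0
        out["cv_ok"] = True
        return out.drop(columns=[c for c in ("replicate",) if c in out.columns])

    meta = [c for c in df.columns if c not in cols and c != "replicate" and not c.startswith("cv_") and c != "cv_ok"]
    grouped = df.groupby("site_id", sort=False)
    rows = []
    for site, grp in grouped:
        if grp.empty:
            raise ValidationError(f"site {site!r} has zero replicates")
        rec = {}
        for c in meta:
            rec[c] = grp[c].iloc[0]
        ok = True
        for col in cols:
            vals = grp[col].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            cv = sd / mean if mean != 0 else 0.0
            rec[col] = mean
            rec[f"cv_{col}"] = cv
            ok = ok and cv <= cv_limit
        rec["cv_ok"] = ok
        rows.append(rec)
    return pd.DataFrame(rows)
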