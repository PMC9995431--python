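"""Per-element pollution indices: Igeo, PI and the ecological risk factor Er.

All three are strictly increasing in the measured concentration Cn for a
fixed background Bn, which is what lets summary statistics of indices be
recovered from summary statistics of concentrations (the median of a
monotone transform is the transform of the median, exactly so for
odd-sized samples).

* geoaccumulation index  Igeo = log2(Cn / (1.5 Bn)); the factor 1.5 absorbs
  natural background fluctuation.  Seven classes, ids 0-6.
* single pollution index  PI = Cn / Bn.  Five classes, ids 1-5.
* ecological risk factor  Er = Tr * PI, with Tr the element's
  toxic-response factor.  Five categories.

The algebraic identity Igeo = log2(PI / 1.5) ties the two scales together.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import SCHEMES, ClassificationScheme
from .reference import ReferenceTable
from .samples import element_columns

__all__ = [
    "geoaccumulation_index",
    "pollution_index",
    "ecological_risk",
    "individual_index_table",
]


def _asarray_nonneg(conc, name: str) -> np.ndarray:
    arr = np.asarray(conc, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name}: negative concentration")
    return arr


def geoaccumulation_index(conc, background) -> np.ndarray | float:
    """Igeo = log2(Cn / (1.5 Bn)).

    ``conc`` may be scalar or array-like (mg/kg).  A zero concentration is
    below the scale and returns ``-inf``; a negative concentration raises.
    """
    arr = _asarray_nonneg(conc, "Igeo")
    bn = np.asarray(background, dtype=float)
    if np.any(bn <= 0):
        raise ValueError("Igeo: background must be strictly positive")
    with np.errstate(divide="ignore"):
        out = np.log2(arr / (1.5 * bn))
    return out if out.ndim else float(out)


def pollution_index(conc, background) -> np.ndarray | float:
    """Single pollution index PI = Cn / Bn (dimensionless, >= 0)."""
    arr = _asarray_nonneg(conc, "PI")
    bn = np.asarray(background, dtype=float)
    if np.any(bn <= 0):
        raise ValueError("PI: background must be strictly positive")
    out = arr / bn
    return out if out.ndim else float(out)


def ecological_risk(pi, toxic_response) -> np.ndarray | float:
    """Ecological risk factor Er = Tr * PI."""
    pi_arr = np.asarray(pi, dtype=float)
    if np.any(pi_arr < 0):
        raise ValueError("Er: PI must be non-negative")
    tr = np.asarray(toxic_response, dtype=float)
    if np.any(tr <= 0):
        raise ValueError("Er: toxic-response factor must be strictly positive")
    out = tr * pi_arr
    return out if out.ndim else float(out)


_INDEX_FUNCS = {"Igeo", "PI", "Er"}


def individual_index_table(
    samples: pd.DataFrame,
    ref: ReferenceTable,
    index: str = "PI",
    scheme: ClassificationScheme | None = None,
    id_column: str = "site_id",
) -> pd.DataFrame:
    """Tidy per-sample, per-element index table with class assignment.

    Returns one row per sample x element with columns ``sample_id, element,
    index_name, value, class_id, class_label, below_scale``.  For Igeo at
    Cn = 0 the value is reported as NaN with ``below_scale=True`` and the
    lowest class (keeps CSV outputs finite); PI and Er are simply 0 there.
    """
    if index not in _INDEX_FUNCS:
        raise ValueError(f"unknown individual index {index!r} (choose from {sorted(_INDEX_FUNCS)})")
    scheme = scheme or SCHEMES[index]
    elements = element_columns(samples, registry=ref.elements)
    if not elements:
        raise ValueError("no element columns overlap the reference table")
    needed = {"Igeo": ("Bn",), "PI": ("Bn",), "Er": ("Bn", "Tr")}[index]
    ref.require(elements, needed, index)

    if id_column in samples.columns:
        sample_ids = samples[id_column]
    else:
        sample_ids = samples.index
    records = []
    for el in elements:
        conc = samples[el].to_numpy(dtype=float)
        bn = ref.background(el)
        if index == "Igeo":
            values = np.asarray(geoaccumulation_index(conc, bn))
        elif index == "PI":
            values = np.asarray(pollution_index(conc, bn))
        else:
            values = np.asarray(ecological_risk(pollution_index(conc, bn), ref.toxic_response(el)))
        below = np.isneginf(values)
        for sid, val, bel in zip(sample_ids, values, below):
            if bel:
                cid, label = scheme.ids[0], scheme.labels[0]
                val = float("nan")
            else:
                cid, label = scheme.classify(val)
            records.append(
                {
                    "sample_id": sid,
                    "element": el,
                    "index_name": index,
                    "value": float(val),
                    "class_id": cid,
                    "class_label": label,
                    "below_scale": bool(bel),
                }
            )
    return pd.DataFrame.from_records(records)
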