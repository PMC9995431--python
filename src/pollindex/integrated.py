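"""Integrated (multi-element) pollution indices and ecological risk.

Six of the indices are functionals of the per-element PI vector of a
sample — PI_sum, PI_avg (arithmetic mean), PI_vector (root mean square),
PLI (geometric mean), PI_Nemerow (mean/max compromise) and PIN (PI-class
weighted sum) — and inherit PI's linear dependence on concentration, so
the mean-over-samples of any *linear* one equals the index of the mean
concentrations.  RI sums the toxic-response-weighted PIs.  CSI and MERMQ
work directly on concentrations against the ERL/ERM benchmarks.

Classical orderings hold for any non-negative PI vector:
PLI <= PI_avg <= PI_vector <= PI_max (AM-GM and AM-QM) and
PI_max/sqrt(2) <= PI_Nemerow <= PI_max.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .classification import SCHEMES, PI_SCHEME
from .individual import pollution_index
from .reference import ReferenceTable
from .samples import element_columns

__all__ = [
    "pi_sum",
    "pi_avg",
    "pi_vector",
    "pollution_load_index",
    "nemerow_index",
    "background_enrichment",
    "ecological_risk_index",
    "contamination_security_index",
    "mean_erm_quotient",
    "integrated_table",
    "INTEGRATED_INDICES",
]

#: All integrated index names, in reporting order.
INTEGRATED_INDICES: tuple[str, ...] = (
    "PI_sum", "PI_avg", "PI_vector", "PLI", "PI_Nemerow", "RI", "PIN", "CSI", "MERMQ",
)

#: Indices with no published quality-class scheme.
UNCLASSED: frozenset[str] = frozenset({"PI_sum", "PI_avg", "PI_vector"})


def _pis(pis) -> np.ndarray:
    arr = np.asarray(pis, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("need at least one finite PI value")
    if np.any(arr < 0):
        raise ValueError("PI values must be non-negative")
    return arr


def pi_sum(pis) -> float:
    """Sum of the per-element single pollution indices."""
    return float(np.sum(_pis(pis)))


def pi_avg(pis) -> float:
    """Arithmetic mean of the per-element PIs (PI_sum / n)."""
    return float(np.mean(_pis(pis)))


def pi_vector(pis) -> float:
    """Vector modulus: root mean square of the per-element PIs."""
    arr = _pis(pis)
    return float(np.sqrt(np.mean(arr**2)))


def pollution_load_index(pis) -> float:
    """Geometric mean of the per-element PIs.

    Any PI of exactly 0 makes the geometric mean 0 (degenerate input; no
    epsilon substitution is applied — callers can detect the condition from
    the zero itself).
    """
    arr = _pis(pis)
    if np.any(arr == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


def nemerow_index(pis) -> float:
    """PI_Nemerow = sqrt((PI_avg^2 + PI_max^2) / 2)."""
    arr = _pis(pis)
    avg, mx = np.mean(arr), np.max(arr)
    return float(np.sqrt((avg**2 + mx**2) / 2.0))


def background_enrichment(pis, class_ids: Sequence[int] | None = None) -> float:
    """PIN = sum of PI_class^2 * PI over elements.

    ``PI_class`` is the integer class id (1-5) from the PI scheme; it is
    derived from the PI values themselves unless supplied.
    """
    arr = _pis(pis)
    if class_ids is None:
        class_ids = [PI_SCHEME.classify(v)[0] for v in arr]
    cls = np.asarray(list(class_ids), dtype=float)
    if cls.shape != arr.shape:
        raise ValueError("class_ids must match the PI vector length")
    return float(np.sum(cls**2 * arr))


def ecological_risk_index(ers) -> float:
    """Potential ecological risk RI = sum of the per-element Er factors."""
    arr = np.asarray(ers, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("need at least one finite Er value")
    if np.any(arr < 0):
        raise ValueError("Er values must be non-negative")
    return float(np.sum(arr))


def contamination_security_index(conc, ref: ReferenceTable, elements: Sequence[str]) -> float:
    """CSI = sum over elements of W * (sqrt(Cn/ERL) + (Cn/ERM)^2).

    The exponents apply to the concentration-to-benchmark ratios, keeping
    every term dimensionless; weights W come from the reference table.
    """
    arr = np.asarray(conc, dtype=float)
    if len(elements) != arr.size:
        raise ValueError("conc and elements length mismatch")
    ref.require(elements, ("ERL", "ERM", "W"), "CSI")
    total = 0.0
    for cn, el in zip(arr, elements):
        if not np.isfinite(cn):
            continue
        if cn < 0:
            raise ValueError("CSI: negative concentration")
        total += ref.csi_weight(el) * (np.sqrt(cn / ref.erl(el)) + (cn / ref.erm(el)) ** 2)
    return float(total)


def mean_erm_quotient(conc, ref: ReferenceTable, elements: Sequence[str]) -> float:
    """MERMQ: mean over elements of Cn / ERM (probability-of-toxicity bands)."""
    arr = np.asarray(conc, dtype=float)
    if len(elements) != arr.size:
        raise ValueError("conc and elements length mismatch")
    ref.require(elements, ("ERM",), "MERMQ")
    quotients = [
        cn / ref.erm(el) for cn, el in zip(arr, elements) if np.isfinite(cn)
    ]
    if not quotients:
        raise ValueError("MERMQ: no finite concentrations")
    if min(quotients) < 0:
        raise ValueError("MERMQ: negative concentration")
    return float(np.mean(quotients))


def integrated_table(
    samples: pd.DataFrame,
    ref: ReferenceTable,
    indices: Sequence[str] | str = "all",
    strict: bool = False,
    id_column: str = "site_id",
) -> pd.DataFrame:
    """Per-sample integrated index records.

    Returns a tidy DataFrame with columns ``sample_id, index_name, value,
    class_id, class_label, n_effective``.  ``n_effective`` is the number of
    elements actually entering the index for that sample (NaN cells are
    skipped); ``strict=True`` instead requires the full panel of reference
    elements in every row.  PI_sum and PI_vector carry no class (no
    published assessment criteria); their class fields are left empty.
    """
    if indices == "all":
        selection: list[str] = list(INTEGRATED_INDICES)
    else:
        selection = [indices] if isinstance(indices, str) else list(indices)
    unknown = sorted(set(selection) - set(INTEGRATED_INDICES))
    if unknown:
        raise ValueError(f"unknown integrated index names: {unknown}")

    elements = element_columns(samples, registry=ref.elements)
    if not elements:
        raise ValueError("no element columns overlap the reference table")
    # fail early on missing constants
    needs = {
        "RI": ("Bn", "Tr"), "CSI": ("ERL", "ERM", "W"), "MERMQ": ("ERM",),
    }
    for name in selection:
        ref.require(elements, needs.get(name, ("Bn",)), name)

    sample_ids = samples[id_column] if id_column in samples.columns else samples.index
    conc_mat = samples[elements].to_numpy(dtype=float)
    records = []
    for sid, conc in zip(sample_ids, conc_mat):
        present = np.isfinite(conc)
        if strict and not present.all():
            raise ValueError(f"strict mode: sample {sid!r} is missing element values")
        if not present.any():
            raise ValueError(f"sample {sid!r} has no element values")
        els = [el for el, p in zip(elements, present) if p]
        cn = conc[present]
        pis = np.array([pollution_index(c, ref.background(el)) for c, el in zip(cn, els)])
        n_eff = int(present.sum())
        for name in selection:
            if name == "PI_sum":
                value = pi_sum(pis)
            elif name == "PI_avg":
                value = pi_avg(pis)
            elif name == "PI_vector":
                value = pi_vector(pis)
            elif name == "PLI":
                value = pollution_load_index(pis)
            elif name == "PI_Nemerow":
                value = nemerow_index(pis)
            elif name == "PIN":
                value = background_enrichment(pis)
            elif name == "RI":
                ers = [p * ref.toxic_response(el) for p, el in zip(pis, els)]
                value = ecological_risk_index(ers)
            elif name == "CSI":
                value = contamination_security_index(cn, ref, els)
            else:  # MERMQ
                value = mean_erm_quotient(cn, ref, els)
            if name in UNCLASSED:
                cid, label = pd.NA, ""
            else:
                cid, label = SCHEMES[name].classify(value)
            records.append(
                {
                    "sample_id": sid,
                    "index_name": name,
                    "value": value,
                    "class_id": cid,
                    "class_label": label,
                    "n_effective": n_eff,
                }
            )
    return pd.DataFrame.from_records(records)
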