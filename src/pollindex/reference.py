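"""Reference constants for soil trace-element pollution assessment.

The registry bundles, per element, the five constants every index in this
package consumes:

``Bn``
    geochemical background concentration (mg/kg dry soil).  The built-in
    default is the upper-continental-crust (UCC) composition, which gives
    indices a site-independent reference so that differently located
    surveys remain comparable.
``Tr``
    Hakanson toxic-response factor (dimensionless) used by the ecological
    risk factor Er and its sum RI.
``ERL`` / ``ERM``
    effects-range-low and effects-range-median sediment-quality benchmarks
    (mg/kg); below ERL adverse biological effects are rare, above ERM they
    are frequent.  Consumed by CSI and MERMQ.
``W``
    contamination-security-index weight (dimensionless).

Two readings of the CSI weights are available: the ``"corrected"`` decimal
weights (default, summing to 1) and a ``"printed"`` variant with
three-digit integer weights for Pb/Ni/Cr that circulates in part of the
literature through a typesetting loss of the decimal points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

#: Canonical panel, in decreasing order of typical roadside soil concentration.
ELEMENTS: tuple[str, ...] = ("Zn", "Cu", "Pb", "Cr", "Ni", "Cd")

#: Upper-continental-crust background concentrations, mg/kg.
UCC_BACKGROUND: dict[str, float] = {
    "Cu": 28.0, "Zn": 67.0, "Pb": 17.0, "Ni": 47.0, "Cr": 92.0, "Cd": 0.09,
}

#: Hakanson toxic-response factors, dimensionless.
TOXIC_RESPONSE: dict[str, float] = {
    "Cu": 5.0, "Zn": 1.0, "Pb": 5.0, "Ni": 5.0, "Cr": 2.0, "Cd": 30.0,
}

#: Effects-range-low sediment-quality benchmark, mg/kg.
ERL: dict[str, float] = {
    "Cu": 34.0, "Zn": 150.0, "Pb": 46.7, "Ni": 20.9, "Cr": 81.0, "Cd": 1.2,
}

#: Effects-range-median sediment-quality benchmark, mg/kg.
ERM: dict[str, float] = {
    "Cu": 270.0, "Zn": 410.0, "Pb": 218.0, "Ni": 51.6, "Cr": 370.0, "Cd": 9.6,
}

#: CSI element weights, decimal (corrected) reading; sums to 1.
CSI_WEIGHTS_CORRECTED: dict[str, float] = {
    "Cu": 0.075, "Zn": 0.075, "Pb": 0.251, "Ni": 0.215, "Cr": 0.134, "Cd": 0.25,
}

#: CSI weights as sometimes printed (decimal points lost for Pb/Ni/Cr).
CSI_WEIGHTS_PRINTED: dict[str, float] = {
    "Cu": 0.075, "Zn": 0.075, "Pb": 251.0, "Ni": 215.0, "Cr": 134.0, "Cd": 0.25,
}

_COLUMNS = ("Bn", "Tr", "ERL", "ERM", "W")


class ReferenceError(ValueError):
    """A reference table is missing or violates a constant's constraints."""


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an element symbol (``"zn"`` -> ``"Zn"``)."""
    sym = str(symbol).strip()
    if not sym or not sym.isalpha() or len(sym) > 2:
        raise ReferenceError(f"not a chemical element symbol: {symbol!r}")
    return sym.capitalize()


@dataclass(frozen=True)
class ReferenceTable:
    """Per-element constant registry backed by a pandas DataFrame.

    The frame is indexed by case-normalized element symbols and carries the
    columns ``Bn, Tr, ERL, ERM, W``.  Missing constants are NaN; an index
    that needs a missing constant fails with an error naming both the index
    and the element (see :meth:`require`).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        tab = self.table.copy()
        tab.index = [normalize_symbol(s) for s in tab.index]
        if tab.index.has_duplicates:
            dups = tab.index[tab.index.duplicated()].tolist()
            raise ReferenceError(f"duplicate element symbols: {dups}")
        for col in _COLUMNS:
            if col not in tab.columns:
                tab[col] = float("nan")
        tab = tab[list(_COLUMNS)].astype(float)
        for col in ("Bn", "ERL", "ERM"):
            bad = tab.index[tab[col].notna() & (tab[col] <= 0)].tolist()
            if bad:
                raise ReferenceError(f"{col} must be strictly positive, got bad values for {bad}")
        bad = tab.index[tab["Tr"].notna() & (tab["Tr"] <= 0)].tolist()
        if bad:
            raise ReferenceError(f"Tr must be strictly positive, got bad values for {bad}")
        both = tab["ERL"].notna() & tab["ERM"].notna()
        bad = tab.index[both & (tab["ERL"] >= tab["ERM"])].tolist()
        if bad:
            raise ReferenceError(f"ERL must be < ERM, violated for {bad}")
        object.__setattr__(self, "table", tab)

    # -- constructors ---------------------------------------------------

    @classmethod
    def ucc_default(cls, csi_weights: str = "corrected") -> "ReferenceTable":
        """Built-in registry: UCC backgrounds, Hakanson Tr, ERL/ERM, CSI weights.

        Parameters
        ----------
        csi_weights:
            ``"corrected"`` (default) for the decimal CSI weights or
            ``"printed"`` for the literal three-digit variant.
        """
        if csi_weights == "corrected":
            weights = CSI_WEIGHTS_CORRECTED
        elif csi_weights == "printed":
            weights = CSI_WEIGHTS_PRINTED
        else:
            raise ReferenceError(f"unknown CSI weight reading: {csi_weights!r}")
        tab = pd.DataFrame(
            {
                "Bn": UCC_BACKGROUND,
                "Tr": TOXIC_RESPONSE,
                "ERL": ERL,
                "ERM": ERM,
                "W": weights,
            }
        ).loc[list(ELEMENTS)]
        return cls(tab)

    @classmethod
    def from_dict(cls, constants: Mapping[str, Mapping[str, float]]) -> "ReferenceTable":
        """Build from ``{element: {Bn: ..., Tr: ..., ...}}``."""
        return cls(pd.DataFrame.from_dict(dict(constants), orient="index"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceTable":
        """Read a YAML file mapping elements to their constants.

        Expected layout::

            elements:
              Cd: {Bn: 0.09, Tr: 30, ERL: 1.2, ERM: 9.6, W: 0.25}
              ...
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ReferenceError(f"reference config {path} is not a mapping")
        constants = raw.get("elements", raw)
        return cls.from_dict(constants)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "elements": {
                el: {k: float(v) for k, v in row.items() if pd.notna(v)}
                for el, row in self.table.iterrows()
            }
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    # -- accessors ------------------------------------------------------

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def _get(self, column: str, element: str) -> float:
        el = normalize_symbol(element)
        try:
            value = self.table.at[el, column]
        except KeyError:
            raise ReferenceError(f"element {el} not in reference table") from None
        return float(value)

    def background(self, element: str) -> float:
        return self._get("Bn", element)

    def toxic_response(self, element: str) -> float:
        return self._get("Tr", element)

    def erl(self, element: str) -> float:
        return self._get("ERL", element)

    def erm(self, element: str) -> float:
        return self._get("ERM", element)

    def csi_weight(self, element: str) -> float:
        return self._get("W", element)

    def require(self, elements: Iterable[str], columns: Iterable[str], index_name: str) -> None:
        """Fail early if ``index_name`` would need a missing constant."""
        for el in elements:
            el = normalize_symbol(el)
            if el not in self.table.index:
                raise ReferenceError(f"index {index_name} needs element {el}, absent from reference table")
            for col in columns:
                if pd.isna(self.table.at[el, col]):
                    raise ReferenceError(f"index {index_name} needs constant {col} for element {el}")


def load_reference(source: str | Path | ReferenceTable = "ucc-default", **kwargs) -> ReferenceTable:
    """Resolve a reference source: ``"ucc-default"``, a YAML path, or a table."""
    if isinstance(source, ReferenceTable):
        return source
    if isinstance(source, str) and source == "ucc-default":
        return ReferenceTable.ucc_default(**kwargs)
    return ReferenceTable.from_yaml(source)
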