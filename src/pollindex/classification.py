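"""Ordered interval classification schemes for pollution indices.

Every index in this package maps its value to a named severity class
through a :class:`ClassificationScheme`: an ascending list of breakpoints
with one label (and integer id) per interval.  Intervals are closed on the
left and open on the right, ``[a, b)``, which resolves the overlapping
shorthand the index literature uses ("PI = 1-2", "PI = 2-3") into a
deterministic rule; the strict inequalities printed at the scale ends
(e.g. "Igeo < 0", "PI > 5") are honoured by that same convention.

The pollution-load index is the one scheme with an exact-value class
("baseline" at PLI = 1), handled through ``exact_labels``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


@dataclass(frozen=True)
class ClassificationScheme:
    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    ids: tuple[int, ...]
    #: exact boundary values carrying their own class, checked before intervals
    exact_labels: Mapping[float, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError(f"{self.name}: breakpoints must be strictly ascending")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError(f"{self.name}: need one label per interval")
        if len(self.ids) != len(self.labels):
            raise ValueError(f"{self.name}: need one id per label")

    def classify(self, value: float) -> tuple[int, str]:
        """Interval lookup: returns ``(class_id, class_label)``.

        NaN raises; -inf falls in the lowest interval, +inf in the highest.
        """
        value = float(value)
        if math.isnan(value):
            raise ValueError(f"{self.name}: cannot classify NaN")
        for point, (cid, label) in self.exact_labels.items():
            if value == point:
                return cid, label
        idx = int(np.searchsorted(self.breakpoints, value, side="right"))
        return self.ids[idx], self.labels[idx]

    def classify_array(self, values) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`classify` over an array-like of values."""
        arr = np.asarray(values, dtype=float)
        out_id = np.empty(arr.shape, dtype=int)
        out_label = np.empty(arr.shape, dtype=object)
        flat_id, flat_label = out_id.ravel(), out_label.ravel()
        for i, v in enumerate(arr.ravel()):
            flat_id[i], flat_label[i] = self.classify(v)
        return out_id, out_label


IGEO_SCHEME = ClassificationScheme(
    name="Igeo",
    breakpoints=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    labels=(
        "unpolluted",
        "unpolluted to moderately polluted",
        "moderately polluted",
        "moderately to highly polluted",
        "highly polluted",
        "highly to extremely polluted",
        "extremely high polluted",
    ),
    ids=(0, 1, 2, 3, 4, 5, 6),
)

PI_SCHEME = ClassificationScheme(
    name="PI",
    breakpoints=(1.0, 2.0, 3.0, 5.0),
    labels=(
        "absent",
        "low pollution",
        "moderate pollution",
        "strong pollution",
        "very strong pollution",
    ),
    ids=(1, 2, 3, 4, 5),
)

ER_SCHEME = ClassificationScheme(
    name="Er",
    breakpoints=(40.0, 80.0, 160.0, 320.0),
    labels=("low", "moderate", "considerable", "high", "very high"),
    ids=(1, 2, 3, 4, 5),
)

RI_SCHEME = ClassificationScheme(
    name="RI",
    breakpoints=(90.0, 180.0, 360.0, 720.0),
    labels=("low", "moderate", "strong", "very strong", "highly strong"),
    ids=(1, 2, 3, 4, 5),
)

NEMEROW_SCHEME = ClassificationScheme(
    name="PI_Nemerow",
    breakpoints=(0.7, 1.0, 2.0, 3.0),
    labels=("clean", "warning limit", "slight pollution", "moderate pollution", "heavy pollution"),
    ids=(1, 2, 3, 4, 5),
)

PIN_SCHEME = ClassificationScheme(
    name="PIN",
    breakpoints=(7.0, 95.1, 518.1, 2548.5),
    labels=(
        "clean",
        "trace contaminated",
        "lightly contaminated",
        "contaminated",
        "highly contaminated",
    ),
    ids=(1, 2, 3, 4, 5),
)

PLI_SCHEME = ClassificationScheme(
    name="PLI",
    breakpoints=(1.0,),
    labels=("perfect quality", "deterioration of quality"),
    ids=(1, 3),
    exact_labels={1.0: (2, "baseline levels of pollution")},
)

CSI_SCHEME = ClassificationScheme(
    name="CSI",
    breakpoints=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0),
    labels=(
        "uncontaminated",
        "very low contamination severity",
        "low contamination severity",
        "low-to-moderate contamination severity",
        "moderate contamination severity",
        "moderate-to-high contamination severity",
        "high contamination severity",
        "very high contamination severity",
        "ultra-high contamination severity",
    ),
    ids=(1, 2, 3, 4, 5, 6, 7, 8, 9),
)

MERMQ_SCHEME = ClassificationScheme(
    name="MERMQ",
    breakpoints=(0.1, 0.5, 1.5),
    labels=(
        "low risk (9% probability of toxicity)",
        "medium risk (21% probability of toxicity)",
        "high risk (49% probability of toxicity)",
        "very high risk (76% probability of toxicity)",
    ),
    ids=(1, 2, 3, 4),
)

#: Registry of built-in schemes keyed by index name.
SCHEMES: dict[str, ClassificationScheme] = {
    "Igeo": IGEO_SCHEME,
    "PI": PI_SCHEME,
    "Er": ER_SCHEME,
    "RI": RI_SCHEME,
    "PI_Nemerow": NEMEROW_SCHEME,
    "PIN": PIN_SCHEME,
    "PLI": PLI_SCHEME,
    "CSI": CSI_SCHEME,
    "MERMQ": MERMQ_SCHEME,
}
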