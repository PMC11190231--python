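"""Per-particle measurement collections and their CSV dialect.

A :class:`MeasurementSet` is the univariate sample handed to the mixture
machinery: one scalar per detected particle (projected area in nm² or
maximal lateral width in nm), tagged with the experimental condition it was
observed under (for this kind of study, a thermal-aging time and the number
of nano-indentation passes).

The on-disk format is a plain CSV with header ``value,unit,condition`` and
an optional ``true_component`` column written by the synthetic generator.
Units are explicit in every file; sets with different units are never merged
silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

AREA_NM2 = "area_nm2"
WIDTH_NM = "width_nm"
VALID_UNITS = frozenset({AREA_NM2, WIDTH_NM})


@dataclass
class MeasurementSet:
    """An ordered univariate sample of per-particle measurements.

    Parameters
    ----------
    values
        One scalar per particle, all in the same unit. Finite, at least one.
    unit
        ``"area_nm2"`` or ``"width_nm"``.
    condition
        Free-text condition label, e.g. ``"2h_singlepass"``.
    """

    values: np.ndarray
    unit: str = AREA_NM2
    condition: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size < 1:
            raise ValidationError("a MeasurementSet needs at least one value")
        if not np.all(np.isfinite(values)):
            raise ValidationError("measurement values must be finite")
        if self.unit not in VALID_UNITS:
            raise ValidationError(
                f"unknown unit {self.unit!r}; expected one of {sorted(VALID_UNITS)}"
            )
        self.values = values

    @property
    def n(self) -> int:
        return int(self.values.size)

    def to_frame(self, true_component: np.ndarray | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "value": self.values,
                "unit": self.unit,
                "condition": self.condition,
            }
        )
        if true_component is not None:
            frame["true_component"] = np.asarray(true_component, dtype=int)
        return frame

    def to_csv(self, path, true_component: np.ndarray | None = None) -> None:
        self.to_frame(true_component).to_csv(path, index=False)


def read_measurements(path) -> list[MeasurementSet]:
    """Read a measurement CSV, returning one set per condition label.

    The file must carry the ``value,unit,condition`` header. A condition
    whose rows mix units is rejected.
    """
    frame = pd.read_csv(path)
    missing = {"value", "unit", "condition"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValidationError(f"{path}: no measurement rows")
    sets = []
    for condition, group in frame.groupby("condition", sort=False):
        units = group["unit"].unique()
        if len(units) > 1:
            raise ValidationError(
                f"{path}: condition {condition!r} mixes units {sorted(units)}"
            )
        sets.append(
            MeasurementSet(
                group["value"].to_numpy(float), unit=units[0], condition=str(condition)
            )
        )
    return sets


def concat_measurements(sets: list[MeasurementSet], condition: str = "pooled") -> MeasurementSet:
    """Pool several same-unit sets into one (for ensemble analyses)."""
    if not sets:
        raise ValidationError("nothing to concatenate")
    units = {s.unit for s in sets}
    if len(units) > 1:
        raise ValidationError(f"cannot pool sets with mixed units {sorted(units)}")
    return MeasurementSet(
        np.concatenate([s.values for s in sets]), unit=sets[0].unit, condition=condition
    )
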