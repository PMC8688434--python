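"""σ-binning of continuous node attributes into six ordered categories A–F.

Per attribute and per network, the mean x̄ and standard deviation σ of the
non-missing values fix five cut points, and a value x is mapped by

    A: x ≤ x̄−2σ      B: x̄−2σ < x ≤ x̄−σ    C: x̄−σ < x ≤ x̄
    D: x̄ < x ≤ x̄+σ   E: x̄+σ < x ≤ x̄+2σ    F: x > x̄+2σ

so the four interior bins all have width exactly σ and the mean itself falls
in C.  Non-finite values become missing (NaN); binning is always fitted on one
network's own values, never pooled across networks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BINS = ("A", "B", "C", "D", "E", "F")


class DegenerateAttributeError(ValueError):
    """All values missing, fewer than two values, or zero spread (σ = 0)."""


@dataclass(frozen=True)
class BinScheme:
    """Fitted σ-binning for one attribute: mean, SD, and the five cut points."""

    attribute: str
    mean: float
    sd: float

    @property
    def boundaries(self) -> tuple[float, float, float, float, float]:
        m, s = self.mean, self.sd
        return (m - 2 * s, m - s, m, m + s, m + 2 * s)

    def assign(self, x: float) -> str | float:
        """Bin label for one value; NaN for non-finite input."""
        if x is None or not math.isfinite(x):
            return math.nan
        b1, b2, b3, b4, b5 = self.boundaries
        if x <= b1:
            return "A"
        if x <= b2:
            return "B"
        if x <= b3:
            return "C"
        if x <= b4:
            return "D"
        if x <= b5:
            return "E"
        return "F"

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "mean": self.mean,
            "sd": self.sd,
            "boundaries": list(self.boundaries),
        }


def fit_bin_scheme(
    values: Iterable[float], attribute: str, *, ddof: int = 1
) -> BinScheme:
    """Fit mean/σ over the non-missing entries of ``values``.

    ``ddof=1`` gives the sample standard deviation (default); ``ddof=0`` the
    population one.  Raises :class:`DegenerateAttributeError` when fewer than
    two finite values remain or the spread is zero.
    """
    arr = np.asarray(list(values), dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise DegenerateAttributeError(
            f"attribute {attribute!r}: need >= 2 non-missing values, got {finite.size}"
        )
    sd = float(np.std(finite, ddof=ddof))
    if sd == 0.0:
        raise DegenerateAttributeError(f"attribute {attribute!r}: constant values (sigma = 0)")
    return BinScheme(attribute=attribute, mean=float(np.mean(finite)), sd=sd)


def fit_bin_schemes(
    features: pd.DataFrame,
    columns: Iterable[str] | None = None,
    *,
    ddof: int = 1,
) -> dict[str, BinScheme]:
    """Fit one :class:`BinScheme` per numeric column; degenerate ones are skipped.

    Returns a dict keyed by attribute name.  Skipped attributes are simply
    absent (callers see which survived).
    """
    import logging

    schemes: dict[str, BinScheme] = {}
    cols = list(columns) if columns is not None else [
        c for c in features.columns if c != "role"
    ]
    for col in cols:
        try:
            schemes[col] = fit_bin_scheme(features[col], col, ddof=ddof)
        except DegenerateAttributeError as exc:
            logging.getLogger(__name__).warning("excluding attribute: %s", exc)
    return schemes


def discretize_table(
    features: pd.DataFrame, schemes: Mapping[str, BinScheme]
) -> pd.DataFrame:
    """Map every scheme'd column of ``features`` to categorical bins A–F.

    Columns without a scheme (other than ``role``) raise ``KeyError`` — a
    scheme fitted on the *same* network must exist for every attribute being
    discretized.  Infinite/undefined cells become NaN ("missing").  The
    ``role`` column, if present, is carried through unchanged.
    """
    out = pd.DataFrame(index=features.index)
    for col in features.columns:
        if col == "role":
            continue
        if col not in schemes:
            raise KeyError(f"no bin scheme fitted for attribute {col!r}")
        scheme = schemes[col]
        vals = pd.to_numeric(features[col], errors="coerce").to_numpy(dtype=float)
        labels = np.full(vals.shape, np.nan, dtype=object)
        finite = np.isfinite(vals)
        b = scheme.boundaries
        idx = np.searchsorted(np.asarray(b), vals[finite], side="left")
        labels[finite] = np.asarray(BINS, dtype=object)[idx]
        out[col] = labels
    if "role" in features.columns:
        out["role"] = features["role"]
    return out


def write_schemes_json(schemes: Mapping[str, BinScheme], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: s.to_dict() for k, s in schemes.items()}, fh, indent=2)
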