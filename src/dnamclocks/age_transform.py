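"""Age transformation used by epigenetic clocks.

Clocks trained on the full human life course regress methylation on a
transformed chronological age that is logarithmic in childhood (rapid
methylome remodelling) and linear in adulthood.  With ``adult_age`` = A the
forward map is

    F(a) = log((a + 1) / (A + 1))      for a <= A
    F(a) = (a - A) / (A + 1)           for a >  A

which is continuous and strictly increasing, with F(A) = 0.  Predictions on
the transformed scale are mapped back to years with the exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransformSpec", "transform_age", "inverse_transform_age"]

#: transform kinds understood by clock definitions
HORVATH = "horvath_transformed"
IDENTITY = "identity"


@dataclass(frozen=True)
class TransformSpec:
    """Which age transform a clock was trained on.

    Parameters
    ----------
    kind:
        ``"horvath_transformed"`` for the log/linear map above, or
        ``"identity"`` for clocks that predict age in years directly.
    adult_age:
        The knot A (years) where the map switches from logarithmic to
        linear.  20 by convention.
    """

    kind: str = HORVATH
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in (HORVATH, IDENTITY):
            raise ValueError(f"unknown transform kind: {self.kind!r}")
        if not (np.isfinite(self.adult_age) and self.adult_age > 0):
            raise ValueError("adult_age must be a positive finite number")


def _as_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def transform_age(age, spec: TransformSpec = TransformSpec()):
    """Map chronological age (years) to the clock's training scale.

    Accepts a scalar or array; negative or non-finite ages raise.
    """
    arr, scalar = _as_array(age)
    if not np.all(np.isfinite(arr)):
        raise ValueError("age must be finite")
    if np.any(arr < 0):
        raise ValueError("age must be >= 0")
    if spec.kind == IDENTITY:
        out = arr.copy()
    else:
        a = spec.adult_age
        out = np.where(
            arr <= a,
            np.log((arr + 1.0) / (a + 1.0)),
            (arr - a) / (a + 1.0),
        )
    return float(out) if scalar else out


def inverse_transform_age(t, spec: TransformSpec = TransformSpec()):
    """Map a transformed-scale value back to age in years (exact inverse)."""
    arr, scalar = _as_array(t)
    if not np.all(np.isfinite(arr)):
        raise ValueError("transformed age must be finite")
    if spec.kind == IDENTITY:
        out = arr.copy()
    else:
        a = spec.adult_age
        out = np.where(
            arr <= 0,
            (a + 1.0) * np.exp(arr) - 1.0,
            (a + 1.0) * arr + a,
        )
    return float(out) if scalar else out
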