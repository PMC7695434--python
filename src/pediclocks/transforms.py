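"""Output transforms mapping a clock's linear predictor to an age.

Age-transform clocks regress a *transformed* age on CpG betas, because
methylation changes much faster in early childhood than later in life.  The
transform family used here is piecewise log-linear around an anchor age
``A`` (in the clock's native unit)::

    F(a)      = log((a + 1) / (A + 1))        for a <= A
    F(a)      = (a - A) / (A + 1)             for a >  A

    F^-1(x)   = (A + 1) * exp(x) - 1          for x <= 0
    F^-1(x)   = (A + 1) * x + A               for x >  0

``F`` compresses the fast early-life dynamics logarithmically and is linear
past the anchor; ``F^-1`` is continuous (both branches give ``A`` at
``x = 0``) and strictly increasing.  The adult multi-tissue clocks use an
anchor of 20 years; the pediatric blood clock uses the same family with a
"toddler age" anchor of 48 months.  Identity transforms (clocks trained
directly on age) pass the predictor through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransformSpec",
    "wu_inverse",
    "wu_forward",
    "loglinear_inverse",
    "loglinear_forward",
]


def _check_finite(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor value")
    return x


def _anti_trafo(x, anchor: float):
    """Piecewise inverse transform with anchor in the clock's native unit."""
    x = _check_finite(x)
    out = np.where(x <= 0, (anchor + 1.0) * np.exp(x) - 1.0, (anchor + 1.0) * x + anchor)
    return out if out.ndim else float(out)


def _trafo(age, anchor: float):
    """Piecewise forward transform; defined for age > -1."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1.0):
        raise ValueError("forward transform requires age > -1")
    out = np.where(
        age <= anchor,
        np.log((age + 1.0) / (anchor + 1.0)),
        (age - anchor) / (anchor + 1.0),
    )
    return out if out.ndim else float(out)


def wu_inverse(x, toddler_age_months: float = 48.0):
    """Inverse transform of the pediatric blood clock, in months.

    Returns ``(t + 1) * exp(x) - 1`` for ``x <= 0`` and ``(t + 1) * x + t``
    for ``x > 0`` where ``t`` is the toddler-age constant (48 months by
    default).  Continuous at ``x = 0`` where both branches give ``t``.
    """
    if toddler_age_months <= 0:
        raise ValueError("toddler age must be positive")
    return _anti_trafo(x, toddler_age_months)


def wu_forward(age_months, toddler_age_months: float = 48.0):
    if toddler_age_months <= 0:
        raise ValueError("toddler age must be positive")
    return _trafo(age_months, toddler_age_months)


def loglinear_inverse(x, anchor_age_years: float = 20.0):
    """Inverse log-linear age transform of the adult multi-tissue clocks,
    in years; same functional family as :func:`wu_inverse` with the anchor
    in years (default 20)."""
    if anchor_age_years <= 0:
        raise ValueError("anchor age must be positive")
    return _anti_trafo(x, anchor_age_years)


def loglinear_forward(age_years, anchor_age_years: float = 20.0):
    if anchor_age_years <= 0:
        raise ValueError("anchor age must be positive")
    return _trafo(age_years, anchor_age_years)


@dataclass(frozen=True)
class TransformSpec:
    """Transform kind plus anchor constant.

    ``kind`` is one of ``identity``, ``loglinear`` (anchor in years) or
    ``wu`` (anchor in months).  The anchor travels with the clock-definition
    file, not the code.
    """

    kind: str
    anchor: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "loglinear", "wu"):
            raise ValueError(f"unknown transform {self.kind!r}")
        if self.kind != "identity":
            if self.anchor is None or self.anchor <= 0:
                raise ValueError(f"{self.kind} transform needs a positive anchor")

    def inverse(self, x):
        """Map linear-predictor values to ages in the clock's native unit."""
        if self.kind == "identity":
            x = _check_finite(x)
            return x if x.ndim else float(x)
        return _anti_trafo(x, self.anchor)

    def forward(self, age):
        """Map ages (native unit) to the linear-predictor scale."""
        if self.kind == "identity":
            age = np.asarray(age, dtype=float)
            return age if age.ndim else float(age)
        return _trafo(age, self.anchor)
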