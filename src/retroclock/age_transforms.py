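"""Age-to-response transforms.

Human clocks regress methylation on chronological age directly (identity
transform).  The pan-mammalian clock instead predicts a "relative age"
response, ``ln(age + offset)`` with a 2-year offset, which compresses late
life and keeps the response finite at age 0; predictions are mapped back to
years with the exact inverse ``exp(y) - offset``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

_KINDS = ("identity", "log_offset")


@dataclass(frozen=True)
class AgeTransform:
    """Strictly increasing map from chronological age (years) to the
    regression response scale.

    Parameters
    ----------
    kind
        ``"identity"`` (human clocks) or ``"log_offset"`` (relative age,
        ``ln(age + offset)``).
    offset
        Offset in years added before the log; only used by ``log_offset``.
        Default 2.0 years.
    """

    kind: str = "identity"
    offset: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(
                f"unknown transform kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.kind == "log_offset" and not self.offset > 0:
            raise ValidationError("log_offset transform requires offset > 0")

    # -- forward / inverse -------------------------------------------------
    def forward(self, age):
        """Transform age in years to the response scale."""
        age = np.asarray(age, dtype=float)
        if self.kind == "identity":
            return age if age.ndim else float(age)
        if np.any(age + self.offset <= 0):
            raise ValidationError(
                f"age + offset must be positive for log_offset (offset={self.offset})"
            )
        out = np.log(age + self.offset)
        return out if out.ndim else float(out)

    def inverse(self, y):
        """Map a response-scale value back to years."""
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y if y.ndim else float(y)
        out = np.exp(y) - self.offset
        return out if out.ndim else float(out)

    # -- serialization (model JSON sidecar) --------------------------------
    def to_dict(self) -> dict:
        return {"kind": self.kind, "offset": self.offset}

    @classmethod
    def from_dict(cls, d: dict) -> "AgeTransform":
        return cls(kind=d["kind"], offset=float(d.get("offset", 2.0)))


def transform_age(age, transform: AgeTransform):
    """Functional alias for :meth:`AgeTransform.forward`."""
    return transform.forward(age)


def inverse_transform_age(y, transform: AgeTransform):
    """Functional alias for :meth:`AgeTransform.inverse`."""
    return transform.inverse(y)
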