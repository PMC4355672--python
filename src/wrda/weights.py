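"""Weight vectors over time points (omega) and sampling times (k).

Three parametric families share the convention that index 0 carries the
largest weight (in the screening-cohort design, index 0 is the diagnosis
stage, the most informative point), with weight decaying as the index grows:

* linear:       w_i = 1 + (L - i - 1) * q
* proportional: w_i = (1 + q) ** (L - i - 1)
* exponential:  w_i = exp((L - i - 1) * q)

``q`` is the changing factor; at ``q = 0`` all three collapse to the equal
family. Explicit vectors cover hand-set designs (e.g. weights concentrated
on a few biologically typical stages, zero elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightScheme", "make_weights", "explicit_weights", "make_k_schemes", "FAMILIES"]

FAMILIES = ("equal", "linear", "proportional", "exponential")


@dataclass(frozen=True)
class WeightScheme:
    family: str
    q: float | None
    length: int
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) != self.length:
            raise ValueError("values must be a 1-D vector of the declared length")
        if (vals < 0).any():
            raise ValueError("weights must be nonnegative")
        if not (vals > 0).any():
            raise ValueError("at least one weight must be positive")
        if self.normalized and abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("normalized scheme must sum to 1 within 1e-12")

    @property
    def label(self) -> str:
        return self.family if self.q is None else f"{self.family}(q={self.q:g})"


def make_weights(
    family: str, q: float | None = None, length: int = 1, normalize: bool = True
) -> WeightScheme:
    """Build a weight scheme from one of the four families.

    ``equal`` ignores *q*; the parametric families require ``q >= 0``.
    When *normalize* is true the vector is scaled to sum to 1.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if family == "equal":
        q = None
        raw = np.ones(length)
    else:
        if q is None or q < 0:
            raise ValueError(f"family {family!r} requires a changing factor q >= 0, got {q}")
        steps = length - 1 - np.arange(length, dtype=float)  # L - i - 1
        if family == "linear":
            raw = 1.0 + steps * q
        elif family == "proportional":
            raw = (1.0 + q) ** steps
        else:  # exponential
            raw = np.exp(steps * q)
    values = raw / raw.sum() if normalize else raw
    if normalize:
        values = values / values.sum()  # second pass kills last-ulp drift
    return WeightScheme(family=family, q=q, length=length, values=values, normalized=normalize)


def explicit_weights(values, normalize: bool = False) -> WeightScheme:
    """Wrap a hand-specified nonnegative weight vector verbatim."""
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 1:
        raise ValueError("explicit weights must be a non-empty 1-D vector")
    if (vals < 0).any():
        raise ValueError("explicit weights must be nonnegative")
    if not (vals > 0).any():
        raise ValueError("explicit weights must contain at least one positive entry")
    if normalize:
        vals = vals / vals.sum()
        vals = vals / vals.sum()
    return WeightScheme(
        family="explicit",
        q=None,
        length=vals.size,
        values=vals,
        normalized=bool(normalize) and abs(vals.sum() - 1.0) <= 1e-12,
    )


def make_k_schemes(
    family: str,
    q: float | None,
    p_per_time_point,
    normalize: bool = True,
) -> list[WeightScheme]:
    """One sampling-time scheme per time point, regenerated from the same
    (family, q) whenever p_i differs across time points."""
    return [make_weights(family, q, int(p), normalize) for p in p_per_time_point]
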