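"""Species-aware age transformations.

Three scales are used throughout the package:

``identity``
    Chronological age in years, unchanged.
``loglinear``
    A continuous two-piece map anchored at the species' age of sexual
    maturity ``m``: logarithmic before maturity, linear after, with matching
    one-sided derivatives at the knot.  With offset ``k > 0``,

        F(a) = log((a + k) / (m + k))   for a <= m
        F(a) = (a - m) / (m + k)        for a >  m

    F(m) = 0 and F'(m-) = F'(m+) = 1/(m+k), so F is C1 and strictly
    increasing on [0, inf).  The log region stretches embryonic and larval
    ages (days to months) so a regression response does not collapse them,
    while adult ages advance linearly.  ``k`` defaults to ``m/5``.
``relative``
    Age divided by the species' maximum lifespan ``L`` (dimensionless,
    normally in [0, 1]).

The transforms are exposed both as plain vectorised functions and as an
:class:`AgeTransformSpec` that resolves per-species parameters from a
:class:`~frogclock.io.SpeciesRegistry`, which is the form clock models carry
around so a saved clock is self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_K_FRACTION",
    "AgeTransformSpec",
    "relative_age",
    "loglinear_forward",
    "loglinear_inverse",
]

#: Default offset k as a fraction of the age at sexual maturity.
DEFAULT_K_FRACTION = 0.2


def _check_mk(m: float, k: float) -> None:
    if not (m > 0):
        raise ValueError(f"maturity m must be positive, got {m!r}")
    if not (k > 0):
        raise ValueError(f"offset k must be positive, got {k!r}")


def relative_age(age, max_lifespan: float):
    """Age as a fraction of the species' maximum lifespan.

    Parameters
    ----------
    age
        Chronological age in years (scalar or array), must be >= 0.
    max_lifespan
        Species maximum lifespan L in years, must be > 0.

    Returns
    -------
    ``age / max_lifespan``.  Values above 1 are allowed (an animal older
    than the recorded species maximum) but trigger a warning.
    """
    if not (max_lifespan > 0):
        raise ValueError(f"max_lifespan must be positive, got {max_lifespan!r}")
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    rel = age / max_lifespan
    if np.any(rel > 1):
        warnings.warn(
            "relative age exceeds 1 (age beyond recorded maximum lifespan)",
            stacklevel=2,
        )
    return rel if rel.ndim else float(rel)


def loglinear_forward(age, m: float, k: float):
    """Log-linear transform of chronological age (see module docstring)."""
    _check_mk(m, k)
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    out = np.where(a <= m, np.log((a + k) / (m + k)), (a - m) / (m + k))
    return out if out.ndim else float(out)


def loglinear_inverse(y, m: float, k: float):
    """Exact inverse of :func:`loglinear_forward`.

    Negative transformed values map back into the pre-maturity log region;
    values below F(0) = log(k/(m+k)) correspond to ages before fertilisation
    and are flagged with a warning (the raw extrapolated value is returned).
    """
    _check_mk(m, k)
    yv = np.asarray(y, dtype=float)
    floor = np.log(k / (m + k))  # F(0)
    if np.any(yv < floor):
        warnings.warn(
            "transformed age below F(0): below-birth extrapolation", stacklevel=2
        )
    out = np.where(yv <= 0, (m + k) * np.exp(yv) - k, m + yv * (m + k))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AgeTransformSpec:
    """A named age transform plus its per-species parameters.

    Parameters
    ----------
    kind
        One of ``identity``, ``loglinear``, ``relative``.
    params
        Mapping ``species -> {"m": ..., "k": ..., "L": ...}``; only the
        entries a kind needs are required (m, k for loglinear; L for
        relative; identity needs none).
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = ("identity", "loglinear", "relative")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")

    @classmethod
    def from_registry(cls, kind: str, registry, species) -> "AgeTransformSpec":
        """Build a spec for the given species, reading m/L from *registry*
        and defaulting k to ``m * DEFAULT_K_FRACTION``."""
        params = {}
        for sp in species:
            info = registry[sp]
            params[sp] = {
                "m": info.maturity_years,
                "k": info.maturity_years * DEFAULT_K_FRACTION,
                "L": info.max_lifespan_years,
            }
        return cls(kind=kind, params=params)

    def _sp(self, species: str) -> dict:
        try:
            return self.params[species]
        except KeyError:
            raise KeyError(
                f"species {species!r} not covered by this transform spec"
            ) from None

    def forward(self, age, species: str):
        """Transform chronological age (years) to the response scale."""
        if self.kind == "identity":
            return np.asarray(age, dtype=float)
        p = self._sp(species)
        if self.kind == "loglinear":
            return loglinear_forward(age, p["m"], p["k"])
        return relative_age(age, p["L"])

    def inverse(self, y, species: str):
        """Map a model score back to reporting units.

        Chronological kinds return years; the relative kind reports the raw
        fraction (predictions are deliberately not clipped to [0, 1]).
        """
        if self.kind in ("identity", "relative"):
            return np.asarray(y, dtype=float)
        p = self._sp(species)
        return loglinear_inverse(y, p["m"], p["k"])

    def observed(self, age, species: str):
        """The observed value predictions are compared against: years for
        chronological kinds, age/L for the relative kind."""
        if self.kind == "relative":
            return relative_age(age, self._sp(species)["L"])
        return np.asarray(age, dtype=float)

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": {s: dict(p) for s, p in self.params.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "AgeTransformSpec":
        return cls(kind=d["kind"], params={s: dict(p) for s, p in d["params"].items()})
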