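"""Restricted cubic spline basis on log time for the baseline log cumulative hazard.

Each trial j gets its own spline s_j(ln t), giving a flexible parametric
baseline on the proportional-hazards (log cumulative hazard) scale.  The
basis is the standard restricted ("natural") cubic construction: linear
beyond the boundary knots, with K internal knots contributing one cubic term
each.  With K = 0 the model collapses to a Weibull baseline, which is the
primary analytic oracle for the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KnotSet", "select_knots", "basis", "basis_derivative"]


@dataclass(frozen=True)
class KnotSet:
    """Boundary and internal knots on the ln(t) scale."""

    k_min: float
    k_max: float
    internal: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ks = (self.k_min, *self.internal, self.k_max)
        if not all(a < b for a, b in zip(ks, ks[1:])):
            raise ValueError(f"knots must be strictly increasing, got {ks}")

    @property
    def n_internal(self) -> int:
        return len(self.internal)

    @property
    def n_basis(self) -> int:
        """Number of basis columns (excluding the intercept)."""
        return 1 + len(self.internal)

    def to_dict(self) -> dict:
        return {"k_min": self.k_min, "k_max": self.k_max, "internal": list(self.internal)}


def select_knots(log_event_times, n_internal: int = 2) -> KnotSet:
    """Place knots from the uncensored log event times.

    Boundary knots sit at the minimum and maximum observed log event time;
    internal knots at equally spaced centiles of the event-time distribution
    (K=1 -> median, K=2 -> 33rd/67th percentiles, ...).
    """
    x = np.asarray(log_event_times, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError(
            "need at least 2 distinct uncensored event times to place knots"
        )
    if n_internal < 0:
        raise ValueError("n_internal must be >= 0")
    if n_internal > distinct.size - 2:
        raise ValueError(
            f"{n_internal} internal knots need at least {n_internal + 2} distinct "
            f"event times (got {distinct.size})"
        )
    k_min, k_max = float(distinct.min()), float(distinct.max())
    if n_internal == 0:
        return KnotSet(k_min, k_max)
    qs = np.arange(1, n_internal + 1) / (n_internal + 1) * 100.0
    internal = np.percentile(x, qs)
    # nudge duplicates produced by heavily tied data off the boundaries
    internal = tuple(float(v) for v in internal)
    ks = (k_min, *internal, k_max)
    if not all(a < b for a, b in zip(ks, ks[1:])):
        raise ValueError(
            "tied centiles: cannot place strictly increasing internal knots; "
            "reduce n_internal"
        )
    return KnotSet(k_min, k_max, internal)


def _plus3(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3


def _plus2(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 2


def basis(x, knots: KnotSet) -> np.ndarray:
    """Evaluate the restricted cubic basis at ``x`` (ln t scale).

    Returns an array of shape ``(..., K+1)``: column 0 is ``x`` itself and
    column m (1 <= m <= K) is

        (x - k_m)+^3 - lam_m (x - k_min)+^3 - (1 - lam_m)(x - k_max)+^3

    with ``lam_m = (k_max - k_m) / (k_max - k_min)``.  The intercept is part
    of the linear predictor, not the basis.
    """
    x = np.asarray(x, dtype=float)
    cols = [x]
    span = knots.k_max - knots.k_min
    for km in knots.internal:
        lam = (knots.k_max - km) / span
        cols.append(
            _plus3(x - km) - lam * _plus3(x - knots.k_min) - (1.0 - lam) * _plus3(x - knots.k_max)
        )
    return np.stack(cols, axis=-1)


def basis_derivative(x, knots: KnotSet) -> np.ndarray:
    """Exact analytic derivative of :func:`basis` with respect to x."""
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x)]
    span = knots.k_max - knots.k_min
    for km in knots.internal:
        lam = (knots.k_max - km) / span
        cols.append(
            3.0 * (_plus2(x - km) - lam * _plus2(x - knots.k_min) - (1.0 - lam) * _plus2(x - knots.k_max))
        )
    return np.stack(cols, axis=-1)
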