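"""Fixed-node quadrature for cumulative hazards.

The cumulative hazard over a subject-specific interval [entry, T] is
approximated with a single Gauss-Kronrod panel whose nodes are affinely
mapped into the interval.  The 15-point Kronrod rule is the default; plain
Gauss-Legendre rules are available for other node counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# 15-point Kronrod rule on (-1, 1): positive abscissae and weights
# (QUADPACK values; the rule is symmetric and its weights sum to 2).
_K15_X = np.array(
    [
        0.991455371120813,
        0.949107912342759,
        0.864864423359769,
        0.741531185599394,
        0.586087235467691,
        0.405845151377397,
        0.207784955007898,
        0.0,
    ]
)
_K15_W = np.array(
    [
        0.022935322010529,
        0.063092092629979,
        0.104790010322250,
        0.140653259715525,
        0.169004726639267,
        0.190350578064785,
        0.204432940075298,
        0.209482141084728,
    ]
)


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes and weights on the reference interval (-1, 1)."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.nodes.shape != self.weights.shape:
            raise ValueError("nodes and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")

    @property
    def node_count(self) -> int:
        return self.nodes.size

    @classmethod
    def gauss_kronrod(cls, q: int = 15) -> "QuadratureRule":
        if q != 15:
            raise ValueError(
                "only the 15-point Gauss-Kronrod rule is tabulated; "
                "use gauss_legendre for other node counts"
            )
        nodes = np.concatenate([-_K15_X[:-1], _K15_X[::-1]])
        weights = np.concatenate([_K15_W[:-1], _K15_W[::-1]])
        return cls(nodes=nodes, weights=weights)

    @classmethod
    def gauss_legendre(cls, q: int) -> "QuadratureRule":
        if q < 1:
            raise ValueError("need at least one node")
        nodes, weights = np.polynomial.legendre.leggauss(q)
        return cls(nodes=nodes, weights=weights)

    def mapped(self, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
        """Nodes and weights mapped to the interval [a, b]."""
        if b < a:
            raise ValueError(f"interval end {b} precedes start {a}")
        half = 0.5 * (b - a)
        return 0.5 * (a + b) + half * self.nodes, half * self.weights


def default_rule() -> QuadratureRule:
    """The rule used throughout: 15-point Gauss-Kronrod."""
    return QuadratureRule.gauss_kronrod(15)


def integrate(fn, a: float, b: float, rule: QuadratureRule | None = None) -> float:
    """Approximate the integral of ``fn`` over [a, b] with a single panel."""
    rule = rule or default_rule()
    s, w = rule.mapped(a, b)
    if s.size == 0 or a == b:
        return 0.0
    return float(np.dot(w, np.asarray(fn(s), dtype=float)))
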