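"""Jukes-Cantor continuous-time Markov chain on the DNA alphabet {A,C,G,T}.

The rate matrix is normalized to one expected substitution per unit branch
length (off-diagonal rate 1/3, diagonal -1), the universal JC scaling, so a
branch length is the expected number of substitutions per site.  Transition
matrices follow the right-stochastic convention: entry (i, j) is P(j | i).

The engine is written against generic 4x4 transition matrices and explicit
transposes, so a non-symmetric substitution model could be dropped in without
touching the traversal code; only this module is JC-specific.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "ALPHABET",
    "jc_rate_matrix",
    "jc_transition_matrix",
    "jc_transition_derivative",
    "stationary_distribution",
]

ALPHABET = "ACGT"


def jc_rate_matrix() -> np.ndarray:
    """The JC rate matrix Q with unit expected substitution rate."""
    q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(q, -1.0)
    return q


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not math.isfinite(theta) or theta < 0.0:
        raise ValueError(f"branch length must be finite and >= 0, got {theta}")
    return theta


def jc_transition_matrix(theta: float) -> np.ndarray:
    """P(theta) = exp(theta Q) in closed form.

    Diagonal entries are 1/4 + (3/4) e^(-4 theta / 3), off-diagonals
    1/4 - (1/4) e^(-4 theta / 3).
    """
    theta = _check_theta(theta)
    x = math.exp(-4.0 * theta / 3.0)
    off = 0.25 - 0.25 * x
    p = np.full((4, 4), off)
    np.fill_diagonal(p, 0.25 + 0.75 * x)
    return p


def jc_transition_derivative(theta: float) -> np.ndarray:
    """Entrywise derivative dP/dtheta; every row sums to zero."""
    theta = _check_theta(theta)
    x = math.exp(-4.0 * theta / 3.0)
    d = np.full((4, 4), x / 3.0)
    np.fill_diagonal(d, -x)
    return d


def stationary_distribution() -> np.ndarray:
    """The JC stationary (and root) distribution: uniform over bases."""
    return np.full(4, 0.25)
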