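"""The covariation statistic C and its one-sided permutation test.

C measures monotone — not necessarily linear — co-movement of two
plot-level variables x and y:

    C = sum_{i<j} (x_i - x_j)(y_i - y_j)  /  sum_{i<j} |x_i - x_j| |y_i - y_j|.

C = 1 means every pair of plots moves in the same direction (entirely
positive covariation), C = -1 strictly opposite movement; tied pairs
contribute zero to both sums.  When the denominator is zero (either
variable constant) C is undefined and is reported as such, never as a
number.

Significance is assessed by permuting y across plots.  With few plots all
orderings are enumerated and the p-value is the exact tail proportion;
otherwise permutations are sampled and the add-one convention
p = (1 + #{C_perm >= C_obs}) / (1 + B) avoids a zero p-value.  Permuted
data sets on which C is undefined cannot be ranked against the observed
statistic and are excluded from both counts (their number is reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

__all__ = ["CovariationResult", "covariation_C", "perm_test_C"]

DEFAULT_N_PERM = 5000


@dataclass
class CovariationResult:
    """Outcome of a covariation permutation test."""

    C: float
    p_value: float
    n_perm: int               # permutations actually ranked (defined C only)
    exact: bool               # True when all orderings were enumerated
    n_extreme: int            # permutations with C_perm >= C_obs (or <= for "less")
    n_undefined: int = 0      # permutations with undefined C, excluded
    alternative: str = "greater"
    labels: tuple[str, str] = ("x", "y")


def _pairwise(x: np.ndarray) -> np.ndarray:
    return x[:, None] - x[None, :]


def covariation_C(x, y) -> float | None:
    """Compute C for aligned plot series; ``None`` when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d series")
    if x.size < 2:
        raise ValueError("need at least two plots")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values in input series")
    dx = _pairwise(x)
    dy = _pairwise(y)
    num = float(np.sum(dx * dy)) / 2.0
    den = float(np.sum(np.abs(dx) * np.abs(dy))) / 2.0
    if den == 0.0:
        return None
    return num / den


def _c_for_permutations(x: np.ndarray, y_perms: np.ndarray) -> np.ndarray:
    """Vectorised C over a (B, n) block of permuted y series; NaN = undefined."""
    dx = _pairwise(x)
    dy = y_perms[:, :, None] - y_perms[:, None, :]
    num = np.einsum("ij,bij->b", dx, dy) / 2.0
    den = np.einsum("ij,bij->b", np.abs(dx), np.abs(dy)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return out


def perm_test_C(
    x,
    y,
    *,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alternative: str = "greater",
    labels: tuple[str, str] = ("x", "y"),
) -> CovariationResult:
    """One-sided permutation test of C by permuting y across plots.

    ``alternative="greater"`` tests P(Z >= C_obs) (positive covariation),
    ``"less"`` the opposite tail.  If n! <= *n_perm* every ordering is
    enumerated (exact mode, plain tail proportion); otherwise *n_perm*
    permutations are drawn from the seeded RNG and the add-one convention
    applies.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c_obs = covariation_C(x, y)
    if c_obs is None:
        raise ValueError(
            "observed C is undefined (zero denominator); no permutation test possible"
        )
    n = x.size
    n_orderings = math.factorial(n)
    exact = n_orderings <= n_perm
    if exact:
        y_perms = np.array(list(permutations(y)), dtype=float)
    else:
        rng = np.random.default_rng(seed)
        y_perms = np.empty((n_perm, n), dtype=float)
        for b in range(n_perm):
            y_perms[b] = rng.permutation(y)
    c_perm = _c_for_permutations(x, y_perms)
    defined = ~np.isnan(c_perm)
    n_defined = int(defined.sum())
    if n_defined == 0:
        raise ValueError("every permutation gave an undefined C; cannot rank")
    if alternative == "greater":
        n_extreme = int(np.sum(c_perm[defined] >= c_obs))
    else:
        n_extreme = int(np.sum(c_perm[defined] <= c_obs))
    if exact:
        p = n_extreme / n_defined
    else:
        p = (1 + n_extreme) / (1 + n_defined)
    return CovariationResult(
        C=float(c_obs),
        p_value=float(p),
        n_perm=n_defined,
        exact=exact,
        n_extreme=n_extreme,
        n_undefined=int(len(c_perm) - n_defined),
        alternative=alternative,
        labels=labels,
    )
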