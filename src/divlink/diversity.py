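"""Hill-number diversity profiles for species abundances and dominant loci.

The Hill number of order ``a`` of a frequency distribution ``p`` is the
"effective number of variants"

    nu_a = ( sum_i p_i^a )^(1 / (1 - a)),

with the limits nu_0 = richness (count of variants present), nu_1 =
exp(Shannon entropy), nu_2 = 1 / sum p_i^2 (reciprocal Simpson
concentration) and nu_inf = 1 / max_i p_i (reciprocal of the most frequent
variant).  nu_a is non-increasing in ``a`` and equals the number of
variants k exactly when the distribution is uniform.

At a dominant binary locus only two phenotypic variants exist — band
present ('1') and band absent ('2') — so the locus-level diversity
``nu_g,2`` lives in [1, 2] before any small-sample correction.  Plot-level
values are averaged over retained loci into the multilocus summary
``nu_mean,2``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import AbundanceTable, BinaryMarkerMatrix, locus_frequencies

__all__ = [
    "hill_number",
    "species_profile",
    "locus_diversity",
    "mean_locus_diversity",
    "plot_locus_diversity",
    "CORRECTION_MODES",
]

#: Orders reported in the species diversity profile.
PROFILE_ORDERS = (0.0, 2.0, math.inf)

CORRECTION_MODES = ("none", "literal_factor", "unbiased_simpson")

_SUM_TOL = 1e-6
_A1_TOL = 1e-9


def hill_number(p, a: float) -> float:
    """Effective number of variants of order ``a`` for distribution ``p``.

    ``p`` must be nonnegative and sum to 1 (within 1e-6).  Zero-frequency
    entries are dropped before evaluation (``0^a = 0`` convention; they do
    not count toward richness either).  ``a`` may be any nonnegative real
    or ``math.inf``; the order-1 case is evaluated as the entropy limit.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d frequency vector")
    if (p < 0).any():
        raise ValueError("negative frequencies in p")
    total = p.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies sum to {total}, not 1")
    if not (a >= 0):  # catches NaN too
        raise ValueError(f"order a must be nonnegative, got {a}")
    p = p[p > 0]
    if a == 0:
        return float(p.size)
    if math.isinf(a):
        return float(1.0 / p.max())
    if abs(a - 1.0) < _A1_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**a) ** (1.0 / (1.0 - a)))


def species_profile(
    table: AbundanceTable, plot: str, orders=PROFILE_ORDERS
) -> dict[float, float]:
    """Species-diversity profile of one plot: {order: nu_sp,a}.

    Frequencies are the plot's species counts normalised within the plot;
    the default orders give richness (a=0), the effective (Simpson) number
    of species (a=2) and the number of prevalent species (a=inf).
    """
    p = table.frequencies(plot)
    return {a: hill_number(p, a) for a in orders}


def locus_diversity(f_v1, n=None, correction: str = "literal_factor"):
    """Effective number nu_g,2 of the two variants at a dominant locus.

    Parameters
    ----------
    f_v1
        Frequency (or array of frequencies) of variant '1'.
    n
        Sample size(s) behind the frequency; required unless
        ``correction == "none"``, and must be >= 2 for a correction.
    correction
        ``"none"``       raw nu_2 = 1 / (f_v1^2 + f_vr^2);
        ``"literal_factor"`` (default) raw value times n/(n-1);
        ``"unbiased_simpson"`` reciprocal of the unbiased concentration
        estimator, 1 / ((n * S - 1) / (n - 1)) with S = f_v1^2 + f_vr^2.

    The literal factor is the small-sample correction reported with the
    study design this package targets; the unbiased-Simpson variant is the
    classical alternative and is offered for comparison.
    """
    if correction not in CORRECTION_MODES:
        raise ValueError(f"unknown correction mode {correction!r}")
    f1 = np.asarray(f_v1, dtype=float)
    if ((f1 < 0) | (f1 > 1)).any():
        raise ValueError("f_v1 outside [0, 1]")
    concentration = f1**2 + (1.0 - f1) ** 2
    raw = 1.0 / concentration
    if correction == "none":
        return raw if raw.ndim else float(raw)
    if n is None:
        raise ValueError(f"sample size n required for correction {correction!r}")
    n = np.asarray(n, dtype=float)
    if (n < 2).any():
        raise ValueError("bias correction requires n >= 2")
    if correction == "literal_factor":
        out = raw * n / (n - 1.0)
    else:
        unbiased = (n * concentration - 1.0) / (n - 1.0)
        if (unbiased <= 0).any():
            raise ValueError(
                "unbiased Simpson concentration is nonpositive (degenerate n, f)"
            )
        out = 1.0 / unbiased
    return out if out.ndim else float(out)


def mean_locus_diversity(values) -> float:
    """Arithmetic mean of per-locus nu_g,2 values (the multilocus nu_mean,2)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no locus diversities to average")
    if np.isnan(values).any():
        raise ValueError("NaN locus diversity in input")
    return float(values.mean())


def plot_locus_diversity(
    m: BinaryMarkerMatrix,
    retained: list[str],
    *,
    correction: str = "literal_factor",
    min_n: int = 2,
) -> pd.DataFrame:
    """Per-plot, per-locus nu_g,2 for the retained loci of one species' matrix.

    Frequencies are computed within each plot (the unit of the covariation
    analysis), so each value carries that plot's sample size.  Loci whose
    within-plot frequency is undefined or whose sample size is below
    *min_n* get NaN for that plot.

    Returns a long frame with columns ``plot, locus_id, n, f_v1, f_vr, v_g2``.
    """
    frames = []
    for plot in m.plots:
        freqs = locus_frequencies(m, plots=[plot]).loc[retained]
        ok = (freqs["n"] >= min_n) & freqs["f_v1"].notna()
        v = np.full(len(freqs), np.nan)
        if ok.any():
            v[ok.to_numpy()] = locus_diversity(
                freqs.loc[ok, "f_v1"].to_numpy(),
                freqs.loc[ok, "n"].to_numpy(),
                correction=correction,
            )
        block = freqs.reset_index()
        block.insert(0, "plot", plot)
        block["v_g2"] = v
        frames.append(block)
    return pd.concat(frames, ignore_index=True)
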