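"""Staged candidate selection and the multiple-testing corrections.

The pipeline declares a locus a community-genetics candidate in stages:

1. scan stage — the locus is a diversifying outlier: q-value (FDR) < 0.05,
   posterior probability > 0.95 and alpha > 0;
2. covariation stage — at least one of its diversity-covariation tests is
   significant at the uncorrected 0.05 level;
3. top-k stage — among the survivors, keep the k (default 5) loci with the
   highest posterior probabilities (ties at rank k are all kept and m is
   enlarged accordingly);
4. Bonferroni stage — each kept locus' covariation p-values face the
   corrected per-test level alpha / m.

The delta test uses the two-sided variant of the correction,
alpha / (2 m), which for alpha = 0.05 and m = 6 gives the conventional
0.004 criterion after rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CandidateDecision", "bonferroni_threshold", "select_candidates"]

SCAN_FDR_MAX = 0.05
SCAN_POST_PROB_MIN = 0.95
UNCORRECTED_LEVEL = 0.05


@dataclass
class CandidateDecision:
    """Per-locus outcome of the staged selection."""

    locus_id: str
    passed_scan: bool
    passed_C: bool
    selected_top5: bool
    significant_after_bonferroni: bool
    post_prob: float
    alpha: float
    fdr: float
    min_C_p: float | None
    corrected_level: float | None


def bonferroni_threshold(alpha: float, m: int, sided: str = "one") -> float:
    """Corrected per-test level: alpha/m one-sided, alpha/(2m) two-sided."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    return alpha / m if sided == "one" else alpha / (2 * m)


def select_candidates(
    scan_results: pd.DataFrame,
    c_pvalues: dict[str, list[float]],
    k: int = 5,
    alpha: float = 0.05,
) -> tuple[list[CandidateDecision], dict]:
    """Apply the staged selection to scan results and covariation p-values.

    Parameters
    ----------
    scan_results
        Frame indexed by locus id with columns ``alpha, post_prob, fdr``
        (the output of the outlier scan).
    c_pvalues
        For each locus id, the p-values of its covariation tests (e.g. the
        three diversity orders x two genetic variables).  A locus absent
        from this mapping is treated as having no significant covariation.
    k
        Number of top loci kept by posterior probability (default 5).

    Returns ``(decisions, info)``; *info* records the m actually used and
    the corrected level.  If fewer than *k* loci survive the first two
    stages, m is set to the survivor count.  Decisions are deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    decisions: list[CandidateDecision] = []
    survivors: list[tuple[str, float]] = []
    for locus_id, row in scan_results.iterrows():
        locus_id = str(locus_id)
        pvals = [p for p in c_pvalues.get(locus_id, [])]
        passed_scan = bool(
            row["fdr"] < SCAN_FDR_MAX
            and row["post_prob"] > SCAN_POST_PROB_MIN
            and row["alpha"] > 0
        )
        passed_c = bool(any(p < UNCORRECTED_LEVEL for p in pvals))
        decisions.append(
            CandidateDecision(
                locus_id=locus_id,
                passed_scan=passed_scan,
                passed_C=passed_c,
                selected_top5=False,
                significant_after_bonferroni=False,
                post_prob=float(row["post_prob"]),
                alpha=float(row["alpha"]),
                fdr=float(row["fdr"]),
                min_C_p=min(pvals) if pvals else None,
                corrected_level=None,
            )
        )
        if passed_scan and passed_c:
            survivors.append((locus_id, float(row["post_prob"])))

    if not survivors:
        return decisions, {"m": 0, "corrected_level": None, "n_survivors": 0}

    survivors.sort(key=lambda t: -t[1])
    if len(survivors) <= k:
        kept = {lid for lid, _ in survivors}
    else:
        cutoff = survivors[k - 1][1]
        # keep all loci tied with the k-th posterior probability
        kept = {lid for lid, pp in survivors if pp >= cutoff}
    m = len(kept)
    level = bonferroni_threshold(alpha, m, sided="one")
    for d in decisions:
        if d.locus_id in kept:
            d.selected_top5 = True
            d.corrected_level = level
            pvals = c_pvalues.get(d.locus_id, [])
            d.significant_after_bonferroni = bool(any(p < level for p in pvals))
    info = {"m": m, "corrected_level": level, "n_survivors": len(survivors)}
    return decisions, info


def decisions_frame(decisions: list[CandidateDecision]) -> pd.DataFrame:
    """Tabular view of a decision list (one row per locus)."""
    return pd.DataFrame([d.__dict__ for d in decisions])
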