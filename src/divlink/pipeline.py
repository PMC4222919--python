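"""End-to-end orchestration: filter -> diversity -> scan -> covariation -> selection.

``run_all`` chains every stage on either a simulated dataset or files on
disk, producing the study's report tables: the per-plot diversity summary
with its "across all plots" mean row, the outlier-scan table, the
candidate covariation table, the staged selection ledger, and the
community differentiation record, together with a manifest recording every
seed and threshold used.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .covariation import perm_test_C
from .differentiation import perm_test_delta
from .diversity import (
    mean_locus_diversity,
    plot_locus_diversity,
    species_profile,
)
from .outlier import ScanConfig, scan
from .selection import bonferroni_threshold, decisions_frame, select_candidates
from .simulate import SimDesign, simulate_dataset, write_dataset

__all__ = ["run_all", "summarize_table2", "covariation_tests_for_candidates"]

MEAN_ROW_LABEL = "across all plots"
DIVERSITY_ORDERS = (0.0, 2.0, math.inf)
_ORDER_NAMES = {0.0: "0", 2.0: "2", math.inf: "inf"}


def summarize_table2(per_plot: pd.DataFrame) -> pd.DataFrame:
    """Append the arithmetic-mean row to a per-plot diversity summary.

    Means are taken per column over the plots where the value exists
    (species not sampled in a plot contribute nothing for that plot).
    """
    if len(per_plot) < 1:
        raise ValueError("need at least one plot")
    numeric = per_plot.select_dtypes(include=[np.number])
    mean_row = numeric.mean(axis=0, skipna=True)
    out = per_plot.copy()
    out.loc[MEAN_ROW_LABEL] = mean_row
    return out


def _stage_seed(base_seed: int, stage: str, k: int = 0) -> int:
    """Deterministic derived seed, kept below 2**31."""
    ss = np.random.SeedSequence((base_seed, sum(stage.encode()), k))
    return int(ss.generate_state(1)[0] % (2**31))


def diversity_summary(
    community: dio.AbundanceTable,
    plot_diversities: dict[str, pd.DataFrame],
    correction_mode: str,
) -> pd.DataFrame:
    """Per-plot species profile columns plus per-species nu_mean,2 columns."""
    rows = {}
    for plot in community.plots:
        prof = species_profile(community, plot, DIVERSITY_ORDERS)
        rows[plot] = {
            f"nu_sp_{_ORDER_NAMES[a]}": v for a, v in prof.items()
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "plot"
    for sp, table in plot_diversities.items():
        col = {}
        for plot, block in table.groupby("plot"):
            values = block["v_g2"].dropna()
            if len(values):
                col[plot] = mean_locus_diversity(values)
        frame[f"nu_mean2_{sp}"] = pd.Series(col)
    return frame


def covariation_tests_for_candidates(
    candidates: list[str],
    plot_table: pd.DataFrame,
    species_profiles: pd.DataFrame,
    *,
    n_perm: int,
    base_seed: int,
    min_plots: int = 3,
) -> tuple[pd.DataFrame, dict[str, list[float]]]:
    """One-sided C tests for each candidate locus: 3 orders x {f_vr, v_g2}.

    *plot_table* is the long per-plot per-locus frame (``plot, locus_id,
    f_vr, v_g2``) of one species; *species_profiles* is indexed by plot
    with columns ``nu_sp_0, nu_sp_2, nu_sp_inf``.  Plots with undefined
    values are dropped per test; tests with fewer than *min_plots* plots
    or an undefined observed C are skipped (recorded with NaN).
    """
    records = []
    pvalues: dict[str, list[float]] = {lid: [] for lid in candidates}
    for li, locus in enumerate(candidates):
        block = plot_table[plot_table["locus_id"] == locus].set_index("plot")
        for oi, a in enumerate(DIVERSITY_ORDERS):
            xcol = f"nu_sp_{_ORDER_NAMES[a]}"
            for vi, var in enumerate(("f_vr", "v_g2")):
                joined = species_profiles[[xcol]].join(block[[var]], how="inner").dropna()
                rec = {
                    "locus_id": locus,
                    "order_a": _ORDER_NAMES[a],
                    "variable": var,
                    "n_plots": len(joined),
                    "C": np.nan,
                    "p_value": np.nan,
                }
                if len(joined) >= min_plots:
                    try:
                        res = perm_test_C(
                            joined[xcol].to_numpy(),
                            joined[var].to_numpy(),
                            n_perm=n_perm,
                            seed=_stage_seed(base_seed, "covary", li * 100 + oi * 10 + vi),
                            alternative="greater",
                            labels=(xcol, var),
                        )
                        rec["C"] = res.C
                        rec["p_value"] = res.p_value
                        pvalues[locus].append(res.p_value)
                    except ValueError:
                        pass  # undefined observed C: no test
                records.append(rec)
    return pd.DataFrame(records), pvalues


def multilocus_covariation(
    species_profiles: pd.DataFrame,
    plot_diversities: dict[str, pd.DataFrame],
    *,
    n_perm: int,
    base_seed: int,
    min_plots: int = 3,
) -> pd.DataFrame:
    """C between species diversity and nu_mean,2 per species and order."""
    records = []
    for si, (sp, table) in enumerate(sorted(plot_diversities.items())):
        means = (
            table.dropna(subset=["v_g2"]).groupby("plot")["v_g2"].mean().rename("nu_mean2")
        )
        for oi, a in enumerate(DIVERSITY_ORDERS):
            xcol = f"nu_sp_{_ORDER_NAMES[a]}"
            joined = species_profiles[[xcol]].join(means, how="inner").dropna()
            rec = {
                "species": sp,
                "order_a": _ORDER_NAMES[a],
                "n_plots": len(joined),
                "C": np.nan,
                "p_value": np.nan,
            }
            if len(joined) >= min_plots:
                try:
                    res = perm_test_C(
                        joined[xcol].to_numpy(),
                        joined["nu_mean2"].to_numpy(),
                        n_perm=n_perm,
                        seed=_stage_seed(base_seed, "covary-mean", si * 10 + oi),
                        alternative="greater",
                    )
                    rec["C"] = res.C
                    rec["p_value"] = res.p_value
                except ValueError:
                    pass
            records.append(rec)
    return pd.DataFrame(records)


def census_covariation(
    census: pd.DataFrame,
    species: str,
    species_profiles: pd.DataFrame,
    plot_table: pd.DataFrame,
    candidates: list[str],
    *,
    n_perm: int,
    base_seed: int,
    min_plots: int = 3,
) -> pd.DataFrame:
    """C between a species' census abundance N per plot and the diversity
    variables: N x nu_sp,2, N x nu_mean,2 and, per candidate locus,
    N x v_g2 and N x f_vr."""
    n_series = (
        census[census["species"] == species].set_index("plot")["N"].astype(float)
    )
    means = (
        plot_table.dropna(subset=["v_g2"]).groupby("plot")["v_g2"].mean().rename("nu_mean2")
    )
    targets: list[tuple[str, pd.Series]] = [
        ("nu_sp_2", species_profiles["nu_sp_2"]),
        ("nu_mean2", means),
    ]
    for locus in candidates:
        block = plot_table[plot_table["locus_id"] == locus].set_index("plot")
        targets.append((f"v_g2[{locus}]", block["v_g2"]))
        targets.append((f"f_vr[{locus}]", block["f_vr"]))
    records = []
    for ti, (name, series) in enumerate(targets):
        joined = pd.concat([n_series.rename("N"), series.rename("y")], axis=1).dropna()
        rec = {"species": species, "variable": name, "n_plots": len(joined),
               "C": np.nan, "p_value": np.nan}
        if len(joined) >= min_plots:
            try:
                res = perm_test_C(
                    joined["N"].to_numpy(),
                    joined["y"].to_numpy(),
                    n_perm=n_perm,
                    seed=_stage_seed(base_seed, "covary-census", ti),
                    alternative="greater",
                    labels=("N", name),
                )
                rec["C"] = res.C
                rec["p_value"] = res.p_value
            except ValueError:
                pass
        records.append(rec)
    return pd.DataFrame(records)


def _load_inputs(config: dict) -> dict:
    paths = config["inputs"]
    community = dio.read_abundance_table(paths["abundance"])
    census = dio.read_census(paths["census"]) if "census" in paths else None
    markers = {
        sp: dio.read_marker_matrix(path) for sp, path in paths["markers"].items()
    }
    return {
        "design": None,
        "community": community,
        "census": census,
        "markers": markers,
        "truth": {},
    }


def run_all(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage and return (and optionally write) the report bundle.

    ``config`` keys:

    - ``seed`` (int, required): master seed for every stochastic stage;
    - ``design``: :class:`SimDesign` kwargs for a simulated dataset, or
      ``inputs`` with file paths (``abundance``, ``census``, ``markers``);
    - ``species``: species to analyse (default: all marker matrices);
    - ``n_perm`` (default 5000), ``k`` (top-candidate count, default 5),
    - ``correction_mode`` (``literal_factor`` or ``unbiased_simpson``),
    - ``scan``: ScanConfig kwargs; ``fast: true`` selects the 10x-shorter
      test profile;
    - ``filter``: ``{"lower": 0.05, "upper": 0.95}`` overrides.
    """
    t0 = time.time()
    seed = int(config["seed"])
    n_perm = int(config.get("n_perm", 5000))
    k = int(config.get("k", 5))
    correction = config.get("correction_mode", "literal_factor")
    flt = config.get("filter", {})
    lower, upper = flt.get("lower", 0.05), flt.get("upper", 0.95)

    if "inputs" in config:
        bundle = _load_inputs(config)
    else:
        design_kwargs = dict(config.get("design", {}))
        design_kwargs.setdefault("seed", _stage_seed(seed, "simulate"))
        design = SimDesign(**design_kwargs)
        bundle = simulate_dataset(design, species=config.get("species"))

    community = bundle["community"]
    markers: dict = bundle["markers"]
    species_list = config.get("species") or sorted(markers)
    timings, manifest_stages = {}, {}

    # -- locus filter per species (pooled across that species' plots) --------
    retained: dict[str, list[str]] = {}
    filter_logs: dict[str, pd.DataFrame] = {}
    for sp in species_list:
        freqs = dio.locus_frequencies(markers[sp])
        kept, log = dio.filter_loci(freqs, lower, upper)
        retained[sp] = kept
        filter_logs[sp] = log
    timings["filter"] = time.time() - t0

    # -- diversity profiles ----------------------------------------------------
    t = time.time()
    plot_div = {
        sp: plot_locus_diversity(markers[sp], retained[sp], correction=correction)
        for sp in species_list
        if retained[sp]
    }
    per_plot = diversity_summary(community, plot_div, correction)
    table2 = summarize_table2(per_plot)
    profiles = per_plot[[c for c in per_plot.columns if c.startswith("nu_sp_")]]
    timings["diversity"] = time.time() - t

    # -- outlier scan ------------------------------------------------------------
    t = time.time()
    scan_cfg_kwargs = dict(config.get("scan", {}))
    fast = scan_cfg_kwargs.pop("fast", False)
    scan_results, scan_diag = {}, {}
    for i, sp in enumerate(species_list):
        if not retained[sp]:
            continue
        scan_cfg_kwargs["seed"] = _stage_seed(seed, "scan", i)
        cfg = (
            ScanConfig.fast(**scan_cfg_kwargs)
            if fast
            else ScanConfig(**scan_cfg_kwargs)
        )
        res, diag = scan(markers[sp], cfg, retained=retained[sp])
        diag.pop("gamma_samples", None)
        scan_results[sp] = res
        scan_diag[sp] = diag
    timings["scan"] = time.time() - t

    # -- community differentiation (species-composition mode) -------------------
    t = time.time()
    tree_species, tree_plots = [], []
    for plot in community.plots:
        row = community.counts.loc[plot]
        for sp_name, cnt in row.items():
            tree_species.extend([sp_name] * int(cnt))
            tree_plots.extend([plot] * int(cnt))
    delta_res = perm_test_delta(
        np.array(tree_species),
        np.array(tree_plots),
        n_perm=n_perm,
        seed=_stage_seed(seed, "delta"),
    )
    timings["delta"] = time.time() - t

    # -- covariation on scan candidates + selection ------------------------------
    t = time.time()
    covariation_tables, selections, selection_info = {}, {}, {}
    census_tables: dict[str, pd.DataFrame] = {}
    for sp in species_list:
        if sp not in scan_results:
            continue
        res = scan_results[sp]
        candidates = [
            str(l)
            for l, row in res.iterrows()
            if row["verdict"] == "diversifying" and row["fdr"] < 0.05
        ]
        ctable, pvals = covariation_tests_for_candidates(
            candidates,
            plot_div[sp],
            profiles,
            n_perm=n_perm,
            base_seed=_stage_seed(seed, "covary-base", sum(sp.encode())),
        )
        covariation_tables[sp] = ctable
        decisions, info = select_candidates(res, pvals, k=k)
        selections[sp] = decisions_frame(decisions)
        selection_info[sp] = info
        if bundle.get("census") is not None:
            census_tables[sp] = census_covariation(
                bundle["census"],
                sp,
                profiles,
                plot_div[sp],
                candidates,
                n_perm=n_perm,
                base_seed=_stage_seed(seed, "census", sum(sp.encode())),
            )
    table5 = multilocus_covariation(
        profiles, plot_div, n_perm=n_perm, base_seed=_stage_seed(seed, "covary-mean")
    )
    timings["covariation"] = time.time() - t

    manifest = {
        "seed": seed,
        "n_perm": n_perm,
        "k": k,
        "correction_mode": correction,
        "filter": {"lower": lower, "upper": upper},
        "species": species_list,
        "retained_loci": {sp: len(retained[sp]) for sp in species_list},
        "delta_criterion": bonferroni_threshold(0.05, 6, sided="two"),
        "selection": selection_info,
        "scan_diagnostics": {
            sp: {kk: vv for kk, vv in d.items() if kk != "config"}
            for sp, d in scan_diag.items()
        },
        "timings_s": {kk: round(vv, 3) for kk, vv in timings.items()},
    }

    report = {
        "bundle": bundle,
        "retained": retained,
        "filter_logs": filter_logs,
        "table2": table2,
        "profiles": profiles,
        "plot_diversities": plot_div,
        "scan": scan_results,
        "covariation": covariation_tables,
        "covariation_mean": table5,
        "covariation_census": census_tables,
        "selection": selections,
        "delta": delta_res,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_reports(report, Path(out_dir))
    return report


def _write_reports(report: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if report["bundle"].get("design") is not None:
        write_dataset(report["bundle"], out / "data")
    report["table2"].round(3).to_csv(out / "table2.tsv", sep="\t")
    for sp, res in report["scan"].items():
        res.round({"alpha": 3, "post_prob": 3, "fdr": 3}).to_csv(
            out / f"scan_{sp}.tsv", sep="\t"
        )
    for sp, tab in report["covariation"].items():
        tab.round({"C": 2, "p_value": 3}).to_csv(
            out / f"covariation_{sp}.tsv", sep="\t", index=False
        )
    report["covariation_mean"].round({"C": 2, "p_value": 3}).to_csv(
        out / "covariation_mean.tsv", sep="\t", index=False
    )
    for sp, tab in report["covariation_census"].items():
        tab.round({"C": 2, "p_value": 3}).to_csv(
            out / f"covariation_census_{sp}.tsv", sep="\t", index=False
        )
    for sp, tab in report["selection"].items():
        tab.to_csv(out / f"selection_{sp}.tsv", sep="\t", index=False)
    (out / "delta.json").write_text(json.dumps(report["delta"].to_dict(), indent=2))
    (out / "manifest.json").write_text(
        json.dumps(report["manifest"], indent=2, default=str)
    )
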