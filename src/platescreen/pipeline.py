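"""End-to-end analysis of a screen: normalization, conventional and GR
dose-response metrics, QC, variance components, and a machine-readable
summary. The CLI is a thin wrapper over this module; library users call
:func:`analyze_screen` directly."""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from . import dose_response as dr
from . import gr as grm
from . import normalize, qc, stats
from .io import Screen
from .wells import WellRole

DEFAULT_COVARIATES = ["cell_line", "drug", "conc", "treat_time_h", "experiment"]


def _fmt(value) -> Any:
    """JSON-friendly rendering; the NOT_REACHED sentinel becomes "NR"."""
    if value is dr.NOT_REACHED:
        return "NR"
    if isinstance(value, (np.floating, np.integer)):
        return float(value)
    return value


def analyze_screen(
    screen: Screen,
    grmax_variant: str = "single_top",
    x0_scope: str = "experiment",
    sw_replicate_corrected: bool = True,
    covariates: list[str] | None = None,
) -> dict[str, Any]:
    """Run the full analysis and return a dict of tidy tables plus a summary.

    Keys: ``series`` (viability + GR per concentration), ``dose_response``,
    ``gr_metrics``, ``qc`` (DataFrames), ``variance`` (DataFrame), and
    ``summary`` (per-condition dict for JSON export).
    """
    conditions = screen.conditions()
    series_frames: list[pd.DataFrame] = []
    dr_rows, gr_rows = [], []
    summary: dict[str, Any] = {"conditions": []}

    has_reference = (screen.data["role"] == WellRole.UNTREATED_REFERENCE.value).any()

    for _, cond in conditions.iterrows():
        cl, drug, tt = cond["cell_line"], cond["drug"], float(cond["treat_time_h"])
        vs = normalize.build_series(screen, cl, drug, tt)
        concs = vs.concentrations
        sf = vs.to_frame().rename(columns={"mean": "viability_pct"})

        fit = dr.fit_viability_curve(vs)
        pot = dr.potency(vs, fit)
        dr_rows.append({
            "cell_line": cl, "drug": drug, "treat_time_h": tt,
            "top": fit.top, "bottom": fit.bottom, "ec50": fit.ec50,
            "hill": fit.hill, "ic50": _fmt(pot.ic50), "emax": pot.emax,
            "auc": pot.auc, "rss": fit.rss, "n_points": fit.n_points,
        })
        cond_summary = {
            "cell_line": cl, "drug": drug, "treat_time_h": tt,
            "ic50": _fmt(pot.ic50), "emax": _fmt(pot.emax), "auc": _fmt(pot.auc),
        }

        if has_reference:
            gs = normalize.build_gr_series(screen, cl, drug, tt, x0_scope=x0_scope)
            gfit = grm.fit_gr_curve(gs)
            gres = grm.gr_result(gs, gfit, grmax_variant)
            sf["gr_value"] = gs.means
            gr_rows.append({
                "cell_line": cl, "drug": drug, "treat_time_h": tt,
                "gr_inf": gfit.gr_inf, "gec50": gfit.gec50, "h_gr": gfit.h_gr,
                "flat": gfit.flat, "gr50": _fmt(gres.gr50),
                "gr_max": gres.gr_max, "gr_aoc": gres.gr_aoc, "rss": gfit.rss,
            })
            cond_summary.update({
                "gr50": _fmt(gres.gr50), "gr_max": _fmt(gres.gr_max),
                "gr_aoc": _fmt(gres.gr_aoc),
            })
        series_frames.append(sf)
        summary["conditions"].append(cond_summary)

    report = qc.qc_report(screen, replicate_corrected=sw_replicate_corrected)
    summary["qc"] = {
        "n_rows": int(len(report.table)),
        "all_pass": report.all_pass(),
        "pass_fraction": _fmt(
            report.table[["pass_z", "pass_sw", "pass_cv"]].all(axis=1).mean()
        ) if not report.table.empty else None,
        "warnings": report.warnings,
    }

    # variance components on treated-well viability
    var_df = pd.DataFrame()
    treated = screen.data[screen.data["role"] == WellRole.TREATED.value]
    if not treated.empty:
        # per-replicate long table for the per-covariate ANOVAs
        rep_rows = []
        for _, cond in conditions.iterrows():
            cl, drug, tt = cond["cell_line"], cond["drug"], float(cond["treat_time_h"])
            vs = normalize.build_series(screen, cl, drug, tt)
            for p in vs.points:
                for v in p.values:
                    rep_rows.append({"cell_line": cl, "drug": drug,
                                     "treat_time_h": tt, "conc": p.concentration,
                                     "viability_pct": v})
        rep_df = pd.DataFrame(rep_rows)
        covs = [c for c in (covariates or DEFAULT_COVARIATES) if c in rep_df.columns]
        covs = [c for c in covs if rep_df[c].nunique() > 1]
        if covs and len(rep_df) > 3:
            var_df = stats.variance_table(rep_df, covs)
    summary["variance"] = var_df.to_dict(orient="records") if not var_df.empty else []

    return {
        "series": pd.concat(series_frames, ignore_index=True) if series_frames else pd.DataFrame(),
        "dose_response": pd.DataFrame(dr_rows),
        "gr_metrics": pd.DataFrame(gr_rows),
        "qc": report.table,
        "qc_warnings": report.warnings,
        "variance": var_df,
        "summary": summary,
    }


def render_report(results: dict[str, Any], out_dir) -> list[str]:
    """Render the three standard figures (dose-response curves, QC scatter
    with cutoff lines, variance bars with the -log10(0.05) line) as PNGs.
    Returns the written paths; empty tables are skipped with a note."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    series = results["series"]
    if not series.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        for (cl, drug), grp in series.groupby(["cell_line", "drug"]):
            grp = grp.sort_values("conc")
            ax.errorbar(grp["conc"], grp["viability_pct"], yerr=grp["sem"],
                        marker="o", capsize=3, label=f"{cl} / {drug}")
        ax.set_xscale("log")
        ax.axhline(50, ls=":", c="red")
        ax.set_xlabel(f"concentration ({series['conc_unit'].iloc[0]})")
        ax.set_ylabel("viability (%)")
        ax.legend(fontsize=7)
        p = out / "dose_response.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))

    qc_t = results["qc"]
    if not qc_t.empty:
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
        for ax, metric, cutoff in zip(
                axes, ["cv", "sw", "z"], [qc.CV_CUTOFF, qc.SW_CUTOFF, qc.Z_CUTOFF]):
            vals = qc_t[metric].replace([np.inf], np.nan).dropna()
            ax.scatter(range(len(vals)), vals, s=12)
            ax.axhline(cutoff, ls=":", c="red")
            ax.set_title(metric.upper())
            ax.set_xlabel("plate/condition")
        p = out / "qc_metrics.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))

    var_t = results["variance"]
    if not var_t.empty:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        finite = var_t["neglog10_p"].replace([np.inf], 300.0)
        ax.bar(var_t["covariate"], finite)
        ax.axhline(-np.log10(stats.SIGNIFICANCE), ls=":", c="red")
        ax.set_ylabel("-log10 p")
        ax.tick_params(axis="x", rotation=45)
        p = out / "variance_components.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))

    return written
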