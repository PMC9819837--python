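"""Staged analysis runner: base case, DSA, PSA and synthetic cohort.

Each stage writes plain CSV tables (and PNG figures where a figure is the
natural product) into the output directory, and every run leaves a
``manifest.json`` recording the configuration digest, seed, convention
flags and per-stage timing — enough to reproduce any output bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__
from .cea import TwoArmResult, decision_at_wtp
from .config import AnalysisConfig
from .dsa import run_dsa, tornado
from .ipd import generate_cohort, summarize_costs, summarize_counts
from .conversions import monthly_transition_probabilities
from .psa import PSAResult, ceac, classify_ice, run_psa

__all__ = ["STAGES", "run_analysis"]

STAGES = ("base", "dsa", "psa", "synth")
log = logging.getLogger("markovcea")


def _base_case_table(res: TwoArmResult, wtp: float) -> pd.DataFrame:
    rows = []
    for r in (res.comparator, res.intervention):
        rows.append(
            {
                "strategy": r.name,
                "total_cost": r.total_cost,
                "cost_pfs": r.cost_pfs,
                "cost_pd": r.cost_pd,
                "life_years": r.life_years,
                "life_years_undiscounted": r.life_years_undiscounted,
                "qalys": r.qalys,
            }
        )
    cea = res.cea
    decision, nmb = decision_at_wtp(cea, wtp)
    rows.append(
        {
            "strategy": f"{cea.intervention} vs {cea.comparator}",
            "total_cost": cea.delta_cost,
            "cost_pfs": res.intervention.cost_pfs - res.comparator.cost_pfs,
            "cost_pd": res.intervention.cost_pd - res.comparator.cost_pd,
            "life_years": cea.delta_ly,
            "life_years_undiscounted": (
                res.intervention.life_years_undiscounted - res.comparator.life_years_undiscounted
            ),
            "qalys": cea.delta_qaly,
            "icer": cea.icer,
            "icur": cea.icur,
            "verdict": cea.verdict(),
            "nmb_at_wtp": nmb,
            "decision_at_wtp": decision,
        }
    )
    return pd.DataFrame(rows)


def _plot_ice(result: PSAResult, wtp: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    dq = result.draws["delta_qaly"]
    dc = result.draws["delta_cost"]
    favor = (dc <= 0) & (dq >= 0) | ((dq > 0) & (dc > 0))
    ax.scatter(dq[favor], dc[favor], s=2, c="seagreen", label="favors intervention")
    ax.scatter(dq[~favor], dc[~favor], s=2, c="firebrick", label="other")
    lim = max(abs(dq.min()), abs(dq.max()))
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP = {wtp:,.0f} QAR/QALY")
    ax.axhline(0, c="grey", lw=0.5)
    ax.axvline(0, c="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (QAR)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_ceac(curve: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["p_cost_effective"])
    ax.set_xlabel("Willingness to pay (QAR/QALY)")
    ax.set_ylabel("P(intervention cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_tornado(table: pd.DataFrame, base_nmb: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(table) + 1.5))
    order = table.iloc[::-1]
    y = np.arange(len(order))
    left = np.minimum(order["nmb_lower"], order["nmb_upper"])
    width = (order["nmb_upper"] - order["nmb_lower"]).abs()
    ax.barh(y, width, left=left, color="steelblue")
    ax.axvline(base_nmb, c="k", lw=1, label="base case")
    ax.set_yticks(y, order["parameter"])
    ax.set_xlabel("Incremental net monetary benefit (QAR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_analysis(
    cfg: AnalysisConfig,
    stages: tuple[str, ...] = ("base",),
    out_dir: str | Path = "results",
    seed: int | None = None,
    psa_n: int | None = None,
) -> dict:
    """Execute the requested stages and write their reports.

    Returns a manifest dict (also written to ``manifest.json``) mapping
    each executed stage to its outputs and timing.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid stages are {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    model = cfg.two_arm_model()
    wtp = model.config.wtp_cost_effective
    manifest: dict = {
        "package_version": __version__,
        "config_name": cfg.name,
        "config_digest": cfg.digest(),
        "seed": seed,
        "conventions": {
            "correction": model.config.correction.value,
            "discount_timing": model.config.discount_timing.value,
            "discount_life_years": model.config.discount_life_years,
            "annual_discount_rate": model.config.annual_discount_rate,
            "horizon_cycles": model.config.horizon_cycles,
        },
        "stages": {},
    }

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        files: list[str] = []

        if stage == "base":
            res = model.run()
            _base_case_table(res, wtp).to_csv(out / "base_case.csv", index=False)
            from .model import build_transition_matrix, run_cohort_trace

            for arm_name, arm in (("intervention", model.intervention), ("comparator", model.comparator)):
                trace = run_cohort_trace(build_transition_matrix(arm), model.config)
                trace.to_frame().to_csv(out / f"trace_{arm.name}.csv", index=False)
                files.append(f"trace_{arm.name}.csv")
            files.insert(0, "base_case.csv")

        elif stage == "dsa":
            rows = run_dsa(cfg.dsa_specs(), model)
            flat = pd.DataFrame([r.as_dict() for pair in rows for r in pair])
            flat.to_csv(out / "dsa_rows.csv", index=False)
            torn = tornado(rows, wtp)
            torn.to_csv(out / "tornado.csv", index=False)
            _plot_tornado(torn, model.run().cea.nmb(wtp), out / "tornado.png")
            files += ["dsa_rows.csv", "tornado.csv", "tornado.png"]

        elif stage == "psa":
            n = cfg.psa_draws if psa_n is None else psa_n
            result = run_psa(model, cfg.psa_distributions(), n=n, seed=seed)
            ice = classify_ice(result, wtp)
            draws = result.draws.copy()
            draws.to_csv(out / "psa_draws.csv", index=False)
            grid = np.linspace(0, 2 * wtp, 81)
            curve = ceac(result, grid)
            curve.to_csv(out / "ceac.csv", index=False)
            with open(out / "psa_summary.json", "w") as fh:
                json.dump(
                    {
                        "n": result.n,
                        "n_redraws": result.n_redraws,
                        "wtp": wtp,
                        "dominant": ice.dominant,
                        "ne_below_wtp": ice.ne_below_wtp,
                        "ne_above_wtp": ice.ne_above_wtp,
                        "sw": ice.sw,
                        "dominated": ice.dominated,
                        "favoring_quadrant": ice.favoring_quadrant,
                        "favoring_below_wtp": ice.favoring_below_wtp,
                        "mean_cost_intervention": float(draws["cost_intervention"].mean()),
                        "mean_cost_comparator": float(draws["cost_comparator"].mean()),
                        "mean_qaly_intervention": float(draws["qaly_intervention"].mean()),
                        "mean_qaly_comparator": float(draws["qaly_comparator"].mean()),
                    },
                    fh,
                    indent=2,
                )
            _plot_ice(result, wtp, out / "ice_plane.png")
            _plot_ceac(curve, out / "ceac.png")
            files += ["psa_draws.csv", "ceac.csv", "psa_summary.json", "ice_plane.png", "ceac.png"]

        elif stage == "synth":
            cohort = generate_cohort(cfg.synthetic_parameters(seed))
            cohort.patients.to_csv(out / "synthetic_patients.csv", index=False)
            cohort.costs.to_csv(out / "synthetic_costs.csv", index=False)
            counts = summarize_counts(cohort)
            probs = monthly_transition_probabilities(counts)
            means = summarize_costs(cohort)
            with open(out / "synthetic_summary.json", "w") as fh:
                json.dump(
                    {
                        "n_total": counts.n_total,
                        "n_pfs_to_pd": counts.n_pfs_to_pd,
                        "n_pfs_to_death": counts.n_pfs_to_death,
                        "n_pd_to_death": counts.n_pd_to_death,
                        "n_at_risk_pd": counts.n_at_risk_pd,
                        "followup_years": counts.followup_years,
                        "p_pfs_to_pd_monthly": probs.p_pfs_to_pd,
                        "p_pfs_to_death_monthly": probs.p_pfs_to_death,
                        "p_pd_to_death_monthly": probs.p_pd_to_death,
                        "mean_monthly_cost": means,
                    },
                    fh,
                    indent=2,
                )
            files += ["synthetic_patients.csv", "synthetic_costs.csv", "synthetic_summary.json"]

        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {"files": files, "seconds": round(elapsed, 3)}
        log.info("stage=%s seconds=%.3f digest=%s files=%s", stage, elapsed, cfg.digest(), files)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
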