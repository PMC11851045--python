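"""Study orchestration: the model-selection cascade and the full report run.

The cascade mirrors standard spatial-panel practice.  Starting from a
two-way within regression it asks, in order:

1. *Is there a spatial effect at all?*  LM-lag / LM-error battery (with
   robust variants) on the within-OLS residuals.  If nothing is
   significant the within regression is kept.
2. *Can the SDM be reduced?*  Fit the SDM, then Wald and LR tests of the
   theta = 0 (to SAR) and common-factor (to SEM) restrictions.  The SDM is
   kept unless BOTH the Wald and the LR test for a given reduction fail to
   reject; if both reductions qualify, the one with the higher restricted
   log-likelihood wins.
3. *Fixed or random effects?*  Hausman comparison on the selected model's
   slope coefficients.
4. *Which fixed effects?*  LR tests of two-way effects against space-only
   and time-only restrictions.

Every decision is recorded in a :class:`SelectionTrace` whose final spec is
reachable from the recorded decisions.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .moran import classify_clusters, global_moran, local_moran
from .panel import (
    PanelData,
    PanelFit,
    TestResult,
    decompose_effects,
    fit_panel_ols,
    fit_spatial_panel,
    hausman_test,
    lm_spatial_tests,
    lr_test,
    vif,
    wald_reduction_tests,
)
from .temporal import annual_summary, dbi_to_pbi
from .weights import SpatialWeights, read_edge_csv, read_gal, build_rook_from_edges, RegionSet

logger = logging.getLogger("sppanel")

__all__ = ["SelectionTrace", "run_selection_cascade", "run_study", "load_config"]


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)
    final_model: str | None = None
    final_effects: str | None = None

    def record(self, test: TestResult, decision: str) -> None:
        self.steps.append(
            {
                "test": test.name,
                "statistic": test.statistic,
                "df": test.df,
                "p": test.p,
                "decision": decision,
            }
        )

    def note(self, name: str, decision: str) -> None:
        self.steps.append({"test": name, "statistic": None, "df": None,
                           "p": None, "decision": decision})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def run_selection_cascade(
    panel: PanelData,
    w: SpatialWeights,
    alpha: float = 0.1,
) -> tuple[SelectionTrace, PanelFit]:
    """Execute the model-selection cascade; returns the trace and the
    selected fit."""
    trace = SelectionTrace()

    ols = fit_panel_ols(panel, effects="both")
    lm = lm_spatial_tests(ols, w, alpha=alpha)
    any_spatial = any(t.reject for t in lm.values())
    for t in lm.values():
        trace.record(t, "spatial effect" if t.reject else "no spatial effect")
    if not any_spatial:
        trace.note("LM battery", "no spatial effect detected; keeping within-OLS")
        trace.final_model, trace.final_effects = "OLS", "both"
        return trace, ols

    sdm = fit_spatial_panel(panel, w, model="SDM", effects="both")
    sar = fit_spatial_panel(panel, w, model="SAR", effects="both")
    sem = fit_spatial_panel(panel, w, model="SEM", effects="both")
    k = panel.k

    wald = wald_reduction_tests(sdm, alpha=alpha)
    lr_sar = lr_test(sar, sdm, df=k, name="LR SDM->SAR", alpha=alpha)
    lr_sem = lr_test(sem, sdm, df=k, name="LR SDM->SEM", alpha=alpha)
    for t in (wald["Wald SDM->SAR"], lr_sar):
        trace.record(t, "SDM not reducible to SAR" if t.reject else "SAR reduction allowed")
    for t in (wald["Wald SDM->SEM"], lr_sem):
        trace.record(t, "SDM not reducible to SEM" if t.reject else "SEM reduction allowed")

    # keep SDM unless BOTH tests of a reduction fail to reject
    to_sar = not wald["Wald SDM->SAR"].reject and not lr_sar.reject
    to_sem = not wald["Wald SDM->SEM"].reject and not lr_sem.reject
    if to_sar and to_sem:
        model = "SAR" if sar.loglik >= sem.loglik else "SEM"
        trace.note("reduction", f"both reductions admissible; {model} has higher loglik")
    elif to_sar:
        model = "SAR"
        trace.note("reduction", "reduced to SAR")
    elif to_sem:
        model = "SEM"
        trace.note("reduction", "reduced to SEM")
    else:
        model = "SDM"
        trace.note("reduction", "SDM retained")

    # Hausman FE vs RE (RE-SEM is unsupported; compare on SDM instead)
    haus_model = model if model != "SEM" else "SDM"
    fe_fit = {"SDM": sdm, "SAR": sar, "SEM": sem}[haus_model]
    try:
        re_fit = fit_spatial_panel(panel, w, model=haus_model, effects="random")
        haus = hausman_test(fe_fit, re_fit, alpha=alpha)
        use_fe = haus.reject
        trace.record(haus, "fixed effects" if use_fe else "random effects")
        if haus_model != model:
            trace.note("Hausman basis", f"run on {haus_model} (RE-{model} unsupported)")
    except Exception as exc:  # RE optimization genuinely fragile on some draws
        logger.warning("RE fit failed (%s); defaulting to fixed effects", exc)
        use_fe = True
        trace.note("Hausman", f"RE fit failed ({exc}); fixed effects retained")

    if not use_fe:
        final = fit_spatial_panel(panel, w, model=haus_model, effects="random")
        trace.final_model, trace.final_effects = haus_model, "random"
        return trace, final

    # LR tests for the fixed-effects structure
    both = {"SDM": sdm, "SAR": sar, "SEM": sem}[model]
    space = fit_spatial_panel(panel, w, model=model, effects="space")
    time_ = fit_spatial_panel(panel, w, model=model, effects="time")
    lr_bs = lr_test(space, both, df=panel.T, name="LR both vs space", alpha=alpha)
    lr_bt = lr_test(time_, both, df=panel.n, name="LR both vs time", alpha=alpha)
    trace.record(lr_bs, "time effects needed" if lr_bs.reject else "time effects dropped")
    trace.record(lr_bt, "space effects needed" if lr_bt.reject else "space effects dropped")
    if lr_bs.reject and lr_bt.reject:
        effects = "both"
    elif lr_bs.reject:
        effects = "time"
    elif lr_bt.reject:
        effects = "space"
    else:
        effects = "both"  # conservative: keep both if tests are uninformative
        trace.note("effects", "neither LR rejected; two-way effects retained conservatively")
    final = {"both": both, "space": space, "time": time_}[effects]
    trace.final_model, trace.final_effects = model, effects
    return trace, final


# ---------------------------------------------------------------------------
# Full study run
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "alpha": 0.1,
    "lisa_alpha": 0.05,
    "n_perm": 999,
    "n_draws": 1000,
    "seed": None,
    "y_col": "pbi",
    "population_col": None,
    "dbi_col": "dbi",
}


def load_config(path: str | Path) -> dict:
    cfg = dict(_DEFAULTS)
    cfg.update(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})
    return cfg


def _load_weights(cfg: dict) -> SpatialWeights:
    if "weights_gal" in cfg:
        return read_gal(cfg["weights_gal"])
    if "weights_edges" in cfg:
        edges = read_edge_csv(cfg["weights_edges"])
        ids = sorted({x for e in edges for x in e})
        return build_rook_from_edges(edges, RegionSet(tuple(ids)))
    raise ValueError("config must name weights_gal or weights_edges")


def run_study(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline from a config mapping (or YAML path) and write
    the result tables; returns them in-memory keyed by table name.

    Tables: global Moran per year; significant LISA clusters per year; the
    selected model's coefficient and effect decomposition; the test battery;
    VIF; and the temporal concentration summary.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(_DEFAULTS)
    cfg.update(config)
    missing = [key for key in ("panel_csv",) if key not in cfg]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    if cfg["seed"] is None:
        raise ValueError("config must set a seed for reproducible permutation inference")
    out_dir = Path(out_dir or cfg.get("out_dir", "sppanel_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    alpha = float(cfg["alpha"])

    w = _load_weights(cfg)
    df = pd.read_csv(cfg["panel_csv"])
    if cfg["population_col"]:
        df[cfg["y_col"]] = dbi_to_pbi(
            df[cfg["dbi_col"]], df[cfg["population_col"]]
        ).to_numpy()
    x_cols = cfg.get("x_cols")
    panel = PanelData.from_long(df, y_col=cfg["y_col"], x_cols=x_cols)
    if panel.unit_ids != w.regions.ids:
        raise ValueError("panel units and weight regions disagree")

    tables: dict[str, pd.DataFrame] = {}

    # temporal concentration (optional monthly input)
    if cfg.get("monthly_csv"):
        monthly = pd.read_csv(cfg["monthly_csv"])
        tables["concentration"] = annual_summary(monthly)

    # per-year global Moran + LISA clusters
    rng = np.random.default_rng(seed)
    moran_rows, lisa_frames = [], []
    for t, yr in enumerate(panel.times):
        x = panel.y[:, t]
        sub = int(rng.integers(0, 2**31 - 1))
        res = global_moran(x, w, inference="permutation",
                           n_perm=int(cfg["n_perm"]), seed=sub)
        moran_rows.append(
            {"year": yr, "I": res.I, "z": res.z,
             "p_analytic": res.p_analytic, "p_perm": res.p_perm}
        )
        lisa = local_moran(x, w, n_perm=int(cfg["n_perm"]), seed=sub,
                           alpha=float(cfg["lisa_alpha"]))
        tab = classify_clusters(lisa)
        tab.insert(0, "year", yr)
        lisa_frames.append(tab[tab["significant"]])
    tables["global_moran"] = pd.DataFrame(moran_rows)
    tables["lisa_clusters"] = (
        pd.concat(lisa_frames, ignore_index=True)
        if lisa_frames else pd.DataFrame()
    )

    # VIF diagnostics on the pooled covariates
    tables["vif"] = vif(panel.X.reshape(-1, panel.k), list(panel.x_names))

    # model-selection cascade and final fit
    trace, fit = run_selection_cascade(panel, w, alpha=alpha)
    tables["test_battery"] = trace.to_frame()
    coef = fit.summary().reset_index(names="parameter")
    coef.insert(0, "block", [
        "Wx" if p.startswith("W_") else ("spatial" if p in ("rho", "lambda") else "Main")
        for p in coef["parameter"]
    ])
    tables["model"] = coef

    if fit.model in ("SAR", "SDM"):
        eff = decompose_effects(fit, w, n_draws=int(cfg["n_draws"]),
                                seed=int(rng.integers(0, 2**31 - 1)))
        tables["effects"] = eff.to_frame()

    for name, tab in tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False)
    run_log = {
        "version": __version__,
        "seed": seed,
        "alpha": alpha,
        "final_model": trace.final_model,
        "final_effects": trace.final_effects,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": sys.version.split()[0],
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")
    logger.info("run_study wrote %d tables to %s", len(tables), out_dir)
    return tables
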