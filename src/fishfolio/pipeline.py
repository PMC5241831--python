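"""End-to-end pipeline: ingest -> filters -> DFA -> metrics -> regressions.

``run_all`` sequences the whole analysis from a single config: load and
deflate landings, apply the community and stock completeness filters, fit
the catch-panel DFA (with AIC model selection), fit the revenue-panel DFA,
correlate the extracted revenue trends with the common catch trend and the
salmon price series, compute per-community diversity and turnover, and fit
the regime-response regressions.  Every stage writes its intermediate CSV
under the output directory and the headline quantities land in
``summary.json``; a plain-text run log records versions, the config echo and
a config hash.  ``make_figures`` re-renders the figures purely from those
saved CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dfa, ingest, metrics, regime

logger = logging.getLogger("fishfolio")

_FLOAT_DIGITS = 12  # significant digits for serialized floats

#: fixed per-stage offsets fanned out from the global seed, so each stage is
#: independently reproducible
STAGE_SEED_OFFSETS = {"simulate": 0, "dfa_catch": 101, "dfa_revenue": 202}


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    landings: str
    cpi: str
    out_dir: str
    price_series: str | None = None  # CSV: year, price (salmon ex-vessel $/lb)
    pre: tuple = (1980, 1989)
    post: tuple = (1990, 1999)
    base_year: int = ingest.DEFAULT_BASE_YEAR
    max_zero_years: int = 3
    exclude_taxa: tuple = ()
    trend_candidates: tuple = (1, 2)
    r_structures: tuple = ("diagonal_equal", "diagonal_unequal")
    jaccard_variant: str = "ruzicka"
    weighting: str = "weighted"
    rotate: bool = True
    log_level: str = "INFO"
    seed: int = 0
    schema: dict | None = None

    def __post_init__(self) -> None:
        pre, post = tuple(self.pre), tuple(self.post)
        if pre[0] > pre[1] or post[0] > post[1]:
            raise ValueError("windows must be ordered (start, end)")
        if pre[1] >= post[0]:
            raise ValueError("pre and post windows must be non-overlapping and ordered")
        self.pre, self.post = pre, post

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("pre", "post", "exclude_taxa", "trend_candidates", "r_structures"):
            d[k] = list(d[k])
        return d


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{_FLOAT_DIGITS}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


REQUIRED_SUMMARY_KEYS = (
    "n_communities",
    "n_stocks",
    "catch_dfa",
    "revenue_dfa",
    "trend_correlations",
    "n_communities_revenue_declined",
    "share_communities_revenue_declined",
    "statewide_pct_change_pounds",
    "statewide_pct_change_revenue",
    "share_negative_catch_loadings",
    "loglinear",
    "interaction",
    "catch_price_product",
)


def validate_summary(summary: dict) -> None:
    missing = [k for k in REQUIRED_SUMMARY_KEYS if k not in summary]
    if missing:
        raise ValueError(f"summary is missing keys: {missing}")


def _fit_panel_dfa(panel: ingest.Panel, config: RunConfig):
    z = dfa.zscore(panel)
    candidates = [
        dfa.DFAModelSpec(m=m, r_structure=r)
        for m in config.trend_candidates
        for r in config.r_structures
    ]
    best, table = dfa.select_model(z, candidates)
    reported = dfa.rotate_and_align(best, rotate=config.rotate)
    return z, best, reported, table


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    stage = "configure"
    try:
        logger.info("starting run; output -> %s", out)
        years = list(range(config.pre[0], config.post[1] + 1))

        stage = "ingest"
        records = ingest.load_landings(config.landings, schema=config.schema)
        cpi = ingest.load_cpi(config.cpi)
        records = ingest.deflate(records, cpi, base_year=config.base_year)
        logger.info("loaded %d landings records", len(records))

        stage = "filters"
        communities = ingest.filter_communities(records, config.pre[0], config.post[1])
        stocks = ingest.filter_stocks(
            records, config.max_zero_years, config.pre[0], config.post[1]
        )
        logger.info("kept %d communities, %d stocks", len(communities), len(stocks))

        stage = "panels"
        kept = records[records["community"].isin(communities)]
        catch_panel = ingest.build_panel(
            records, "stock", "pounds", years, entity_ids=stocks,
            exclude_taxa=config.exclude_taxa or None,
        )
        revenue_panel = ingest.build_panel(
            kept, "community", "revenue_real", years,
            exclude_taxa=config.exclude_taxa or None,
        )
        catch_panel.to_csv(out / "catch_panel.csv")
        revenue_panel.to_csv(out / "revenue_panel.csv")

        stage = "dfa_catch"
        _, best_c, rep_c, table_c = _fit_panel_dfa(catch_panel, config)
        table_c.to_csv(out / "catch_model_selection.csv", index=False)
        _write_fit(out, "catch", rep_c, catch_panel)

        stage = "dfa_revenue"
        _, best_r, rep_r, table_r = _fit_panel_dfa(revenue_panel, config)
        table_r.to_csv(out / "revenue_model_selection.csv", index=False)
        _write_fit(out, "revenue", rep_r, revenue_panel)

        stage = "correlations"
        catch_trend = rep_c.states[0]
        corrs = {}
        for j in range(rep_r.m):
            corrs[f"revenue_trend_{j + 1}_vs_catch_trend"] = dfa.trend_covariate_corr(
                rep_r.states[j], catch_trend
            )
        if config.price_series:
            price = pd.read_csv(config.price_series)
            price = price.set_index(price.columns[0]).iloc[:, 0].reindex(years)
            if price.notna().all():
                for j in range(rep_r.m):
                    corrs[f"revenue_trend_{j + 1}_vs_salmon_price"] = (
                        dfa.trend_covariate_corr(rep_r.states[j], price.to_numpy())
                    )

        stage = "responses"
        pre = range(config.pre[0], config.pre[1] + 1)
        post = range(config.post[0], config.post[1] + 1)
        responses = regime.build_responses(
            kept, pre, post, communities=communities,
            jaccard_variant=config.jaccard_variant, weighting=config.weighting,
        )
        responses.to_csv(out / "responses.csv", index=False)

        stage = "regressions"
        loglin = regime.fit_loglinear(responses)
        inter, surface = regime.fit_interaction(responses)
        surface.to_csv(out / "interaction_surface.csv", index=False)
        valid = responses.dropna(subset=["pct_change_catch"])
        try:
            cpp = regime.fit_catch_price_product(
                valid["pct_change_revenue"], valid["pct_change_catch"],
                _price_pct_change(config, pre, post),
            ).to_dict()
        except ValueError as exc:
            logger.warning("catch/price/product regression skipped: %s", exc)
            cpp = {"skipped": str(exc)}

        stage = "summary"
        statewide_rev = kept.groupby("year")["revenue_real"].sum()
        statewide_lbs = records.groupby("year")["pounds"].sum()
        declined = int((responses["pct_change_revenue"] < 0).sum())
        summary = {
            "n_communities": len(communities),
            "n_stocks": len(stocks),
            "catch_dfa": _fit_summary(best_c),
            "revenue_dfa": _fit_summary(best_r),
            "trend_correlations": corrs,
            "n_communities_revenue_declined": declined,
            "share_communities_revenue_declined": declined / max(len(responses), 1),
            "statewide_pct_change_pounds": regime.percent_change(
                statewide_lbs.reindex(pre).to_numpy(), statewide_lbs.reindex(post).to_numpy()
            ),
            "statewide_pct_change_revenue": regime.percent_change(
                statewide_rev.reindex(pre).to_numpy(), statewide_rev.reindex(post).to_numpy()
            ),
            "share_negative_catch_loadings": float((rep_c.Z[:, 0] < 0).mean()),
            "loglinear": loglin.to_dict(),
            "interaction": inter.to_dict(),
            "catch_price_product": cpp,
            "config_hash": _config_hash(config),
        }
        summary = _round_floats(summary)
        validate_summary(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("run complete")
        return summary
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _price_pct_change(config: RunConfig, pre, post) -> float:
    if not config.price_series:
        raise ValueError("no price series configured")
    price = pd.read_csv(config.price_series)
    price = price.set_index(price.columns[0]).iloc[:, 0]
    return regime.percent_change(
        price.reindex(list(pre)).to_numpy(), price.reindex(list(post)).to_numpy()
    )


def _fit_summary(fit: dfa.DFAFit) -> dict:
    return {
        "m": fit.m,
        "r_structure": fit.spec.r_structure,
        "logL": fit.logL,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "converged": bool(fit.converged),
        "iterations": fit.iterations,
    }


def _write_fit(out: Path, label: str, fit: dfa.DFAFit, panel: ingest.Panel) -> None:
    pd.DataFrame(
        fit.Z, index=panel.entity_ids,
        columns=[f"trend_{j + 1}" for j in range(fit.m)],
    ).to_csv(out / f"{label}_loadings.csv")
    pd.DataFrame(
        fit.states.T, index=panel.years,
        columns=[f"trend_{j + 1}" for j in range(fit.m)],
    ).rename_axis("year").to_csv(out / f"{label}_trends.csv")


def _config_hash(config: RunConfig) -> str:
    # out_dir and log level do not affect the science; reruns of the same
    # analysis into different directories must hash identically
    d = config.to_dict()
    d.pop("out_dir", None)
    d.pop("log_level", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(out: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        h.setFormatter(fmt)
        logger.addHandler(h)
    import fishfolio

    logger.info(
        "fishfolio %s | numpy %s | pandas %s",
        getattr(fishfolio, "__version__", "?"), np.__version__, pd.__version__,
    )


# ---------------------------------------------------------------------------
# figures (re-renderable from the saved CSVs alone)


def make_figures(out_dir, fig_dir=None) -> list:
    """Render the standard figures from a completed run's CSV outputs.

    Produces: the shared catch trend with two example standardized series,
    the loading histogram, percent revenue change vs log diversity with the
    fitted line and 95% CI band, and the diversity x turnover prediction
    surface.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    figs = Path(fig_dir) if fig_dir else out / "figures"
    figs.mkdir(parents=True, exist_ok=True)
    written = []

    def _need(name):
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"required run output missing: {p}")
        return p

    trends = pd.read_csv(_need("catch_trends.csv"), index_col="year")
    panel = pd.read_csv(_need("catch_panel.csv"), index_col=0)
    loadings = pd.read_csv(_need("catch_loadings.csv"), index_col=0)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trends.index, trends["trend_1"], lw=2, label="shared catch trend")
    vals = panel.to_numpy(float)
    zs = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    order = np.argsort(-np.abs(loadings["trend_1"].to_numpy()))[:2]
    for i in order:
        ax.plot(trends.index, zs[i], "o", ms=3, alpha=0.5, label=panel.index[i])
    ax.axvline(1989, ls="--", c="k", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("standardized catch")
    ax.legend(fontsize=7)
    p = figs / "catch_trend.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(loadings["trend_1"], bins=15, edgecolor="k")
    ax.axvline(0, c="k", lw=0.8)
    ax.set_xlabel("factor loading")
    ax.set_ylabel("count")
    p = figs / "loading_histogram.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    responses = pd.read_csv(_need("responses.csv"))
    with open(_need("summary.json")) as fh:
        summary = json.load(fh)
    ll = summary["loglinear"]["coefficients"]
    fig, ax = plt.subplots(figsize=(5, 4))
    x = responses["diversity"].to_numpy(float)
    y = responses["pct_change_revenue"].to_numpy(float)
    ax.scatter(x, y, s=14, alpha=0.7)
    xx = np.linspace(x.min(), x.max(), 200)
    yy = ll["const"] + ll["log_diversity"] * np.log(xx)
    ax.plot(xx, yy, "k-", lw=2)
    lo, hi = summary["loglinear"]["conf_int"]["log_diversity"]
    ax.fill_between(
        xx,
        ll["const"] + lo * np.log(xx),
        ll["const"] + hi * np.log(xx),
        color="k", alpha=0.15,
    )
    ax.set_xscale("log")
    ax.set_xlabel("diversity (reciprocal Simpson, log scale)")
    ax.set_ylabel("% change in revenue")
    p = figs / "diversity_response.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    surf = pd.read_csv(_need("interaction_surface.csv"))
    if len(surf):
        dcol, tcol = surf.columns[0], surf.columns[1]
        nd = surf[dcol].nunique()
        fig = plt.figure(figsize=(5.5, 4.5))
        ax = fig.add_subplot(projection="3d")
        ax.plot_surface(
            surf[dcol].to_numpy().reshape(-1, nd),
            surf[tcol].to_numpy().reshape(-1, nd),
            surf["predicted_pct_change"].to_numpy().reshape(-1, nd),
            cmap="viridis", alpha=0.9,
        )
        ax.set_xlabel("diversity")
        ax.set_ylabel("turnover")
        ax.set_zlabel("% change in revenue")
        p = figs / "interaction_surface.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

    return written
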