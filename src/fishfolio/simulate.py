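"""Synthetic CFEC-style landings with known latent structure.

Two generators, both seeded and fully reproducible:

``gen_dfa_panel``
    A bare multivariate random-walk factor panel (shared latent trends, known
    loadings, Gaussian observation noise) for exercising the DFA estimator
    with ground truth in hand.

``gen_regime_scenario``
    A full community landings scenario: fishery-level catches driven by
    shared latent trends with a level shift at the regime year, ex-vessel
    prices with an abrupt post-regime decline for a salmon-like subset of
    fisheries, and community portfolios drawn from Dirichlet distributions
    whose concentration sweeps from single-fishery specialists to broadly
    diversified generalists.  Low-diversity communities are biased toward the
    salmon-like fisheries, mirroring the geography of remote, salmon-dependent
    villages; that coupling is what creates a mean diversity-resilience
    gradient rather than a pure variance effect.

Catches are kept positive through an exponential link of the latent trend;
the estimator itself works on z-scores, so the link is purely a generator
choice.  The ecosystem shift (a step in the latent trends) and the market
shift (the price drop) are switchable independently.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import DEFAULT_BASE_YEAR, Panel


@dataclasses.dataclass
class ScenarioConfig:
    """Knobs of the synthetic study system.

    Defaults mirror the real study's dimensions: ~105 communities holding
    permits across ~60 fisheries over 1980-1999, a regime shift after 1989,
    unit process error, and a halving of salmon-like ex-vessel prices.
    """

    n_communities: int = 105
    n_fisheries: int = 60
    years: tuple = (1980, 1999)
    n_trends: int = 1
    regime_year: int = 1989
    trend_step_sd: float = 2.0
    process_sd: float = 1.0
    obs_sd: float | Sequence[float] = 0.5
    diversity_concentration_range: tuple = (0.02, 100.0)
    price_drop_factor: float = 0.5
    salmon_fraction: float = 0.3
    specialist_salmon_bias: float = 16.0
    catch_loading_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trends < 1:
            raise ValueError("n_trends must be >= 1")
        if self.process_sd <= 0 or np.any(np.asarray(self.obs_sd) < 0):
            raise ValueError("sds must be positive")
        if not (0 < self.price_drop_factor <= 1):
            raise ValueError("price_drop_factor must be in (0, 1]")
        lo, hi = self.years
        if hi < lo:
            raise ValueError("years must be an increasing (start, end) pair")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["diversity_concentration_range"] = list(self.diversity_concentration_range)
        if np.ndim(self.obs_sd) > 0:
            d["obs_sd"] = list(np.asarray(self.obs_sd, float))
        return d


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth latent quantities behind a generated panel/scenario."""

    trends: np.ndarray  # m x T latent random walks
    loadings: np.ndarray  # n x m
    community_shares: np.ndarray | None = None  # community x fishery proportions
    price_series: pd.DataFrame | None = None  # year x fishery prices
    true_diversity: np.ndarray | None = None  # per community
    salmon_like: np.ndarray | None = None  # boolean per fishery
    cpi: pd.Series | None = None  # annual CPI used to nominal-ize revenues

    def to_json(self, path) -> None:
        out = {
            "trends": self.trends.tolist(),
            "loadings": self.loadings.tolist(),
        }
        if self.community_shares is not None:
            out["community_shares"] = self.community_shares.tolist()
        if self.price_series is not None:
            out["price_series"] = {
                str(c): self.price_series[c].tolist() for c in self.price_series.columns
            }
            out["price_years"] = [int(y) for y in self.price_series.index]
        if self.true_diversity is not None:
            out["true_diversity"] = self.true_diversity.tolist()
        if self.salmon_like is not None:
            out["salmon_like"] = self.salmon_like.astype(bool).tolist()
        if self.cpi is not None:
            out["cpi"] = {str(int(y)): float(v) for y, v in self.cpi.items()}
        with open(path, "w") as fh:
            json.dump(out, fh)


def _latent_trends(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """m x T random walks, x_0 = 0, plus a level step after the regime year."""
    m, T = config.n_trends, config.n_years
    steps = rng.normal(0.0, config.process_sd, size=(m, T))
    x = np.cumsum(steps, axis=1)
    if config.trend_step_sd > 0:
        post = config.year_list > config.regime_year
        if post.any():
            shift = rng.normal(0.0, config.trend_step_sd, size=m)
            x[:, post] += shift[:, None]
    return x


def gen_dfa_panel(
    config: ScenarioConfig, loadings: np.ndarray | None = None
) -> tuple[Panel, SyntheticTruth]:
    """Generate an n_fisheries x T factor panel y = Z x + noise.

    ``loadings`` overrides the random standard-normal Z (useful for
    noise-free limiting cases and two-trend separation designs).
    """
    rng = np.random.default_rng(config.seed)
    n, m, T = config.n_fisheries, config.n_trends, config.n_years
    x = _latent_trends(config, rng)
    Z = rng.standard_normal((n, m)) if loadings is None else np.asarray(loadings, float)
    if Z.shape != (n, m):
        raise ValueError(f"loadings must be {n} x {m}")
    obs_sd = np.broadcast_to(np.atleast_1d(np.asarray(config.obs_sd, float)), (n,))
    y = Z @ x + rng.standard_normal((n, T)) * obs_sd[:, None]
    panel = Panel(
        entity_ids=[f"series_{i:03d}" for i in range(n)],
        years=config.year_list,
        values=y,
        kind="catch",
    )
    return panel, SyntheticTruth(trends=x, loadings=Z)


def _fishery_names(config: ScenarioConfig, salmon_like: np.ndarray) -> list:
    names = []
    for f in range(config.n_fisheries):
        taxon = "salmon" if salmon_like[f] else f"finfish_{f:02d}"
        names.append((taxon, f"area_{f:02d}"))
    return names


def gen_regime_scenario(config: ScenarioConfig):
    """Generate community landings records plus the fishery catch panel.

    Returns
    -------
    (records, catch_panel, truth)
        ``records`` is a long-format landings DataFrame with the canonical
        columns plus ``revenue_real`` already implied by truth.cpi (nominal
        revenues are CPI-inflated from the real values, so deflating with
        ``truth.cpi`` recovers them).  ``catch_panel`` holds fishery pounds
        by year.  ``truth`` carries trends, loadings, shares, prices, CPI
        and per-community pre-period diversity.
    """
    rng = np.random.default_rng(config.seed)
    n_f, n_c, T = config.n_fisheries, config.n_communities, config.n_years
    years = config.year_list

    n_salmon = max(1, int(round(config.salmon_fraction * n_f)))
    salmon_like = np.zeros(n_f, dtype=bool)
    salmon_like[:n_salmon] = True

    x = _latent_trends(config, rng)
    # mild loadings keep exp(Z x) within a plausible dynamic range
    Z = rng.normal(0.0, config.catch_loading_sd, size=(n_f, config.n_trends))
    base_catch = np.exp(rng.normal(12.0, 1.0, size=n_f))  # pounds scale
    catch = base_catch[:, None] * np.exp(Z @ x)  # fishery x year

    base_price = np.exp(rng.normal(0.0, 0.5, size=n_f))  # $/lb around 1
    price = np.tile(base_price[:, None], (1, T)) * np.exp(
        rng.normal(0.0, 0.05, size=(n_f, T))
    )
    post = years > config.regime_year
    price[np.ix_(salmon_like, post)] *= config.price_drop_factor

    # diversity gradient: log-spaced Dirichlet concentration; the most
    # specialized communities are also the most salmon-dependent
    lo, hi = config.diversity_concentration_range
    alphas = np.geomspace(lo, hi, n_c)
    rank = np.linspace(0.0, 1.0, n_c)  # 0 = most specialist
    shares = np.empty((n_c, n_f))
    for c in range(n_c):
        w = np.ones(n_f)
        w[salmon_like] = 1.0 + (config.specialist_salmon_bias - 1.0) * (1.0 - rank[c])
        shares[c] = rng.dirichlet(alphas[c] * n_f * w / w.sum())

    # CPI: ~3% annual inflation anchored so the base year is a realistic index
    all_years = np.arange(min(years[0], DEFAULT_BASE_YEAR), max(years[-1], DEFAULT_BASE_YEAR) + 1)
    cpi = pd.Series(100.0 * 1.03 ** (all_years - all_years[0]), index=all_years)

    communities = [f"community_{c:03d}" for c in range(n_c)]
    names = _fishery_names(config, salmon_like)
    infl = (cpi.loc[years].to_numpy() / cpi.loc[DEFAULT_BASE_YEAR])  # nominal = real * infl

    pounds = shares[:, :, None] * catch[None, :, :]  # community x fishery x year
    revenue_real = pounds * price[None, :, :]
    rows = {
        "community": np.repeat(communities, n_f * T),
        "year": np.tile(np.repeat(years, 1), n_c * n_f),
        "taxon": np.tile(np.repeat([t for t, _ in names], T), n_c),
        "location": np.tile(np.repeat([l for _, l in names], T), n_c),
        "gear": "all",
        "pounds": pounds.reshape(-1),
        "revenue_nominal": (revenue_real * infl[None, None, :]).reshape(-1),
        "revenue_real": revenue_real.reshape(-1),
    }
    records = pd.DataFrame(rows)

    catch_panel = Panel(
        entity_ids=[f"{t}|{l}" for t, l in names],
        years=years,
        values=catch,
        kind="catch",
    )

    pre = years <= config.regime_year
    rev_pre = revenue_real[:, :, pre].sum(axis=2)  # community x fishery
    p = rev_pre / rev_pre.sum(axis=1, keepdims=True)
    true_diversity = 1.0 / np.sum(p**2, axis=1)

    truth = SyntheticTruth(
        trends=x,
        loadings=Z,
        community_shares=shares,
        price_series=pd.DataFrame(price.T, index=years, columns=[f"{t}|{l}" for t, l in names]),
        true_diversity=true_diversity,
        salmon_like=salmon_like,
        cpi=cpi,
    )
    return records, catch_panel, truth


def salmon_price_index(truth: SyntheticTruth) -> pd.Series:
    """Mean real ex-vessel price across the salmon-like fisheries, by year."""
    cols = [c for c, s in zip(truth.price_series.columns, truth.salmon_like) if s]
    return truth.price_series[cols].mean(axis=1)
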