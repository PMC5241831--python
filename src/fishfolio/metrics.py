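"""Portfolio diversity and compositional turnover for fishing communities.

Diversity of a community's fishing portfolio is the reciprocal Simpson index
1/D with D = sum_i p_i^2, where p_i is fishery i's share of the community's
revenue; 1/D is the effective number of fisheries (1 for a single-fishery
specialist, k for an even k-way split).  A community's overall diversity over
a window is the revenue-weighted mean of its annual indices, each year
weighted by that year's share of total window revenue (a pooled variant --
1/D of the shares of revenue summed over the window -- is also computed).

Turnover between two periods is Jaccard dissimilarity on the per-fishery
composition of catches.  On proportion data the abundance-based (Ruzicka)
form is used: J = 1 - sum_i min(A_i, B_i) / sum_i max(A_i, B_i); a binary
presence/absence variant is available behind ``variant="binary"``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

_FISHERY_KEY = ["taxon", "location"]


@dataclasses.dataclass
class DiversityProfile:
    """Annual and window-level reciprocal Simpson diversity of one community."""

    community: str
    years: np.ndarray
    annual_simpson_D: np.ndarray  # sum p_i^2 per year, in (0, 1]
    annual_reciprocal: np.ndarray  # 1/D per year, >= 1
    year_weights: np.ndarray  # annual revenue shares, sum to 1
    weighted_reciprocal: float  # sum_y w_y * (1/D_y)
    pooled_reciprocal: float  # 1/D of window-pooled revenue shares
    richness: int  # fisheries with positive revenue in the window


@dataclasses.dataclass
class TurnoverResult:
    """Pre/post compositional change of one community's catch portfolio."""

    community: str
    fisheries: list  # union fishery labels the compositions align on
    composition_pre: np.ndarray
    composition_post: np.ndarray
    jaccard: float


def simpson_reciprocal(shares) -> float:
    """Reciprocal Simpson index 1 / sum(p_i^2) of a proportion vector.

    Shares must be non-negative and sum to 1 (renormalized silently if the
    total is within 1e-6 of 1, an error otherwise).
    """
    p = np.asarray(shares, dtype=float)
    if (p < 0).any():
        raise ValueError("shares must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero share vector")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"shares sum to {total:.6g}, not 1")
    p = p / total
    return float(1.0 / np.sum(p**2))


def community_diversity(
    records: pd.DataFrame, years, community: str | None = None
) -> DiversityProfile:
    """Diversity profile of one community over a year window.

    ``records`` may be pre-restricted to the community or carry several
    (then ``community`` selects one).  Fisheries are taxon x location with
    gear aggregated; shares are of real revenue.  Every window year must
    have positive revenue (the community filter guarantees this upstream).
    """
    years = np.asarray(list(years), dtype=int)
    df = records
    if community is not None:
        df = df[df["community"] == community]
    elif df["community"].nunique() == 1:
        community = df["community"].iloc[0]
    else:
        raise ValueError("records contain several communities; pass `community`")
    df = df[df["year"].isin(years)]

    rev = df.groupby(_FISHERY_KEY + ["year"])["revenue_real"].sum().unstack("year")
    rev = rev.reindex(columns=years).fillna(0.0)
    annual_totals = rev.sum(axis=0).to_numpy()
    if (annual_totals <= 0).any():
        bad = years[annual_totals <= 0][:5]
        raise ValueError(f"community {community!r} has zero revenue in year(s) {list(bad)}")

    p = rev.to_numpy() / annual_totals  # fishery x year shares
    D = np.sum(p**2, axis=0)
    recip = 1.0 / D
    weights = annual_totals / annual_totals.sum()

    pooled = rev.sum(axis=1).to_numpy()
    pooled_recip = simpson_reciprocal(pooled / pooled.sum())

    return DiversityProfile(
        community=community,
        years=years,
        annual_simpson_D=D,
        annual_reciprocal=recip,
        year_weights=weights,
        weighted_reciprocal=float(np.dot(weights, recip)),
        pooled_reciprocal=pooled_recip,
        richness=int((pooled > 0).sum()),
    )


def diversity_table(records: pd.DataFrame, years, communities=None) -> pd.DataFrame:
    """Window diversity for many communities, one row each."""
    if communities is None:
        communities = sorted(records["community"].unique())
    wanted = set(communities)
    groups = {c: g for c, g in records.groupby("community") if c in wanted}
    rows = []
    for c in communities:
        prof = community_diversity(groups[c], years, community=c)
        rows.append(
            {
                "community": c,
                "weighted_reciprocal": prof.weighted_reciprocal,
                "pooled_reciprocal": prof.pooled_reciprocal,
                "richness": prof.richness,
            }
        )
    return pd.DataFrame(rows)


def period_composition(
    records: pd.DataFrame, period, value: str = "pounds", community: str | None = None
) -> pd.Series:
    """Per-fishery share of a community's period total (catch by default).

    Returns a Series indexed by ``taxon|location`` labels summing to 1.
    """
    period = set(int(y) for y in period)
    df = records
    if community is not None:
        df = df[df["community"] == community]
    df = df[df["year"].isin(period)]
    totals = df.groupby(_FISHERY_KEY)[value].sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("zero period total; cannot form a composition")
    shares = totals / grand
    shares.index = [f"{t}|{l}" for t, l in shares.index]
    return shares


def jaccard_turnover(A, B, variant: str = "ruzicka") -> float:
    """Jaccard dissimilarity between two aligned composition vectors.

    ``"ruzicka"`` (default) is the quantitative form
    1 - sum(min(A, B)) / sum(max(A, B)); ``"binary"`` reduces both vectors to
    presence/absence first.  Vectors must already be aligned on the union of
    fisheries, absent entries as 0.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("compositions must be aligned on the same fishery set")
    if variant == "binary":
        A = (A > 0).astype(float)
        B = (B > 0).astype(float)
    elif variant != "ruzicka":
        raise ValueError(f"unknown variant {variant!r}")
    denom = np.sum(np.maximum(A, B))
    if denom <= 0:
        raise ValueError("both compositions are all-zero")
    return float(1.0 - np.sum(np.minimum(A, B)) / denom)


def community_turnover(
    records: pd.DataFrame,
    pre,
    post,
    community: str,
    value: str = "pounds",
    variant: str = "ruzicka",
) -> TurnoverResult:
    """Pre/post turnover of one community, compositions on the union fishery set."""
    comp_pre = period_composition(records, pre, value=value, community=community)
    comp_post = period_composition(records, post, value=value, community=community)
    union = sorted(set(comp_pre.index) | set(comp_post.index))
    a = comp_pre.reindex(union).fillna(0.0).to_numpy()
    b = comp_post.reindex(union).fillna(0.0).to_numpy()
    return TurnoverResult(
        community=community,
        fisheries=union,
        composition_pre=a,
        composition_post=b,
        jaccard=jaccard_turnover(a, b, variant=variant),
    )
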