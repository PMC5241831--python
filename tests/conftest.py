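import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_records():
    """Two communities x two fisheries x three years, hand-enumerable."""
    rows = []
    for year in (1980, 1981, 1982):
        rows += [
            ("Alpha", year, "salmon", "north", "gillnet", 1000.0, 500.0),
            ("Alpha", year, "crab", "north", "pot", 200.0, 300.0),
            ("Beta", year, "salmon", "north", "gillnet", 800.0, 400.0),
        ]
    df = pd.DataFrame(
        rows,
        columns=["community", "year", "taxon", "location", "gear", "pounds", "revenue_nominal"],
    )
    df["revenue_real"] = df["revenue_nominal"]
    return df


@pytest.fixture
def flat_cpi():
    """CPI constant at 100 over 1980-2013: deflation is the identity."""
    return pd.Series(100.0, index=range(1980, 2014))


@pytest.fixture
def landings_csv(tmp_path, tiny_records):
    path = tmp_path / "landings.csv"
    tiny_records.drop(columns="revenue_real").to_csv(path, index=False)
    return path


def make_records(table):
    """Long records from (community, year, taxon, location, pounds, revenue) rows."""
    df = pd.DataFrame(
        table, columns=["community", "year", "taxon", "location", "pounds", "revenue_real"]
    )
    df["gear"] = "all"
    df["revenue_nominal"] = df["revenue_real"]
    return df
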