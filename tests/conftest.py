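import numpy as np
import pandas as pd
import pytest

from carioca import AreaGraph, ModelSpec, make_lattice_graph, make_rio_fixture


@pytest.fixture(scope="session")
def k2():
    """Two areas, each the other's sole neighbor."""
    return make_lattice_graph(1, 2)


@pytest.fixture(scope="session")
def path3():
    """Three areas in a path: A - B - C."""
    return AreaGraph.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def lattice33():
    return make_lattice_graph(3, 3)


@pytest.fixture(scope="session")
def rio():
    return make_rio_fixture()


@pytest.fixture(scope="session")
def spec():
    return ModelSpec()


@pytest.fixture()
def toy_design():
    """3-area design with one active binary covariate (airport slot)."""
    X = np.zeros((3, 6))
    X[:, 0] = [0.0, 1.0, 0.0]
    return X


def make_count_panel(area_ids, years, counts_by_year, stratum="total"):
    rows = []
    for year in years:
        for a, c in zip(area_ids, counts_by_year[year]):
            rows.append((a, year, stratum, int(c)))
    return pd.DataFrame(rows, columns=["area_id", "year", "stratum", "count"])


def make_population_panel(area_ids, years, pops, stratum="total"):
    rows = []
    for year in years:
        for a, p in zip(area_ids, pops):
            rows.append((a, year, stratum, float(p)))
    return pd.DataFrame(rows, columns=["area_id", "year", "stratum", "population"])
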