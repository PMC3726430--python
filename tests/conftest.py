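"""Shared fixtures: canonical designs and a session-wide planted simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import inbredscan as ib


@pytest.fixture(scope="session")
def planted_sim():
    """Default study-condition simulation: 9000 probes, 14 planted effects."""
    cfg = ib.SimulationConfig(seed=1)
    matrix, sheet, truth = ib.simulate_expression(cfg)
    return cfg, matrix, sheet, truth


@pytest.fixture(scope="session")
def planted_down_calls(planted_sim):
    """Sequential down-direction scan of the planted simulation at alpha=0.05."""
    _, matrix, sheet, _ = planted_sim
    return ib.sequential_outlier_scan(matrix, sheet=sheet, alpha=0.05,
                                      direction="down")


@pytest.fixture()
def canonical_sheet():
    return ib.design_sheet(ib.SimulationConfig())


@pytest.fixture()
def toy_sheet_2x2x2():
    """Minimal 2 lines x 2 levels x 2 sublines design (8 inbred samples)."""
    rows = []
    for line in ("x", "y"):
        for level in ("most_depressed", "least_depressed"):
            for k in (1, 2):
                rows.append((f"{line}_{level[:4]}_{k}", "inbred", line,
                             level, k))
    return ib.SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "role", "line", "level", "subline_index"]))


def make_matrix(values, probe_ids=None, sample_ids=None) -> ib.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ib.ExpressionMatrix(pd.DataFrame(values, index=probe_ids,
                                            columns=sample_ids))


@pytest.fixture()
def matrix_factory():
    return make_matrix
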