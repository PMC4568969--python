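import numpy as np
import pandas as pd
import pytest

from coexmotif.expression import ExpressionMatrix


def make_matrix(probe_values: dict, conditions: dict, probe_map: dict) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from plain dicts (test convenience)."""
    values = pd.DataFrame.from_dict(probe_values, orient="index", dtype=float)
    values.columns = list(conditions)
    return ExpressionMatrix(
        values=values,
        sample_conditions=pd.Series(conditions),
        probe_to_gene=probe_map,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_matrix():
    """6 samples (3 control, 3 DR), 4 probes over 3 genes."""
    conditions = {f"c{i}": "control" for i in range(1, 4)} | {f"d{i}": "DR" for i in range(1, 4)}
    return make_matrix(
        probe_values={
            "0_at": [10.1, 10.3, 9.9, 12.0, 12.4, 11.8],
            "1_at": [5.0, 5.2, 5.1, 5.0, 5.1, 5.2],
            "1_s_at": [7.0, 6.8, 7.1, 7.2, 6.9, 7.0],
            "2_x_at": [3.0, 3.3, 3.1, 3.2, 3.0, 3.1],
        },
        conditions=conditions,
        probe_map={"0_at": "SIRT3", "1_at": "GENEA", "1_s_at": "GENEA", "2_x_at": "GENEB"},
    )
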