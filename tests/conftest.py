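import numpy as np
import pytest

from buzznet import (
    aggregate_counts,
    build_all_currencies,
    single_visit_efficacies,
)
from buzznet.synthetic import default_config, generate


@pytest.fixture(scope="session")
def synth():
    """One default-scale synthetic community run, shared across tests."""
    cfg = default_config(seed=7)
    tables = generate(cfg)
    vn = aggregate_counts(tables.visits, tables.plant_labels, tables.bee_labels)
    efficacies = single_visit_efficacies(tables.single_visits, tables.references)
    matrices, reports = build_all_currencies(vn, efficacies, tables.group_map)
    return {
        "config": cfg,
        "tables": tables,
        "vn": vn,
        "efficacies": efficacies,
        "matrices": matrices,
        "imputation_reports": reports,
        "trimmed": {k: m.drop_empty()[0] for k, m in matrices.items()},
    }


@pytest.fixture()
def toy_matrix():
    """[[2,0],[1,1]] used by several worked examples."""
    return np.array([[2.0, 0.0], [1.0, 1.0]])
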