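import pandas as pd
import pytest

import speccount as sc
from speccount.filtering import filter_report


@pytest.fixture(scope="session")
def default_experiment():
    """One shared synthetic experiment at the default 3-stage x 3-run design."""
    cfg = sc.SimConfig(seed=1)
    reports, design, truth = sc.generate_experiment(cfg)
    filtered = [filter_report(r) for r in reports]
    matrix = sc.assemble_count_matrix(filtered, design)
    expr = sc.normalize_matrix(matrix)
    detection = sc.call_detection(matrix, reports=filtered)
    return {
        "config": cfg,
        "reports": reports,
        "filtered": filtered,
        "design": design,
        "truth": truth,
        "matrix": matrix,
        "expr": expr,
        "detection": detection,
    }


@pytest.fixture()
def toy_report(tmp_path):
    path = tmp_path / "run1.tsv"
    df = pd.DataFrame(
        {
            "accession": ["P1", "P2", "P3"],
            "description": ["alpha", "beta", "gamma"],
            "score": [40.0, 20.0, 36.0],
            "matches": [5, 3, 7],
            "coverage": [12.5, 8.0, 30.0],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path
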