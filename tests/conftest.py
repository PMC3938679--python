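import numpy as np
import pandas as pd
import pytest

from rhexpress.containers import ExpressionMatrix


def make_paired_matrix(values, pair_ids=None):
    """Build a small paired ExpressionMatrix from a probe -> row mapping.

    Rows alternate (control, treated) per pair: columns are
    c1, t1, c2, t2, ...
    """
    values = {k: list(v) for k, v in values.items()}
    n_samples = len(next(iter(values.values())))
    assert n_samples % 2 == 0
    n_pairs = n_samples // 2
    sample_ids, meta = [], []
    for i in range(1, n_pairs + 1):
        for cond in ("control", "treated"):
            sid = f"{cond[0]}{i}"
            sample_ids.append(sid)
            meta.append((sid, cond, f"pair{i}", f"subj{i}", "", ""))
    frame = pd.DataFrame(values, index=sample_ids).T
    samples = pd.DataFrame(
        meta,
        columns=["sample_id", "condition", "pair_id", "subject_id", "timepoint", "arm"],
    ).set_index("sample_id")
    return ExpressionMatrix(frame, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def toy_paired():
    """One informative probe among rows exercising both filter criteria."""
    return make_paired_matrix(
        {
            "flat": (5, 5, 5, 5),
            "low": (2, 2, 2, 2.5),
            "keep": (4, 3, 5, 6),
            "dim": (3.05, 3.05, 3.05, 3.2),
        }
    )
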