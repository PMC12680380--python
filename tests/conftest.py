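import numpy as np
import pandas as pd
import pytest

from zoymap import genocode, simdata


@pytest.fixture(scope="session")
def two_chrom_truth():
    """F2 of 200 progeny on two chromosomes (60 and 80 cM), markers every 5 cM."""
    genome = simdata.GenomeSpec.uniform([60.0, 80.0], spacing_cm=5.0)
    return simdata.simulate_cross(genome, n_progeny=200, seed=11)


@pytest.fixture(scope="session")
def two_chrom_scores(two_chrom_truth):
    return simdata.observe_genotypes(
        two_chrom_truth, simdata.PERFECT_OBSERVATION, seed=12
    )


@pytest.fixture(scope="session")
def clean_f2_scores():
    """Distortion-free default-template F2 (5 cM spacing, 530 progeny),
    observed without noise — the baseline for filter/grouping checks."""
    genome = simdata.GenomeSpec.default(spacing_cm=5.0)
    truth = simdata.simulate_cross(genome, n_progeny=530, seed=21)
    return truth, simdata.observe_genotypes(truth, simdata.PERFECT_OBSERVATION, seed=22)


def make_scores(rows: dict, parents=("P1", "P2"), f1="F1", scaffold="sc1"):
    """Hand-built ScoreMatrix from {marker_id: code string} rows.

    Column order: P1, P2, F1, then progeny p1..pk taken from the string tail.
    """
    n = len(next(iter(rows.values())))
    cols = [parents[0], parents[1], f1] + [f"p{i + 1}" for i in range(n - 3)]
    scores = pd.DataFrame(
        {mid: list(s) for mid, s in rows.items()}, index=cols
    ).T.astype(str)
    scores.columns = cols
    meta = pd.DataFrame(
        {
            "scaffold": scaffold,
            "bp": np.arange(1, len(rows) + 1) * 100,
            "tag_id": list(rows),
            "reversed": [m.endswith("r") for m in rows],
        },
        index=list(rows),
    )
    return genocode.ScoreMatrix(scores, meta, parents=parents, f1=f1)
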