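import itertools

import numpy as np
import pandas as pd
import pytest

from brainatlas import SimCountConfig, simulate_counts


@pytest.fixture(scope="session")
def paper_design_counts():
    """Small null count matrix on the study's balanced 2x2x2 design."""
    cfg = SimCountConfig(n_genes=30, n_regions=3, seed=11)
    cm, truth = simulate_counts(cfg)
    return cm, truth


@pytest.fixture(scope="session")
def paper_design_samples(paper_design_counts):
    return paper_design_counts[0].samples


def brute_force_plan_size(samples: pd.DataFrame, covariate: str) -> int:
    """Independent oracle: enumerate every covariate label vector over
    individuals that preserves cell sizes and pools within the other
    covariate's levels, then collapse global-label-swap equivalence."""
    other = {"sex": "age", "age": "sex"}[covariate]
    per = samples.drop_duplicates("individual").set_index("individual")
    inds = sorted(per.index)
    c = len(inds) // 4  # individuals per (sex, age) cell, balanced
    classes = set()
    for labels in itertools.product((0, 1), repeat=len(inds)):
        vec = dict(zip(inds, labels))
        ok = all(
            sum(1 for i in inds if per.loc[i, other] == lv and vec[i] == 0) == c
            for lv in per[other].unique()
        )
        if not ok:
            continue
        flipped = tuple(1 - l for l in labels)
        classes.add(min(labels, flipped))
    return len(classes)
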