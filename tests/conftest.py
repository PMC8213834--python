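"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import dataclasses
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlpcm.data_model import Dataset
from mlpcm.mrmr import MRMRSetting, discretize
from mlpcm.synthetic import GeneratorParams, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dataset400() -> Dataset:
    """A default-conditions benchmark at reduced size."""
    return generate(GeneratorParams(n_records=400), 3)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    return generate(GeneratorParams(n_records=60, n_solvents=8), 1)


def permute_targets(dataset: Dataset, seed: int) -> Dataset:
    """Null dataset: experimental dG values shuffled across records."""
    rng = np.random.default_rng(seed)
    y = dataset.dg_exp()
    yp = y[rng.permutation(len(y))]
    recs = [
        dataclasses.replace(r, dg_exp=float(v))
        for r, v in zip(dataset.records, yp)
    ]
    return Dataset(recs, dict(dataset.provenance))


# ---------------------------------------------------------------------------
# independent brute-force MRMR oracle (pure-python, recomputes every score
# from scratch at every step; shares only the discretization primitive)

def oracle_mi(a, b, pseudo: bool) -> float:
    a = [int(x) for x in a]
    b = [int(x) for x in b]
    na, nb = max(a) + 1, max(b) + 1
    counts = Counter(zip(a, b))
    joint = [[counts.get((i, j), 0) for j in range(nb)] for i in range(na)]
    if pseudo:
        joint = [[c + 1 for c in row] for row in joint]
    total = sum(sum(row) for row in joint)
    pa = [sum(row) / total for row in joint]
    pb = [sum(joint[i][j] for i in range(na)) / total for j in range(nb)]
    mi = 0.0
    for i in range(na):
        for j in range(nb):
            p = joint[i][j] / total
            if p > 0:
                mi += p * math.log(p / (pa[i] * pb[j]))
    return mi


def _oracle_score(labels, y, i, chosen, setting) -> float:
    rel = oracle_mi(labels[i], y, setting.pseudo_samples)
    if not chosen:
        red = 0.0
    else:
        red = sum(oracle_mi(labels[i], labels[j], setting.pseudo_samples) for j in chosen)
        red /= len(chosen)
    if setting.scheme == "difference":
        return rel - red
    return rel / (red + 1e-12)


def oracle_select(fm, k: int, setting: MRMRSetting) -> list[str]:
    """Exhaustive per-step greedy selection, recomputed from scratch."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = [discretize(fm.values[:, j], setting.n_bins) for j in range(fm.values.shape[1])]
        y = discretize(fm.target, setting.n_bins)
    if setting.direction == "forward":
        chosen: list[int] = []
        remaining = list(range(len(labels)))
        while len(chosen) < k:
            scores = [_oracle_score(labels, y, i, chosen, setting) for i in remaining]
            best_pos = max(range(len(scores)), key=lambda p: (scores[p], -p))
            # first maximum wins: emulate column-order tie-break
            best_pos = next(p for p in range(len(scores)) if scores[p] == scores[best_pos])
            chosen.append(remaining.pop(best_pos))
        order = chosen
    else:
        surviving = list(range(len(labels)))
        while len(surviving) > k:
            scores = [
                _oracle_score(labels, y, i, [j for j in surviving if j != i], setting)
                for i in surviving
            ]
            worst = next(
                p for p in range(len(scores)) if scores[p] == min(scores)
            )
            surviving.pop(worst)
        order = surviving
    return [fm.column_names[i] for i in order]
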