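"""Minimum-redundancy maximum-relevance (MRMR) feature screening.

Candidate model inputs (the SCRF components, the solvent dielectric
constant and, optionally, an auxiliary COSMO-RS free energy) are ranked
by mutual information with the experimental solvation free energy,
penalized by their redundancy with features already selected.  Variables
are discretized by equal-frequency binning and mutual information is the
plug-in estimate from the joint histogram, in nats, with optional
Laplace (add-one pseudo-count) smoothing.

The screen is run under a grid of settings — quantization level,
dependency scheme (difference or quotient), forward or backward greedy
direction, pseudo-count smoothing on or off — because different settings
select genuinely different variable subsets on real data.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import FeatureMatrix

__all__ = [
    "MRMRSetting",
    "FeatureSelection",
    "discretize",
    "mutual_information",
    "select_features",
    "enumerate_settings",
    "default_grid",
    "DEFAULT_GRID",
]

_SCHEMES = ("difference", "quotient")
_DIRECTIONS = ("forward", "backward")
_QUOTIENT_EPS = 1e-12


@dataclass(frozen=True)
class MRMRSetting:
    """One configuration of the MRMR screen."""

    n_bins: int = 5
    scheme: str = "difference"
    direction: str = "forward"
    pseudo_samples: bool = False

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )


@dataclass
class FeatureSelection:
    """Ordered output of one MRMR run: the k selected feature labels."""

    setting: MRMRSetting
    k: int
    ordered_features: list[str]
    scores: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "setting": {
                    "n_bins": self.setting.n_bins,
                    "scheme": self.setting.scheme,
                    "direction": self.setting.direction,
                    "pseudo_samples": self.setting.pseudo_samples,
                },
                "k": self.k,
                "ordered_features": self.ordered_features,
                "scores": self.scores,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSelection":
        d = json.loads(text)
        return cls(
            setting=MRMRSetting(**d["setting"]),
            k=d["k"],
            ordered_features=list(d["ordered_features"]),
            scores=list(d["scores"]),
        )


def discretize(column, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into integer labels 0..n_bins-1.

    Bin edges are the 1/n_bins .. (n_bins-1)/n_bins quantiles; values
    equal to an edge go to the lower bin, so tied values always share a
    label.  A constant column yields all-zero labels and a warning.
    """
    col = np.asarray(column, dtype=float)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if not np.all(np.isfinite(col)):
        raise ValueError("column contains non-finite values")
    if col.size == 0:
        return np.zeros(0, dtype=np.intp)
    if np.all(col == col[0]):
        warnings.warn("constant column: all samples assigned to bin 0", stacklevel=2)
        return np.zeros(col.size, dtype=np.intp)
    edges = np.quantile(col, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, col, side="left").astype(np.intp)


def mutual_information(a, b, pseudo_samples: bool = False) -> float:
    """Plug-in mutual information of two label vectors, in nats.

    With ``pseudo_samples``, one pseudo-count is added to every cell of
    the joint histogram before normalizing (Laplace smoothing), a crude
    Bayesian guard against empty cells at high quantization levels.
    """
    a = np.asarray(a, dtype=np.intp)
    b = np.asarray(b, dtype=np.intp)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be equal length, got {a.shape}, {b.shape}")
    if a.size < 1:
        raise ValueError("need at least one sample")
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    if pseudo_samples:
        joint += 1.0
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))


class _MICache:
    """Lazily-computed pairwise MI over the discretized columns + target."""

    def __init__(self, labels: list[np.ndarray], y_labels: np.ndarray, pseudo: bool):
        self.labels = labels
        self.y = y_labels
        self.pseudo = pseudo
        self._pair: dict[tuple[int, int], float] = {}
        self._rel: dict[int, float] = {}

    def relevance(self, i: int) -> float:
        if i not in self._rel:
            self._rel[i] = mutual_information(self.labels[i], self.y, self.pseudo)
        return self._rel[i]

    def redundancy(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self._pair:
            self._pair[key] = mutual_information(
                self.labels[key[0]], self.labels[key[1]], self.pseudo
            )
        return self._pair[key]


def _score(cache: _MICache, i: int, others: list[int], scheme: str) -> float:
    rel = cache.relevance(i)
    if not others:
        red = 0.0
    else:
        red = float(np.mean([cache.redundancy(i, j) for j in others]))
    if scheme == "difference":
        return rel - red
    return rel / (red + _QUOTIENT_EPS)


def select_features(fm: FeatureMatrix, k: int, setting: MRMRSetting) -> FeatureSelection:
    """Greedy MRMR selection of ``k`` features from a feature matrix.

    Forward: start empty, seed with the most relevant feature, then add
    the feature maximizing relevance-minus-redundancy (difference scheme)
    or relevance-over-redundancy (quotient scheme) with respect to the
    current set.  Backward: start full and repeatedly drop the feature
    with the lowest score against the other survivors.  Ties break on
    column order.
    """
    n_features = fm.values.shape[1]
    if not 1 <= k <= n_features:
        raise ValueError(f"k must be in [1, {n_features}], got {k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are scored anyway
        labels = [discretize(fm.values[:, j], setting.n_bins) for j in range(n_features)]
        y_labels = discretize(fm.target, setting.n_bins)
    cache = _MICache(labels, y_labels, setting.pseudo_samples)

    if setting.direction == "forward":
        selected: list[int] = []
        scores: list[float] = []
        remaining = list(range(n_features))
        while len(selected) < k:
            cand_scores = [_score(cache, i, selected, setting.scheme) for i in remaining]
            best = int(np.argmax(cand_scores))
            scores.append(float(cand_scores[best]))
            selected.append(remaining.pop(best))
        order = selected
    else:
        surviving = list(range(n_features))
        removal_scores: list[float] = []
        while len(surviving) > k:
            cand_scores = [
                _score(cache, i, [j for j in surviving if j != i], setting.scheme)
                for i in surviving
            ]
            worst = int(np.argmin(cand_scores))
            removal_scores.append(float(cand_scores[worst]))
            surviving.pop(worst)
        order = surviving
        scores = [
            _score(cache, i, [j for j in surviving if j != i], setting.scheme)
            for i in surviving
        ]

    return FeatureSelection(
        setting=setting,
        k=k,
        ordered_features=[fm.column_names[i] for i in order],
        scores=scores,
    )


#: Default screening grid: 5 quantization levels crossed with both
#: dependency schemes and both directions (20 settings), plus the 5
#: quantization levels of the forward/difference screen rerun with
#: pseudo-count smoothing — 25 settings in total.
DEFAULT_GRID = {
    "bins": (3, 5, 7, 9, 11),
    "schemes": _SCHEMES,
    "directions": _DIRECTIONS,
    "pseudo": (False,),
}


def enumerate_settings(grid: dict | None = None) -> list[MRMRSetting]:
    """Expand a settings grid into a deduplicated Cartesian product.

    ``grid`` maps ``bins``/``schemes``/``directions``/``pseudo`` to value
    lists.  With no argument the documented 25-setting default is
    returned.
    """
    if grid is None:
        base = enumerate_settings(DEFAULT_GRID)
        extra = [
            MRMRSetting(b, "difference", "forward", True) for b in DEFAULT_GRID["bins"]
        ]
        return base + extra
    for axis in ("bins", "schemes", "directions", "pseudo"):
        if not grid.get(axis):
            raise ValueError(f"settings grid axis {axis!r} is empty")
    out: list[MRMRSetting] = []
    seen = set()
    for b, s, d, p in itertools.product(
        grid["bins"], grid["schemes"], grid["directions"], grid["pseudo"]
    ):
        st = MRMRSetting(int(b), s, d, bool(p))
        if st not in seen:
            seen.add(st)
            out.append(st)
    return out


def default_grid() -> list[MRMRSetting]:
    """The documented 25-setting default grid."""
    return enumerate_settings(None)
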