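"""Clonal-selection immune classifier with a hormone-concentration field.

The model treats training samples as *antigens* living on the min-max
normalized unit cube.  Per class, a small population of *antibodies* is
seeded by k-means and then refined by clonal selection: each antibody is
cloned in proportion to its affinity (a bounded decreasing function of
Euclidean distance to the class's antigens), clones are mutated with a
variance that shrinks as affinity grows, and a mutant replaces its parent
only when it improves affinity.  The surviving antibodies are archived as
*memory cells* (MC).

Classification uses two signals:

* the class of the nearest memory cell, and
* a *hormone* field — per class, a Gaussian-kernel mixture centred on that
  class's memory cells (bandwidth = ``radius_of_influence``), normalized
  across classes into a probability vector at any query point.

When the two signals agree, that class is returned.  When they conflict
inside the *burring area* — the top two hormone probabilities nearly tied
(within ``burring_epsilon``) and the nearest memory cell within
``burring_radius`` of the query — the nearest memory cell wins; otherwise
the strongest hormone concentration decides.

Affinity, clone-count and mutation functional forms are this package's
reconstruction of the qualitative scheme (higher affinity -> more clones,
less mutation); see the methods note for the exact choices and rationale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist

from .data_model import FeatureTable, NormalizationParams


@dataclass
class AISConfig:
    """Tunable parameters of the immune classifier.

    All radii live on the normalized [0, 1] feature scale.
    """

    clonal_rate: int = 10
    radius_of_influence: float = 0.1
    burring_radius: float = 0.1
    burring_epsilon: float = 0.1
    n_best: int = 5
    mutation_scale: float = 0.2
    max_iterations: int = 50
    convergence_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clonal_rate < 1:
            raise ValueError("clonal_rate must be >= 1")
        if not (0 < self.radius_of_influence <= 1):
            raise ValueError("radius_of_influence must lie in (0, 1]")
        if self.n_best < 1:
            raise ValueError("n_best must be >= 1")


@dataclass
class Antibody:
    """A candidate recognizer: a point in antigen space with an affinity
    score against its class's antigens."""

    vector: np.ndarray
    class_id: int
    affinity: float


@dataclass
class MemoryCell:
    vector: np.ndarray
    class_id: int


@dataclass
class HormoneMatrix:
    """Per-class concentration field over antigen space.

    Raw concentration of class c at x is the sum of Gaussian kernels
    centred on c's memory cells; probabilities normalize the raw values
    across classes (uniform where all kernels underflow to zero).
    """

    centers: np.ndarray  # (m, d)
    class_ids: np.ndarray  # (m,)
    classes: np.ndarray  # sorted unique class ids
    bandwidth: float

    def concentrations(self, x: np.ndarray) -> np.ndarray:
        return self.concentrations_batch(np.atleast_2d(x))[0]

    def concentrations_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centers.shape[1]:
            raise ValueError("query dimension does not match memory cells")
        sq = cdist(X, self.centers, metric="sqeuclidean")
        kern = np.exp(-sq / (2.0 * self.bandwidth**2))
        raw = np.empty((X.shape[0], len(self.classes)))
        for ci, c in enumerate(self.classes):
            raw[:, ci] = kern[:, self.class_ids == c].sum(axis=1)
        return raw

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        return self.probabilities_batch(np.atleast_2d(x))[0]

    def probabilities_batch(self, X: np.ndarray) -> np.ndarray:
        raw = self.concentrations_batch(X)
        total = raw.sum(axis=1, keepdims=True)
        out = np.full_like(raw, 1.0 / raw.shape[1])
        ok = total[:, 0] > 0
        out[ok] = raw[ok] / total[ok]
        return out


@dataclass
class AISModel:
    memory_cells: list[MemoryCell]
    hormone: HormoneMatrix
    normalization: NormalizationParams | None
    config: AISConfig
    iteration_trace: list[float]
    affinity_trace: list[np.ndarray] = field(default_factory=list)

    @property
    def mc_matrix(self) -> np.ndarray:
        return np.vstack([mc.vector for mc in self.memory_cells])

    @property
    def mc_classes(self) -> np.ndarray:
        return np.array([mc.class_id for mc in self.memory_cells])

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "memory_cells": [
                {"vector": mc.vector.tolist(), "class_id": int(mc.class_id)}
                for mc in self.memory_cells
            ],
            "config": asdict(self.config),
            "normalization": None
            if self.normalization is None
            else {
                "minimum": self.normalization.minimum.tolist(),
                "maximum": self.normalization.maximum.tolist(),
            },
            "iteration_trace": list(map(float, self.iteration_trace)),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AISModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        mcs = [
            MemoryCell(np.array(mc["vector"], dtype=float), int(mc["class_id"]))
            for mc in doc["memory_cells"]
        ]
        config = AISConfig(**doc["config"])
        norm = None
        if doc.get("normalization"):
            norm = NormalizationParams(
                np.array(doc["normalization"]["minimum"]),
                np.array(doc["normalization"]["maximum"]),
            )
        model = cls(mcs, _hormone_from_cells(mcs, config), norm, config, doc["iteration_trace"])
        return model


def _hormone_from_cells(cells: list[MemoryCell], config: AISConfig) -> HormoneMatrix:
    centers = np.vstack([mc.vector for mc in cells])
    class_ids = np.array([mc.class_id for mc in cells])
    return HormoneMatrix(centers, class_ids, np.unique(class_ids), config.radius_of_influence)


def affinity(a: np.ndarray, b: np.ndarray) -> float:
    """Affinity between two points: 1 / (1 + Euclidean distance), in (0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return 1.0 / (1.0 + float(np.linalg.norm(a - b)))


def _mean_affinity(candidates: np.ndarray, antigens: np.ndarray) -> np.ndarray:
    """Mean affinity of each candidate row vector to a set of antigens."""
    d = cdist(np.atleast_2d(candidates), antigens)
    return (1.0 / (1.0 + d)).mean(axis=1)


def clone_count(aff: float, clonal_rate: int) -> int:
    """Number of clones for an antibody: round(clonal_rate * affinity),
    half away from zero, floored at one clone."""
    if not (0 < aff <= 1):
        raise ValueError("affinity must lie in (0, 1]")
    return max(1, int(np.floor(clonal_rate * aff + 0.5)))


def mutate(ab: Antibody, config: AISConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian coordinate perturbation with sigma = mutation_scale *
    (1 - affinity), clipped to the unit cube: high-affinity antibodies
    mutate less."""
    sigma = config.mutation_scale * (1.0 - ab.affinity)
    if sigma == 0:
        return ab.vector.copy()
    return np.clip(ab.vector + rng.normal(0.0, sigma, size=ab.vector.shape), 0.0, 1.0)


def _class_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means centroids of one class's antigens, robust to degenerate
    classes (fewer distinct points than k)."""
    uniq = np.unique(X, axis=0)
    if len(uniq) <= k:
        return uniq.astype(float)
    seed = int(rng.integers(0, 2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kmeans2 warns on empty clusters
        centroids, lab = kmeans2(X, k, minit="++", seed=seed)
    return centroids[np.unique(lab)]  # drop empty-cluster centroids


def initialize_population(
    train: FeatureTable, config: AISConfig
) -> tuple[list[Antibody], HormoneMatrix]:
    """Seed the B-cell population: per class, k-means centroids of that
    class's antigens become the initial antibodies and hormone sources."""
    X, y = _check_normalized(train)
    rng = np.random.default_rng(config.seed)
    antibodies: list[Antibody] = []
    for c in np.unique(y):
        Xc = X[y == c]
        k = min(config.n_best, len(Xc))
        if k < config.n_best:
            warnings.warn(
                f"class {c} has {len(Xc)} samples < n_best={config.n_best}; "
                "reducing antibody count",
                stacklevel=2,
            )
        centroids = _class_centroids(Xc, k, rng)
        affs = _mean_affinity(centroids, Xc)
        antibodies.extend(
            Antibody(v.copy(), int(c), float(a)) for v, a in zip(centroids, affs)
        )
    cells = [MemoryCell(ab.vector.copy(), ab.class_id) for ab in antibodies]
    return antibodies, _hormone_from_cells(cells, config)


def _check_normalized(train: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    if train.labels is None:
        raise ValueError("training table must be labeled")
    X = train.values
    if X.min() < -1e-9 or X.max() > 1 + 1e-9:
        raise ValueError("training data must be min-max normalized to [0, 1]")
    return np.clip(X, 0.0, 1.0), train.labels


def fit_ais(train: FeatureTable, config: AISConfig | None = None) -> AISModel:
    """Fit the immune classifier on a normalized, labeled table.

    Runs clonal selection rounds until the largest memory-cell displacement
    between rounds falls below ``convergence_tol`` or ``max_iterations`` is
    reached.  Deterministic given ``config.seed``.
    """
    config = config or AISConfig()
    X, y = _check_normalized(train)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fit_ais requires at least two classes")

    rng = np.random.default_rng(config.seed)
    antibodies, _ = initialize_population(train, config)
    class_antigens = {int(c): X[y == c] for c in classes}
    prev = np.vstack([ab.vector for ab in antibodies])
    trace: list[float] = []
    affinity_trace: list[np.ndarray] = [np.array([ab.affinity for ab in antibodies])]

    for _ in range(config.max_iterations):
        for ab in antibodies:
            antigens = class_antigens[ab.class_id]
            n_clones = clone_count(ab.affinity, config.clonal_rate)
            clones = np.vstack([mutate(ab, config, rng) for _ in range(n_clones)])
            clone_affs = _mean_affinity(clones, antigens)
            best = int(np.argmax(clone_affs))
            # a mutant replaces its parent only on strict improvement, so
            # per-slot affinity never decreases across rounds
            if clone_affs[best] > ab.affinity:
                ab.vector = clones[best]
                ab.affinity = float(clone_affs[best])
        current = np.vstack([ab.vector for ab in antibodies])
        displacement = float(np.max(np.linalg.norm(current - prev, axis=1)))
        trace.append(displacement)
        affinity_trace.append(np.array([ab.affinity for ab in antibodies]))
        prev = current
        if displacement < config.convergence_tol:
            break

    cells = [MemoryCell(ab.vector.copy(), ab.class_id) for ab in antibodies]
    return AISModel(
        memory_cells=cells,
        hormone=_hormone_from_cells(cells, config),
        normalization=None,
        config=config,
        iteration_trace=trace,
        affinity_trace=affinity_trace,
    )


def hormone_concentration(model: AISModel, x: np.ndarray) -> np.ndarray:
    """Per-class hormone probability vector at ``x`` (sums to 1)."""
    return model.hormone.probabilities(x)


def classify_ais(model: AISModel, x: np.ndarray) -> tuple[int, float]:
    """Classify one point with the dual memory-cell / hormone rule."""
    cls, score = predict_ais(model, np.atleast_2d(np.asarray(x, dtype=float)))
    return int(cls[0]), float(score[0])


def predict_ais(model: AISModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dual decision rule.

    Decision A: class of the nearest memory cell.  Decision B: hormone
    argmax.  Agreement wins outright; a conflict inside the burring area
    (hormone gap < ``burring_epsilon`` and nearest MC within
    ``burring_radius``) falls to the nearest memory cell, otherwise to the
    strongest hormone.  The score is the hormone probability of the
    returned class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mc = model.mc_matrix
    if X.shape[1] != mc.shape[1]:
        raise ValueError("query dimension does not match the model")
    dist = cdist(X, mc)
    nearest = np.argmin(dist, axis=1)
    decision_a = model.mc_classes[nearest]
    nearest_dist = dist[np.arange(len(X)), nearest]

    probs = model.hormone.probabilities_batch(X)
    classes = model.hormone.classes
    order = np.argsort(probs, axis=1)
    decision_b = classes[order[:, -1]]
    gap = probs[np.arange(len(X)), order[:, -1]] - probs[np.arange(len(X)), order[:, -2]]

    burring = (gap < model.config.burring_epsilon) & (
        nearest_dist <= model.config.burring_radius
    )
    final = np.where(decision_a == decision_b, decision_a, np.where(burring, decision_a, decision_b))
    class_pos = {int(c): i for i, c in enumerate(classes)}
    scores = probs[np.arange(len(X)), [class_pos[int(c)] for c in final]]
    return final, scores
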