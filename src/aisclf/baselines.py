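"""Comparison learners behind one fit/predict contract.

Four baselines accompany the immune classifier:

* **BPNN** — a back-propagation network with a fixed N-15-2 topology,
  sigmoid activations throughout and a mean-squared-error loss against
  the two-digit targets (1,0) / (0,1).  Trained full-batch.
* **RBF-SVM** — the dual optimization is delegated to a standard solver,
  but the fitted model exposes support vectors, dual coefficients
  (alpha_i * d_i) and bias b so the decision function
  sgn(sum_i alpha_i d_i K(x, x_i) + b) can be recomputed by direct
  kernel summation.
* **FCM** — fuzzy c-means with the standard inverse-square-distance
  membership weights; every membership row sums to one at every
  iteration.
* **AK** — ant k-means: cluster assignment is sampled from per-sample
  pheromone concentrations, centroids are recomputed from the sampled
  assignment, pheromone is deposited in proportion to 1/(1 + distance)
  and evaporates at rate rho; the best in-group-distance solution over
  the iterations is retained.

FCM and AK are unsupervised; ``map_clusters_to_classes`` converts their
cluster IDs into class predictions by majority vote so they can be scored
with the same confusion-matrix metrics as the supervised methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .data_model import FeatureTable


# --------------------------------------------------------------------------
# Back-propagation neural network (N-15-2)
# --------------------------------------------------------------------------

HIDDEN_WIDTH = 15
OUTPUT_WIDTH = 2


@dataclass
class BPNNModel:
    W1: np.ndarray  # (d, 15)
    b1: np.ndarray
    W2: np.ndarray  # (15, 2)
    b2: np.ndarray
    learning_rate: float
    epochs: int


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _bpnn_forward(model: BPNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = _sigmoid(X @ model.W1 + model.b1)
    O = _sigmoid(H @ model.W2 + model.b2)
    return H, O


def fit_bpnn(
    train: FeatureTable,
    epochs: int = 1000,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> BPNNModel:
    """Full-batch gradient descent on the MSE between sigmoid outputs and
    the one-hot targets (1,0) for class 0 and (0,1) for class 1."""
    if train.labels is None:
        raise ValueError("fit_bpnn requires labels")
    y = train.labels
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("fit_bpnn requires binary 0/1 labels")
    X = train.values
    n, d = X.shape
    T = np.zeros((n, 2))
    T[np.arange(n), y] = 1.0

    rng = np.random.default_rng(seed)
    model = BPNNModel(
        W1=rng.uniform(-0.5, 0.5, size=(d, HIDDEN_WIDTH)),
        b1=rng.uniform(-0.5, 0.5, size=HIDDEN_WIDTH),
        W2=rng.uniform(-0.5, 0.5, size=(HIDDEN_WIDTH, OUTPUT_WIDTH)),
        b2=rng.uniform(-0.5, 0.5, size=OUTPUT_WIDTH),
        learning_rate=learning_rate,
        epochs=epochs,
    )
    for _ in range(epochs):
        H, O = _bpnn_forward(model, X)
        dO = (O - T) * O * (1 - O) * (2.0 / n)
        dH = (dO @ model.W2.T) * H * (1 - H)
        model.W2 -= learning_rate * (H.T @ dO)
        model.b2 -= learning_rate * dO.sum(axis=0)
        model.W1 -= learning_rate * (X.T @ dH)
        model.b1 -= learning_rate * dH.sum(axis=0)
    return model


def predict_bpnn(model: BPNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class = argmax of the two output units; score = activation
    of the positive (recurrence) unit."""
    _, O = _bpnn_forward(model, np.atleast_2d(X))
    return np.argmax(O, axis=1), O[:, 1]


# --------------------------------------------------------------------------
# RBF support vector machine
# --------------------------------------------------------------------------


@dataclass
class SVMModel:
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * d_i, shape (m,)
    bias: float
    gamma: float
    C: float


def fit_svm(train: FeatureTable, C: float = 1.0, gamma: float | None = None) -> SVMModel:
    """Fit a soft-margin RBF SVM on labels coded +/-1 (1 = recurrent).

    The returned model carries the full dual solution so the decision
    function can be verified by explicit kernel summation.
    """
    if train.labels is None:
        raise ValueError("fit_svm requires labels")
    y = np.where(train.labels == 1, 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_svm requires both classes present")
    X = train.values
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(X, y)
    # sklearn orders classes [-1, +1], so decision_function > 0 <=> class +1
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        gamma=gamma,
        C=C,
    )


def decision_svm(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Signed decision value sum_i alpha_i d_i exp(-gamma ||x - x_i||^2) + b."""
    X = np.atleast_2d(X)
    K = np.exp(-model.gamma * cdist(X, model.support_vectors, "sqeuclidean"))
    return K @ model.dual_coef + model.bias


def predict_svm(model: SVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dec = decision_svm(model, X)
    return (dec > 0).astype(int), dec


# --------------------------------------------------------------------------
# Fuzzy c-means
# --------------------------------------------------------------------------


@dataclass
class FCMModel:
    codebooks: np.ndarray  # (c, d)
    membership: np.ndarray  # (n, c), rows sum to 1
    m: float
    tol: float
    n_iter: int
    membership_history: list[np.ndarray] = field(default_factory=list)


def _fcm_membership(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM weights u_ij proportional to (1/d_ij^2)^(1/(m-1));
    a sample coincident with a codebook gets membership 1 there."""
    d2 = cdist(X, V, "sqeuclidean")
    zero = d2 < 1e-12
    U = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():
        U[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        w = d2[rest] ** (-1.0 / (m - 1.0))
        U[rest] = w / w.sum(axis=1, keepdims=True)
    return U


def fit_fcm(
    table: FeatureTable,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> FCMModel:
    """Alternate membership/codebook updates until every codebook moves by
    less than ``tol``.  The per-iteration membership matrices are recorded
    so the sum-to-one invariant can be audited after the fact."""
    if c < 2:
        raise ValueError("c must be >= 2")
    X = table.values
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(c), size=X.shape[0])
    history = [U.copy()]
    V = np.zeros((c, X.shape[1]))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Um = U**m
        V_new = (Um.T @ X) / Um.sum(axis=0)[:, None]
        U = _fcm_membership(X, V_new, m)
        history.append(U.copy())
        shift = np.max(np.linalg.norm(V_new - V, axis=1)) if n_iter > 1 else np.inf
        V = V_new
        if shift < tol:
            break
    return FCMModel(V, U, m, tol, n_iter, history)


def predict_fcm(model: FCMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hardened cluster of each query plus its full membership row."""
    U = _fcm_membership(np.atleast_2d(X), model.codebooks, model.m)
    return np.argmax(U, axis=1), U


# --------------------------------------------------------------------------
# Ant k-means
# --------------------------------------------------------------------------


@dataclass
class AKModel:
    centroids: np.ndarray
    pheromone: np.ndarray  # (n, k), tau >= 0
    assign_probs: np.ndarray  # (n, k), rows sum to 1
    rho: float
    objective_trace: list[float]  # best-so-far, monotone non-increasing
    pheromone_min: float = 0.0  # smallest tau seen over the run


def fit_ak(
    table: FeatureTable,
    k: int = 2,
    rho: float = 0.1,
    max_iter: int = 50,
    seed: int = 0,
) -> AKModel:
    """Ant k-means clustering.

    Each iteration every sample ("ant") is assigned to a cluster with
    probability proportional to its pheromone row, centroids are updated
    from that assignment, pheromone toward each centroid is deposited in
    proportion to 1/(1 + distance), and all pheromone evaporates at rate
    ``rho``.  The solution with the lowest total in-group distance over
    all iterations is retained; with ``rho = 1`` the trail carries no
    memory and assignment degenerates to a pure distance rule.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = table.values
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    # farthest-point spread for the initial centroids: a random first point,
    # then repeatedly the point farthest from the chosen set
    first = int(rng.integers(n))
    chosen = [first]
    for _ in range(k - 1):
        d_near = cdist(X, X[chosen]).min(axis=1)
        chosen.append(int(np.argmax(d_near)))
    centroids = X[chosen].copy()
    tau = 1.0 / (1.0 + cdist(X, centroids))
    tau_min = float(tau.min())

    best = None
    trace: list[float] = []
    for _ in range(max_iter):
        probs = tau / tau.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        assign = (cum < rng.random((n, 1))).sum(axis=1)
        # an empty cluster is re-seeded at the point farthest from its
        # nearest current centroid
        for j in range(k):
            if not np.any(assign == j):
                d_near = cdist(X, centroids).min(axis=1)
                far = int(np.argmax(d_near))
                centroids[j] = X[far]
                assign[far] = j
        for j in range(k):
            centroids[j] = X[assign == j].mean(axis=0)
        dist = cdist(X, centroids)
        objective = float(dist[np.arange(n), assign].sum())
        deposit = 1.0 / (1.0 + dist)
        tau = (1.0 - rho) * tau + deposit
        tau_min = min(tau_min, float(tau.min()))
        if best is None or objective < best[0]:
            probs_now = tau / tau.sum(axis=1, keepdims=True)
            best = (objective, centroids.copy(), tau.copy(), probs_now)
        trace.append(best[0])

    objective, centroids, tau, probs = best
    return AKModel(centroids, tau, probs, rho, trace, tau_min)


def predict_ak(model: AKModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cluster of each query by pheromone-style proximity: probability
    proportional to 1/(1 + distance to centroid), hardened by argmax."""
    w = 1.0 / (1.0 + cdist(np.atleast_2d(X), model.centroids))
    probs = w / w.sum(axis=1, keepdims=True)
    return np.argmax(probs, axis=1), probs


# --------------------------------------------------------------------------
# JSON serialization shared by all four model dataclasses
# --------------------------------------------------------------------------

_MODEL_TYPES = {"BPNNModel": BPNNModel, "SVMModel": SVMModel,
                "FCMModel": FCMModel, "AKModel": AKModel}


def model_to_json(model) -> str:
    """Serialize any baseline model dataclass to a JSON document."""
    doc = {"type": type(model).__name__}
    for f in fields(model):
        v = getattr(model, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, list) and v and isinstance(v[0], np.ndarray):
            v = [a.tolist() for a in v]
        doc[f.name] = v
    return json.dumps(doc)


def model_from_json(text: str):
    doc = json.loads(text)
    cls = _MODEL_TYPES[doc.pop("type")]
    kwargs = {}
    for f in fields(cls):
        v = doc[f.name]
        if f.type.startswith("np.ndarray"):
            v = np.asarray(v, dtype=float)
        elif f.name == "membership_history":
            v = [np.asarray(a, dtype=float) for a in v]
        kwargs[f.name] = v
    return cls(**kwargs)


# --------------------------------------------------------------------------
# Cluster -> class mapping
# --------------------------------------------------------------------------


def map_clusters_to_classes(assignments: np.ndarray, labels: np.ndarray) -> dict[int, int]:
    """Majority-vote mapping from cluster IDs to class labels (ties go to
    the smaller class index), so unsupervised clusterings can be scored
    with classification metrics."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape != labels.shape:
        raise ValueError("assignments and labels must have equal length")
    mapping: dict[int, int] = {}
    classes = np.unique(labels)
    for cl in np.unique(assignments):
        sub = labels[assignments == cl]
        counts = [(np.sum(sub == c), -c) for c in classes]
        mapping[int(cl)] = int(-max(counts)[1])
    return mapping
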