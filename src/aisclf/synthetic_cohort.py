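"""Synthetic stand-ins for a non-public endometrial-cancer registry cohort.

The registry that motivated this package (599 records, 38 recurrent vs 561
non-recurrent, 20 mixed-type predictors) cannot be redistributed.  This
module generates desk-scale cohorts with the same statistical skeleton:
the class imbalance, a continuous age variable with the published mean and
SD (52.73 +/- 11.82 years), a mix of continuous, binary, ordinal and
nominal clinical codes, and a *planted* discriminative signal concentrated
on the analogues of histology (feature 2) and chemotherapy (feature 10).
Ground truth being known, planted-signal recovery becomes a testable
property of every downstream classifier and feature selector.

Also provided: isotropic Gaussian blobs as a generic clustering fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import FeatureTable

# Canonical 20-variable layout mirroring a gynecologic-oncology registry:
# (name, kind, n_categories or None).  Ordinal codes are small integer
# scales (grade, stage, fraction counts); nominal codes are unordered.
COHORT_LAYOUT: list[tuple[str, str, int | None]] = [
    ("age", "continuous", None),
    ("histology", "nominal", 4),
    ("behavior_code", "nominal", 3),
    ("grade", "ordinal", 3),
    ("tumor_size", "continuous", None),
    ("stage", "ordinal", 4),
    ("surgery", "binary", 2),
    ("radiotherapy", "binary", 2),
    ("surgical_margin", "binary", 2),
    ("chemotherapy", "binary", 2),
    ("therapy_sequence", "nominal", 3),
    ("dose_ctv_h", "continuous", None),
    ("fractions_ctv_h", "ordinal", 6),
    ("dose_ctv_l", "continuous", None),
    ("fractions_ctv_l", "ordinal", 6),
    ("rt_surgery_sequence", "nominal", 3),
    ("bmi_ge_24", "binary", 2),
    ("smoking", "binary", 2),
    ("betel_nut", "binary", 2),
    ("drinking", "binary", 2),
]

# Baseline category probabilities for coded variables (majority class and
# any non-informative feature).  Invented marginals: the registry publishes
# only the age distribution.
_BASE_PROBS = {
    2: np.array([0.5, 0.5]),
    3: np.array([0.55, 0.3, 0.15]),
    4: np.array([0.55, 0.25, 0.12, 0.08]),
    6: np.array([0.25, 0.2, 0.2, 0.15, 0.12, 0.08]),
}

# Means/SDs for the continuous non-age variables (tumor size in cm, CTV
# doses in cGy) — invented but clinically plausible scales.
_CONTINUOUS_PARAMS = {
    "tumor_size": (3.5, 1.8),
    "dose_ctv_h": (4500.0, 800.0),
    "dose_ctv_l": (3000.0, 600.0),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``informative_indices`` are 1-based to match the registry's variable
    numbering.  ``effect_size`` is a standardized mean shift for continuous
    informative features; for coded features it sets the total-variation
    distance between the class-conditional category distributions
    (TV = min(0.3 * effect_size, 0.9)).
    """

    n_minority: int = 38
    n_majority: int = 561
    n_features: int = 20
    informative_indices: frozenset[int] = frozenset({2, 10})
    effect_size: float = 1.5
    age_mean: float = 52.73
    age_sd: float = 11.82
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_minority > self.n_majority:
            raise ValueError("n_minority must not exceed n_majority")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        bad = [i for i in self.informative_indices if not (1 <= i <= self.n_features)]
        if bad:
            raise ValueError(f"informative indices {bad} outside 1..{self.n_features}")


def _layout(n_features: int) -> list[tuple[str, str, int | None]]:
    """Feature layout; the canonical 20 first, pattern recycled beyond."""
    out = []
    for i in range(n_features):
        name, kind, ncat = COHORT_LAYOUT[i % len(COHORT_LAYOUT)]
        if i >= len(COHORT_LAYOUT):
            name = f"{name}_{i + 1}"
        out.append((name, kind, ncat))
    return out


def _shift_probs(base: np.ndarray, tv: float) -> np.ndarray:
    """Shift a category distribution by total-variation distance ``tv``.

    Mass is moved from the most likely category toward the least likely
    ones, which keeps all probabilities valid for tv <= min(1 - p_min, ...).
    """
    p = base.copy()
    order = np.argsort(p)  # ascending: rare categories first
    take = min(tv, p[order[-1]] - 1e-6)
    p[order[-1]] -= take
    # distribute the removed mass over the rarer categories evenly
    p[order[:-1]] += take / (len(p) - 1)
    return p


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a labeled cohort table according to ``spec``.

    Majority (label 0) rows come first, minority (label 1) rows last;
    generation is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _layout(spec.n_features)
    n = spec.n_majority + spec.n_minority
    labels = np.concatenate(
        [np.zeros(spec.n_majority, dtype=int), np.ones(spec.n_minority, dtype=int)]
    )
    tv = min(0.3 * spec.effect_size, 0.9)
    values = np.empty((n, spec.n_features), dtype=float)
    minority = labels == 1

    for j, (name, kind, ncat) in enumerate(layout):
        informative = (j + 1) in spec.informative_indices
        if kind == "continuous":
            if name.startswith("age"):
                mu, sd = spec.age_mean, spec.age_sd
            else:
                mu, sd = _CONTINUOUS_PARAMS.get(name, (10.0, 3.0))
            col = rng.normal(mu, sd, size=n)
            if informative:
                col[minority] += spec.effect_size * sd
            values[:, j] = col
        else:
            base = _BASE_PROBS[ncat]
            p_min = _shift_probs(base, tv) if informative else base
            maj_draw = rng.choice(ncat, size=spec.n_majority, p=base)
            min_draw = rng.choice(ncat, size=spec.n_minority, p=p_min)
            values[:, j] = np.concatenate([maj_draw, min_draw]).astype(float)

    names = [name for name, _, _ in layout]
    kinds = [kind for _, kind, _ in layout]
    return FeatureTable(values, names, kinds, labels, np.zeros(n, dtype=bool))


def generate_blobs(
    k: int,
    n_per_cluster: int,
    separation: float,
    dims: int = 2,
    seed: int = 0,
) -> FeatureTable:
    """Isotropic unit-SD Gaussian clusters with pairwise centroid spacing
    ``separation`` (in within-cluster SD units); true cluster IDs are stored
    as labels."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    if dims >= k:
        centers = np.eye(k, dims) * separation / np.sqrt(2.0)
    elif dims == 2:
        angles = 2 * np.pi * np.arange(k) / k
        radius = separation / (2 * np.sin(np.pi / k))
        centers = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    else:
        raise ValueError("dims must be >= k, or 2 (points on a circle)")
    points = np.vstack(
        [c + rng.normal(size=(n_per_cluster, dims)) for c in centers]
    )
    labels = np.repeat(np.arange(k), n_per_cluster)
    names = [f"x{j + 1}" for j in range(dims)]
    return FeatureTable(points, names, ["continuous"] * dims, labels)
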