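"""Weekly behavior clustering from day-pattern relative frequencies.

Each participant's seven day-pattern labels collapse into a 5-vector of
relative frequencies (multiples of 1/7 over AD, M, E, BP, IM).  Participants
are then clustered with standard k-means (k=4, squared Euclidean, k-means++
initialization) and clusters are named by their dominant components: a single
"<pattern> dominant" name when the top component clearly exceeds the second,
otherwise a combined "<a>+<b> dominant" name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import MalformedInputError, NamingConflictError
from .synthetic import PATTERN_NAMES

DOMINANCE_GAP = 0.15  # top-minus-second gap below which a combined name is used

FREQ_COLUMNS = [f"freq_{p}" for p in PATTERN_NAMES]


def relative_frequencies(labels: list[str] | np.ndarray) -> np.ndarray:
    """Proportion of each pattern across the 7 days of one participant."""
    labels = list(labels)
    if len(labels) != 7:
        raise MalformedInputError(f"expected 7 day labels, got {len(labels)}")
    unknown = set(labels) - set(PATTERN_NAMES)
    if unknown:
        raise MalformedInputError(f"unknown pattern labels: {sorted(unknown)}")
    counts = np.array([labels.count(p) for p in PATTERN_NAMES], dtype=float)
    return counts / 7.0


def behavior_profiles(assignments: pd.DataFrame, label_col: str = "pattern_name") -> pd.DataFrame:
    """Per-participant frequency table from the day-level pattern assignment."""
    rows = []
    for pid, grp in assignments.groupby("participant_id", sort=True):
        freq = relative_frequencies(grp[label_col].tolist())
        rows.append({"participant_id": pid, **dict(zip(FREQ_COLUMNS, freq))})
    return pd.DataFrame(rows, columns=["participant_id", *FREQ_COLUMNS])


@dataclass
class BehaviorAssignment:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    names: list[str] | None = None

    def named_labels(self) -> np.ndarray:
        if self.names is None:
            raise MalformedInputError("behavior clusters are unnamed")
        return np.array([self.names[int(c)] for c in self.labels])


def kmeans_euclidean(
    profiles: np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> BehaviorAssignment:
    """Lloyd's k-means (k-means++ init, best of n_init restarts) on frequency vectors."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise MalformedInputError("profiles must be 2-D")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise MalformedInputError(f"k={k} exceeds the {n_distinct} distinct profiles")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(X)
    return BehaviorAssignment(labels, km.cluster_centers_, float(km.inertia_))


def name_behavior_clusters(centroids: np.ndarray, delta: float = DOMINANCE_GAP) -> list[str]:
    """Name each centroid by its dominant pattern component(s).

    If the top component exceeds the runner-up by more than delta the cluster
    is "<top> dominant"; otherwise the two leaders combine as "<a>+<b>
    dominant" with components in canonical (AD, M, E, BP, IM) order.
    """
    C = np.asarray(centroids, dtype=float)
    if C.ndim != 2 or C.shape[1] != len(PATTERN_NAMES):
        raise MalformedInputError("centroids must be k x 5")
    names = []
    for row in C:
        order = np.argsort(-row, kind="stable")
        top, second = int(order[0]), int(order[1])
        if row[top] - row[second] > delta:
            names.append(f"{PATTERN_NAMES[top]} dominant")
        else:
            a, b = sorted((top, second))  # canonical pattern order
            names.append(f"{PATTERN_NAMES[a]}+{PATTERN_NAMES[b]} dominant")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise NamingConflictError(
            f"duplicate behavior names {sorted(dupes)}; adjust delta or k"
        )
    return names


def cluster_behaviors(
    profiles: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    delta: float = DOMINANCE_GAP,
) -> tuple[pd.DataFrame, BehaviorAssignment]:
    """Cluster the profile table and attach named behavior labels."""
    ordered = profiles.sort_values("participant_id").reset_index(drop=True)
    X = ordered[FREQ_COLUMNS].to_numpy(dtype=float)
    assignment = kmeans_euclidean(X, k=k, seed=seed, n_init=n_init)
    assignment.names = name_behavior_clusters(assignment.centroids, delta=delta)
    out = ordered.copy()
    out["behavior_cluster"] = assignment.labels
    out["behavior_name"] = assignment.named_labels()
    return out, assignment


def centroid_table(assignment: BehaviorAssignment) -> pd.DataFrame:
    """Mean frequency vector per behavior (rows sum to 1)."""
    if assignment.names is None:
        raise MalformedInputError("behavior clusters are unnamed")
    df = pd.DataFrame(assignment.centroids, columns=FREQ_COLUMNS)
    df.insert(0, "behavior_name", assignment.names)
    return df
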