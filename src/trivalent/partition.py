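"""Three-class promoter partitioning by k-means on concatenated mark matrices.

Features are the per-mark signal matrices, winsorized at the 99th percentile
and column-standardized per mark so no single high-amplitude mark dominates
the Euclidean distance.  Clusters are labelled by role: *bivalent* has the
highest mean H3K27me3 body signal, *active* the higher mean H3K4me3 body
signal of the remaining two, *low* is the rest.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateDataError, SchemaError
from .signal import SignalMatrix, summarize_region, winsorize_scale

ROLES = ("low", "bivalent", "active")


@dataclass
class ClusterAssignment:
    """Per-promoter cluster index plus the cluster -> role map."""

    labels: pd.Series             # index = cgi_id, values = cluster index
    roles: dict = field(default_factory=dict)   # cluster index -> role
    marks: tuple = ()
    seed: int = 0
    k: int = 3
    scaling: str = "winsorize99+zscore"
    inertia: float = float("nan")

    def role_series(self) -> pd.Series:
        if not self.roles:
            raise SchemaError("cluster roles have not been labelled yet")
        return self.labels.map(self.roles).rename("role")

    def members(self, role: str) -> set:
        return set(self.role_series().pipe(lambda s: s.index[s == role]))

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.rename("cluster").to_frame()
        if self.roles:
            df["role"] = self.role_series()
        return df


def _feature_block(matrix: SignalMatrix, winsor_pct: float) -> np.ndarray:
    m = winsorize_scale(matrix, winsor_pct)
    x = m.values.to_numpy(dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0   # constant columns carry no distance information
    return (x - mu) / sd


def kmeans_partition(
    matrices: dict,
    k: int = 3,
    seed: int = 0,
    winsor_pct: float = 99.0,
    n_init: int = 10,
) -> ClusterAssignment:
    """Partition promoters by k-means on concatenated per-mark features.

    ``matrices`` maps mark name -> :class:`SignalMatrix`; all matrices must
    share row keys in the same order.  Returns the best of ``n_init``
    k-means++ restarts (lowest within-cluster sum of squares), deterministic
    under ``seed``.
    """
    if k < 2:
        raise SchemaError("k must be >= 2")
    if not matrices:
        raise SchemaError("at least one mark matrix is required")
    marks = tuple(matrices)
    index = matrices[marks[0]].row_ids
    for m in marks[1:]:
        if not index.equals(matrices[m].row_ids):
            raise SchemaError("mark matrices do not share row keys/order")
    if len(index) < k:
        raise DegenerateDataError(f"{len(index)} rows cannot form {k} clusters")
    feats = np.hstack([_feature_block(matrices[m], winsor_pct) for m in marks])
    if np.allclose(feats, feats[0]):
        raise DegenerateDataError("feature matrix is constant across rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(feats)
    return ClusterAssignment(
        labels=pd.Series(labels + 1, index=index, name="cluster"),
        marks=marks, seed=seed, k=k,
        scaling=f"winsorize{winsor_pct:g}+zscore", inertia=float(km.inertia_),
    )


def label_cluster_roles(
    assignment: ClusterAssignment,
    matrices: dict,
    tol: float = 1e-9,
) -> ClusterAssignment:
    """Map cluster indices to chromatin roles from mean body signals.

    The cluster with the greatest mean H3K27me3 body signal is *bivalent*;
    of the remaining two, the one with greater mean H3K4me3 is *active*.
    Ties within ``tol`` are refused — role labels would be arbitrary.
    """
    for mark in ("H3K4me3", "H3K27me3"):
        if mark not in matrices:
            raise SchemaError(f"role labelling requires the {mark} matrix")
    body27 = summarize_region(matrices["H3K27me3"], "body")
    body43 = summarize_region(matrices["H3K4me3"], "body")
    clusters = sorted(assignment.labels.unique())
    mean27 = {c: body27[assignment.labels == c].mean() for c in clusters}
    vals = sorted(mean27.values(), reverse=True)
    if len(vals) > 1 and vals[0] - vals[1] <= tol:
        raise DegenerateDataError("H3K27me3 cluster means tie; cannot label bivalent")
    bivalent = max(clusters, key=lambda c: mean27[c])
    rest = [c for c in clusters if c != bivalent]
    mean43 = {c: body43[assignment.labels == c].mean() for c in rest}
    v43 = sorted(mean43.values(), reverse=True)
    if len(v43) > 1 and v43[0] - v43[1] <= tol:
        raise DegenerateDataError("H3K4me3 cluster means tie; cannot label active")
    active = max(rest, key=lambda c: mean43[c])
    roles = {bivalent: "bivalent", active: "active"}
    for c in rest:
        roles.setdefault(c, "low")
    assignment.roles = roles
    return assignment


@dataclass
class OverlapReport:
    """Agreement between two role-labelled partitions of one promoter set."""

    contingency: pd.DataFrame     # roles of A (rows) x roles of B (columns)
    directional: pd.DataFrame     # per role: |A∩B|/|A|, |A∩B|/|B| (percent)
    jaccard: pd.Series
    n_shared: int

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "contingency": self.contingency.to_dict(),
            "directional": self.directional.to_dict(orient="index"),
            "jaccard": self.jaccard.to_dict(),
        }


def overlap_comparison(
    assign_a: ClusterAssignment, assign_b: ClusterAssignment
) -> OverlapReport:
    """Compare two partitions role-by-role.

    For each role r the directional percentages are |A_r ∩ B_r| / |A_r| and
    |A_r ∩ B_r| / |B_r| — the form of the headline "94% of non-traditional
    bivalent promoters are traditional-bivalent, comprising 73% of them"
    statistic — plus the full 3x3 contingency and per-role Jaccard.
    """
    ra, rb = assign_a.role_series(), assign_b.role_series()
    if set(ra.index) != set(rb.index):
        raise SchemaError("partitions cover different promoter universes")
    rb = rb.reindex(ra.index)
    contingency = pd.crosstab(ra, rb).reindex(
        index=list(ROLES), columns=list(ROLES), fill_value=0
    )
    rows = {}
    jac = {}
    for role in ROLES:
        a = set(ra.index[ra == role])
        b = set(rb.index[rb == role])
        inter = len(a & b)
        union = len(a | b)
        rows[role] = {
            "n_A": len(a), "n_B": len(b), "n_shared": inter,
            "pct_of_A": 100.0 * inter / len(a) if a else float("nan"),
            "pct_of_B": 100.0 * inter / len(b) if b else float("nan"),
        }
        jac[role] = inter / union if union else float("nan")
    return OverlapReport(
        contingency=contingency,
        directional=pd.DataFrame(rows).T,
        jaccard=pd.Series(jac, name="jaccard"),
        n_shared=len(ra),
    )
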