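"""ART 2-A adaptive-resonance clustering of descriptor vectors.

ART 2-A (Carpenter–Grossberg–Rosen) is an open-categorical clustering
algorithm for analog input vectors: the number of clusters is not fixed in
advance but emerges from a *vigilance* parameter ρ ∈ (0, 1).  Each input is
contrast-enhanced and normalized to unit Euclidean length; the winning
prototype is the one with maximal dot product (cosine similarity on unit
vectors).  If the winner's activation reaches ρ the input joins that cluster
and the prototype moves toward it,

    w  ←  normalize(η·x + (1 − η)·w),

with learning rate η; otherwise the input seeds a new cluster with prototype
x.  Higher vigilance demands more similarity to join, so the cluster count
grows with ρ — a single pass over a vigilance range yields a resolution
hierarchy.  Compared with k-means the method is cheap (one dot-product sweep
per input per epoch) and needs no preset cluster count, which made it the
workhorse for large descriptor-space diversity analyses.

Convergence: the run stops when assignments are unchanged over an epoch, or
when every prototype's dot product with its previous-epoch self reaches the
required similarity, or on the epoch/time limit.

The estimator follows the scikit-learn clustering API (``fit`` →
``labels_``); the module-level functions operate on descriptor tables keyed
by molecule uid and add vigilance scans, gzip-compressed XML result
round-trips, and cluster-occupancy analysis.
"""

from __future__ import annotations

import gzip
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from .qsar import QSARVectorTable

__all__ = [
    "ART2AParams",
    "ART2AResult",
    "ART2AClassifier",
    "scale_unit_interval",
    "art2a_classify",
    "art2a_scan",
    "write_result_xml",
    "read_result_xml",
    "occupancy",
    "successive_clustering",
]


# ---------------------------------------------------------------------------
# Parameters and results


@dataclass
class ART2AParams:
    """Run options for ART 2-A clustering.

    scale_to_unit_interval
        Linearly rescale every column of the input table to [0, 1] before
        clustering (per component: min → 0, max → 1).
    presentation_order
        "deterministic-random": one seeded shuffle, identical across epochs;
        "random-random": a fresh shuffle every epoch from the run seed.
    required_similarity
        Convergence threshold on the dot product of successive-epoch
        prototypes, in (0, 1].
    vigilance_range
        (low, high, step) scanned by :func:`art2a_scan`, each value in (0, 1).
    contrast_threshold
        Components below this value are zeroed after unit normalization
        (noise suppression); ``None`` means the canonical 1/√dim.
    """

    scale_to_unit_interval: bool = True
    presentation_order: str = "deterministic-random"
    seed: int = 0
    required_similarity: float = 0.99
    max_time_seconds: float = 60.0
    max_epochs: int = 100
    vigilance_range: tuple[float, float, float] = (0.1, 0.9, 0.1)
    learning_rate: float = 0.1
    contrast_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.presentation_order not in ("deterministic-random", "random-random"):
            raise ValueError(f"unknown presentation order: {self.presentation_order!r}")
        if not 0.0 < self.required_similarity <= 1.0:
            raise ValueError("required_similarity must lie in (0, 1]")
        if self.max_time_seconds <= 0:
            raise ValueError("max_time_seconds must be positive")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be positive")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        low, high, step = self.vigilance_range
        if not (0.0 < low < 1.0 and 0.0 < high < 1.0):
            raise ValueError("vigilance bounds must lie in (0, 1)")
        if low > high:
            raise ValueError("vigilance range low must not exceed high")
        if step <= 0:
            raise ValueError("vigilance step must be positive")
        if self.contrast_threshold is not None and self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be non-negative")

    def vigilance_values(self) -> list[float]:
        low, high, step = self.vigilance_range
        values = []
        v = low
        while v <= high + 1e-12:
            values.append(round(v, 12))
            v += step
        return values


@dataclass
class ART2AResult:
    """One clustering at a single vigilance value.

    ``assignments`` maps every uid to exactly one cluster index; clusters are
    non-empty and ``class_vectors[k]`` is the unit-norm prototype of cluster
    ``k`` with the dimensionality of the (cleaned) input table.
    """

    vigilance: float
    assignments: dict[str, int]
    class_vectors: list[np.ndarray]
    epochs_run: int
    converged_by: str  # assignment-stability | prototype-similarity | epoch-limit | time-limit
    params: ART2AParams = field(default_factory=ART2AParams)

    @property
    def n_clusters(self) -> int:
        return len(self.class_vectors)

    def members(self, cluster: int) -> list[str]:
        return [u for u, c in self.assignments.items() if c == cluster]


# ---------------------------------------------------------------------------
# Scaling


def scale_unit_interval(table: QSARVectorTable) -> QSARVectorTable:
    """Affine per-column rescale of a cleaned table so min → 0 and max → 1.

    Raises ``ValueError`` on a constant column — those should have been
    removed by cleaning.
    """
    arr = table.to_numpy(dtype=float)
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    constant = [c for c, l, h in zip(table.columns, lo, hi) if l == h]
    if constant:
        raise ValueError(f"constant columns encountered (clean first): {constant}")
    scaled = (arr - lo) / (hi - lo)
    out = pd.DataFrame(scaled, index=table.index, columns=table.columns)
    out.index.name = table.index.name
    return out


# ---------------------------------------------------------------------------
# Estimator


class ART2AClassifier(ClusterMixin, BaseEstimator):
    """ART 2-A clustering with the scikit-learn estimator interface.

    Parameters
    ----------
    vigilance : float in (0, 1)
        Minimum activation (cosine similarity to the winning prototype) an
        input needs to join an existing cluster; below it the input seeds a
        new cluster.
    learning_rate : float in (0, 1]
        Step size of the prototype update toward each committed input.
    contrast_threshold : float or None
        Components of the unit-normalized input below this value are zeroed
        (then the vector is renormalized).  ``None`` selects 1/√n_features.
    required_similarity : float in (0, 1]
        Prototype-stability convergence threshold: the run converges when
        every prototype's dot product with its previous-epoch self is at
        least this value.
    max_epochs, max_time_seconds
        Hard limits; hitting one still yields a valid result, flagged in
        ``converged_by_``.
    presentation_order : {"deterministic-random", "random-random"}
        Whether the seeded presentation shuffle is fixed across epochs or
        redrawn each epoch.
    random_state : int
        Seed for the presentation shuffle; runs are bit-reproducible given
        the same data, parameters and seed.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster index of every sample; clusters are compacted so each index
        in ``range(n_clusters_)`` is non-empty.
    cluster_centers_ : ndarray of shape (n_clusters_, n_features)
        Unit-norm class (prototype) vectors.
    n_epochs_ : int
    converged_by_ : str
    """

    def __init__(
        self,
        vigilance: float = 0.7,
        learning_rate: float = 0.1,
        contrast_threshold: float | None = None,
        required_similarity: float = 0.99,
        max_epochs: int = 100,
        max_time_seconds: float = 60.0,
        presentation_order: str = "deterministic-random",
        random_state: int = 0,
    ):
        self.vigilance = vigilance
        self.learning_rate = learning_rate
        self.contrast_threshold = contrast_threshold
        self.required_similarity = required_similarity
        self.max_epochs = max_epochs
        self.max_time_seconds = max_time_seconds
        self.presentation_order = presentation_order
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        """Unit-normalize rows, zero sub-threshold components, renormalize."""
        theta = self.contrast_threshold
        if theta is None:
            theta = 1.0 / math.sqrt(X.shape[1])
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero input vector cannot be unit-normalized")
        U = X / norms[:, None]
        if theta > 0:
            V = np.where(np.abs(U) < theta, 0.0, U)
            vnorms = np.linalg.norm(V, axis=1)
            # if contrast enhancement annihilates a vector, keep it unenhanced
            keep = vnorms > 0
            V[keep] = V[keep] / vnorms[keep, None]
            V[~keep] = U[~keep]
            U = V
        return U

    def fit(self, X, y=None):
        """Cluster the rows of X; returns self."""
        if not 0.0 < self.vigilance < 1.0:
            raise ValueError("vigilance must lie in (0, 1)")
        X = check_array(X, dtype=float, ensure_min_samples=1, ensure_min_features=1)
        U = self._preprocess(X)
        n = U.shape[0]
        rng = np.random.default_rng(self.random_state)
        fixed_order = rng.permutation(n)

        prototypes: list[np.ndarray] = []
        assign = np.full(n, -1, dtype=int)
        t0 = time.monotonic()
        converged_by = "epoch-limit"
        epoch = 0
        while epoch < self.max_epochs:
            epoch += 1
            if self.presentation_order == "random-random":
                order = rng.permutation(n)
            else:
                order = fixed_order
            prev_assign = assign.copy()
            prev_protos = [p.copy() for p in prototypes]
            for i in order:
                x = U[i]
                if prototypes:
                    acts = np.array([p @ x for p in prototypes])
                    winner = int(np.argmax(acts))  # argmax ties -> lowest index
                    if acts[winner] >= self.vigilance:
                        assign[i] = winner
                        w = (
                            self.learning_rate * x
                            + (1.0 - self.learning_rate) * prototypes[winner]
                        )
                        prototypes[winner] = w / np.linalg.norm(w)
                        continue
                assign[i] = len(prototypes)
                prototypes.append(x.copy())
            if np.array_equal(assign, prev_assign):
                converged_by = "assignment-stability"
                break
            if len(prev_protos) == len(prototypes) and prev_protos:
                sims = [p @ q for p, q in zip(prev_protos, prototypes)]
                if min(sims) >= self.required_similarity:
                    converged_by = "prototype-similarity"
                    break
            if time.monotonic() - t0 > self.max_time_seconds:
                converged_by = "time-limit"
                break

        # compact: drop clusters left empty by reassignment, keep index order
        used = sorted(set(assign.tolist()))
        remap = {old: new for new, old in enumerate(used)}
        self.labels_ = np.array([remap[a] for a in assign], dtype=int)
        self.cluster_centers_ = np.array([prototypes[k] for k in used])
        self.n_clusters_ = len(used)
        self.n_epochs_ = epoch
        self.converged_by_ = converged_by
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# Table-level operations


def _estimator_from(params: ART2AParams, vigilance: float) -> ART2AClassifier:
    return ART2AClassifier(
        vigilance=vigilance,
        learning_rate=params.learning_rate,
        contrast_threshold=params.contrast_threshold,
        required_similarity=params.required_similarity,
        max_epochs=params.max_epochs,
        max_time_seconds=params.max_time_seconds,
        presentation_order=params.presentation_order,
        random_state=params.seed,
    )


def art2a_classify(
    table: QSARVectorTable, params: ART2AParams, vigilance: float
) -> ART2AResult:
    """Cluster a cleaned descriptor table at one vigilance value.

    The table must be cleaned (finite cells, no constant columns); when
    ``params.scale_to_unit_interval`` is set, columns are rescaled to [0, 1]
    here before clustering.
    """
    if table.shape[1] == 0:
        raise ValueError("descriptor table has dimensionality 0")
    if table.shape[0] == 0:
        raise ValueError("descriptor table has no rows")
    work = scale_unit_interval(table) if params.scale_to_unit_interval else table
    est = _estimator_from(params, vigilance).fit(work.to_numpy(dtype=float))
    assignments = {uid: int(c) for uid, c in zip(table.index, est.labels_)}
    return ART2AResult(
        vigilance=float(vigilance),
        assignments=assignments,
        class_vectors=[v.copy() for v in est.cluster_centers_],
        epochs_run=est.n_epochs_,
        converged_by=est.converged_by_,
        params=params,
    )


def art2a_scan(table: QSARVectorTable, params: ART2AParams) -> list[ART2AResult]:
    """Cluster once per vigilance value in the params' range, ascending."""
    values = params.vigilance_values()
    if not values:
        raise ValueError("empty vigilance range")
    return [art2a_classify(table, params, v) for v in values]


def successive_clustering(
    table: QSARVectorTable,
    params: ART2AParams,
    vigilance: float,
    depth: int = 2,
    min_cluster_size: int = 2,
) -> dict[str, str]:
    """Top-down successive clustering: re-cluster within each cluster.

    Returns a map uid → hierarchical cluster path such as ``"2/0"``.  A
    cluster smaller than ``min_cluster_size`` (or at maximal depth) is not
    split further.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    result = art2a_classify(table, params, vigilance)
    paths = {uid: str(c) for uid, c in result.assignments.items()}
    if depth == 1:
        return paths
    for c in range(result.n_clusters):
        members = result.members(c)
        if len(members) < min_cluster_size:
            continue
        sub = table.loc[members]
        try:
            subpaths = successive_clustering(
                sub, params, vigilance, depth - 1, min_cluster_size
            )
        except ValueError:  # degenerate subset (e.g. constant column)
            continue
        for uid, sp in subpaths.items():
            paths[uid] = f"{c}/{sp}"
    return paths


# ---------------------------------------------------------------------------
# Compressed-XML result round-trip
#
# Schema: <art2a-run><params .../><result vigilance=.. epochs=.. converged-by=..>
#           <assignment uid=.. cluster=../>* <class-vector index=..>c1 c2 ...</class-vector>*
#         </result>*</art2a-run>, gzip-compressed on disk.

_FMT = "%.17g"


def write_result_xml(results: list[ART2AResult], path: str | os.PathLike) -> str:
    """Store clustering results as a gzip-compressed XML document."""
    root = etree.Element("art2a-run")
    if results:
        p = results[0].params
        el = etree.SubElement(root, "params")
        el.set("scale-to-unit-interval", str(p.scale_to_unit_interval).lower())
        el.set("presentation-order", p.presentation_order)
        el.set("seed", str(p.seed))
        el.set("required-similarity", _FMT % p.required_similarity)
        el.set("max-time-seconds", _FMT % p.max_time_seconds)
        el.set("max-epochs", str(p.max_epochs))
        el.set("learning-rate", _FMT % p.learning_rate)
        if p.contrast_threshold is not None:
            el.set("contrast-threshold", _FMT % p.contrast_threshold)
        el.set("vigilance-range", ",".join(_FMT % v for v in p.vigilance_range))
    for res in results:
        rel = etree.SubElement(root, "result")
        rel.set("vigilance", _FMT % res.vigilance)
        rel.set("epochs", str(res.epochs_run))
        rel.set("converged-by", res.converged_by)
        for uid, cluster in res.assignments.items():
            a = etree.SubElement(rel, "assignment")
            a.set("uid", uid)
            a.set("cluster", str(cluster))
        for k, vec in enumerate(res.class_vectors):
            cv = etree.SubElement(rel, "class-vector")
            cv.set("index", str(k))
            cv.text = " ".join(_FMT % x for x in vec)
    payload = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="utf-8")
    with gzip.open(os.fspath(path), "wb") as fh:
        fh.write(payload)
    return os.fspath(path)


def read_result_xml(path: str | os.PathLike) -> list[ART2AResult]:
    """Read a gzip-compressed XML result document back into memory."""
    raw = open(os.fspath(path), "rb").read(2)
    if raw != b"\x1f\x8b":
        raise ValueError(f"{path}: not a gzip-compressed result document")
    with gzip.open(os.fspath(path), "rb") as fh:
        root = etree.parse(fh).getroot()
    pel = root.find("params")
    params = ART2AParams()
    if pel is not None:
        vr = tuple(float(x) for x in pel.get("vigilance-range").split(","))
        params = ART2AParams(
            scale_to_unit_interval=pel.get("scale-to-unit-interval") == "true",
            presentation_order=pel.get("presentation-order"),
            seed=int(pel.get("seed")),
            required_similarity=float(pel.get("required-similarity")),
            max_time_seconds=float(pel.get("max-time-seconds")),
            max_epochs=int(pel.get("max-epochs")),
            vigilance_range=vr,  # type: ignore[arg-type]
            learning_rate=float(pel.get("learning-rate")),
            contrast_threshold=(
                float(pel.get("contrast-threshold"))
                if pel.get("contrast-threshold") is not None
                else None
            ),
        )
    out: list[ART2AResult] = []
    for rel in root.findall("result"):
        assignments = {
            a.get("uid"): int(a.get("cluster")) for a in rel.findall("assignment")
        }
        vectors = [
            np.array([float(x) for x in cv.text.split()])
            for cv in sorted(rel.findall("class-vector"), key=lambda e: int(e.get("index")))
        ]
        out.append(
            ART2AResult(
                vigilance=float(rel.get("vigilance")),
                assignments=assignments,
                class_vectors=vectors,
                epochs_run=int(rel.get("epochs")),
                converged_by=rel.get("converged-by"),
                params=params,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Occupancy analysis


def occupancy(result: ART2AResult, source_labels: dict[str, str]) -> pd.DataFrame:
    """Per-(cluster, source) occupancy of a clustering result.

    ``source_labels`` maps every clustered uid to the label of the collection
    it came from.  Returns a tidy DataFrame with columns ``cluster``,
    ``source``, ``count`` and ``fraction``, where fraction is the share of
    that source's molecules landing in the cluster (fractions per source sum
    to 1 over clusters).
    """
    missing = [u for u in result.assignments if u not in source_labels]
    if missing:
        raise ValueError(f"{len(missing)} uids lack a source label (first: {missing[0]})")
    counts: dict[tuple[int, str], int] = {}
    totals: dict[str, int] = {}
    for uid, cluster in result.assignments.items():
        label = source_labels[uid]
        counts[(cluster, label)] = counts.get((cluster, label), 0) + 1
        totals[label] = totals.get(label, 0) + 1
    rows = [
        {
            "cluster": cluster,
            "source": label,
            "count": n,
            "fraction": n / totals[label],
        }
        for (cluster, label), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["cluster", "source", "count", "fraction"])
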