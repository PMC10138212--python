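"""Low-dimensional reconstruction of the code fitness landscape.

Codes are embedded as 64-dimensional polar-requirement vectors (entry c =
PR of the amino acid at codon c; stop positions carry a constant).  PCA
of the low-cost slice gives the two-dimensional view in which the fitness
peaks separate; k-means with an elbow criterion, run on the full
64-dimensional vectors, identifies the peaks themselves.  Cluster
occupancies within a cost slice estimate the phase-volume share of each
peak; on multicanonical samples the within-slice distribution is already
the ensemble one, so raw fractions apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .codons import GeneticCode, N_CODONS, STOP_CODONS, sgc
from .ga import delta_pr_of_vectors
from .scales import PropertyScale, polar_requirement


def vectorize(
    assigns: np.ndarray | list,
    scale: PropertyScale | None = None,
    stop_value: float = 0.0,
) -> np.ndarray:
    """Map codes to 64-dim property vectors; stop positions get a fixed
    constant (identical across the ensemble, hence zero variance)."""
    vals = (scale or polar_requirement()).values
    if isinstance(assigns, list):
        assigns = np.stack(
            [a.assign if isinstance(a, GeneticCode) else np.asarray(a) for a in assigns]
        )
    A = np.atleast_2d(np.asarray(assigns))
    V = vals[A.clip(0)]
    V[A < 0] = stop_value
    return V


@dataclass
class LandscapeProjection:
    """A PCA projection fitted on the low-cost slice of the ensemble.

    Sign convention: PC1 is flipped so the SGC's coordinate is
    nonnegative, PC2 so that it correlates positively with Delta_PR
    (putting the left-column-enriched peak on the negative PC2 side) —
    both deterministic, making projections reproducible across runs.
    """

    components: np.ndarray  # (n_components, 64)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    cutoff: float
    degenerate: bool = False

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(vectors) - self.mean) @ self.components.T


def pca_fit(
    vectors: np.ndarray,
    costs: np.ndarray,
    cutoff: float,
    n_components: int = 3,
    scale: PropertyScale | None = None,
) -> LandscapeProjection:
    """Fit the projection on samples with cost < cutoff.

    All samples (any cost) remain projectable through the returned object,
    which is how the stacked landscape extends the low-cost projection
    upward.  Mean-centering only — no per-coordinate rescaling, since all
    coordinates share polar-requirement units.
    """
    vectors = np.atleast_2d(vectors)
    costs = np.asarray(costs)
    sel = vectors[costs < cutoff]
    if sel.shape[0] < 2:
        raise ValueError(
            f"need >= 2 samples below cutoff {cutoff}, got {sel.shape[0]}"
        )
    total_var = sel.var(axis=0).sum()
    if total_var <= 1e-12 * max(1.0, float((sel ** 2).mean())):
        return LandscapeProjection(
            components=np.zeros((n_components, vectors.shape[1])),
            mean=sel.mean(axis=0),
            explained_variance_ratio=np.zeros(n_components),
            cutoff=float(cutoff),
            degenerate=True,
        )
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    pca.fit(sel)
    comp = pca.components_.copy()
    proj = LandscapeProjection(
        comp, pca.mean_.copy(), pca.explained_variance_ratio_.copy(), float(cutoff)
    )
    sc = (scale or polar_requirement())
    sgc_vec = vectorize(sgc().assign, sc)
    if proj.transform(sgc_vec)[0, 0] < 0:
        comp[0] *= -1
    if comp.shape[0] > 1:
        scores = proj.transform(sel)[:, 1]
        dpr = delta_pr_of_vectors(sel)
        if np.corrcoef(scores, dpr)[0, 1] < 0:
            comp[1] *= -1
    return proj


def elbow_k(
    points: np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 50,
    min_ratio: float = 3.0,
) -> tuple[int, np.ndarray]:
    """Select the cluster count at the knee of the k-means SSE curve.

    SSE is computed for k = 1..k_max with ``n_restarts`` seeded restarts
    each.  The knee is the k with the largest relative drop-off: the
    ratio of the SSE drop achieved by going to k over the drop achieved
    by going one step further.  A smooth featureless curve (all ratios
    below ``min_ratio``) has no elbow and reports k = 1.
    """
    points = np.atleast_2d(points)
    if k_max < 2:
        raise ValueError("need k_max >= 2")
    if points.shape[0] < k_max:
        raise ValueError("fewer points than k_max")
    sse = np.empty(k_max)
    for k in range(1, k_max + 1):
        if k == 1:
            sse[0] = ((points - points.mean(axis=0)) ** 2).sum()
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            km.fit(points)
            sse[k - 1] = km.inertia_
    if sse[0] == 0:  # all points identical
        return 1, sse
    eps = 1e-12 * sse[0]
    drops = np.maximum(sse[:-1] - sse[1:], eps)  # drop achieved by k = 2..k_max
    ratios = drops[:-1] / drops[1:]  # relative drop-off at k = 2..k_max-1
    if ratios.max() < min_ratio:
        return 1, sse
    return int(np.argmax(ratios)) + 2, sse


@dataclass
class ClusterModel:
    """Fitted k-means clusters in projection space with color naming."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    color_of: dict  # cluster index -> color name
    occupancy: np.ndarray | None = None  # per-cluster slice fractions

    def color_labels(self) -> np.ndarray:
        return np.array([self.color_of[int(l)] for l in self.labels])


def fit_clusters(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterModel:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(np.atleast_2d(points))
    return ClusterModel(k, km.cluster_centers_, labels, {i: str(i) for i in range(k)})


def assign_clusters(model: ClusterModel, points: np.ndarray) -> np.ndarray:
    """Nearest-center cluster labels for new points (e.g. GA codes)."""
    d = np.linalg.norm(
        np.atleast_2d(points)[:, None, :] - model.centers[None, :, :], axis=-1
    )
    return d.argmin(axis=1)


def name_clusters(
    model: ClusterModel,
    vectors: np.ndarray,
    scale: PropertyScale | None = None,
) -> ClusterModel:
    """Assign the conventional peak names.

    "green" contains the SGC (nearest center to its vector); "blue" is
    the left-column-enriched peak (most negative mean Delta_PR among the
    rest); of the remaining, "red" is the larger by membership and
    "orange" the smaller.  With k != 4 extra clusters get numeric names.
    ``model`` must have been fitted in the same space as ``vectors``.
    """
    sc = scale or polar_requirement()
    sgc_pt = vectorize(sgc().assign, sc)[:, : model.centers.shape[1]]
    green = int(assign_clusters(model, sgc_pt)[0])
    dpr = delta_pr_of_vectors(vectors)
    mean_dpr = np.array(
        [
            dpr[model.labels == i].mean() if (model.labels == i).any() else np.inf
            for i in range(model.k)
        ]
    )
    rest = [i for i in range(model.k) if i != green]
    blue = min(rest, key=lambda i: mean_dpr[i])
    others = [i for i in rest if i != blue]
    sizes = np.bincount(model.labels, minlength=model.k)
    others.sort(key=lambda i: -sizes[i])
    names = {green: "green", blue: "blue"}
    for idx, name in zip(others, ["red", "orange"]):
        names[idx] = name
    for j, idx in enumerate(others[2:]):
        names[idx] = f"extra-{j}"
    model.color_of = names
    return model


def cluster_occupancy(
    labels: np.ndarray,
    costs: np.ndarray,
    slice_bounds: tuple,
    k: int,
) -> np.ndarray:
    """Per-cluster sample fractions within a cost slice (sums to 1).

    For multicanonical samples the weight is flat in cost, so within a
    narrow slice the raw sample shares estimate the ensemble phase-volume
    shares; GA samples are counted raw by construction.
    """
    lo, hi = slice_bounds
    m = (costs >= lo) & (costs < hi)
    if not m.any():
        raise ValueError(f"no samples in cost slice [{lo}, {hi})")
    counts = np.bincount(np.asarray(labels)[m], minlength=k).astype(float)
    return counts / counts.sum()


def average_code(
    assigns: np.ndarray,
    scale: PropertyScale | None = None,
) -> np.ndarray:
    """Per-codon mean property over a set of codes (64 values; stop
    positions report the stop constant)."""
    V = vectorize(assigns, scale)
    return V.mean(axis=0)


def average_code_table(mean_vector: np.ndarray) -> np.ndarray:
    """Reshape a 64-entry per-codon table to the 16x4 codon-table layout
    (rows: 1st x 3rd base, columns: 2nd base)."""
    t = np.asarray(mean_vector).reshape(4, 4, 4)  # (b1, b2, b3)
    return t.transpose(0, 2, 1).reshape(16, 4)


def landscape_stack(
    coords: np.ndarray,
    costs: np.ndarray,
    slab_width: float = 0.5,
    cost_range: tuple | None = None,
) -> list:
    """Layered scatter export: per cost slab (ordered by decreasing cost)
    the projected coordinates of its samples.  Empty slabs are preserved.

    Returns a list of dicts {"lo", "hi", "coords"}.
    """
    costs = np.asarray(costs)
    lo = costs.min() if cost_range is None else cost_range[0]
    hi = costs.max() + 1e-9 if cost_range is None else cost_range[1]
    nslab = max(int(np.ceil((hi - lo) / slab_width)), 1)
    layers = []
    for i in range(nslab - 1, -1, -1):
        a, b = lo + i * slab_width, lo + (i + 1) * slab_width
        m = (costs >= a) & (costs < b)
        layers.append({"lo": float(a), "hi": float(b), "coords": np.atleast_2d(coords)[m]})
    return layers
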