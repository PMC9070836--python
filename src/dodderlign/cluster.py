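"""Expression-pattern clustering on a Barnes–Hut t-SNE embedding.

Gene profiles are z-scored across samples, embedded in 2-D with
Barnes–Hut t-SNE, and grouped by density on the embedding.  Candidate
groups smaller than a minimum size ("cutoff", default 20) are dissolved
into an explicit noise group; surviving clusters are numbered by
decreasing size.  Defaults follow the published analysis: perplexity 20,
250 early-exaggeration ("lying") iterations, size cutoff 20, seed 2.

The density grouping is DBSCAN with its neighborhood radius taken from
the knee of the sorted k-nearest-neighbor distance curve (k = cutoff).
Coordinates are reproducible for a fixed seed within one environment;
cross-implementation coordinate equality is not promised (t-SNE is
implementation-sensitive), only structure recovery is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

NOISE_LABEL = -1

# scikit-learn's Barnes-Hut t-SNE runs a fixed 250-iteration
# early-exaggeration phase, matching the published "lying" value.
_BACKEND_EXAGGERATION_ITERS = 250


@dataclass
class TsneParams:
    """Barnes–Hut t-SNE settings (defaults as published)."""

    perplexity: float = 20.0
    early_exaggeration_iters: int = 250
    seed: int = 2
    n_iter: int = 1000
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.early_exaggeration_iters != _BACKEND_EXAGGERATION_ITERS:
            raise ValueError(
                "the Barnes-Hut backend runs a fixed "
                f"{_BACKEND_EXAGGERATION_ITERS}-iteration early-exaggeration "
                "phase; other values are not supported"
            )
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


@dataclass
class ClusterAssignment:
    """Per-gene labels; NOISE_LABEL (-1) marks the noise group."""

    labels: pd.Series
    cutoff: int
    n_clusters: int


def zscore_rows(expr: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardize each row to mean 0, sd 1 (sample sd, ddof=1).

    Constant rows become all-zero; the returned boolean array flags them.
    """
    df = pd.DataFrame(expr) if not isinstance(expr, pd.DataFrame) else expr
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    mat = df.values.astype(float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (mat - mean) / safe_sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns), constant


def tsne_embed(matrix: pd.DataFrame | np.ndarray, params: TsneParams | None = None) -> np.ndarray:
    """2-D Barnes–Hut t-SNE; deterministic for a fixed seed within one environment."""
    params = params or TsneParams()
    mat = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    n = mat.shape[0]
    if n <= 3 * params.perplexity:
        raise ValueError(
            f"perplexity {params.perplexity} too large for {n} points "
            "(need n > 3 * perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        max_iter=params.n_iter,
        angle=params.theta,
        method="barnes_hut",
        init="pca",
        random_state=params.seed,
        n_jobs=1,
    )
    return tsne.fit_transform(mat)


def _knee_eps(coords: np.ndarray, k: int) -> float:
    """DBSCAN radius from the knee of the sorted k-NN distance curve.

    The knee is the point of maximum perpendicular distance to the chord
    joining the curve's endpoints.
    """
    k = min(k, coords.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    curve = np.sort(dist[:, -1])
    n = len(curve)
    if n < 3 or curve[-1] == curve[0]:
        return float(curve[-1]) or 1.0
    x = np.arange(n, dtype=float)
    chord = np.array([n - 1.0, curve[-1] - curve[0]])
    chord /= np.linalg.norm(chord)
    rel = np.stack([x, curve - curve[0]], axis=1)
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return float(curve[int(np.argmax(perp))]) or float(np.median(curve)) or 1.0


def density_cluster(
    coords: np.ndarray,
    cutoff: int = 20,
    index: pd.Index | None = None,
    min_samples: int | None = None,
) -> ClusterAssignment:
    """Density grouping on the embedding with a minimum cluster size.

    Any DBSCAN group smaller than ``cutoff`` is dissolved into the noise
    label; survivors are renumbered 1, 2, ... by decreasing size.
    ``min_samples`` defaults to ``cutoff``: a core point must then sit in
    a neighborhood as populous as the smallest admissible cluster, which
    suppresses density bridges between adjacent groups.
    """
    if min_samples is None:
        min_samples = cutoff
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if index is None:
        index = pd.RangeIndex(coords.shape[0])

    if coords.shape[0] <= cutoff:
        labels = np.full(coords.shape[0], NOISE_LABEL)
    else:
        eps = _knee_eps(coords, k=cutoff)
        raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
        labels = np.full_like(raw, NOISE_LABEL)
        sizes = pd.Series(raw[raw >= 0]).value_counts()
        keep = sizes[sizes >= cutoff].index  # value_counts: size desc
        for new, old in enumerate(keep, start=1):
            labels[raw == old] = new
    series = pd.Series(labels, index=index)
    return ClusterAssignment(
        labels=series, cutoff=cutoff, n_clusters=int((series.unique() >= 1).sum())
    )


def cluster_genes(
    z: pd.DataFrame, params: TsneParams | None = None, cutoff: int = 20
) -> tuple[ClusterAssignment, np.ndarray]:
    """Embed z-scored profiles and density-cluster them; returns (assignment, coords)."""
    coords = tsne_embed(z, params)
    return density_cluster(coords, cutoff=cutoff, index=z.index), coords


def cluster_summary(
    assignment: ClusterAssignment, expr: pd.DataFrame
) -> pd.DataFrame:
    """Mean profile per non-noise cluster, plus a noise row when non-empty."""
    if not assignment.labels.index.equals(expr.index):
        raise ValueError("assignment labels do not align with expression rows")
    rows = {}
    for label in sorted(assignment.labels.unique()):
        members = expr.loc[assignment.labels == label]
        if label == NOISE_LABEL:
            if len(members):
                rows["noise"] = members.mean(axis=0)
        else:
            rows[f"cluster{label}"] = members.mean(axis=0)
    return pd.DataFrame(rows).T
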