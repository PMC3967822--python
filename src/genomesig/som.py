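"""PCA-initialized batch-learning self-organizing map (BLSOM).

A conventional SOM updates weights per presented sample, so the trained map
depends on the order of data input.  The batch-learning variant removes that
dependence: each cycle assigns *all* samples to their best-matching nodes and
then moves every node toward the mean of the samples captured by its
neighborhood.  Initial weights are placed on the plane spanned by the first
two principal components of the data instead of random values, so the whole
procedure is deterministic — identical inputs give bit-identical maps, and
row permutations of the input leave the final weights unchanged.

Schedule (all constants configurable): radius decays linearly from ``r0`` to
``r_end`` over the cycles with a rectangular (Chebyshev) neighborhood and
uniform weighting; the learning rate is alpha(t) = max(alpha_min,
alpha0 * (1 - t/T)).  Nodes whose neighborhood captured no samples keep their
previous weights.  Distances are squared Euclidean.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .kmers import FeatureMatrix

__all__ = [
    "TrainingError",
    "BatchSOM",
    "pca_initialize",
    "best_matching_node",
    "train",
    "train_som",
    "assign_fragments",
    "quantization_error",
    "save_map",
    "load_map",
]


class TrainingError(ValueError):
    """Raised for degenerate inputs or dimensionality mismatches."""


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise TrainingError(f"expected a 2-D matrix, got shape {X.shape}")
    return X


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Lexicographic row order by content: permutation-invariant reduction order."""
    return np.lexsort(X.T[::-1])


class BatchSOM(ClusterMixin, BaseEstimator):
    """Batch-learning self-organizing map with PCA weight initialization.

    Parameters
    ----------
    grid_width : int, default=30
        Node count along the first (horizontal) axis; must be >= 2.
    grid_height : int or "auto", default="auto"
        Node count along the second axis.  "auto" proportions the axes to the
        first two principal standard deviations: J = max(1, round(I*s2/s1)).
    cycles : int, default=145
        Number of batch learning cycles.
    initial_radius : float or None, default=None
        Starting Chebyshev neighborhood radius; None means max(I, J)/2.
    final_radius : float, default=1.0
        Radius reached on the last cycle (linear decay, rounded per cycle).
    init_span : float, default=5.0
        Multiples of standard deviation spanned along each principal axis by
        the initial weights (5 means +-2.5 sigma).
    alpha0, alpha_min : float, default 0.6, 0.01
        Learning-rate schedule alpha(t) = max(alpha_min, alpha0*(1 - t/T)).
    orientation : array-like or None, default=None
        Optional loading vector; PC1's sign is chosen so b1 @ (v - mean(v))
        >= 0.  Used by the signature pipeline to make map %GC increase along
        the first axis.  None falls back to a max-|component| sign rule.
    rng_seed : int, default=0
        Reserved for alternative tie-breaking policies; the default policy is
        fully deterministic and never draws from it.

    Attributes
    ----------
    weights_ : ndarray of shape (I, J, d)
    grid_height_ : int
    pca_mean_, pca_components_, pca_sigmas_ : PCA basis used for initialization.
    training_log_ : DataFrame with cycle, radius, alpha, quantization_error.
    labels_ : flat node index (i*J + j) of each training row, input order.
    """

    def __init__(
        self,
        grid_width: int = 30,
        grid_height="auto",
        cycles: int = 145,
        initial_radius: float | None = None,
        final_radius: float = 1.0,
        init_span: float = 5.0,
        alpha0: float = 0.6,
        alpha_min: float = 0.01,
        orientation=None,
        rng_seed: int = 0,
    ):
        self.grid_width = grid_width
        self.grid_height = grid_height
        self.cycles = cycles
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.init_span = init_span
        self.alpha0 = alpha0
        self.alpha_min = alpha_min
        self.orientation = orientation
        self.rng_seed = rng_seed

    # ------------------------------------------------------------------ PCA

    def initialize(self, X) -> "BatchSOM":
        """Compute the PCA basis and lay initial weights on the PC1-PC2 plane.

        weight(i, j) = mean + span*s1*(i/(I-1) - 1/2)*b1
                            + span*s2*(j/(J-1) - 1/2)*b2   (second term 0 if J == 1)
        """
        X = _as_matrix(X)
        n, d = X.shape
        if n < 3:
            raise TrainingError(f"need at least 3 rows to initialize, got {n}")
        I = int(self.grid_width)
        if I < 2:
            raise TrainingError(f"grid_width must be >= 2, got {I}")
        if self.cycles < 1:
            raise TrainingError(f"cycles must be >= 1, got {self.cycles}")

        # canonical row order makes the mean/covariance sums (and hence the
        # whole initialization) independent of input row order, bit for bit
        Xs = X[_canonical_order(X)]
        mean = Xs.mean(axis=0)
        Xc = Xs - mean
        cov = (Xc.T @ Xc) / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] <= 0 or not np.isfinite(evals[-1]):
            raise TrainingError("degenerate input: all fragments identical")
        order = [-1, -2] if d >= 2 else [-1, -1]
        b1 = evecs[:, order[0]].copy()
        b2 = evecs[:, order[1]].copy() if d >= 2 else np.zeros(d)
        s1 = float(np.sqrt(max(evals[order[0]], 0.0)))
        s2 = float(np.sqrt(max(evals[order[1]], 0.0))) if d >= 2 else 0.0

        v = self.orientation
        if v is not None:
            v = np.asarray(v, dtype=np.float64)
            if float(b1 @ (v - v.mean())) < 0:
                b1 = -b1
        elif b1[np.argmax(np.abs(b1))] < 0:
            b1 = -b1
        if d >= 2 and b2[np.argmax(np.abs(b2))] < 0:
            b2 = -b2

        if self.grid_height == "auto":
            J = max(1, round(I * s2 / s1)) if s1 > 0 else 1
        else:
            J = int(self.grid_height)
            if J < 1:
                raise TrainingError(f"grid_height must be >= 1, got {J}")

        u = self.init_span * s1 * (np.arange(I) / (I - 1) - 0.5)
        if J == 1:
            v2 = np.zeros(1)
        else:
            v2 = self.init_span * s2 * (np.arange(J) / (J - 1) - 0.5)
        W = mean[None, None, :] + u[:, None, None] * b1 + v2[None, :, None] * b2

        self.n_features_in_ = d
        self.grid_height_ = J
        self.pca_mean_ = mean
        self.pca_components_ = np.vstack([b1, b2])
        self.pca_sigmas_ = np.array([s1, s2])
        self.weights_ = W
        self.training_log_ = pd.DataFrame(
            columns=["cycle", "radius", "alpha", "quantization_error"]
        )
        return self

    # ------------------------------------------------------------- training

    def _bmu_flat(self, X: np.ndarray, Wf: np.ndarray) -> np.ndarray:
        # argmin of ||x - w||^2; ties go to the smallest flat (i-major) index,
        # which np.argmin's first-minimum rule provides
        d2 = (
            (X * X).sum(axis=1)[:, None]
            - 2.0 * (X @ Wf.T)
            + (Wf * Wf).sum(axis=1)[None, :]
        )
        return np.argmin(d2, axis=1)

    def _qe(self, X: np.ndarray, Wf: np.ndarray, bmu: np.ndarray) -> float:
        diff = X - Wf[bmu]
        return float(np.mean((diff * diff).sum(axis=1)))

    def fit(self, X, y=None) -> "BatchSOM":
        """Run T batch cycles; deterministic and input-order independent."""
        X = _as_matrix(X)
        self.initialize(X)
        I, J, d = self.weights_.shape
        T = int(self.cycles)
        r0 = max(I, J) / 2 if self.initial_radius is None else float(self.initial_radius)
        r_end = float(self.final_radius)
        if r0 < r_end or r_end < 0:
            raise TrainingError(
                f"need initial_radius >= final_radius >= 0, got {r0}, {r_end}"
            )

        Xs = X[_canonical_order(X)]
        W = self.weights_
        log = []
        for t in range(1, T + 1):
            Wf = W.reshape(I * J, d)
            bmu = self._bmu_flat(Xs, Wf)
            qe = self._qe(Xs, Wf, bmu)
            r = round(r0) if T == 1 else round(r0 + (r_end - r0) * (t - 1) / (T - 1))
            alpha = max(self.alpha_min, self.alpha0 * (1.0 - t / T))

            counts = np.bincount(bmu, minlength=I * J).astype(np.float64)
            sums = np.zeros((I * J, d))
            np.add.at(sums, bmu, Xs)

            nb_counts, nb_sums = _box_sums(
                counts.reshape(I, J), sums.reshape(I, J, d), int(r)
            )
            mask = nb_counts > 0
            means = np.zeros_like(nb_sums)
            means[mask] = nb_sums[mask] / nb_counts[mask][:, None]
            Wm = W.reshape(I * J, d)
            if alpha >= 1.0:
                Wm[mask] = means[mask]
            else:
                Wm[mask] += alpha * (means[mask] - Wm[mask])
            log.append((t, int(r), alpha, qe))

        self.weights_ = W
        self.training_log_ = pd.DataFrame(
            log, columns=["cycle", "radius", "alpha", "quantization_error"]
        )
        Wf = W.reshape(I * J, d)
        bmu = self._bmu_flat(X, Wf)
        self.labels_ = bmu
        diff = X - Wf[bmu]
        self.distances_ = (diff * diff).sum(axis=1)
        return self

    # ------------------------------------------------------------ inference

    def _check_fitted_X(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise TrainingError("map is not initialized; call fit or initialize first")
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise TrainingError(
                f"feature dimensionality {X.shape[1]} does not match map ({self.n_features_in_})"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """Flat best-matching-node index (i * J + j) per row."""
        X = self._check_fitted_X(X)
        I, J, d = self.weights_.shape
        return self._bmu_flat(X, self.weights_.reshape(I * J, d))

    def bmu(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) best-matching nodes and squared distances per row."""
        X = self._check_fitted_X(X)
        I, J, d = self.weights_.shape
        Wf = self.weights_.reshape(I * J, d)
        flat = self._bmu_flat(X, Wf)
        diff = X - Wf[flat]
        ij = np.stack([flat // J, flat % J], axis=1)
        return ij, (diff * diff).sum(axis=1)

    def quantization_error(self, X) -> float:
        """Mean squared distance of rows to their best-matching nodes."""
        X = self._check_fitted_X(X)
        I, J, d = self.weights_.shape
        Wf = self.weights_.reshape(I * J, d)
        return self._qe(X, Wf, self._bmu_flat(X, Wf))


def _box_sums(
    counts: np.ndarray, sums: np.ndarray, r: int
) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev-ball (square box) neighborhood totals via integral images."""
    I, J = counts.shape
    if r == 0:
        return counts.reshape(-1), sums.reshape(I * J, -1)
    Ic = np.zeros((I + 1, J + 1))
    Ic[1:, 1:] = counts.cumsum(axis=0).cumsum(axis=1)
    Is = np.zeros((I + 1, J + 1, sums.shape[2]))
    Is[1:, 1:] = sums.cumsum(axis=0).cumsum(axis=1)
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    i0 = np.clip(ii - r, 0, I)
    i1 = np.clip(ii + r + 1, 0, I)
    j0 = np.clip(jj - r, 0, J)
    j1 = np.clip(jj + r + 1, 0, J)
    box_c = Ic[i1, j1] - Ic[i0, j1] - Ic[i1, j0] + Ic[i0, j0]
    box_s = Is[i1, j1] - Is[i0, j1] - Is[i1, j0] + Is[i0, j0]
    return box_c.reshape(-1), box_s.reshape(I * J, -1)


# ------------------------------------------------------- functional wrappers


def pca_initialize(features, **params) -> BatchSOM:
    """Untrained map with PCA-derived initial weights (wrapper over BatchSOM)."""
    som = BatchSOM(**params)
    return som.initialize(features)


def best_matching_node(weights: np.ndarray, x: np.ndarray) -> tuple[int, int]:
    """Grid coordinates of the node nearest x (squared Euclidean); ties to
    the smallest (i, then j)."""
    W = np.asarray(weights, dtype=np.float64)
    I, J, d = W.shape
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (d,):
        raise TrainingError(f"vector shape {x.shape} does not match weights ({d},)")
    diff = W.reshape(I * J, d) - x
    flat = int(np.argmin((diff * diff).sum(axis=1)))
    return flat // J, flat % J


def train(features, **params) -> tuple[BatchSOM, pd.DataFrame | np.ndarray]:
    """Fit a BatchSOM; returns (map, assignment).

    With a FeatureMatrix the assignment is a DataFrame (genome_id, start, i,
    j, distance); with a bare array it is the (n, 2) array of node coordinates.
    """
    som = BatchSOM(**params)
    som.fit(features)
    if isinstance(features, FeatureMatrix):
        return som, assign_fragments(som, features)
    ij, _ = som.bmu(features)
    return som, ij


def train_som(features: FeatureMatrix, **params) -> tuple[BatchSOM, pd.DataFrame]:
    """Signature-pipeline entry point: orients PC1 by per-column GC loading so
    %GC increases along the first map axis, then trains."""
    params.setdefault(
        "orientation", features.index.gc_counts.astype(np.float64) / features.index.k
    )
    som = BatchSOM(**params).fit(features.values)
    return som, assign_fragments(som, features)


def assign_fragments(som: BatchSOM, features: FeatureMatrix) -> pd.DataFrame:
    """Per-fragment best-matching node table (distance = squared Euclidean)."""
    ij, dist = som.bmu(features.values)
    return pd.DataFrame(
        {
            "genome_id": [g for g, _ in features.fragment_keys],
            "start": [s for _, s in features.fragment_keys],
            "i": ij[:, 0],
            "j": ij[:, 1],
            "distance": dist,
        }
    )


def quantization_error(features, som: BatchSOM) -> float:
    return som.quantization_error(
        features.values if isinstance(features, FeatureMatrix) else features
    )


# ------------------------------------------------------------- serialization


def save_map(som: BatchSOM, path) -> None:
    """Text serialization (JSON metadata + weight rows); round-trips bit-exactly."""
    I, J, d = som.weights_.shape
    meta = {
        "params": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in som.get_params().items()
        },
        "shape": [I, J, d],
        "pca_sigmas": som.pca_sigmas_.tolist(),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("# pca_mean\t" + "\t".join(f"{v:.17g}" for v in som.pca_mean_) + "\n")
        for row in som.pca_components_:
            fh.write("# pca_axis\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
        fh.write("i\tj\t" + "\t".join(f"w{c}" for c in range(d)) + "\n")
        Wf = som.weights_.reshape(I * J, d)
        for flat in range(I * J):
            vals = "\t".join(f"{v:.17g}" for v in Wf[flat])
            fh.write(f"{flat // J}\t{flat % J}\t{vals}\n")


def load_map(path) -> BatchSOM:
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
        mean = np.array(fh.readline().split("\t")[1:], dtype=np.float64)
        axes = [np.array(fh.readline().split("\t")[1:], dtype=np.float64) for _ in range(2)]
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    I, J, d = meta["shape"]
    params = meta["params"]
    if isinstance(params.get("orientation"), list):
        params["orientation"] = np.asarray(params["orientation"])
    som = BatchSOM(**params)
    som.n_features_in_ = d
    som.grid_height_ = J
    som.pca_mean_ = mean
    som.pca_components_ = np.vstack(axes)
    som.pca_sigmas_ = np.asarray(meta["pca_sigmas"])
    W = df[[f"w{c}" for c in range(d)]].to_numpy(dtype=np.float64)
    som.weights_ = W.reshape(I, J, d)
    return som
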