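"""Point-cloud shape classifier for aneurysm domes.

A hierarchical point-set network in the PointNet++ mould, implemented
directly on NumPy (forward pass and analytic backprop): set-abstraction
levels built from farthest-point sampling, radius grouping and shared
per-point perceptrons with batch normalisation, a symmetric max-pool to
a global descriptor, and a perceptron head emitting log-probabilities
over {stable, growing}.  Max-pooling makes the output invariant to the
order of the input points; inputs are centred and scaled to the unit
sphere, which makes the representation scale invariant by construction,
and random-rotation augmentation during training pushes it toward
rotation invariance.

Two configuration profiles are provided: a full-scale profile
(2048 points, 200 epochs, batch 32) and a desk-scale profile
(256 points, one set-abstraction level, up to 50 epochs) sized for
CPU-only experimentation; both share the optimiser settings
(SGD, momentum 0.9, learning rate 0.005, weight decay 1e-4,
negative log-likelihood loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh

from .meshes import LabeledCase

# ---------------------------------------------------------------------------
# surface sampling


@dataclass
class PointCloudSample:
    """N points with unit surface normals (a 6 x N input, stored N x 6)."""

    points: np.ndarray   # (N, 3) mm
    normals: np.ndarray  # (N, 3) unit vectors

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.points.shape != self.normals.shape or self.points.ndim != 2:
            raise ValueError("points and normals must both be (N, 3)")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must have unit length")

    def __len__(self) -> int:
        return len(self.points)


def sample_point_cloud(
    mesh: trimesh.Trimesh, n_points: int = 2048, seed: int | np.random.Generator = 0
) -> PointCloudSample:
    """Area-weighted surface resampling with per-face uniform placement.

    Faces are drawn with probability proportional to their area; each
    point is placed uniformly in its face via barycentric coordinates
    and inherits the face's unit normal.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    areas = mesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    face_idx = rng.choice(len(areas), size=n_points, p=areas / total)
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    w0, w1, w2 = 1.0 - r1, r1 * (1.0 - r2), r1 * r2
    tri = mesh.triangles[face_idx]
    pts = w0[:, None] * tri[:, 0] + w1[:, None] * tri[:, 1] + w2[:, None] * tri[:, 2]
    normals = mesh.face_normals[face_idx]
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloudSample(points=pts, normals=normals)


def normalize_cloud(sample: PointCloudSample) -> PointCloudSample:
    """Centre at the centroid and scale to the unit sphere."""
    pts = sample.points - sample.points.mean(axis=0)
    scale = np.linalg.norm(pts, axis=1).max()
    if scale <= 0:
        raise ValueError("degenerate point cloud")
    return PointCloudSample(points=pts / scale, normals=sample.normals.copy())


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (full SO(3)) via a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SetAbstraction:
    n_centroids: int
    radius: float        # in normalised (unit-sphere) units
    k_neighbors: int
    widths: tuple[int, ...]


@dataclass
class NetworkConfig:
    """Architecture of the point-set classifier.

    The full profile maps the 6-d inputs through local feature widths of
    64 and a 1024-wide global descriptor, with a 3-layer perceptron head
    to the 2-class output.
    """

    n_points: int = 2048
    sa_levels: tuple[SetAbstraction, ...] = (
        SetAbstraction(256, 0.2, 32, (64, 64)),
        SetAbstraction(64, 0.4, 32, (64, 128)),
    )
    global_widths: tuple[int, ...] = (256, 1024)
    head_widths: tuple[int, ...] = (512, 256)
    n_classes: int = 2
    augment_rotation: bool = True

    def __post_init__(self) -> None:
        widths = [w for lvl in self.sa_levels for w in lvl.widths]
        widths += list(self.global_widths) + list(self.head_widths)
        if any(w <= 0 for w in widths):
            raise ValueError("all layer widths must be positive")
        if self.n_classes != 2:
            raise ValueError("the classifier is binary (stable vs growing)")

    @property
    def local_feature_width(self) -> int:
        return self.sa_levels[0].widths[-1] if self.sa_levels else self.global_widths[0]

    @property
    def global_feature_width(self) -> int:
        return self.global_widths[-1]


def desk_config(n_points: int = 256) -> NetworkConfig:
    """Scaled-down profile for CPU-only runs: fewer points, one
    set-abstraction level, same descriptor width."""
    return NetworkConfig(
        n_points=n_points,
        sa_levels=(SetAbstraction(64, 0.3, 16, (32, 64)),),
        global_widths=(128, 1024),
        head_widths=(512, 256),
    )


def paper_config() -> NetworkConfig:
    return NetworkConfig()


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    momentum: float = 0.9
    weight_decay: float = 0.0001  # L2 penalty (the conventional reading of "decay rate")
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0 or self.momentum < 0:
            raise ValueError("training parameters must be positive")


def desk_train_config(epochs: int = 50, seed: int = 0) -> TrainConfig:
    return TrainConfig(batch_size=16, epochs=epochs, seed=seed)


# ---------------------------------------------------------------------------
# layers


class _Linear:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.gW += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.gb += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.T

    def step(self, lr: float, momentum: float, weight_decay: float) -> None:
        self.vW = momentum * self.vW - lr * (self.gW + weight_decay * self.W)
        self.vb = momentum * self.vb - lr * self.gb
        self.W += self.vW
        self.b += self.vb
        self.gW[...] = 0.0
        self.gb[...] = 0.0


class _BatchNorm:
    """Normalises over every axis except the channel axis (last)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.vg = np.zeros(c)
        self.vb = np.zeros(c)
        self.gg = np.zeros(c)
        self.gb = np.zeros(c)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, axes, x.size // x.shape[-1])
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, axes, n = self._cache
        self.gg += (dy * xhat).sum(axis=axes)
        self.gb += dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * invstd
        del n
        return dx

    def step(self, lr: float, momentum: float, weight_decay: float) -> None:
        del weight_decay  # never applied to normalisation parameters
        self.vg = momentum * self.vg - lr * self.gg
        self.vb = momentum * self.vb - lr * self.gb
        self.gamma += self.vg
        self.beta += self.vb
        self.gg[...] = 0.0
        self.gb[...] = 0.0


class _SharedMLP:
    """Stack of (linear, batch-norm, ReLU) applied per point."""

    def __init__(self, widths: Sequence[int], c_in: int, rng: np.random.Generator):
        self.layers: list[tuple[_Linear, _BatchNorm]] = []
        for w in widths:
            self.layers.append((_Linear(c_in, w, rng), _BatchNorm(w)))
            c_in = w
        self._masks: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._masks = []
        for lin, bn in self.layers:
            x = bn.forward(lin.forward(x), train)
            mask = x > 0
            self._masks.append(mask)
            x = x * mask
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for (lin, bn), mask in zip(reversed(self.layers), reversed(self._masks)):
            dy = lin.backward(bn.backward(dy * mask))
        return dy

    def modules(self):
        for lin, bn in self.layers:
            yield lin
            yield bn


def _farthest_point_indices(pts: np.ndarray, m: int) -> np.ndarray:
    """Deterministic farthest-point sampling seeded at the point farthest
    from the centroid, so the selection depends only on the point set,
    not on its ordering."""
    n = len(pts)
    if m >= n:
        return np.arange(n)
    start = int(np.argmax(((pts - pts.mean(axis=0)) ** 2).sum(axis=1)))
    sel = np.empty(m, dtype=np.int64)
    sel[0] = start
    mind = ((pts - pts[start]) ** 2).sum(axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(mind))
        sel[i] = nxt
        np.minimum(mind, ((pts - pts[nxt]) ** 2).sum(axis=1), out=mind)
    return sel


def _ball_group(pts: np.ndarray, centroids: np.ndarray, radius: float, k: int) -> np.ndarray:
    """K nearest points within ``radius`` of each centroid, cyclically
    padded when fewer are available; falls back to the nearest point if
    the ball is empty."""
    d2 = ((centroids[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    order = np.argsort(d2, axis=1, kind="stable")
    r2 = radius * radius
    out = np.empty((len(centroids), k), dtype=np.int64)
    for m in range(len(centroids)):
        row = order[m]
        within = row[d2[m, row] <= r2][:k]
        if len(within) == 0:
            within = row[:1]
        out[m] = np.resize(within, k)
    return out


# ---------------------------------------------------------------------------
# network


class PointSetClassifier:
    """Hierarchical point-set network with a global max-pool descriptor."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c_prev = 3  # input point features: the surface normal
        self.sa_mlps: list[_SharedMLP] = []
        for lvl in config.sa_levels:
            self.sa_mlps.append(_SharedMLP(lvl.widths, 3 + c_prev, rng))
            c_prev = lvl.widths[-1]
        self.global_mlp = _SharedMLP(config.global_widths, 3 + c_prev, rng)
        widths = list(config.head_widths)
        c = config.global_widths[-1]
        self.head: list[tuple[_Linear, _BatchNorm]] = []
        for w in widths:
            self.head.append((_Linear(c, w, rng), _BatchNorm(w)))
            c = w
        self.head_out = _Linear(c, config.n_classes, rng)
        self._cache = None

    # -- forward -----------------------------------------------------------

    def forward(self, points: np.ndarray, normals: np.ndarray, train: bool = False) -> np.ndarray:
        """Log-probabilities, shape (B, 2), for inputs (B, N, 3) + (B, N, 3)."""
        B = points.shape[0]
        coords = points
        feats = normals
        level_caches = []
        for lvl, mlp in zip(self.config.sa_levels, self.sa_mlps):
            M, K = lvl.n_centroids, lvl.k_neighbors
            n_prev = coords.shape[1]
            grouped = np.empty((B, M, K, 3 + feats.shape[-1]))
            nbr_idx = np.empty((B, M, K), dtype=np.int64)
            new_coords = np.empty((B, M, 3))
            for b in range(B):
                fps = _farthest_point_indices(coords[b], M)
                cent = coords[b][fps]
                idx = _ball_group(coords[b], cent, lvl.radius, K)
                nbr_idx[b] = idx
                new_coords[b] = cent
                grouped[b, :, :, :3] = coords[b][idx] - cent[:, None, :]
                grouped[b, :, :, 3:] = feats[b][idx]
            out = mlp.forward(grouped, train)
            pool_idx = out.argmax(axis=2)
            pooled = np.take_along_axis(out, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]
            level_caches.append((nbr_idx, pool_idx, out.shape, n_prev, feats.shape[-1]))
            coords, feats = new_coords, pooled
        # global abstraction: one group containing every remaining point
        gin = np.concatenate([coords, feats], axis=-1)[:, None, :, :]  # (B,1,M,3+C)
        gout = self.global_mlp.forward(gin, train)
        gpool_idx = gout.argmax(axis=2)
        desc = np.take_along_axis(gout, gpool_idx[:, :, None, :], axis=2)[:, 0, 0, :]
        x = desc
        head_masks = []
        for lin, bn in self.head:
            x = bn.forward(lin.forward(x), train)
            mask = x > 0
            head_masks.append(mask)
            x = x * mask
        logits = self.head_out.forward(x)
        logp = logits - _logsumexp(logits)
        self._cache = (level_caches, gpool_idx, gout.shape, head_masks, logp, feats.shape[-1])
        return logp

    # -- backward ----------------------------------------------------------

    def backward(self, labels: np.ndarray) -> float:
        """Accumulate gradients of the mean negative log-likelihood for the
        labels of the batch the last forward pass saw; returns the loss."""
        level_caches, gpool_idx, gout_shape, head_masks, logp, c_last = self._cache
        B = logp.shape[0]
        loss = float(-logp[np.arange(B), labels].mean())
        dlogits = np.exp(logp)
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dx = self.head_out.backward(dlogits)
        for (lin, bn), mask in zip(reversed(self.head), reversed(head_masks)):
            dx = lin.backward(bn.backward(dx * mask))
        # unpool into the global MLP
        dgout = np.zeros(gout_shape)
        np.put_along_axis(dgout, gpool_idx[:, :, None, :], dx[:, None, None, :], axis=2)
        dgin = self.global_mlp.backward(dgout)[:, 0, :, :]  # (B, M, 3+C)
        dfeats = dgin[:, :, 3:]
        for (nbr_idx, pool_idx, out_shape, n_prev, c_prev), mlp in zip(
            reversed(level_caches), reversed(self.sa_mlps)
        ):
            dout = np.zeros(out_shape)
            np.put_along_axis(dout, pool_idx[:, :, None, :], dfeats[:, :, None, :], axis=2)
            dgrouped = mlp.backward(dout)  # (B, M, K, 3+c_prev)
            dprev = np.zeros((out_shape[0], n_prev, c_prev))
            dg = dgrouped[:, :, :, 3:]
            for b in range(out_shape[0]):
                np.add.at(dprev[b], nbr_idx[b].ravel(), dg[b].reshape(-1, c_prev))
            dfeats = dprev
        return loss

    # -- optimisation ------------------------------------------------------

    def modules(self):
        for mlp in self.sa_mlps:
            yield from mlp.modules()
        yield from self.global_mlp.modules()
        for lin, bn in self.head:
            yield lin
            yield bn
        yield self.head_out

    def step(self, tc: TrainConfig) -> None:
        for mod in self.modules():
            mod.step(tc.learning_rate, tc.momentum, tc.weight_decay)

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, _Linear):
                state[f"{i}.W"], state[f"{i}.b"] = mod.W, mod.b
            else:
                state[f"{i}.gamma"], state[f"{i}.beta"] = mod.gamma, mod.beta
                state[f"{i}.rm"], state[f"{i}.rv"] = mod.running_mean, mod.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, _Linear):
                mod.W, mod.b = state[f"{i}.W"], state[f"{i}.b"]
            else:
                mod.gamma, mod.beta = state[f"{i}.gamma"], state[f"{i}.beta"]
                mod.running_mean, mod.running_var = state[f"{i}.rm"], state[f"{i}.rv"]


def _logsumexp(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(logits - m).sum(axis=-1, keepdims=True))


def build_network(config: NetworkConfig, seed: int = 0) -> PointSetClassifier:
    """Initialise the classifier (He-initialised linear layers)."""
    return PointSetClassifier(config, seed=seed)


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainResult:
    model: PointSetClassifier
    loss_history: list[float] = field(default_factory=list)
    accuracy_history: list[float] = field(default_factory=list)


def _case_mesh(case: LabeledCase, use_vasculature: bool) -> trimesh.Trimesh:
    if use_vasculature:
        if case.vasculature is None:
            raise ValueError(f"case {case.case_id} has no vasculature mesh")
        return case.vasculature
    return case.dome.mesh


def train(
    model: PointSetClassifier,
    cases: Sequence[LabeledCase],
    tc: TrainConfig,
    use_vasculature: bool = False,
) -> TrainResult:
    """Minimise the negative log-likelihood with momentum SGD.

    Every epoch draws a fresh surface resampling of each case and (when
    enabled) a fresh random SO(3) rotation, then trains on shuffled
    mini-batches.  Returns the per-epoch loss and training-accuracy
    history.
    """
    labels = np.array([c.y for c in cases], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    cfg = model.config
    rng = np.random.default_rng(tc.seed)
    result = TrainResult(model=model)
    n = len(cases)
    for _epoch in range(tc.epochs):
        pts = np.empty((n, cfg.n_points, 3))
        nrm = np.empty((n, cfg.n_points, 3))
        for i, case in enumerate(cases):
            sample = sample_point_cloud(_case_mesh(case, use_vasculature), cfg.n_points, rng)
            sample = normalize_cloud(sample)
            if cfg.augment_rotation:
                R = random_rotation(rng)
                sample = PointCloudSample(points=sample.points @ R.T, normals=sample.normals @ R.T)
            pts[i], nrm[i] = sample.points, sample.normals
        order = rng.permutation(n)
        batches = [order[i : i + tc.batch_size] for i in range(0, n, tc.batch_size)]
        if len(batches) > 1 and len(batches[-1]) < 2:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches.pop()
        losses, correct = [], 0
        for idx in batches:
            logp = model.forward(pts[idx], nrm[idx], train=True)
            loss = model.backward(labels[idx])
            model.step(tc)
            losses.append(loss * len(idx))
            correct += int((logp.argmax(axis=1) == labels[idx]).sum())
        result.loss_history.append(float(np.sum(losses) / n))
        result.accuracy_history.append(correct / n)
    return result


def predict(model: PointSetClassifier, sample: PointCloudSample) -> float:
    """Probability that the shape belongs to the growing class."""
    if len(sample) != model.config.n_points:
        raise ValueError(
            f"sample has {len(sample)} points, network expects {model.config.n_points}"
        )
    sample = normalize_cloud(sample)
    logp = model.forward(sample.points[None], sample.normals[None], train=False)
    return float(np.exp(logp[0, 1]))


def predict_cases(
    model: PointSetClassifier,
    cases: Sequence[LabeledCase],
    use_vasculature: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """P(growing) per case from a fixed resampling of each surface."""
    rng = np.random.default_rng(seed)
    return np.array(
        [
            predict(
                model,
                sample_point_cloud(_case_mesh(c, use_vasculature), model.config.n_points, rng),
            )
            for c in cases
        ]
    )
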