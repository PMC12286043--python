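"""Few-shot AOI classification by feature-map reconstruction.

A small convolutional embedding maps a fixation-centered image patch to a
feature map ``Q`` of shape r×d (r = h·w spatial positions, d channels).
Each AOI class k keeps a stack of support feature maps ``S_k`` of shape
(N·r)×d built from its labeled patches.  The class score is the negative
ridge-regression residual of reconstructing ``Q`` from the rows of ``S_k``:

    W_k = argmin ||Q - W S_k||_F^2 + lam ||W||_F^2,
    err_k = ||Q - W_k S_k||_F^2 / r,
    p = softmax(-err / gamma).

The background class is never trained directly: it is assigned downstream
when the winning probability falls below a threshold.  Training combines
the cross-entropy of these probabilities with an auxiliary penalty on
cross-class support Gram blocks,

    L_aux = sum_{i != j} ||S_i S_j^T||_F^2,

which pushes the support features of different classes toward mutually
orthogonal subspaces.  Optimization is plain SGD over episodic N-shot
K-way passes, warm-started from the previous weights during interactive
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor, concat, conv2d, sgd_step
from .io import AOISchema, SchemaError

__all__ = [
    "TrainConfig", "ReconstructionResult", "LabeledPool",
    "reconstruct", "class_probabilities", "aux_loss", "oversample_pool",
    "FewShotReconstructionClassifier",
]


@dataclass(frozen=True)
class TrainConfig:
    """Architecture and optimization settings.

    Defaults follow the interactive-annotation regime: 30 SGD epochs per
    (re)fit at learning rate 1e-4 with the auxiliary loss scaled by 0.03.
    """

    patch_size: int = 64
    channels: tuple = (16, 32, 48, 48)
    strides: tuple = (2, 2, 2, 1)
    in_channels: int = 3
    epochs: int = 30
    learning_rate: float = 1e-4
    aux_scale: float = 0.03
    shots: int = 3               # support items per class per episode
    queries: int = 3             # query items per class per episode
    ridge_init: float = 1.0      # ridge penalty lam, scaled by (N·r)/d in use
    temperature_init: float = 0.02   # initial softmax temperature gamma
    learn_ridge: bool = True
    learn_temperature: bool = True
    normalize: bool = True       # L2-normalize feature-map rows
    max_support: int = 100       # support items per class kept for inference
    seed: int = 0


@dataclass
class ReconstructionResult:
    """Closed-form ridge reconstruction of a query map from class supports."""

    W: np.ndarray        # r × (N·r) coefficients
    Q_hat: np.ndarray    # r × d reconstruction
    error: float         # ||Q - Q_hat||_F^2 / r


def reconstruct(Q: np.ndarray, S: np.ndarray, lam: float = 0.0) -> ReconstructionResult:
    """Best ridge reconstruction ``W = Q S^T (S S^T + lam I)^{-1}``.

    With ``lam == 0`` and a singular Gram matrix the pseudo-inverse is
    used, yielding the minimum-norm least-squares coefficients.
    """
    Q = np.asarray(Q, dtype=float)
    S = np.asarray(S, dtype=float)
    if Q.ndim != 2 or S.ndim != 2 or Q.shape[1] != S.shape[1]:
        raise ValueError("Q (r×d) and S (N·r×d) must share the channel dimension d")
    A = S @ S.T + lam * np.eye(S.shape[0])
    W = Q @ S.T @ (np.linalg.pinv(A) if lam == 0 else np.linalg.inv(A))
    Q_hat = W @ S
    error = float(np.sum((Q - Q_hat) ** 2) / Q.shape[0])
    return ReconstructionResult(W=W, Q_hat=Q_hat, error=error)


def _reconstruction_errors(Q: np.ndarray, supports: Sequence[np.ndarray],
                           lam: float) -> np.ndarray:
    """Per-class residuals via the equivalent d×d (dual) solve."""
    Q = np.asarray(Q, dtype=float)
    errs = np.empty(len(supports))
    for k, S in enumerate(supports):
        G = S.T @ S
        if lam == 0:
            M = np.linalg.pinv(G) @ G
        else:
            M = G @ np.linalg.inv(G + lam * np.eye(G.shape[0]))
        diff = Q - Q @ M
        errs[k] = np.sum(diff ** 2) / Q.shape[0]
    return errs


def class_probabilities(Q: np.ndarray, supports: Sequence[np.ndarray],
                        lam: float = 0.1, gamma: float = 0.02) -> np.ndarray:
    """Softmax over negative reconstruction errors; sums to 1, argmax =
    argmin error, invariant under adding a constant to all errors."""
    if len(supports) == 0:
        raise ValueError("support set is empty")
    errs = _reconstruction_errors(Q, supports, lam)
    z = -errs / gamma
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def aux_loss(supports: Sequence[np.ndarray]) -> float:
    """Cross-class orthogonality penalty: sum over ordered pairs i != j of
    the squared Frobenius norm of S_i S_j^T."""
    if len(supports) < 2:
        raise ValueError("need at least two classes")
    d = supports[0].shape[1]
    if any(S.shape[1] != d for S in supports):
        raise ValueError("all support matrices must share the channel dimension")
    total = 0.0
    for i, Si in enumerate(supports):
        for j, Sj in enumerate(supports):
            if i != j:
                total += float(np.sum((Si @ Sj.T) ** 2))
    return total


class LabeledPool:
    """Patches per AOI label: an initial pool plus confirm/correct feedback.

    Background feedback is persisted at the annotation layer but never
    enters the pool, since the background class is not a training class.
    Re-annotating a fixation replaces (or removes) its pool entry instead
    of duplicating it.
    """

    def __init__(self, schema: AOISchema):
        self.schema = schema
        self._initial: dict = {name: [] for name in schema.aoi_names}
        self._feedback: dict = {}       # fixation_id -> (label, patch)
        self.new_since_fit = 0

    def add(self, label: str, patch: np.ndarray) -> None:
        """Add an initial-pool patch for an AOI class."""
        if label not in self._initial:
            raise SchemaError(f"label {label!r} is not an AOI class")
        self._initial[label].append(np.asarray(patch))
        self.new_since_fit += 1

    def set_feedback(self, fixation_id: int, label: str, patch: np.ndarray) -> str:
        """Record feedback for a fixation; returns one of
        ``added | replaced | removed | ignored``."""
        self.schema.validate_label(label)
        if label == self.schema.bg_name:
            if fixation_id in self._feedback:
                del self._feedback[fixation_id]
                return "removed"
            return "ignored"
        status = "replaced" if fixation_id in self._feedback else "added"
        self._feedback[fixation_id] = (label, np.asarray(patch))
        if status == "added":
            self.new_since_fit += 1
        return status

    def items(self, label: str) -> list:
        out = list(self._initial[label])
        out.extend(p for (lab, p) in self._feedback.values() if lab == label)
        return out

    def counts(self) -> dict:
        return {name: len(self.items(name)) for name in self.schema.aoi_names}

    def as_dict(self) -> dict:
        return {name: self.items(name) for name in self.schema.aoi_names}

    def mark_fitted(self) -> None:
        self.new_since_fit = 0

    def __len__(self) -> int:
        return sum(self.counts().values())


def oversample_pool(pool: Mapping[str, Sequence], n_target: int,
                    seed: int = 0) -> dict:
    """Balance a label->patches mapping to exactly ``n_target`` per class.

    Classes below target gain seeded uniform-with-replacement duplicates of
    their own items; classes above target are subsampled without
    replacement.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for label in pool:
        items = list(pool[label])
        n = len(items)
        if n == 0:
            raise ValueError(f"class {label!r} has no samples")
        if n < n_target:
            extra = rng.choice(n, size=n_target - n, replace=True)
            out[label] = items + [items[i] for i in extra]
        elif n > n_target:
            keep = rng.choice(n, size=n_target, replace=False)
            out[label] = [items[i] for i in keep]
        else:
            out[label] = items
    return out


class FewShotReconstructionClassifier:
    """The trainable reconstruction classifier over an AOI schema.

    Weights live in a 4-block strided conv embedding plus two learnable
    scalars (log ridge penalty, log temperature).  ``fit`` runs episodic
    SGD on a labeled pool; ``predict_proba`` scores patches against the
    cached per-class support feature maps.
    """

    def __init__(self, schema: AOISchema, config: TrainConfig | None = None,
                 seed: int | None = None):
        self.schema = schema
        self.config = config or TrainConfig()
        if seed is not None:
            self.config = replace(self.config, seed=seed)
        self._rng = np.random.default_rng(self.config.seed)
        self.version = 0
        self._init_params()
        self.supports_: list | None = None

    # -- parameters --------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.params: dict = {}
        c_in = cfg.in_channels
        for i, (c_out, _s) in enumerate(zip(cfg.channels, cfg.strides)):
            fan_in = c_in * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
            self.params[f"conv{i}_w"] = Tensor(w, requires_grad=True)
            self.params[f"conv{i}_b"] = Tensor(np.zeros(c_out), requires_grad=True)
            c_in = c_out
        self.params["log_ridge"] = Tensor(np.log(cfg.ridge_init), requires_grad=True)
        self.params["log_temp"] = Tensor(np.log(cfg.temperature_init), requires_grad=True)

    def _trainable(self) -> list:
        cfg = self.config
        out = []
        for name, p in self.params.items():
            if name == "log_ridge" and not cfg.learn_ridge:
                continue
            if name == "log_temp" and not cfg.learn_temperature:
                continue
            out.append(p)
        return out

    @property
    def ridge(self) -> float:
        return float(np.exp(self.params["log_ridge"].data))

    @property
    def temperature(self) -> float:
        return float(np.exp(self.params["log_temp"].data))

    def get_weights(self) -> dict:
        return {name: p.data.copy() for name, p in self.params.items()}

    def set_weights(self, weights: Mapping[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            p.data = np.array(weights[name], dtype=float).reshape(p.data.shape)
        self.supports_ = None

    # -- embedding ---------------------------------------------------------

    def _prepare(self, patches) -> np.ndarray:
        """Stack patches into a float batch (B, C, H, W) in [0, 1]."""
        cfg = self.config
        arr = np.asarray(patches, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :, None]
        elif arr.ndim == 3 and arr.shape[-1] in (1, 3):
            arr = arr[None]
        if arr.shape[1] != cfg.patch_size or arr.shape[2] != cfg.patch_size:
            raise ValueError(
                f"expected {cfg.patch_size}×{cfg.patch_size} patches, got "
                f"{arr.shape[1]}×{arr.shape[2]}")
        if arr.shape[-1] == 1:
            arr = np.repeat(arr, cfg.in_channels, axis=-1)
        if arr.max() > 1.5:
            arr = arr / 255.0
        return arr.transpose(0, 3, 1, 2)

    def _forward(self, x: np.ndarray) -> Tensor:
        """Conv stack -> feature maps (B, r, d), optionally row-normalized."""
        cfg = self.config
        t = Tensor(x)
        for i, stride in enumerate(cfg.strides):
            t = conv2d(t, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"],
                       stride=stride, pad=1)
            t = t.relu()
        b, d, h, w = t.shape
        t = t.reshape(b, d, h * w).transpose(0, 2, 1)        # (B, r, d)
        if cfg.normalize:
            norm = (t.square().sum(axis=2, keepdims=True) + 1e-8).sqrt()
            t = t / norm
        return t

    def embed(self, patch) -> np.ndarray:
        """Feature map (r × d) of one patch under the current weights."""
        return self._forward(self._prepare(patch)).data[0]

    def embed_batch(self, patches, chunk: int = 64) -> np.ndarray:
        x = self._prepare(patches)
        if x.shape[0] <= chunk:
            return self._forward(x).data
        # bound im2col memory for large support pools
        return np.concatenate([self._forward(x[i:i + chunk]).data
                               for i in range(0, x.shape[0], chunk)])

    # -- training ----------------------------------------------------------

    def _sample_episode(self, pool_dict: dict, rng) -> tuple:
        cfg = self.config
        xs, sup_slices, qry_rows, qry_labels = [], [], [], []
        row = 0
        for k, label in enumerate(self.schema.aoi_names):
            items = pool_dict[label]
            n = len(items)
            if n == 0:
                raise ValueError(f"class {label!r} has no training samples")
            if n >= cfg.shots + cfg.queries:
                perm = rng.permutation(n)
                s_idx = perm[:cfg.shots]
                q_idx = perm[cfg.shots:cfg.shots + cfg.queries]
            else:
                s_idx = rng.choice(n, size=cfg.shots, replace=True)
                q_idx = rng.choice(n, size=cfg.queries, replace=True)
            for i in s_idx:
                xs.append(items[i])
            sup_slices.append((row, row + cfg.shots))
            row += cfg.shots
            for i in q_idx:
                xs.append(items[i])
                qry_rows.append(row)
                qry_labels.append(k)
                row += 1
        return np.stack([np.asarray(p) for p in xs]), sup_slices, qry_rows, qry_labels

    def _episode_loss(self, fmaps: Tensor, sup_slices, qry_rows, qry_labels):
        cfg = self.config
        K = self.schema.n_classes
        b, r, d = fmaps.shape
        lam = self.params["log_ridge"].exp()
        gamma = self.params["log_temp"].exp()
        eye = np.eye(d)
        supports = []
        for (a, bb) in sup_slices:
            supports.append(fmaps[a:bb].reshape((bb - a) * r, d))
        Q = fmaps[np.array(qry_rows)]                  # (Bq, r, d)
        nq = len(qry_rows)
        Qflat = Q.reshape(nq * r, d)
        cols = []
        for S in supports:
            n_rows = S.shape[0]
            G = S.T @ S
            # ridge scaled by (N·r)/d keeps the shrinkage commensurate with
            # the Gram spectrum as the support stack grows
            M = G @ (G + (lam * (n_rows / d)) * Tensor(eye)).inv()
            diff = Qflat - Qflat @ M
            err = diff.square().reshape(nq, r * d).sum(axis=1) * (1.0 / r)
            cols.append(err.reshape(nq, 1))
        errors = concat(cols, axis=1)                  # (Bq, K)
        logits = (errors * (-1.0)) / gamma
        shift = Tensor(logits.data.max(axis=1, keepdims=True))
        z = logits - shift
        lse = z.exp().sum(axis=1, keepdims=True).log()
        logp = z - lse
        onehot = np.zeros((nq, K))
        onehot[np.arange(nq), qry_labels] = 1.0
        ce = (logp * Tensor(onehot)).sum() * (-1.0 / nq)
        # per-element mean of the cross-class Gram blocks: same zero set as
        # the literal pairwise sum, but commensurate with the cross-entropy
        # regardless of support-stack size
        aux = None
        for i in range(K):
            for j in range(i + 1, K):
                term = (supports[i] @ supports[j].T).square().mean() * 2.0
                aux = term if aux is None else aux + term
        aux = aux * (1.0 / (K * (K - 1)))
        loss = ce + aux * cfg.aux_scale
        return loss, ce, aux

    def training_loss(self, query_patches, labels, support_patches_by_class) -> dict:
        """Loss components for an explicit episode, without a gradient step.

        Returns ``{"total", "cross_entropy", "aux"}`` computed with the
        current weights.
        """
        cfg = self.config
        sup_maps = [self.embed_batch(np.stack([np.asarray(p) for p in ps]))
                    for ps in support_patches_by_class]
        supports = [S.reshape(-1, S.shape[-1]) for S in sup_maps]
        ce_sum = 0.0
        for patch, lab in zip(query_patches, labels):
            k = self.schema.index(lab) if isinstance(lab, str) else int(lab)
            if not 0 <= k < self.schema.n_classes:
                raise SchemaError(f"label {lab!r} outside schema")
            p = self._probabilities(self.embed(patch), supports)
            ce_sum += -np.log(p[k])
        ce = ce_sum / len(query_patches)
        aux = aux_loss(supports)
        K = len(supports)
        pair_elems = sum(supports[i].shape[0] * supports[j].shape[0]
                         for i in range(K) for j in range(K) if i != j)
        aux_mean = aux / pair_elems
        return {"total": ce + cfg.aux_scale * aux_mean, "cross_entropy": ce,
                "aux": aux, "aux_mean": aux_mean}

    def fit(self, pool: LabeledPool | Mapping[str, Sequence],
            init: Mapping[str, np.ndarray] | None = None,
            epochs: int | None = None) -> "FewShotReconstructionClassifier":
        """Episodic SGD over the pool; warm-starts from ``init`` if given.

        Deterministic given the configured seed and the fit counter (each
        retrain consumes a fresh, reproducible RNG stream).
        """
        cfg = self.config
        pool_dict = pool.as_dict() if isinstance(pool, LabeledPool) else dict(pool)
        for label in self.schema.aoi_names:
            if not pool_dict.get(label):
                raise ValueError(f"class {label!r} has no training samples")
        if init is not None:
            self.set_weights(init)
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng([cfg.seed, self.version])
        for _ in range(n_epochs):
            x, sup_slices, qry_rows, qry_labels = self._sample_episode(pool_dict, rng)
            fmaps = self._forward(self._prepare(x))
            loss, _, _ = self._episode_loss(fmaps, sup_slices, qry_rows, qry_labels)
            loss.backward()
            sgd_step(self._trainable(), cfg.learning_rate)
        self.version += 1
        self.set_supports(pool_dict)
        if isinstance(pool, LabeledPool):
            pool.mark_fitted()
        return self

    # -- inference ---------------------------------------------------------

    def set_supports(self, pool: LabeledPool | Mapping[str, Sequence]) -> None:
        """Cache per-class support feature maps for inference.

        Keeps at most ``max_support`` items per class (the most recent
        ones), mirroring the capped-shot training regime.
        """
        pool_dict = pool.as_dict() if isinstance(pool, LabeledPool) else dict(pool)
        supports = []
        for label in self.schema.aoi_names:
            items = pool_dict[label]
            if not items:
                raise ValueError(f"class {label!r} has no support samples")
            items = items[-self.config.max_support:]
            maps = self.embed_batch(np.stack([np.asarray(p) for p in items]))
            supports.append(maps.reshape(-1, maps.shape[-1]))
        self.supports_ = supports

    def _probabilities(self, fmap: np.ndarray, supports) -> np.ndarray:
        """Softmax over negative errors with the size-scaled ridge
        lam_eff = lam · (N·r)/d per class."""
        d = fmap.shape[1]
        errs = np.empty(len(supports))
        for k, S in enumerate(supports):
            lam_eff = self.ridge * S.shape[0] / d
            errs[k] = _reconstruction_errors(fmap, [S], lam_eff)[0]
        z = -errs / self.temperature
        z -= z.max()
        e = np.exp(z)
        return e / e.sum()

    def predict_proba(self, patches) -> np.ndarray:
        """Class probabilities (B × K) against the cached supports."""
        if self.supports_ is None:
            raise RuntimeError("no support set: call fit() or set_supports() first")
        fmaps = self.embed_batch(patches)
        out = np.empty((fmaps.shape[0], self.schema.n_classes))
        for i in range(fmaps.shape[0]):
            out[i] = self._probabilities(fmaps[i], self.supports_)
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights, scalars, config and schema fingerprint."""
        meta = {f"param_{k}": v.data for k, v in self.params.items()}
        np.savez(path,
                 schema_labels=np.array(self.schema.labels),
                 version=np.array(self.version),
                 config=np.array(repr(asdict(self.config))),
                 **meta)

    @classmethod
    def load(cls, path, schema: AOISchema) -> "FewShotReconstructionClassifier":
        with np.load(path, allow_pickle=False) as npz:
            stored = tuple(npz["schema_labels"])
            if stored != schema.labels:
                raise SchemaError(
                    f"checkpoint was trained for schema {stored}, not {schema.labels}")
            import ast
            config = TrainConfig(**ast.literal_eval(str(npz["config"])))
            model = cls(schema, config)
            model.version = int(npz["version"])
            for name, p in model.params.items():
                p.data = npz[f"param_{name}"].reshape(p.data.shape).astype(float)
        return model
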