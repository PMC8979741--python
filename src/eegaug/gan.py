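"""Conditional Wasserstein GAN for labeled feature vectors, plus the
distribution-similarity quality gate used before augmentation.

The generator maps (Gaussian noise, one-hot label) to a feature vector in
the [-1, 1] normalised feature space (tanh output); the critic maps
(feature vector, one-hot label) to an unbounded realness score.  Training
follows the WGAN-GP recipe: ``n_critic`` critic updates per generator
update, the critic minimising ``E[D(fake)] - E[D(real)]`` plus a gradient
penalty ``lambda * (||grad_x D(x_hat)|| - 1)^2`` on random interpolates,
the generator maximising ``E[D(fake)]``.  Because the critic is a ReLU
network with a linear head, the penalty's parameter gradient has an exact
closed form (second derivatives of ReLU vanish almost everywhere): with
backward signals ``s_l = d out / d z_l`` and a tangent pass
``q_l = (q_{l-1} W_l) * mask_l`` seeded by ``q_0 = dP/dg``, the weight
gradient is ``dP/dW_l = q_{l-1}^T s_l`` and bias gradients vanish.

The usual visual check (PCA scatter of real vs generated data) is
operationalised as a quantitative gate: squared maximum mean discrepancy
(RBF kernel, median-heuristic bandwidth) between real and generated
vectors, passed iff it does not exceed the 95th percentile of the MMD
between random half-splits of the real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mlp import MLP, Adam

__all__ = [
    "CWGANConfig",
    "ConditionalWGAN",
    "QualityReport",
    "mmd2",
    "quality_gate",
    "augment_trainset",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class CWGANConfig:
    """Hyperparameters of the conditional WGAN.

    ``steps`` counts generator updates (500 by default); ``epochs`` is an
    alternative way to express the same budget and converts to
    ``epochs * ceil(n / batch_size)`` generator updates when ``steps`` is
    set to None.
    """

    latent_dim: int = 100
    gen_hidden: tuple[int, ...] = (256, 512)
    critic_hidden: tuple[int, ...] = (512, 256)
    n_critic: int = 5
    gp_lambda: float = 10.0
    learning_rate: float = 2e-4
    batch_size: int = 32
    steps: int | None = 500
    epochs: int = 10
    betas: tuple[float, float] = (0.5, 0.9)
    seed: int = 0

    def validate(self) -> None:
        for name in ("latent_dim", "n_critic", "batch_size", "epochs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.steps is not None and self.steps < 1:
            raise ValueError("steps must be >= 1 (or None to derive from epochs)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")

    def resolve_steps(self, n: int) -> int:
        if self.steps is not None:
            return int(self.steps)
        return int(self.epochs) * int(np.ceil(n / self.batch_size))


def _one_hot(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    out = np.zeros((y.size, 2))
    out[np.arange(y.size), y] = 1.0
    return out


class ConditionalWGAN:
    """Conditional WGAN-GP over normalised feature vectors.

    Typical use::

        model = ConditionalWGAN(CWGANConfig(seed=0))
        model.fit(X_norm, y)          # X_norm in [-1, 1], y in {0, 1}
        fake, labels = model.sample(1000, label=1)
    """

    def __init__(self, config: CWGANConfig | None = None):
        self.config = config or CWGANConfig()
        self.config.validate()
        self.generator_: MLP | None = None
        self.critic_: MLP | None = None
        self.loss_history_: pd.DataFrame | None = None
        self.scaler = None          # optional FeatureScaler for de-normalisation
        self.condition_name: str | None = None
        self._rng: np.random.Generator | None = None
        self._d: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, scaler=None,
            condition_name: str | None = None) -> "ConditionalWGAN":
        """Train on normalised features ``X`` (n x d) with binary labels."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n, d) with one label per row")
        n, d = X.shape
        if n < cfg.batch_size:
            raise ValueError(
                f"need at least batch_size={cfg.batch_size} rows, got {n}"
            )
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        self.scaler = scaler
        self.condition_name = condition_name
        self._d = d
        rng = np.random.default_rng(cfg.seed)
        self._rng = rng
        gen = MLP((cfg.latent_dim + 2, *cfg.gen_hidden, d), rng,
                  out_activation="tanh")
        critic = MLP((d + 2, *cfg.critic_hidden, 1), rng)
        g_opt = Adam(gen.parameters(), lr=cfg.learning_rate, betas=cfg.betas)
        c_opt = Adam(critic.parameters(), lr=cfg.learning_rate, betas=cfg.betas)
        Y1h = _one_hot(y)
        B = cfg.batch_size
        steps = cfg.resolve_steps(n)
        history = np.empty((steps, 3))
        for step in range(steps):
            c_loss = gap = 0.0
            for _ in range(cfg.n_critic):
                idx = rng.integers(0, n, B)
                x_real, y_b = X[idx], Y1h[idx]
                z = rng.standard_normal((B, cfg.latent_dim))
                fake, _ = gen.forward(np.hstack([z, y_b]))
                out_r, cache_r = critic.forward(np.hstack([x_real, y_b]))
                out_f, cache_f = critic.forward(np.hstack([fake, y_b]))
                dW_r, db_r, _ = critic.backward(cache_r, np.full((B, 1), -1.0 / B))
                dW_f, db_f, _ = critic.backward(cache_f, np.full((B, 1), 1.0 / B))
                dWs = [a + b for a, b in zip(dW_r, dW_f)]
                dbs = [a + b for a, b in zip(db_r, db_f)]
                penalty = 0.0
                if cfg.gp_lambda > 0:
                    eps = rng.random((B, 1))
                    x_hat = eps * x_real + (1.0 - eps) * fake
                    penalty = self._gp_grads(
                        critic, x_hat, y_b, dWs, cfg.gp_lambda
                    )
                c_loss = float(out_f.mean() - out_r.mean() + cfg.gp_lambda * penalty)
                gap = float(out_r.mean() - out_f.mean())
                if not np.isfinite(c_loss):
                    raise DivergenceError(f"critic loss non-finite at step {step}")
                c_opt.step(dWs + dbs)
            # generator update: maximise E[D(fake)]
            idx = rng.integers(0, n, B)
            y_b = Y1h[idx]
            z = rng.standard_normal((B, cfg.latent_dim))
            fake, g_cache = gen.forward(np.hstack([z, y_b]))
            out_f, c_cache = critic.forward(np.hstack([fake, y_b]))
            g_loss = float(-out_f.mean())
            if not np.isfinite(g_loss):
                raise DivergenceError(f"generator loss non-finite at step {step}")
            _, _, d_in = critic.backward(c_cache, np.full((B, 1), -1.0 / B))
            gW, gb, _ = gen.backward(g_cache, d_in[:, :d])
            g_opt.step(gW + gb)
            history[step] = (c_loss, g_loss, gap)
        self.generator_ = gen
        self.critic_ = critic
        self.loss_history_ = pd.DataFrame(
            history, columns=["critic_loss", "gen_loss", "score_gap"]
        )
        self.loss_history_.insert(0, "step", np.arange(steps))
        return self

    @staticmethod
    def _gp_grads(critic: MLP, x_hat: np.ndarray, y_b: np.ndarray,
                  dWs: list[np.ndarray], gp_lambda: float) -> float:
        """Accumulate the gradient-penalty weight gradients into ``dWs``
        (scaled by ``gp_lambda``) and return the raw penalty value.

        The gradient is taken w.r.t. the feature part of the interpolate;
        the one-hot label dims are held fixed.
        """
        B, d = x_hat.shape
        _, cache = critic.forward(np.hstack([x_hat, y_b]))
        g, s_list = critic.input_jacobian_vectors(cache)
        gx = g[:, :d]
        norm = np.sqrt((gx**2).sum(axis=1) + 1e-12)
        penalty = float(((norm - 1.0) ** 2).mean())
        coef = (2.0 * (norm - 1.0) / norm / B)[:, None]
        q = np.hstack([coef * gx, np.zeros((B, y_b.shape[1]))])
        masks = cache["masks"]
        for l in range(critic.n_layers):
            dWs[l] += gp_lambda * (q.T @ s_list[l + 1])
            if l < critic.n_layers - 1:
                q = (q @ critic.W[l]) * masks[l + 1]
        return penalty

    def sample(self, n: int, label: int,
               rng: np.random.Generator | None = None):
        """Draw ``n`` generated feature vectors conditioned on ``label``.

        Returns ``(X_fake, labels)`` in the normalised [-1, 1] space.  With
        ``rng=None`` the model's internal stream is used (and advanced).
        """
        if self.generator_ is None:
            raise RuntimeError("model is not trained; call fit() first")
        if n < 1:
            raise ValueError(f"need n >= 1 generated rows, got {n}")
        if label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        rng = rng if rng is not None else self._rng
        z = rng.standard_normal((n, self.config.latent_dim))
        y = np.full(n, int(label))
        fake, _ = self.generator_.forward(np.hstack([z, _one_hot(y)]))
        return fake, y


# --------------------------------------------------------------------- MMD


def _rbf_gamma(real: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise distance of the real data."""
    from sklearn.metrics import euclidean_distances

    d = euclidean_distances(real)
    med = float(np.median(d[np.triu_indices_from(d, k=1)])) if d.shape[0] > 1 else 0.0
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med**2)


def mmd2(X: np.ndarray, Y: np.ndarray, gamma: float | None = None) -> float:
    """Biased (V-statistic) squared MMD with an RBF kernel; always >= 0.

    With ``gamma=None`` the bandwidth is the median pairwise distance of
    ``X`` (the "real" sample by convention).
    """
    from sklearn.metrics.pairwise import rbf_kernel

    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if gamma is None:
        gamma = _rbf_gamma(X)
    kxx = rbf_kernel(X, X, gamma=gamma).mean()
    kyy = rbf_kernel(Y, Y, gamma=gamma).mean()
    kxy = rbf_kernel(X, Y, gamma=gamma).mean()
    return float(max(kxx + kyy - 2.0 * kxy, 0.0))


@dataclass
class QualityReport:
    """Outcome of the generated-data quality gate.

    ``pca_real``/``pca_fake`` are the projections onto the two leading
    principal components (Z1, Z2) of the real data; ``distance`` is the
    squared MMD on the full feature vectors.
    """

    pca_real: np.ndarray
    pca_fake: np.ndarray
    distance: float
    threshold: float
    passed: bool
    gamma: float = float("nan")


def quality_gate(real: np.ndarray, fake: np.ndarray, seed: int = 0,
                 n_resamples: int = 200, quantile: float = 0.95) -> QualityReport:
    """Gate generated data by distribution similarity to the real data.

    The pass threshold is calibrated as the ``quantile`` (default 95th
    percentile) of the squared MMD between seeded random half-splits of the
    real data; rows are put in a canonical (lexicographic) order first so
    the threshold does not depend on row order.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics.pairwise import rbf_kernel

    real = np.atleast_2d(np.asarray(real, dtype=float))
    fake = np.atleast_2d(np.asarray(fake, dtype=float))
    n, m = real.shape[0], fake.shape[0]
    if n < 2 or m < 2:
        raise ValueError(f"need >= 2 rows on each side, got {n} real / {m} fake")
    # canonical row order makes every number bit-invariant to input row order
    order = np.lexsort(real.T[::-1])
    rs = real[order]
    gamma = _rbf_gamma(rs)
    distance = mmd2(rs, fake, gamma)
    # threshold: null distribution of MMD between half-splits of the real data
    K = rbf_kernel(rs, rs, gamma=gamma)
    rng = np.random.default_rng(seed)
    half = n // 2
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        perm = rng.permutation(n)
        a, b = perm[:half], perm[half : 2 * half]
        kaa = K[np.ix_(a, a)].mean()
        kbb = K[np.ix_(b, b)].mean()
        kab = K[np.ix_(a, b)].mean()
        null[i] = max(kaa + kbb - 2.0 * kab, 0.0)
    threshold = float(np.quantile(null, quantile))
    n_comp = min(2, real.shape[1], n)
    pca = PCA(n_components=n_comp).fit(real)
    return QualityReport(
        pca_real=pca.transform(real),
        pca_fake=pca.transform(fake),
        distance=distance,
        threshold=threshold,
        passed=bool(distance <= threshold),
        gamma=gamma,
    )


def augment_trainset(train_features, train_labels, model: ConditionalWGAN,
                     n_fake: int, gate: bool = True, seed: int = 0):
    """Append gated generated rows to a training set.

    ``train_features`` are on the original feature scale (the model's
    stored scaler maps to/from the generator's [-1, 1] space);
    ``train_labels`` is the binary label vector for the model's condition
    target.  Generated labels are balanced in proportion to the training
    labels.  If the gate fails, the inputs are returned unchanged together
    with the failing report.

    Returns ``(features, labels, report)``.
    """
    feats = pd.DataFrame(train_features)
    y = np.asarray(train_labels).astype(int).ravel()
    if len(feats) != y.size:
        raise ValueError("feature and label row counts disagree")
    if n_fake < 0:
        raise ValueError("n_fake must be >= 0")
    if n_fake == 0:
        report = QualityReport(
            pca_real=np.empty((0, 2)), pca_fake=np.empty((0, 2)),
            distance=0.0, threshold=0.0, passed=True,
        )
        return feats.copy(), y.copy(), report
    if model.scaler is not None:
        Xn = model.scaler.transform(feats)
    else:
        Xn = feats.to_numpy(dtype=float)
    n1 = int(round(n_fake * float(np.mean(y == 1))))
    n0 = n_fake - n1
    rng = np.random.default_rng(seed)
    parts_x, parts_y = [], []
    for label, count in ((0, n0), (1, n1)):
        if count > 0:
            fx, fy = model.sample(count, label, rng=rng)
            parts_x.append(fx)
            parts_y.append(fy)
    fake = np.vstack(parts_x)
    fake_y = np.concatenate(parts_y)
    report = quality_gate(Xn, fake, seed=seed) if gate else QualityReport(
        pca_real=np.empty((0, 2)), pca_fake=np.empty((0, 2)),
        distance=0.0, threshold=0.0, passed=True,
    )
    if not report.passed:
        return feats.copy(), y.copy(), report
    fake_scale = (
        model.scaler.inverse_transform(fake) if model.scaler is not None else fake
    )
    out_feats = pd.concat(
        [feats, pd.DataFrame(fake_scale, columns=feats.columns)],
        ignore_index=True,
    )
    out_y = np.concatenate([y, fake_y])
    return out_feats, out_y, report


def plot_quality(report: QualityReport, path=None):
    """Scatter of real vs generated data in the leading PCA plane
    (Z1, Z2).  Requires matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.pca_real[:, 0], report.pca_real[:, 1],
               s=8, alpha=0.5, label="real")
    if len(report.pca_fake):
        ax.scatter(report.pca_fake[:, 0], report.pca_fake[:, 1],
                   s=8, alpha=0.5, label="generated")
    ax.set_xlabel("Z1")
    ax.set_ylabel("Z2")
    ax.legend()
    ax.set_title(f"MMD$^2$ = {report.distance:.4g} "
                 f"(threshold {report.threshold:.4g})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
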