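"""Per-space Siamese signaturizer: architecture, losses, training, inference.

The signaturizer for a target space S_i is a feed-forward network applied
identically to the three members of a molecule triplet.  Input is the
stacked covariates matrix (one 128-wide block per contributing space, NaN
for absent blocks, zero-filled at the network input); output is a 128-d
embedding, Tanh-activated and L2-normalized so Euclidean distances are
comparable across spaces.  Training combines three terms:

* a triplet loss with margin 1 on Euclidean embedding distances,
* a self mean-squared error tying the anchor embedding under signature
  dropout to the embedding computed from the S_i block alone, and
* a global orthogonal regularization (GOR) term pushing anchor-negative
  inner products toward the orthogonality moments, spreading embeddings
  over the unit sphere.

Signature dropout masks each non-target covariate block with the
probability that the block is *available* for molecules outside S_i (the
realistic prediction scenario), while the S_i block itself is dropped with
a probability oscillating between 0 and 1 over the training iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .store import CovariatesMatrix, SignatureSpace, Store, stack_covariates

__all__ = [
    "layer_sizes",
    "SiameseSpec",
    "DropoutProfile",
    "triplet_loss",
    "self_mse_loss",
    "gor_penalty",
    "embedding_gradients",
    "default_epochs",
    "dropout_profile",
    "oscillation_schedule",
    "apply_signature_dropout",
    "SpaceSignaturizer",
    "train",
    "predict",
]

EPOCH_THRESHOLD = 30_000  # molecules; below -> 5 epochs, at/above -> 2


def layer_sizes(m: int, d: int = 128) -> tuple:
    """Hidden layer widths for m covariate blocks of width d.

    Interpolates between input and output width, saturating at (512, 256):
    h1 = min(512, m*d/2), h2 = min(256, m*d/4).  For m = 7 this gives
    (448, 224); for the full 25-block input, (512, 256).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return int(min(512, m * d // 2)), int(min(256, m * d // 4))


@dataclass
class SiameseSpec:
    """Hyperparameters of one signaturizer network."""

    d_in: int = 0
    d_out: int = 128
    hidden: tuple | None = None
    input_noise_sd: float = 0.1
    alpha_dropout: float = 0.2
    margin: float = 1.0
    gor_alpha: float = 1.0
    learning_rate: float = 1e-4
    epochs: int | None = None
    oscillation_cycles_per_epoch: int = 5000
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class DropoutProfile:
    """Per-block keep probabilities estimated from not-in-S_i molecules.

    The target space's own block is governed by the oscillation schedule,
    not this profile.
    """

    block_ids: list
    keep_probability: np.ndarray
    fallback_global: bool = False

    def __post_init__(self) -> None:
        self.keep_probability = np.asarray(self.keep_probability, dtype=float)
        if np.any((self.keep_probability < 0) | (self.keep_probability > 1)):
            raise ValueError("keep probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# loss components (pure reference forms; training uses equivalent vectorized
# internals with analytic gradients)


def triplet_loss(e_a, e_p, e_n, margin: float = 1.0) -> float:
    """max(0, ||e_a - e_p|| - ||e_a - e_n|| + margin), Euclidean."""
    e_a, e_p, e_n = (np.asarray(e) for e in (e_a, e_p, e_n))
    if not (e_a.shape == e_p.shape == e_n.shape):
        raise ValueError("embedding dimension mismatch")
    d_ap = np.linalg.norm(e_a - e_p, axis=-1)
    d_an = np.linalg.norm(e_a - e_n, axis=-1)
    return float(np.mean(np.maximum(0.0, d_ap - d_an + margin)))


def self_mse_loss(e_dropped, e_only) -> float:
    """Mean squared componentwise difference between the two anchor embeddings."""
    e_dropped, e_only = np.asarray(e_dropped), np.asarray(e_only)
    if e_dropped.shape != e_only.shape:
        raise ValueError("embedding dimension mismatch")
    return float(np.mean((e_dropped - e_only) ** 2))


def gor_penalty(e_anchors, e_negatives, d: int = 128) -> float:
    """Global orthogonal regularization: M1^2 + max(0, M2 - 1/d).

    M1 and M2 are the first and second moments of anchor-negative inner
    products; the penalty vanishes when non-matching embeddings behave
    like random unit vectors in d dimensions.
    """
    e_anchors = np.atleast_2d(np.asarray(e_anchors, dtype=float))
    e_negatives = np.atleast_2d(np.asarray(e_negatives, dtype=float))
    if e_anchors.shape != e_negatives.shape or e_anchors.shape[0] == 0:
        raise ValueError("batches must be non-empty and of equal shape")
    s = np.sum(e_anchors * e_negatives, axis=1)
    m1 = s.mean()
    m2 = (s**2).mean()
    return float(m1**2 + max(0.0, m2 - 1.0 / d))


def embedding_gradients(e_a, e_p, e_n, e_t, margin: float = 1.0, gor_alpha: float = 1.0):
    """Analytic gradients of the combined loss at the three embeddings.

    Total loss = mean triplet hinge + self-MSE against the stop-gradient
    target ``e_t`` + gor_alpha * GOR over anchor-negative pairs.  Returns
    (g_anchor, g_positive, g_negative, batch statistics).
    """
    B, D = e_a.shape
    eps = 1e-12
    diff_ap = e_a - e_p
    diff_an = e_a - e_n
    d_ap = np.maximum(np.linalg.norm(diff_ap, axis=1), eps)
    d_an = np.maximum(np.linalg.norm(diff_an, axis=1), eps)
    viol = d_ap - d_an + margin
    active = viol > 0
    l_trip = float(np.mean(np.maximum(viol, 0.0)))

    g_a = np.zeros_like(e_a)
    g_p = np.zeros_like(e_p)
    g_n = np.zeros_like(e_n)
    w = active[:, None] / B
    g_a += w * (diff_ap / d_ap[:, None] - diff_an / d_an[:, None])
    g_p += -w * diff_ap / d_ap[:, None]
    g_n += w * diff_an / d_an[:, None]

    diff_t = e_a - e_t
    l_mse = float(np.mean(diff_t**2))
    g_a += 2.0 * diff_t / (B * D)

    s = np.sum(e_a * e_n, axis=1)
    m1, m2 = s.mean(), (s**2).mean()
    l_gor = float(m1**2 + max(0.0, m2 - 1.0 / D))
    ds = np.full(B, 2.0 * m1 / B) + (2.0 * s / B if m2 > 1.0 / D else 0.0)
    g_a += gor_alpha * ds[:, None] * e_n
    g_n += gor_alpha * ds[:, None] * e_a

    stats = {
        "loss": l_trip + l_mse + gor_alpha * l_gor,
        "triplet": l_trip,
        "mse": l_mse,
        "gor": l_gor,
        "acc": float(np.mean(d_ap < d_an)),
    }
    return g_a, g_p, g_n, stats


def default_epochs(n_molecules: int) -> int:
    """Training length rule: 5 epochs below 30,000 molecules, else 2."""
    return 5 if n_molecules < EPOCH_THRESHOLD else 2


# ---------------------------------------------------------------------------
# signature dropout


def dropout_profile(
    store: Store, target_space: str, block_ids: list | None = None
) -> DropoutProfile:
    """Keep probability per block = availability among not-in-S_i molecules.

    If every molecule of the universe belongs to S_i the profile falls back
    to global coverage (flagged).
    """
    if target_space not in store:
        raise KeyError(target_space)
    if block_ids is None:
        block_ids = store.space_ids
    target_keys = set(store[target_space].keys.tolist())
    outside = [k for k in store.universe() if k not in target_keys]
    fallback = not outside
    pool = outside if outside else store.universe()
    keep = np.zeros(len(block_ids))
    for j, sid in enumerate(block_ids):
        have = set(store[sid].keys.tolist()) if sid in store else set()
        keep[j] = sum(1 for k in pool if k in have) / len(pool)
    return DropoutProfile(
        block_ids=list(block_ids), keep_probability=keep, fallback_global=fallback
    )


def oscillation_schedule(step: int, steps_per_epoch: int, cycles: int = 5000) -> float:
    """Raised-cosine self-dropout probability, `cycles` maxima per epoch.

    p(step) = (1 - cos(2 pi cycles step / steps_per_epoch)) / 2, in [0, 1],
    starting at 0.
    """
    if steps_per_epoch <= 0:
        raise ValueError("steps_per_epoch must be positive")
    if step < 0:
        raise ValueError("step must be >= 0")
    return float(
        (1.0 - np.cos(2.0 * np.pi * cycles * step / steps_per_epoch)) / 2.0
    )


def apply_signature_dropout(
    rows: np.ndarray,
    profile: DropoutProfile,
    self_p: float,
    rng,
    target_block: int | None = None,
    d: int = 128,
) -> np.ndarray:
    """Mask covariate blocks at random; dropped blocks become NaN.

    Non-target block j is kept with ``profile.keep_probability[j]``; the
    target block (if given) is kept with probability ``1 - self_p``.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float)).copy()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    m = len(profile.block_ids)
    if rows.shape[1] != m * d:
        raise ValueError("row width does not match profile block structure")
    keep = profile.keep_probability.copy()
    if target_block is not None:
        keep = keep.copy()
        keep[target_block] = 1.0 - self_p
    mask = rng.random((rows.shape[0], m)) < keep  # True = keep
    for j in range(m):
        rows[~mask[:, j], j * d : (j + 1) * d] = np.nan
    return rows


# ---------------------------------------------------------------------------
# estimator


class SpaceSignaturizer(BaseEstimator, TransformerMixin):
    """Siamese embedding model for one target space (scikit-learn style).

    Fit on a :class:`~biosig.store.CovariatesMatrix` and a
    :class:`~biosig.triplets.TripletSet`; transform covariate rows into
    unit-norm 128-d inferred signatures.

    Parameters
    ----------
    space_id : str or None
        Target space; inferred from the covariates matrix when None.
    hidden : tuple or None
        Hidden layer sizes; None applies the interpolation rule.
    epochs : int or None
        None applies the data-size rule (5 epochs below 30,000 molecules,
        2 at or above).
    Remaining parameters mirror :class:`SiameseSpec`.

    Attributes
    ----------
    network_ : trained network
    block_ids_ : covariate block order, enforced at prediction time
    dropout_profile_ : :class:`DropoutProfile` used during training
    training_report_ : dict of per-epoch loss/accuracy traces
    """

    def __init__(
        self,
        space_id: str | None = None,
        hidden: tuple | None = None,
        input_noise_sd: float = 0.1,
        alpha_dropout: float = 0.2,
        margin: float = 1.0,
        gor_alpha: float = 1.0,
        learning_rate: float = 1e-4,
        epochs: int | None = None,
        oscillation_cycles: int = 5000,
        batch_size: int = 128,
        seed: int = 0,
    ) -> None:
        self.space_id = space_id
        self.hidden = hidden
        self.input_noise_sd = input_noise_sd
        self.alpha_dropout = alpha_dropout
        self.margin = margin
        self.gor_alpha = gor_alpha
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.oscillation_cycles = oscillation_cycles
        self.batch_size = batch_size
        self.seed = seed

    # -- construction ------------------------------------------------------

    def _build(self, d_in: int, rng) -> nn.Network:
        # output width = block width (128 at full scale) so inferred
        # signatures drop back into the store as regular blocks
        h1, h2 = self.hidden or layer_sizes(d_in // self.d_, self.d_)
        return nn.Network(
            [
                nn.GaussianDropout(self.input_noise_sd),
                nn.Dense(d_in, h1, rng, init="lecun"),
                nn.SeLU(),
                nn.AlphaDropout(self.alpha_dropout),
                nn.Dense(h1, h2, rng, init="lecun"),
                nn.SeLU(),
                nn.AlphaDropout(self.alpha_dropout),
                nn.Dense(h2, self.d_, rng, init="glorot"),
                nn.Tanh(),
                nn.L2Norm(),
            ]
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, X: CovariatesMatrix, y=None, profile: DropoutProfile | None = None):
        """Train on covariates ``X`` and triplet set ``y``.

        Only train_train triplets are used for gradient steps (test splits
        are reserved for evaluation); if the triplet set carries no split
        labels all triplets are used.
        """
        triplets = y
        if triplets is None or len(triplets) == 0:
            raise ValueError("an empty triplet set cannot train a signaturizer")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        self.d_ = X.d
        self.block_ids_ = list(X.block_ids)
        target = self.space_id or X.target_space
        self.space_id_ = target
        if target not in self.block_ids_:
            raise ValueError(f"target space {target!r} not among covariate blocks")
        self.target_block_ = self.block_ids_.index(target)

        if profile is None:
            # fallback: availability among the target space's own molecules
            profile = DropoutProfile(
                block_ids=self.block_ids_,
                keep_probability=X.presence.mean(axis=0),
                fallback_global=True,
            )
        if list(profile.block_ids) != self.block_ids_:
            raise ValueError("dropout profile block order mismatch")
        self.dropout_profile_ = profile

        rng = np.random.default_rng(self.seed)
        net = self._build(X.values.shape[1], rng)
        opt = nn.Adam(net, learning_rate=self.learning_rate)

        idx_of = {k: i for i, k in enumerate(X.keys)}
        use = np.arange(len(triplets.anchors))
        if len(getattr(triplets, "splits", [])) and (triplets.splits == "train_train").any():
            use = np.where(triplets.splits == "train_train")[0]
        ia = np.asarray([idx_of[k] for k in triplets.anchors[use]])
        ip = np.asarray([idx_of[k] for k in triplets.positives[use]])
        ineg = np.asarray([idx_of[k] for k in triplets.negatives[use]])

        n_mol = X.values.shape[0]
        epochs = self.epochs if self.epochs is not None else default_epochs(n_mol)
        d = self.d_
        tb = self.target_block_
        full = np.nan_to_num(X.values, nan=0.0)
        only = np.zeros_like(full)
        only[:, tb * d : (tb + 1) * d] = full[:, tb * d : (tb + 1) * d]

        n_tr = len(ia)
        bs = min(self.batch_size, n_tr)
        steps_per_epoch = int(np.ceil(n_tr / bs))
        report = {"loss": [], "triplet": [], "mse": [], "gor": [], "accuracy": []}

        for epoch in range(epochs):
            order = rng.permutation(n_tr)
            ep = {"loss": 0.0, "triplet": 0.0, "mse": 0.0, "gor": 0.0, "acc": 0.0}
            for step in range(steps_per_epoch):
                batch = order[step * bs : (step + 1) * bs]
                a, p, ngt = ia[batch], ip[batch], ineg[batch]
                self_p = oscillation_schedule(
                    step, steps_per_epoch, self.oscillation_cycles
                )
                xa = apply_signature_dropout(
                    X.values[a], profile, self_p, rng, target_block=tb, d=d
                )
                xa = np.nan_to_num(xa, nan=0.0)
                stats = self._train_step(
                    net, opt, rng, xa, full[p], full[ngt], only[a]
                )
                w = len(batch) / n_tr
                for k in ep:
                    ep[k] += stats[k] * w
            report["loss"].append(ep["loss"])
            report["triplet"].append(ep["triplet"])
            report["mse"].append(ep["mse"])
            report["gor"].append(ep["gor"])
            report["accuracy"].append(ep["acc"])

        self.network_ = net
        self.training_report_ = report
        self.n_molecules_ = n_mol
        self.epochs_ = epochs
        return self

    def _train_step(self, net, opt, rng, xa, xp, xn, x_only):
        """One Adam step on the combined loss; returns batch statistics."""
        e_a, ca = net.forward(xa, training=True, rng=rng)
        e_p, cp = net.forward(xp, training=True, rng=rng)
        e_n, cn = net.forward(xn, training=True, rng=rng)
        e_t, _ = net.forward(x_only, training=False, rng=rng)  # stop-gradient target

        g_a, g_p, g_n, stats = embedding_gradients(
            e_a, e_p, e_n, e_t, margin=self.margin, gor_alpha=self.gor_alpha
        )
        net.zero_grad()
        net.backward(g_a, ca)
        net.backward(g_p, cp)
        net.backward(g_n, cn)
        opt.step()
        return stats

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise AttributeError("signaturizer is not fitted")

    def _rows(self, X, drop_blocks=None, only_target: bool = False) -> np.ndarray:
        if isinstance(X, CovariatesMatrix):
            if list(X.block_ids) != self.block_ids_:
                raise ValueError(
                    "covariate block order does not match the fitted signaturizer"
                )
            rows = X.values
        else:
            rows = np.atleast_2d(np.asarray(X, dtype=float))
        rows = np.nan_to_num(rows, nan=0.0).copy()
        d = self.d_
        if only_target:
            keep = np.zeros_like(rows)
            tb = self.target_block_
            keep[:, tb * d : (tb + 1) * d] = rows[:, tb * d : (tb + 1) * d]
            return keep
        for sid in drop_blocks or []:
            j = self.block_ids_.index(sid)
            rows[:, j * d : (j + 1) * d] = 0.0
        return rows

    def transform(self, X, drop_blocks=None, only_target: bool = False) -> np.ndarray:
        """Embed covariate rows; stochastic layers disabled (deterministic)."""
        self._check_fitted()
        return self.network_.predict(self._rows(X, drop_blocks, only_target))

    def predict(self, X) -> SignatureSpace:
        """Inferred signature space (unit-norm rows) for the given covariates."""
        self._check_fitted()
        emb = self.transform(X)
        keys = (
            X.keys
            if isinstance(X, CovariatesMatrix)
            else np.asarray([f"row{i}" for i in range(len(emb))], dtype=object)
        )
        return SignatureSpace(
            space_id=self.space_id_, keys=keys, values=emb, kind="inferred"
        )

    def ensemble_transform(
        self, X, n_draws: int = 10, seed: int = 0
    ) -> np.ndarray:
        """(n_draws, n, 128) embeddings under prediction-time signature dropout."""
        self._check_fitted()
        rng = np.random.default_rng(seed)
        if isinstance(X, CovariatesMatrix):
            if list(X.block_ids) != self.block_ids_:
                raise ValueError("covariate block order mismatch")
            raw = X.values
        else:
            raw = np.atleast_2d(np.asarray(X, dtype=float))
        outs = []
        for _ in range(n_draws):
            dropped = apply_signature_dropout(
                raw, self.dropout_profile_, 1.0, rng,
                target_block=self.target_block_, d=self.d_,
            )
            outs.append(self.network_.predict(np.nan_to_num(dropped, nan=0.0)))
        return np.stack(outs)


# ---------------------------------------------------------------------------
# functional wrappers


def train(
    store: Store,
    target_space: str,
    triplet_set,
    spec: SiameseSpec | None = None,
    min_coverage: float = 0.10,
) -> SpaceSignaturizer:
    """Stack covariates, estimate the dropout profile, and fit a signaturizer."""
    spec = spec or SiameseSpec()
    cov = stack_covariates(store, target_space, min_coverage=min_coverage)
    profile = dropout_profile(store, target_space, block_ids=cov.block_ids)
    model = SpaceSignaturizer(
        space_id=target_space,
        hidden=spec.hidden,
        input_noise_sd=spec.input_noise_sd,
        alpha_dropout=spec.alpha_dropout,
        margin=spec.margin,
        gor_alpha=spec.gor_alpha,
        learning_rate=spec.learning_rate,
        epochs=spec.epochs,
        oscillation_cycles=spec.oscillation_cycles_per_epoch,
        batch_size=spec.batch_size,
        seed=spec.seed,
    )
    return model.fit(cov, triplet_set, profile=profile)


def predict(signaturizer: SpaceSignaturizer, covariates) -> SignatureSpace:
    """Functional alias for :meth:`SpaceSignaturizer.predict`."""
    return signaturizer.predict(covariates)
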