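"""Light-weight chemistry-to-signature (CTS) models.

A trained signaturizer needs the molecule's other bioactivity signatures
as input; a CTS model removes even that requirement by mapping a 2048-bit
Morgan fingerprint (radius 2) directly to the inferred 128-d signature of
one space.  Trained against a large corpus of pre-computed signatures it
acts mostly as a fast mapping function, giving on-the-fly signatures for
arbitrary structures.  Architecture: three ReLU hidden layers (1024, 512,
256) with dropout 0.2, a Tanh output head of 128 units (L2-normalized by
default to match the inferred-signature convention), Adam at 1e-3 for 30
epochs with an 80:20 train-test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .store import SignatureSpace

__all__ = [
    "FingerprintTable",
    "ChemToSigRegressor",
    "train_cts",
    "predict_cts",
    "evaluate_cts",
]

FP_BITS = 2048
HIDDEN = (1024, 512, 256)


@dataclass
class FingerprintTable:
    """Binary Morgan-fingerprint matrix keyed by molecule."""

    keys: np.ndarray
    bits: np.ndarray
    radius: int = 2

    def __post_init__(self) -> None:
        self.keys = np.asarray(self.keys, dtype=object)
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-d matrix")
        if not np.isin(self.bits, [0, 1]).all():
            raise ValueError("fingerprint entries must be binary")
        if len(self.keys) != len(self.bits):
            raise ValueError("keys/bits length mismatch")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    @classmethod
    def from_smiles(cls, keys, smiles, n_bits: int = FP_BITS, radius: int = 2):
        """Morgan fingerprints from SMILES via RDKit (optional dependency)."""
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        rows = []
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"unparsable SMILES: {smi!r}")
            rows.append(np.asarray(gen.GetFingerprint(mol), dtype=np.uint8))
        return cls(keys=np.asarray(keys, dtype=object), bits=np.vstack(rows), radius=radius)


class ChemToSigRegressor(BaseEstimator, RegressorMixin):
    """Fingerprint-to-signature network (scikit-learn style).

    Parameters
    ----------
    epochs : int, default 30
    learning_rate : float, default 1e-3
    dropout : float, default 0.2
    normalize_output : bool, default True
        L2-normalize the Tanh output to match inferred-signature
        invariants.
    test_fraction : float, default 0.2
        Held-out fraction used for the per-molecule correlation report.

    Attributes
    ----------
    network_ : trained network
    report_ : dict with per-epoch train loss and per-test-molecule
        correlations (``test_correlations``)
    """

    def __init__(
        self,
        epochs: int = 30,
        learning_rate: float = 1e-3,
        dropout: float = 0.2,
        batch_size: int = 128,
        normalize_output: bool = True,
        test_fraction: float = 0.2,
        seed: int = 0,
    ) -> None:
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.batch_size = batch_size
        self.normalize_output = normalize_output
        self.test_fraction = test_fraction
        self.seed = seed

    def _build(self, d_in: int, d_out: int, rng) -> nn.Network:
        layers: list = []
        prev = d_in
        for h in HIDDEN:
            layers += [nn.Dense(prev, h, rng, init="he"), nn.ReLU(), nn.Dropout(self.dropout)]
            prev = h
        layers += [nn.Dense(prev, d_out, rng, init="glorot"), nn.Tanh()]
        if self.normalize_output:
            layers.append(nn.L2Norm())
        return nn.Network(layers)

    def fit(self, X, y):
        """Train on a fingerprint matrix (or FingerprintTable) and targets."""
        if isinstance(X, FingerprintTable):
            X = X.bits
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.isin(X, [0, 1]).all():
            raise ValueError("fingerprints must be binary")
        if len(X) != len(y):
            raise ValueError("misaligned fingerprints and target signatures")
        rng = np.random.default_rng(self.seed)
        net = self._build(X.shape[1], y.shape[1], rng)
        opt = nn.Adam(net, learning_rate=self.learning_rate)

        n = len(X)
        order = rng.permutation(n)
        n_test = int(round(self.test_fraction * n))
        test_idx, train_idx = order[:n_test], order[n_test:]
        bs = min(self.batch_size, len(train_idx))
        losses = []
        for _ in range(self.epochs):
            perm = rng.permutation(len(train_idx))
            ep = 0.0
            for s in range(0, len(train_idx), bs):
                b = train_idx[perm[s : s + bs]]
                out, caches = net.forward(X[b], training=True, rng=rng)
                diff = out - y[b]
                loss = float(np.mean(diff**2))
                net.zero_grad()
                net.backward(2.0 * diff / diff.size, caches)
                opt.step()
                ep += loss * len(b) / len(train_idx)
            losses.append(ep)

        self.network_ = net
        self.train_idx_, self.test_idx_ = train_idx, test_idx
        test_corr = (
            evaluate_cts(self, X[test_idx], y[test_idx]) if n_test else np.array([])
        )
        self.report_ = {"train_loss": losses, "test_correlations": test_corr}
        return self

    def predict(self, X) -> np.ndarray:
        """Deterministic signatures for width-2048 binary fingerprints."""
        if isinstance(X, FingerprintTable):
            X = X.bits
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isin(X, [0, 1]).all():
            raise ValueError("fingerprints must be binary")
        return self.network_.predict(X)

    def predict_space(self, fingerprints: FingerprintTable, space_id: str) -> SignatureSpace:
        emb = self.predict(fingerprints)
        return SignatureSpace(
            space_id=space_id, keys=fingerprints.keys.copy(), values=emb, kind="inferred"
        )


def train_cts(fingerprints, target_signatures, seed: int = 0, **kwargs) -> ChemToSigRegressor:
    """Fit a CTS model on aligned fingerprints and target signatures.

    ``fingerprints`` may be a FingerprintTable (keys are checked against a
    SignatureSpace target) or a raw bit matrix.
    """
    if isinstance(fingerprints, FingerprintTable) and isinstance(
        target_signatures, SignatureSpace
    ):
        fp_keys = fingerprints.keys.tolist()
        if set(fp_keys) - set(target_signatures.keys.tolist()):
            raise ValueError("fingerprint keys not aligned with target signatures")
        y = target_signatures.rows(fp_keys)
        X = fingerprints.bits
    else:
        X = fingerprints.bits if isinstance(fingerprints, FingerprintTable) else fingerprints
        y = np.asarray(target_signatures, dtype=float)
    return ChemToSigRegressor(seed=seed, **kwargs).fit(X, y)


def predict_cts(model: ChemToSigRegressor, fingerprints) -> np.ndarray:
    return model.predict(fingerprints)


def evaluate_cts(model, fingerprints, targets) -> np.ndarray:
    """Per-molecule Pearson correlation between predicted and target vectors.

    A zero-variance vector makes the correlation undefined; NaN is
    returned for that molecule.
    """
    pred = model.predict(fingerprints)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    out = np.empty(len(pred))
    for i, (p, t) in enumerate(zip(pred, targets)):
        sp, st = p.std(), t.std()
        if sp == 0 or st == 0:
            out[i] = np.nan
            continue
        out[i] = float(np.corrcoef(p, t)[0, 1])
    return out
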