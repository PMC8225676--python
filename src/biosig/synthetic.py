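"""Synthetic miniature signature universes with known ground truth.

Real multi-space bioactivity collections have two statistical features the
inference method depends on: the per-space signatures are noisy views of a
shared set of latent bioactivity factors (so spaces are cross-correlated),
and coverage is blockwise-missing (chemistry spaces near-complete, clinical
spaces sparse).  This module generates miniature universes with exactly that
structure — each space's signature is ``tanh(L z + eps)`` for a sparse
loading matrix L over n x h standard-normal latent factors z — plus binary
label tasks tied to the latent factors and synthetic Morgan-like
fingerprints, so that every downstream module is testable without any
external data.  The latent factors are stored alongside the universe
(hidden from models, visible to tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .store import SignatureSpace, Store

__all__ = [
    "UniverseConfig",
    "TaskTable",
    "generate_universe",
    "generate_tasks",
    "generate_fingerprints",
    "scramble_fingerprints",
    "SPACE_NAMES",
]

#: CC-style space labels, chemistry-to-clinics order
SPACE_NAMES = [f"{level}{sub}" for level in "ABCDE" for sub in range(1, 6)]


@dataclass
class UniverseConfig:
    """Parameters of a synthetic signature universe.

    Parameters
    ----------
    n_molecules : int
    n_spaces : int
        Up to 25; named A1..E5 in chemistry-to-clinics order.
    d : int
        Signature width per space (128 in the full-scale setting).
    h : int
        Latent factor dimension shared across spaces.
    loading_density : float
        Proportion of the h latent factors visible to each space.
    noise_sd : float
        Standard deviation of the pre-Tanh observation noise.
    missingness : float or sequence
        Per-space proportion of molecules withheld (the first two,
        chemistry-like, spaces are always fully covered).  Must leave at
        least max(50, 0.05 n) observed molecules per space.
    seed : int
    factor_subsets : list of arrays, optional
        Explicit factor indices per space; overrides ``loading_density``.
        Used to build factor-disjoint control spaces.
    """

    n_molecules: int = 2000
    n_spaces: int = 8
    d: int = 128
    h: int = 16
    loading_density: float = 0.5
    noise_sd: float = 0.1
    missingness: float | tuple = 0.3
    seed: int = 0
    factor_subsets: list | None = None

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if not 1 <= self.n_spaces <= 25:
            raise ValueError("n_spaces must be in [1, 25]")


@dataclass
class TaskTable:
    """A binary activity task over universe molecules.

    ``scaffold`` holds a categorical stand-in for Murcko scaffolds
    (cluster ids on the first chemistry space) so scaffold-split tests are
    meaningful without real chemistry.
    """

    keys: np.ndarray
    labels: np.ndarray
    scaffold: np.ndarray
    active_fraction: float = field(default=0.0)
    task_id: str = "task"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")
        self.active_fraction = float(self.labels.mean()) if len(self.labels) else 0.0


def _make_keys(n: int) -> np.ndarray:
    # InChIKey-like: 14-char connectivity prefix + fixed tail
    return np.asarray([f"SYN{i:011d}-UHFFFAOYSA-N" for i in range(n)], dtype=object)


def generate_universe(config: UniverseConfig) -> Store:
    """Generate a deterministic synthetic multi-space signature store.

    Each space sees a sparse subset of the shared latent factors; its
    signature matrix is ``tanh(z L^T / sqrt(k) + eps)`` restricted to the
    molecules the space covers.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, h = cfg.n_molecules, cfg.h
    keys = _make_keys(n)
    z = rng.standard_normal((n, h))

    if np.isscalar(cfg.missingness):
        miss = [0.0, 0.0] + [float(cfg.missingness)] * max(0, cfg.n_spaces - 2)
        miss = miss[: cfg.n_spaces]
    else:
        miss = [float(x) for x in cfg.missingness]
        if len(miss) != cfg.n_spaces:
            raise ValueError("per-space missingness length mismatch")
    floor = max(50, int(np.ceil(0.05 * n)))
    for s, p in enumerate(miss):
        if not 0 <= p < 1:
            raise ValueError("missingness must be in [0, 1)")
        if round(n * (1 - p)) < floor:
            raise ValueError(
                f"space {s}: missingness {p} leaves fewer than {floor} molecules"
            )

    if cfg.factor_subsets is not None:
        subsets = [np.asarray(s, dtype=int) for s in cfg.factor_subsets]
        if len(subsets) != cfg.n_spaces:
            raise ValueError("factor_subsets length mismatch")
    else:
        k = max(1, int(round(cfg.loading_density * h)))
        subsets = [rng.choice(h, size=k, replace=False) for _ in range(cfg.n_spaces)]

    spaces = {}
    for s in range(cfg.n_spaces):
        sid = SPACE_NAMES[s]
        sub = subsets[s]
        loading = np.zeros((cfg.d, h))
        loading[:, sub] = rng.standard_normal((cfg.d, len(sub))) / np.sqrt(len(sub))
        raw = z @ loading.T + cfg.noise_sd * rng.standard_normal((n, cfg.d))
        sig = np.tanh(raw)
        if miss[s] > 0:
            keep = rng.permutation(n)[: int(round(n * (1 - miss[s])))]
            keep = np.sort(keep)
        else:
            keep = np.arange(n)
        spaces[sid] = SignatureSpace(
            space_id=sid, keys=keys[keep], values=sig[keep], kind="experimental"
        )
    meta = {"seed": cfg.seed, "kind": "synthetic-universe", "h": h}
    return Store(spaces, width=cfg.d, meta=meta, latent=(keys, z))


def generate_tasks(
    store: Store, n_tasks: int, flip_rate: float = 0.0, seed: int = 0
) -> list:
    """Binary label tasks tied to the universe's latent factors.

    Each task thresholds a random linear score of a random latent-factor
    subset at its median (balanced labels), then flips each label with
    probability ``flip_rate``; ``flip_rate=0.5`` is the no-signal limit.
    Scaffold labels come from k-means clusters (k = n/50) of the first
    chemistry space.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    if store.latent is None:
        raise ValueError("store has no latent factors recorded")
    keys, z = store.latent
    n, h = z.shape
    rng = np.random.default_rng(seed)

    first = store[store.space_ids[0]]
    k_scaff = max(2, n // 50)
    km = KMeans(n_clusters=k_scaff, n_init=4, random_state=seed)
    scaff_of = dict(zip(first.keys.tolist(), km.fit_predict(first.values)))
    # molecules outside the first space get their own singleton-ish bucket
    scaffolds = np.asarray(
        [scaff_of.get(k, k_scaff) for k in keys], dtype=int
    )

    tasks = []
    for t in range(n_tasks):
        sub = rng.choice(h, size=max(1, h // 4), replace=False)
        w = rng.standard_normal(len(sub))
        score = z[:, sub] @ w
        labels = (score > np.median(score)).astype(int)
        flips = rng.random(n) < flip_rate
        labels = np.where(flips, 1 - labels, labels)
        tasks.append(
            TaskTable(
                keys=keys.copy(),
                labels=labels,
                scaffold=np.asarray([f"scf{c}" for c in scaffolds], dtype=object),
                task_id=f"task{t}",
            )
        )
    return tasks


def generate_fingerprints(store: Store, n_bits: int = 2048, seed: int = 0):
    """Synthetic Morgan-like bit vectors correlated with the latent factors.

    Bit k fires when a random projection of the molecule's latent vector
    exceeds a random threshold; this is a stand-in for real 2048-bit
    Morgan fingerprints (radius 2) with the property that structure
    (latents) determines bits, as chemistry determines real fingerprints.
    """
    from .distill import FingerprintTable

    if store.latent is None:
        raise ValueError("store has no latent factors recorded")
    keys, z = store.latent
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((z.shape[1], n_bits)) / np.sqrt(z.shape[1])
    b = rng.normal(0.5, 0.5, size=n_bits)  # biases -> sparse-ish bits
    bits = (z @ w + b > 0).astype(np.uint8)
    return FingerprintTable(keys=keys.copy(), bits=bits)


def scramble_fingerprints(fingerprints, seed: int = 0):
    """Per-molecule random permutation of bit positions.

    Destroys the structure-bit association while preserving each
    molecule's popcount; the control input for distillation experiments.
    """
    from .distill import FingerprintTable

    bits = np.asarray(fingerprints.bits)
    if not np.isin(bits, [0, 1]).all():
        raise ValueError("fingerprints must be binary")
    rng = np.random.default_rng(seed)
    out = np.empty_like(bits)
    for i in range(bits.shape[0]):
        out[i] = bits[i, rng.permutation(bits.shape[1])]
    return FingerprintTable(keys=np.asarray(fingerprints.keys).copy(), bits=out)
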