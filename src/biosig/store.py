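"""Multi-space signature store: data model, HDF5 I/O, coverage accounting.

A *store* holds, for up to 25 bioactivity "spaces" (A1..E5 semantics:
chemistry, targets, networks, cells, clinics), a fixed-width real-valued
signature matrix over a shared molecule universe keyed by InChIKey-like
strings.  Spaces differ in coverage: chemistry spaces are near-complete,
clinical spaces are sparse.  The store supports the two bookkeeping
operations everything downstream relies on: cross-coverage between spaces
and stacking of per-space signature blocks into a covariates matrix for one
target space, with missing blocks marked absent (NaN sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SignatureSpace",
    "CoverageMatrix",
    "CovariatesMatrix",
    "Store",
    "connectivity",
    "load_store",
    "save_store",
    "cross_coverage",
    "stack_covariates",
]

#: width of one signature block unless a store says otherwise
DEFAULT_WIDTH = 128

#: number of characters of an InChIKey that encode skeleton connectivity
CONNECTIVITY_LEN = 14


class StoreFormatError(ValueError):
    """Raised when an on-disk container is malformed."""


def connectivity(key: str) -> str:
    """Connectivity layer of an InChIKey-like key (first 14 characters).

    Matching *across* collections is done on this prefix; within a store
    full keys are compared.
    """
    return str(key)[:CONNECTIVITY_LEN]


def _as_key_array(keys: Iterable[str]) -> np.ndarray:
    arr = np.asarray(list(keys), dtype=object)
    if arr.ndim != 1:
        raise ValueError("keys must be one-dimensional")
    return arr


@dataclass
class SignatureSpace:
    """One space's signature matrix with its ordered molecule keys.

    Parameters
    ----------
    space_id : str
        Space label, e.g. ``"B4"``.
    keys : array of str, shape (n,)
        Unique, non-empty molecule identifiers.
    values : ndarray, shape (n, d)
        Signature matrix.  For ``kind="experimental"`` every entry must be
        finite; for ``kind="inferred"`` every row must be unit Euclidean
        norm (+-1e-6) with components in [-1, 1] (the Tanh + L2 output
        convention of the signaturizers).
    kind : {"experimental", "inferred"}
    """

    space_id: str
    keys: np.ndarray
    values: np.ndarray
    kind: str = "experimental"

    def __post_init__(self) -> None:
        self.keys = _as_key_array(self.keys)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.keys.size == 0:
            self.values = self.values.reshape(0, self.values.shape[-1])
        if self.values.shape[0] != self.keys.shape[0]:
            raise ValueError(
                f"space {self.space_id}: {self.keys.shape[0]} keys but "
                f"{self.values.shape[0]} signature rows"
            )
        if any(len(str(k)) == 0 for k in self.keys):
            raise ValueError(f"space {self.space_id}: empty molecule key")
        if len(set(self.keys.tolist())) != self.keys.shape[0]:
            raise ValueError(f"space {self.space_id}: duplicate molecule keys")
        if self.kind not in ("experimental", "inferred"):
            raise ValueError(f"unknown signature kind {self.kind!r}")
        if self.kind == "experimental":
            if not np.all(np.isfinite(self.values)):
                raise ValueError(
                    f"space {self.space_id}: experimental signatures must be finite"
                )
        else:
            if self.n:
                norms = np.linalg.norm(self.values, axis=1)
                if not np.allclose(norms, 1.0, atol=1e-6):
                    raise ValueError(
                        f"space {self.space_id}: inferred signatures must be unit norm"
                    )
                if np.abs(self.values).max() > 1 + 1e-9:
                    raise ValueError(
                        f"space {self.space_id}: inferred components must lie in [-1, 1]"
                    )

    @property
    def n(self) -> int:
        return self.keys.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def key_index(self) -> dict:
        return {k: i for i, k in enumerate(self.keys)}

    def rows(self, keys: Iterable[str]) -> np.ndarray:
        idx = self.key_index()
        return self.values[[idx[k] for k in keys]]


@dataclass
class CoverageMatrix:
    """Square matrix of proportions: entry (i, j) = |keys_i ∩ keys_j| / |keys_i|."""

    space_ids: list
    values: np.ndarray
    empty_spaces: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.space_ids, columns=self.space_ids)


@dataclass
class CovariatesMatrix:
    """Horizontally stacked signature blocks for one target space.

    ``values`` has shape (n, d*m) with NaN filling absent blocks;
    ``presence`` is the (n, m) block availability mask.  Rows follow the
    target space's key order.
    """

    target_space: str
    block_ids: list
    keys: np.ndarray
    values: np.ndarray
    presence: np.ndarray
    d: int = DEFAULT_WIDTH

    @property
    def m(self) -> int:
        return len(self.block_ids)

    def block(self, space_id: str) -> np.ndarray:
        j = self.block_ids.index(space_id)
        return self.values[:, j * self.d : (j + 1) * self.d]


class Store:
    """In-memory collection of :class:`SignatureSpace` objects.

    Optionally carries the latent factor matrix of a synthetic universe
    (hidden from models, visible to tests) and free-form metadata.
    """

    def __init__(
        self,
        spaces: Mapping[str, SignatureSpace] | None = None,
        width: int = DEFAULT_WIDTH,
        meta: dict | None = None,
        latent: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        self.spaces: dict[str, SignatureSpace] = dict(spaces or {})
        self.width = int(width)
        self.meta = dict(meta or {})
        # latent = (keys, factor matrix) for synthetic universes
        self.latent = latent

    def __contains__(self, space_id: str) -> bool:
        return space_id in self.spaces

    def __getitem__(self, space_id: str) -> SignatureSpace:
        return self.spaces[space_id]

    def __len__(self) -> int:
        return len(self.spaces)

    @property
    def space_ids(self) -> list:
        return sorted(self.spaces)

    def add(self, space: SignatureSpace) -> None:
        self.spaces[space.space_id] = space

    def universe(self) -> list:
        """Sorted union of molecule keys across all spaces."""
        keys: set = set()
        for sp in self.spaces.values():
            keys.update(sp.keys.tolist())
        return sorted(keys)


def save_store(store: Store, path) -> None:
    """Write a store to an HDF5 container.

    Layout: ``/spaces/<space_id>/{values, keys, kind}`` and
    ``/meta/{width, ...}``; synthetic latent factors under
    ``/latent/{keys, values}``.  Round-trips bit-exactly.
    """
    with h5py.File(path, "w") as f:
        g_meta = f.create_group("meta")
        g_meta.attrs["width"] = store.width
        for k, v in store.meta.items():
            g_meta.attrs[k] = v
        g_spaces = f.create_group("spaces")
        for sid, sp in store.spaces.items():
            g = g_spaces.create_group(sid)
            g.create_dataset("values", data=sp.values.astype(np.float64))
            g.create_dataset(
                "keys", data=np.asarray([str(k) for k in sp.keys], dtype="S")
            )
            g.attrs["kind"] = sp.kind
        if store.latent is not None:
            lkeys, lvals = store.latent
            g = f.create_group("latent")
            g.create_dataset("keys", data=np.asarray([str(k) for k in lkeys], dtype="S"))
            g.create_dataset("values", data=np.asarray(lvals, dtype=np.float64))


def load_store(path) -> Store:
    """Load a store written by :func:`save_store`.

    Raises
    ------
    StoreFormatError
        If a required group or dataset is missing, naming the offender.
    ValueError
        If a space violates its invariants (e.g. duplicate keys).
    """
    with h5py.File(path, "r") as f:
        if "spaces" not in f:
            raise StoreFormatError("missing group /spaces")
        if "meta" not in f:
            raise StoreFormatError("missing group /meta")
        width = int(f["meta"].attrs.get("width", DEFAULT_WIDTH))
        meta = {
            k: v for k, v in f["meta"].attrs.items() if k != "width"
        }
        spaces = {}
        for sid, g in f["spaces"].items():
            for ds in ("values", "keys"):
                if ds not in g:
                    raise StoreFormatError(f"missing dataset /spaces/{sid}/{ds}")
            keys = [k.decode() for k in g["keys"][()]]
            spaces[sid] = SignatureSpace(
                space_id=sid,
                keys=keys,
                values=g["values"][()],
                kind=g.attrs.get("kind", "experimental"),
            )
        latent = None
        if "latent" in f:
            latent = (
                np.asarray([k.decode() for k in f["latent"]["keys"][()]], dtype=object),
                f["latent"]["values"][()],
            )
    return Store(spaces, width=width, meta=meta, latent=latent)


def cross_coverage(store: Store) -> CoverageMatrix:
    """Proportion of molecules of each space also present in every other.

    Entry (i, j) is computed over the molecules of space i; the diagonal is
    1 for non-empty spaces.  Empty spaces give a zero row (diagonal 0) and
    are flagged in ``empty_spaces``.
    """
    if not store.spaces:
        raise ValueError("store is empty")
    ids = store.space_ids
    key_sets = {sid: set(store[sid].keys.tolist()) for sid in ids}
    vals = np.zeros((len(ids), len(ids)))
    empty = [sid for sid in ids if not key_sets[sid]]
    for i, si in enumerate(ids):
        ni = len(key_sets[si])
        if ni == 0:
            continue
        for j, sj in enumerate(ids):
            vals[i, j] = len(key_sets[si] & key_sets[sj]) / ni
    return CoverageMatrix(space_ids=ids, values=vals, empty_spaces=empty)


def stack_covariates(
    store: Store, target_space: str, min_coverage: float = 0.10
) -> CovariatesMatrix:
    """Stack per-space signature blocks into a covariates matrix.

    Only spaces covering at least ``min_coverage`` of the target space's
    molecules contribute a block (the target space always covers itself and
    is always included).  Rows are ordered by the target space's keys; a
    molecule's block j is NaN wherever the molecule is absent from space j,
    with the availability recorded in the presence mask.
    """
    if target_space not in store:
        raise KeyError(f"unknown target space {target_space!r}")
    target = store[target_space]
    target_keys = set(target.keys.tolist())
    n = target.n
    block_ids = []
    for sid in store.space_ids:
        sp = store[sid]
        cov = len(set(sp.keys.tolist()) & target_keys) / max(n, 1)
        if cov >= min_coverage or sid == target_space:
            block_ids.append(sid)
    if not block_ids:
        raise ValueError(
            f"no space covers >= {min_coverage:.0%} of target {target_space!r}"
        )
    d = store[block_ids[0]].d
    m = len(block_ids)
    values = np.full((n, d * m), np.nan)
    presence = np.zeros((n, m), dtype=bool)
    for j, sid in enumerate(block_ids):
        sp = store[sid]
        idx = sp.key_index()
        rows = np.asarray([idx.get(k, -1) for k in target.keys])
        have = rows >= 0
        presence[:, j] = have
        values[np.where(have)[0], j * d : (j + 1) * d] = sp.values[rows[have]]
    return CovariatesMatrix(
        target_space=target_space,
        block_ids=block_ids,
        keys=target.keys.copy(),
        values=values,
        presence=presence,
        d=d,
    )
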