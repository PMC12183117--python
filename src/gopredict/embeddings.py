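"""Uniform access to per-protein embedding vectors.

Protein language model embeddings (ESM-2 for sequence, ProstT5 for
structure-aware representations) are consumed here as precomputed
key -> float-array dumps; this module never runs a language model.  The
same interface serves the synthetic generator's embeddings, so the rest of
the pipeline is agnostic to where vectors come from.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import MissingIdError, ValidationError


def pool_residue_embeddings(matrix: np.ndarray, method: str = "mean") -> np.ndarray:
    """Collapse an L x D per-residue embedding matrix to one D-vector.

    Mean pooling is the default (the usual convention for ESM-2/ProstT5
    downstream use); ``max`` takes the per-dimension maximum.
    """
    matrix = np.asarray(matrix, dtype=np.float32)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValidationError(
            f"expected an L x D matrix with L >= 1, got shape {matrix.shape}"
        )
    if not np.isfinite(matrix).all():
        raise ValidationError("non-finite entries in residue embedding matrix")
    if method == "mean":
        return matrix.mean(axis=0)
    if method == "max":
        return matrix.max(axis=0)
    raise ValueError(f"unknown pooling method: {method!r}")


@dataclass
class EmbeddingStore:
    """protein id -> fixed-dimension float32 vector, with a modality tag."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    modality: str = "unspecified"

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValidationError("embedding dimension must be >= 1")
        for key in list(self.vectors):
            self.vectors[key] = self._check(key, self.vectors[key])

    def _check(self, key: str, vec: np.ndarray) -> np.ndarray:
        vec = np.asarray(vec, dtype=np.float32)
        if vec.shape != (self.dim,):
            raise ValidationError(
                f"vector for {key!r} has shape {vec.shape}, expected ({self.dim},)"
            )
        if not np.isfinite(vec).all():
            raise ValidationError(f"vector for {key!r} contains NaN/Inf")
        return vec

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, key: str) -> bool:
        return key in self.vectors

    def add(self, key: str, vec: np.ndarray) -> None:
        self.vectors[key] = self._check(key, vec)

    def get(self, key: str) -> np.ndarray:
        try:
            return self.vectors[key]
        except KeyError:
            raise MissingIdError(f"no embedding for id: {key}")

    def batch(self, keys) -> np.ndarray:
        """n x dim matrix in request order."""
        if len(keys) == 0:
            return np.zeros((0, self.dim), dtype=np.float32)
        return np.stack([self.get(k) for k in keys])

    def ids(self) -> list[str]:
        return list(self.vectors)


def get_embedding(store: EmbeddingStore, key: str) -> np.ndarray:
    """Module-level alias for :meth:`EmbeddingStore.get`."""
    return store.get(key)


def save_store(store: EmbeddingStore, path) -> None:
    """Write a store to ``.npz`` or ``.h5``/``.hdf5`` (chosen by suffix),
    or to a directory of per-protein ``.npy`` files otherwise."""
    path = os.fspath(path)
    if path.endswith(".npz"):
        np.savez(path, **{k: v for k, v in store.vectors.items()})
    elif path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.attrs["modality"] = store.modality
            for k, v in store.vectors.items():
                f.create_dataset(k, data=v)
    else:
        os.makedirs(path, exist_ok=True)
        for k, v in store.vectors.items():
            np.save(os.path.join(path, f"{k}.npy"), v)


def load_store(
    path,
    modality: str = "unspecified",
    pool_on_load: str | None = None,
) -> EmbeddingStore:
    """Load a key -> array container saved by :func:`save_store` (or any
    npz/HDF5/directory dump in that layout).

    Entries may be per-residue L x D matrices, in which case *pool_on_load*
    (``mean`` or ``max``) must be given; mixed vector dimensions raise
    :class:`ValidationError`.
    """
    path = os.fspath(path)
    arrays: dict[str, np.ndarray] = {}
    if path.endswith(".npz"):
        with np.load(path) as data:
            for k in data.files:
                arrays[k] = data[k]
    elif path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            if modality == "unspecified":
                modality = str(f.attrs.get("modality", "unspecified"))
            for k in f.keys():
                arrays[k] = f[k][()]
    elif os.path.isdir(path):
        for name in sorted(os.listdir(path)):
            if name.endswith(".npy"):
                arrays[name[: -len(".npy")]] = np.load(os.path.join(path, name))
    else:
        raise ValueError(f"cannot infer container format for {path!r}")

    vectors: dict[str, np.ndarray] = {}
    for k, arr in arrays.items():
        if arr.ndim == 2:
            if pool_on_load is None:
                raise ValidationError(
                    f"entry {k!r} is a per-residue matrix; pass pool_on_load"
                )
            arr = pool_residue_embeddings(arr, method=pool_on_load)
        elif arr.ndim != 1:
            raise ValidationError(f"entry {k!r} has ndim {arr.ndim}, expected 1 or 2")
        vectors[k] = np.asarray(arr, dtype=np.float32)

    dims = {v.shape[0] for v in vectors.values()}
    if len(dims) > 1:
        raise ValidationError(f"mixed embedding dimensions in container: {sorted(dims)}")
    dim = dims.pop() if dims else 1
    return EmbeddingStore(dim=dim, vectors=vectors, modality=modality)
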