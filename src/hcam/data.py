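"""Patient-level hospital-compare dataset container.

Rows are patients; each carries a hospital identifier, a binary outcome
``y`` (1 = death), patient covariates ``X``, optionally zero-inflation
covariates ``T``, and a single hospital-level attribute ``V`` shared by all
rows of a hospital.  Rows are stored sorted by hospital (stable within
hospital) so per-cluster reductions are contiguous; hospital indices are
assigned by first appearance of each identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HospitalDataset"]


@dataclass
class HospitalDataset:
    hospital_ids: np.ndarray  # per-row opaque string ids (sorted by hospital)
    y: np.ndarray  # per-row binary outcome
    X: np.ndarray  # per-row patient covariates, no intercept column
    V: np.ndarray  # one attribute per hospital (length H)
    T: np.ndarray | None = None  # optional zero-inflation covariates
    unique_ids: np.ndarray = field(init=False)
    hospital_index: np.ndarray = field(init=False)  # per-row 0-based index
    group_starts: np.ndarray = field(init=False)

    def __post_init__(self):
        ids = np.asarray(self.hospital_ids).astype(str)
        y = np.asarray(self.y)
        if not np.isin(y, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        y = y.astype(float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != len(ids):
            X = X.T
        T = None if self.T is None else np.atleast_2d(np.asarray(self.T, dtype=float))
        if T is not None and T.shape[0] != len(ids):
            T = T.T
        if np.isnan(X).any() or np.isnan(y).any() or (T is not None and np.isnan(T).any()):
            raise ValueError("dataset contains missing values; drop them at load time")

        # index hospitals by first appearance, then sort rows by that index
        uniq, first = np.unique(ids, return_index=True)
        uniq = uniq[np.argsort(first)]
        lookup = {u: i for i, u in enumerate(uniq)}
        idx = np.array([lookup[i] for i in ids])
        order = np.argsort(idx, kind="stable")

        self.hospital_ids = ids[order]
        self.y = y[order]
        self.X = X[order]
        self.T = None if T is None else T[order]
        self.unique_ids = uniq
        self.hospital_index = idx[order]

        V = np.asarray(self.V, dtype=float).reshape(-1)
        if V.size == len(ids):  # per-row attribute: collapse, check constancy
            V = V[order]
            firsts = np.concatenate([[0], np.flatnonzero(np.diff(self.hospital_index)) + 1])
            Vh = V[firsts]
            if not np.allclose(V, Vh[self.hospital_index]):
                raise ValueError("hospital attribute V varies within a hospital")
            V = Vh
        if V.size != len(uniq):
            raise ValueError(f"V has length {V.size}, expected H={len(uniq)} (or one per row)")
        self.V = V
        self.group_starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(self.hospital_index)) + 1]
        )

    # ---- derived sizes -------------------------------------------------
    @property
    def H(self) -> int:
        return len(self.unique_ids)

    @property
    def N(self) -> int:
        return len(self.y)

    @property
    def n_h(self) -> np.ndarray:
        return np.bincount(self.hospital_index, minlength=self.H)

    def group_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum per-row values (last axis = rows not supported; rows on axis 0
        or the final axis of a 2-D array laid out (k, N)) within hospitals."""
        values = np.asarray(values)
        if values.ndim == 1:
            return np.add.reduceat(values, self.group_starts)
        return np.add.reduceat(values, self.group_starts, axis=-1)

    def subset(self, row_mask_or_index) -> "HospitalDataset":
        r = np.asarray(row_mask_or_index)
        rows = np.flatnonzero(r) if r.dtype == bool else r
        keep_ids = self.hospital_ids[rows]
        keep_hidx = self.hospital_index[rows]
        return HospitalDataset(
            hospital_ids=keep_ids,
            y=self.y[rows],
            X=self.X[rows],
            V=self.V[keep_hidx],
            T=None if self.T is None else self.T[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"hospital": self.hospital_ids, "y": self.y.astype(int)})
        for j in range(self.X.shape[1]):
            df[f"x{j + 1}"] = self.X[:, j]
        if self.T is not None:
            for j in range(self.T.shape[1]):
                df[f"t{j + 1}"] = self.T[:, j]
        df["v"] = self.V[self.hospital_index]
        return df
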