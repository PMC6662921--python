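"""Multi-hot feature matrices and repeated stratified splits.

Every code in the vocabulary becomes one binary indicator column, followed by
indicator columns for each demographic level (integer age, sex, race,
ethnicity).  Latent generative state never enters the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import StratificationError
from .synthetic import (
    ETHNICITY_LEVELS,
    N_AGE_LEVELS,
    RACE_LEVELS,
    SEX_LEVELS,
    Cohort,
    PatientRecord,
    codes_csr,
)

#: demographic indicator levels, in declared column order
DEMOGRAPHIC_COLUMNS: tuple[str, ...] = (
    tuple(f"age_{a}" for a in range(N_AGE_LEVELS))
    + tuple(f"sex_{s}" for s in SEX_LEVELS)
    + tuple(f"race_{r}" for r in RACE_LEVELS)
    + tuple(f"ethnicity_{e}" for e in ETHNICITY_LEVELS)
)


@dataclass
class FeatureMatrix:
    """Sparse binary patients x features matrix with column names and row ids."""

    values: sparse.csr_matrix
    column_names: list[str]
    row_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_feature_matrix(
    records: Sequence[PatientRecord] | Cohort, n_codes: int | None = None
) -> FeatureMatrix:
    """Multi-hot featurization: code indicators (ascending code index) followed
    by demographic indicators in declared order."""
    if isinstance(records, Cohort):
        n_codes = records.config.n_codes
        records = records.records
    if n_codes is None:
        n_codes = max((max(r.codes) for r in records if r.codes), default=-1) + 1
    code_part = codes_csr(records, n_codes)

    n = len(records)
    n_demo = len(DEMOGRAPHIC_COLUMNS)
    sex_pos = {s: i for i, s in enumerate(SEX_LEVELS)}
    race_pos = {r: i for i, r in enumerate(RACE_LEVELS)}
    eth_pos = {e: i for i, e in enumerate(ETHNICITY_LEVELS)}
    rows = np.repeat(np.arange(n), 4)
    cols = np.empty(4 * n, dtype=np.int64)
    for i, rec in enumerate(records):
        cols[4 * i] = rec.age
        cols[4 * i + 1] = N_AGE_LEVELS + sex_pos[rec.sex]
        cols[4 * i + 2] = N_AGE_LEVELS + len(SEX_LEVELS) + race_pos[rec.race]
        cols[4 * i + 3] = (
            N_AGE_LEVELS + len(SEX_LEVELS) + len(RACE_LEVELS) + eth_pos[rec.ethnicity]
        )
    demo_part = sparse.csr_matrix(
        (np.ones(4 * n, dtype=np.int8), (rows, cols)), shape=(n, n_demo)
    )
    values = sparse.hstack([code_part, demo_part], format="csr").astype(np.int8)
    column_names = [f"code_{c}" for c in range(n_codes)] + list(DEMOGRAPHIC_COLUMNS)
    return FeatureMatrix(
        values=values,
        column_names=column_names,
        row_ids=[r.patient_id for r in records],
    )


def load_feature_table(path: str | Path, label_columns: Sequence[str]) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Read a user-supplied binary patient-by-feature table (CSV with a
    ``patient_id`` column) and split off the named label columns."""
    df = pd.read_csv(path)
    labels = df[list(label_columns)].copy()
    feats = df.drop(columns=list(label_columns))
    row_ids = feats.pop("patient_id").astype(str).tolist()
    values = sparse.csr_matrix(feats.to_numpy(dtype=np.int8))
    return FeatureMatrix(values, list(feats.columns), row_ids), labels


# ---------------------------------------------------------------------------
# stratified splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """One train/validation/test partition of ``0..n-1``."""

    split_id: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def partitions(self) -> dict[str, np.ndarray]:
        return {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}


def largest_remainder_allocation(n: int, fractions: Sequence[float]) -> list[int]:
    """Split ``n`` items into integer counts proportional to ``fractions``:
    floor first, then hand out the remainder by largest fractional part
    (ties broken by position)."""
    exact = np.asarray(fractions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    remainder = int(n - counts.sum())
    if remainder:
        frac = exact - np.floor(exact)
        order = np.lexsort((np.arange(len(fractions)), -frac))
        for i in order[:remainder]:
            counts[i] += 1
    return counts.tolist()


def stratified_splits(
    target_labels: np.ndarray,
    n_splits: int = 10,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    master_seed: int = 0,
) -> list[SplitSpec]:
    """Repeated stratified 3-way splits.

    Positives and negatives are allocated to train/val/test separately (floor
    plus largest-remainder rounding), so the target prevalence of every
    partition matches the overall prevalence up to integer rounding.  Each
    split uses an independent child seed of ``(master_seed, split_id)``.
    """
    y = np.asarray(target_labels).astype(int).ravel()
    if not np.isclose(sum(fractions), 1.0):
        raise StratificationError(f"fractions must sum to 1, got {fractions!r}")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size < 10:
        raise StratificationError(
            f"need at least 10 positive cases to stratify, got {pos.size}"
        )
    splits = []
    for split_id in range(n_splits):
        rng = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(split_id,))
        )
        parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
        for group in (pos, neg):
            perm = rng.permutation(group)
            counts = largest_remainder_allocation(perm.size, fractions)
            a, b = counts[0], counts[0] + counts[1]
            parts["train"].append(perm[:a])
            parts["val"].append(perm[a:b])
            parts["test"].append(perm[b:])
        splits.append(
            SplitSpec(
                split_id=split_id,
                train_idx=np.sort(np.concatenate(parts["train"])),
                val_idx=np.sort(np.concatenate(parts["val"])),
                test_idx=np.sort(np.concatenate(parts["test"])),
                fractions=tuple(fractions),
            )
        )
    return splits


def splits_to_json(splits: Sequence[SplitSpec], path: str | Path) -> None:
    doc = {
        str(s.split_id): {
            "train": s.train_idx.tolist(),
            "val": s.val_idx.tolist(),
            "test": s.test_idx.tolist(),
            "fractions": list(s.fractions),
        }
        for s in splits
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def splits_from_json(path: str | Path) -> list[SplitSpec]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for sid in sorted(doc, key=int):
        d = doc[sid]
        out.append(
            SplitSpec(
                split_id=int(sid),
                train_idx=np.asarray(d["train"], dtype=np.int64),
                val_idx=np.asarray(d["val"], dtype=np.int64),
                test_idx=np.asarray(d["test"], dtype=np.int64),
                fractions=tuple(d["fractions"]),
            )
        )
    return out
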