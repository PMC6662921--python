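"""Phenotype-complexity metrics over hashed oracle-feature combinations.

Each patient's oracle signature (the binary string of presence indicators for
the rule's oracle codes) is hashed into a fixed number of buckets; separate
histograms are accumulated for cases and controls.  The case histogram's
Shannon entropy summarizes how diverse the positive cases are along the
oracle axes; the KL divergence D(P+ || P-) between the normalized case and
control histograms summarizes how separable cases are from controls.  High
entropy means a complex phenotype; low KL means a hard-to-discriminate one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .rules import PhenotypeRule, oracle_signatures
from .synthetic import Cohort, PatientRecord

DEFAULT_N_BUCKETS = 32

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


def fnv1a64(s: str) -> int:
    """64-bit FNV-1a string hash: fixed, fast, stable across runs and platforms."""
    h = _FNV_OFFSET
    for byte in s.encode("ascii"):
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h


def _bucket(sig: str, n_buckets: int, hash_name: str) -> int:
    if hash_name == "fnv1a":
        return fnv1a64(sig) % n_buckets
    if hash_name == "direct":
        # injective fallback: interpret the signature as a binary integer
        return int(sig, 2)
    raise ConfigurationError(f"unknown hash {hash_name!r}; use 'fnv1a' or 'direct'")


@dataclass
class BucketHistogram:
    """Per-bucket counts of hashed oracle signatures for cases and controls."""

    n_buckets: int
    counts_pos: np.ndarray
    counts_neg: np.ndarray
    hash_name: str = "fnv1a"


def build_histogram(
    signatures_pos: Sequence[str],
    signatures_neg: Sequence[str],
    n_buckets: int = DEFAULT_N_BUCKETS,
    hash_name: str = "fnv1a",
) -> BucketHistogram:
    """Hash case and control signatures into ``n_buckets`` and count.

    ``hash_name="direct"`` indexes buckets by the signature value itself (no
    collisions); it requires ``2**len(signature) <= n_buckets``.
    """
    if not signatures_pos or not signatures_neg:
        raise InsufficientDataError("need at least one case and one control signature")
    if n_buckets < 1:
        raise ConfigurationError("n_buckets must be >= 1")
    if hash_name == "direct":
        width = len(signatures_pos[0])
        if 2 ** width > n_buckets:
            raise ConfigurationError(
                f"direct indexing needs 2**{width} <= n_buckets ({n_buckets})"
            )
    counts_pos = np.zeros(n_buckets, dtype=np.int64)
    counts_neg = np.zeros(n_buckets, dtype=np.int64)
    for sig in signatures_pos:
        counts_pos[_bucket(sig, n_buckets, hash_name)] += 1
    for sig in signatures_neg:
        counts_neg[_bucket(sig, n_buckets, hash_name)] += 1
    return BucketHistogram(n_buckets, counts_pos, counts_neg, hash_name)


def entropy(counts, base: float | None = None) -> float:
    """Shannon entropy of a count histogram, H = -sum p_i log p_i.

    Counts are normalized to probabilities; zero buckets contribute 0
    (0 log 0 := 0).  Natural log by default; pass ``base=2`` for bits.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or np.any(c < 0):
        raise ConfigurationError("counts must be a nonnegative vector")
    total = c.sum()
    if total == 0:
        raise InsufficientDataError("entropy of an all-zero histogram is undefined")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def kl_divergence(
    counts_pos, counts_neg, smoothing_alpha: float = 0.5, base: float | None = None
) -> float:
    """KL divergence D(P+ || P-) between smoothed, normalized histograms.

    ``smoothing_alpha`` is added to every count of both vectors before
    normalization, so buckets occupied by cases but empty of controls stay
    finite.  With ``smoothing_alpha=0`` and such a bucket present the
    divergence is infinite, and a warning is issued.
    """
    cp = np.asarray(counts_pos, dtype=float).ravel()
    cn = np.asarray(counts_neg, dtype=float).ravel()
    if cp.shape != cn.shape:
        raise ValueError(f"count vectors differ in length ({cp.size} != {cn.size})")
    if np.any(cp < 0) or np.any(cn < 0):
        raise ConfigurationError("counts must be nonnegative")
    if cp.sum() == 0 or cn.sum() == 0:
        raise InsufficientDataError("both histograms need at least one nonzero count")
    if smoothing_alpha < 0:
        raise ConfigurationError("smoothing_alpha must be nonnegative")
    cp = cp + smoothing_alpha
    cn = cn + smoothing_alpha
    p = cp / cp.sum()
    q = cn / cn.sum()
    support = p > 0
    if np.any(support & (q == 0)):
        warnings.warn(
            "case distribution has support where the control distribution is "
            "zero; KL divergence is infinite (use smoothing_alpha > 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    d = float((p[support] * np.log(p[support] / q[support])).sum())
    if base is not None:
        d /= math.log(base)
    # clip tiny negative rounding residue; Gibbs' inequality guarantees >= 0
    return max(d, 0.0)


@dataclass
class ComplexityReport:
    """Entropy and KL divergence of a phenotype's oracle-signature histograms."""

    rule_id: str
    prevalence: float
    entropy_pos: float
    kl_pos_vs_neg: float
    smoothing_alpha: float
    histogram: BucketHistogram


def complexity_report(
    rule: PhenotypeRule,
    records: Sequence[PatientRecord] | Cohort,
    labels: np.ndarray,
    n_buckets: int = DEFAULT_N_BUCKETS,
    smoothing_alpha: float = 0.5,
    hash_name: str | None = None,
) -> ComplexityReport:
    """Full pipeline: oracle signatures -> bucket histogram -> entropy + KL.

    ``hash_name=None`` picks direct indexing when every signature fits
    (``2**n_oracle <= n_buckets``) and the FNV-1a hash otherwise.
    """
    if isinstance(records, Cohort):
        records = records.records
    y = np.asarray(labels).astype(int).ravel()
    if y.size != len(records):
        raise ValueError("labels must align with records")
    sigs = oracle_signatures(rule, records)
    pos = [sigs[i] for i in np.flatnonzero(y == 1)]
    neg = [sigs[i] for i in np.flatnonzero(y == 0)]
    if not pos or not neg:
        raise InsufficientDataError("need at least one case and one control")
    if hash_name is None:
        hash_name = "direct" if 2 ** rule.n_oracle <= n_buckets else "fnv1a"
    hist = build_histogram(pos, neg, n_buckets=n_buckets, hash_name=hash_name)
    return ComplexityReport(
        rule_id=rule.rule_id,
        prevalence=float(y.mean()),
        entropy_pos=entropy(hist.counts_pos),
        kl_pos_vs_neg=kl_divergence(
            hist.counts_pos, hist.counts_neg, smoothing_alpha=smoothing_alpha
        ),
        smoothing_alpha=smoothing_alpha,
        histogram=hist,
    )


def complexity_table(
    reports: Sequence[ComplexityReport], path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate reports (one row per rule); optionally write CSV."""
    df = pd.DataFrame(
        [
            {
                "rule_id": r.rule_id,
                "prevalence": r.prevalence,
                "entropy": r.entropy_pos,
                "kl_divergence": r.kl_pos_vs_neg,
                "n_buckets": r.histogram.n_buckets,
                "alpha": r.smoothing_alpha,
                "hash_name": r.histogram.hash_name,
            }
            for r in reports
        ]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
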