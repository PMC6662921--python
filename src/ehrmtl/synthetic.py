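"""Seed-controlled synthetic EHR cohorts.

The generator emulates the statistical structure that supervised electronic
phenotyping assumes: a sparse binary code vocabulary (abstract stand-ins for
diagnosis / procedure / drug indicators), latent disease factors that induce
code co-occurrence, demographic attributes, and phecode-style auxiliary labels
defined as groupings of codes.  Latent factors are independent Bernoulli
variables; an active factor emits each of its associated codes independently
(a noisy-OR-style emission model), on top of a spontaneous background rate.

A per-patient *hidden flag* is also sampled.  Phenotype rules may require it,
but it is never exported as a feature, so rule-defined case status is not
perfectly recoverable from the feature matrix and the Bayes-optimal classifier
scores strictly below 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError, InsufficientTasksError

SEX_LEVELS = ("F", "M")
RACE_LEVELS = ("asian", "black", "pacific_islander", "white", "other")
ETHNICITY_LEVELS = ("hispanic", "non_hispanic")
N_AGE_LEVELS = 100

_SEX_P = (0.52, 0.48)
_RACE_P = (0.15, 0.08, 0.02, 0.55, 0.20)
_ETHNICITY_P = (0.16, 0.84)

# per factor: tuple of (code_index, emission_probability) pairs
Emissions = tuple[tuple[tuple[int, float], ...], ...]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; (config, seed) determines the cohort.

    Parameters
    ----------
    n_patients, n_codes
        Cohort size and code-vocabulary size.
    latent_prevalences
        Marginal probability that each latent disease factor is active; the
        number of factors is ``len(latent_prevalences)``.
    emissions
        Per factor, the ``(code_index, probability)`` pairs emitted when the
        factor is active.
    background_rate
        Probability that any code appears spontaneously, independently of the
        latent factors.
    hidden_flag_rate
        Probability that a patient carries the hidden (never-featurized)
        qualifier that rules may require.
    """

    n_patients: int
    n_codes: int
    latent_prevalences: tuple[float, ...]
    emissions: Emissions
    background_rate: float = 0.003
    hidden_flag_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_codes < 1 or self.n_latent < 1:
            raise ConfigurationError("n_patients, n_codes and n_latent must be >= 1")
        if len(self.emissions) != self.n_latent:
            raise ConfigurationError(
                "emissions must have one entry per latent factor "
                f"({len(self.emissions)} != {self.n_latent})"
            )
        for i, p in enumerate(self.latent_prevalences):
            if not (0.0 < p < 1.0):
                raise ConfigurationError(
                    f"latent_prevalences[{i}] must lie in (0, 1), got {p!r}"
                )
        _check_prob("background_rate", self.background_rate)
        _check_prob("hidden_flag_rate", self.hidden_flag_rate)
        for f, factor_emissions in enumerate(self.emissions):
            for code, p in factor_emissions:
                if not (0 <= code < self.n_codes):
                    raise ConfigurationError(
                        f"emission code {code} of factor {f} outside vocabulary"
                    )
                _check_prob(f"emission_probs[{f}][{code}]", p)
        # normalize to hashable nested tuples even if lists were passed
        object.__setattr__(
            self, "latent_prevalences", tuple(float(p) for p in self.latent_prevalences)
        )
        object.__setattr__(
            self,
            "emissions",
            tuple(
                tuple((int(c), float(p)) for c, p in factor)
                for factor in self.emissions
            ),
        )

    @property
    def n_latent(self) -> int:
        return len(self.latent_prevalences)

    def factor_codes(self, factor: int) -> tuple[int, ...]:
        """Codes emitted by ``factor`` (in declaration order)."""
        return tuple(c for c, _ in self.emissions[factor])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(
            n_patients=int(d["n_patients"]),
            n_codes=int(d["n_codes"]),
            latent_prevalences=tuple(d["latent_prevalences"]),
            emissions=tuple(tuple(tuple(pair) for pair in f) for f in d["emissions"]),
            background_rate=float(d["background_rate"]),
            hidden_flag_rate=float(d["hidden_flag_rate"]),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient.

    ``latent_flags`` and ``hidden_flag`` are generative state used by
    phenotype rules; they are never exported to the feature matrix.
    """

    patient_id: str
    codes: frozenset[int]
    age: int
    sex: str
    race: str
    ethnicity: str
    latent_flags: frozenset[int]
    hidden_flag: bool


@dataclass(frozen=True)
class PhecodeGroup:
    """A phecode-style grouping of code indices; the label of one auxiliary task."""

    group_id: str
    member_codes: frozenset[int]

    def __post_init__(self) -> None:
        if not self.member_codes:
            raise ConfigurationError(f"phecode group {self.group_id!r} is empty")


@dataclass
class Cohort:
    """A generated cohort: the records plus the config that produced them."""

    config: CohortConfig
    records: list[PatientRecord]

    def __len__(self) -> int:
        return len(self.records)


def block_structured_config(
    n_patients: int,
    n_codes: int,
    latent_prevalences: Sequence[float],
    block_size: int,
    emission_range: tuple[float, float] = (0.4, 0.7),
    background_rate: float = 0.003,
    hidden_flag_rate: float = 0.0,
    seed: int = 0,
) -> CohortConfig:
    """Build a :class:`CohortConfig` where factor ``f`` emits a contiguous block
    of ``block_size`` codes starting at ``f * block_size``, with per-code
    emission probabilities drawn once (from ``seed``) in ``emission_range``.
    """
    n_latent = len(latent_prevalences)
    if n_latent * block_size > n_codes:
        raise ConfigurationError("factor blocks exceed the code vocabulary")
    lo, hi = emission_range
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    emissions = []
    for f in range(n_latent):
        probs = rng.uniform(lo, hi, size=block_size)
        block = range(f * block_size, (f + 1) * block_size)
        emissions.append(tuple((int(c), float(p)) for c, p in zip(block, probs)))
    return CohortConfig(
        n_patients=n_patients,
        n_codes=n_codes,
        latent_prevalences=tuple(latent_prevalences),
        emissions=tuple(emissions),
        background_rate=background_rate,
        hidden_flag_rate=hidden_flag_rate,
        seed=seed,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Sample a cohort from ``config``; identical config (incl. seed) gives an
    identical cohort.

    Each patient's code set is the union of background-sampled codes and codes
    emitted by their active latent factors.
    """
    n, m = config.n_patients, config.n_codes
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    latent = rng.random((n, config.n_latent)) < np.asarray(config.latent_prevalences)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    # background: per code, sample how many patients carry it spontaneously
    if config.background_rate > 0:
        for code in range(m):
            k = rng.binomial(n, config.background_rate)
            if k:
                rows.append(rng.choice(n, size=k, replace=False))
                cols.append(np.full(k, code, dtype=np.int64))
    # factor emissions among factor-active patients
    for f in range(config.n_latent):
        active = np.flatnonzero(latent[:, f])
        if active.size == 0:
            continue
        for code, p in config.emissions[f]:
            hit = active[rng.random(active.size) < p]
            if hit.size:
                rows.append(hit)
                cols.append(np.full(hit.size, code, dtype=np.int64))

    if rows:
        coo = sparse.coo_matrix(
            (np.ones(sum(len(r) for r in rows), dtype=np.int8),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, m),
        )
        code_csr = coo.tocsr()
        code_csr.data[:] = 1  # de-duplicate background/emission overlaps
    else:
        code_csr = sparse.csr_matrix((n, m), dtype=np.int8)

    ages = rng.integers(0, N_AGE_LEVELS, size=n)
    sexes = rng.choice(len(SEX_LEVELS), size=n, p=_SEX_P)
    races = rng.choice(len(RACE_LEVELS), size=n, p=_RACE_P)
    eths = rng.choice(len(ETHNICITY_LEVELS), size=n, p=_ETHNICITY_P)
    hidden = rng.random(n) < config.hidden_flag_rate

    records = []
    indptr, indices = code_csr.indptr, code_csr.indices
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i:07d}",
                codes=frozenset(int(c) for c in indices[indptr[i]:indptr[i + 1]]),
                age=int(ages[i]),
                sex=SEX_LEVELS[sexes[i]],
                race=RACE_LEVELS[races[i]],
                ethnicity=ETHNICITY_LEVELS[eths[i]],
                latent_flags=frozenset(int(f) for f in np.flatnonzero(latent[i])),
                hidden_flag=bool(hidden[i]),
            )
        )
    return Cohort(config=config, records=records)


def codes_csr(records: Sequence[PatientRecord], n_codes: int) -> sparse.csr_matrix:
    """Binary patients x codes CSR matrix from record code sets."""
    indptr = [0]
    indices: list[int] = []
    for rec in records:
        row = sorted(rec.codes)
        if row and (row[0] < 0 or row[-1] >= n_codes):
            raise ConfigurationError(
                f"patient {rec.patient_id} has codes outside [0, {n_codes})"
            )
        indices.extend(row)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.int8)
    return sparse.csr_matrix(
        (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(records), n_codes),
    )


def make_phecode_groups(
    config: CohortConfig,
    groups_per_factor: Sequence[int],
    n_background_groups: int = 0,
    size_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> list[PhecodeGroup]:
    """Construct phecode-style groups.

    ``groups_per_factor[f]`` groups draw their member codes from factor ``f``'s
    emission set (so the group label carries signal about that factor);
    ``n_background_groups`` more draw members uniformly from the vocabulary.
    """
    if len(groups_per_factor) != config.n_latent:
        raise ConfigurationError("groups_per_factor must have one entry per factor")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"bad size_range {size_range!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    groups: list[PhecodeGroup] = []
    for f, k in enumerate(groups_per_factor):
        pool = np.asarray(config.factor_codes(f))
        for j in range(k):
            size = min(int(rng.integers(lo, hi + 1)), pool.size)
            members = rng.choice(pool, size=size, replace=False)
            groups.append(
                PhecodeGroup(f"phecode_f{f}_{j}", frozenset(int(c) for c in members))
            )
    for j in range(n_background_groups):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.n_codes, size=size, replace=False)
        groups.append(
            PhecodeGroup(f"phecode_bg_{j}", frozenset(int(c) for c in members))
        )
    return groups


def derive_phecode_labels(
    records: Sequence[PatientRecord] | Cohort,
    groups: Sequence[PhecodeGroup],
    n_codes: int | None = None,
) -> np.ndarray:
    """Binary (patients x groups) label matrix: 1 iff the patient's code set
    intersects the group's member set."""
    if isinstance(records, Cohort):
        n_codes = records.config.n_codes
        records = records.records
    if not groups:
        raise ConfigurationError("no phecode groups supplied")
    if n_codes is None:
        max_member = max(max(g.member_codes) for g in groups)
        max_code = max((max(r.codes) for r in records if r.codes), default=-1)
        n_codes = max(max_member, max_code) + 1
    for g in groups:
        if max(g.member_codes) >= n_codes or min(g.member_codes) < 0:
            raise ConfigurationError(
                f"group {g.group_id!r} references codes outside the vocabulary"
            )
    mat = codes_csr(records, n_codes)
    labels = np.zeros((len(records), len(groups)), dtype=np.int8)
    for j, g in enumerate(groups):
        member_idx = np.asarray(sorted(g.member_codes))
        hit = np.asarray(mat[:, member_idx].sum(axis=1)).ravel() > 0
        labels[:, j] = hit.astype(np.int8)
    return labels


def sample_auxiliary_tasks(
    label_matrix: np.ndarray,
    prevalence_low: float,
    prevalence_high: float,
    sizes: Sequence[int],
    seed: int = 0,
) -> dict[int, list[int]]:
    """Draw nested auxiliary-task sets from groups whose empirical prevalence
    lies in ``[prevalence_low, prevalence_high]``.

    The largest set is drawn uniformly without replacement; every smaller set
    is a prefix of it, so the sets are strictly nested.
    """
    sizes = [int(s) for s in sizes]
    if not sizes or any(s < 1 for s in sizes) or sorted(sizes) != sizes:
        raise ConfigurationError(f"sizes must be ascending positive counts, got {sizes!r}")
    prevalence = np.asarray(label_matrix, dtype=float).mean(axis=0)
    eligible = np.flatnonzero(
        (prevalence >= prevalence_low) & (prevalence <= prevalence_high)
    )
    if eligible.size < sizes[-1]:
        raise InsufficientTasksError(
            f"need {sizes[-1]} groups with prevalence in "
            f"[{prevalence_low}, {prevalence_high}] but only {eligible.size} qualify "
            f"(short by {sizes[-1] - eligible.size})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    order = rng.permutation(eligible)[: sizes[-1]]
    return {s: [int(i) for i in order[:s]] for s in sizes}


# ---------------------------------------------------------------------------
# cohort export / import (plain-text tables + JSON sidecar)
# ---------------------------------------------------------------------------

def export_cohort(
    cohort: Cohort,
    outdir: str | Path,
    labels: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write a cohort as plain-text tables.

    ``demographics.csv`` (patient_id + demographics), ``codes.csv`` (triplets
    patient_id, code_index, 1), ``latent.csv`` (latent flags + hidden flag, so
    re-loading is lossless), optional ``labels.csv``, and a JSON sidecar with
    the full config and realized label prevalences.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recs = cohort.records
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in recs],
            "age": [r.age for r in recs],
            "sex": [r.sex for r in recs],
            "race": [r.race for r in recs],
            "ethnicity": [r.ethnicity for r in recs],
        }
    ).to_csv(outdir / "demographics.csv", index=False)
    with open(outdir / "codes.csv", "w") as fh:
        fh.write("patient_id,code_index,value\n")
        for r in recs:
            for c in sorted(r.codes):
                fh.write(f"{r.patient_id},{c},1\n")
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in recs],
            "latent_flags": [";".join(map(str, sorted(r.latent_flags))) for r in recs],
            "hidden_flag": [int(r.hidden_flag) for r in recs],
        }
    ).to_csv(outdir / "latent.csv", index=False)
    sidecar = {"config": cohort.config.to_dict(), "realized_prevalences": {}}
    if labels is not None:
        df = pd.DataFrame({"patient_id": [r.patient_id for r in recs]})
        for name, vec in labels.items():
            df[name] = np.asarray(vec, dtype=int)
            sidecar["realized_prevalences"][name] = float(np.mean(vec))
        df.to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "cohort_config.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_cohort(indir: str | Path) -> Cohort:
    """Inverse of :func:`export_cohort` (labels are not re-attached)."""
    indir = Path(indir)
    with open(indir / "cohort_config.json") as fh:
        config = CohortConfig.from_dict(json.load(fh)["config"])
    demo = pd.read_csv(indir / "demographics.csv")
    latent = pd.read_csv(indir / "latent.csv", keep_default_na=False)
    codes = pd.read_csv(indir / "codes.csv")
    by_patient: dict[str, set[int]] = {pid: set() for pid in demo["patient_id"]}
    for pid, code in zip(codes["patient_id"], codes["code_index"]):
        by_patient[pid].add(int(code))
    records = []
    for row, lrow in zip(demo.itertuples(index=False), latent.itertuples(index=False)):
        flags = frozenset(
            int(x) for x in str(lrow.latent_flags).split(";") if str(x).strip() != ""
        )
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                codes=frozenset(by_patient[row.patient_id]),
                age=int(row.age),
                sex=row.sex,
                race=row.race,
                ethnicity=row.ethnicity,
                latent_flags=flags,
                hidden_flag=bool(int(lrow.hidden_flag)),
            )
        )
    return Cohort(config=config, records=records)
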