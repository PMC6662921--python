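"""Rule-based phenotype definitions.

A phenotype is defined by a flat DNF (OR of AND clauses) over *oracle codes* —
the code indicators its definition consults — with optional presence/absence
literals and an optional requirement on the patient's hidden (non-featurized)
qualifier.  The ordered oracle-code list doubles as the digit positions of the
binary *signature* used by the complexity metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .synthetic import Cohort, PatientRecord


@dataclass(frozen=True)
class Clause:
    """One conjunction: required-present codes, required-absent codes, and
    whether the hidden qualifier must be set."""

    require_present: frozenset[int]
    require_absent: frozenset[int] = frozenset()
    require_hidden: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "require_present", frozenset(self.require_present))
        object.__setattr__(self, "require_absent", frozenset(self.require_absent))
        if self.require_present & self.require_absent:
            raise ConfigurationError(
                "a clause requires the same code present and absent"
            )


@dataclass(frozen=True)
class PhenotypeRule:
    """Boolean case definition: a patient is a case iff any clause holds.

    ``oracle_codes`` is ordered; digit *i* of a patient's signature indicates
    the presence of ``oracle_codes[i]``.  ``label_noise`` flips each assigned
    label independently (models chart-review disagreement; default off).
    """

    rule_id: str
    oracle_codes: tuple[int, ...]
    clauses: tuple[Clause, ...]
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "oracle_codes", tuple(int(c) for c in self.oracle_codes))
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if not self.clauses:
            raise ConfigurationError("a rule needs at least one clause")
        if len(set(self.oracle_codes)) != len(self.oracle_codes):
            raise ConfigurationError("oracle_codes contains duplicates")
        oracle = set(self.oracle_codes)
        for cl in self.clauses:
            if not (cl.require_present | cl.require_absent) <= oracle:
                raise ConfigurationError(
                    f"rule {self.rule_id!r}: clause references codes outside oracle_codes"
                )
        if not (0.0 <= self.label_noise < 0.5):
            raise ConfigurationError("label_noise must lie in [0, 0.5)")

    @property
    def n_oracle(self) -> int:
        return len(self.oracle_codes)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule_id": self.rule_id,
                "oracle_codes": list(self.oracle_codes),
                "label_noise": self.label_noise,
                "clauses": [
                    {
                        "require_present": sorted(cl.require_present),
                        "require_absent": sorted(cl.require_absent),
                        "require_hidden": cl.require_hidden,
                    }
                    for cl in self.clauses
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhenotypeRule":
        d = json.loads(text)
        return cls(
            rule_id=d["rule_id"],
            oracle_codes=tuple(d["oracle_codes"]),
            clauses=tuple(
                Clause(
                    frozenset(c["require_present"]),
                    frozenset(c.get("require_absent", [])),
                    bool(c.get("require_hidden", False)),
                )
                for c in d["clauses"]
            ),
            label_noise=float(d.get("label_noise", 0.0)),
        )


def save_rules(rules: Sequence[PhenotypeRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([json.loads(r.to_json()) for r in rules], fh, indent=2)


def load_rules(path: str | Path) -> list[PhenotypeRule]:
    with open(path) as fh:
        docs = json.load(fh)
    return [PhenotypeRule.from_json(json.dumps(d)) for d in docs]


# ---------------------------------------------------------------------------
# rule application
# ---------------------------------------------------------------------------

def _oracle_matrix(rule: PhenotypeRule, records: Sequence[PatientRecord]) -> np.ndarray:
    """(n_patients, n_oracle) presence indicators, column i = oracle_codes[i]."""
    out = np.zeros((len(records), rule.n_oracle), dtype=bool)
    pos = {c: i for i, c in enumerate(rule.oracle_codes)}
    for r, rec in enumerate(records):
        for c in rec.codes:
            i = pos.get(c)
            if i is not None:
                out[r, i] = True
    return out


def apply_rule(
    rule: PhenotypeRule,
    records: Sequence[PatientRecord] | Cohort,
    seed: int = 0,
    n_codes: int | None = None,
) -> tuple[np.ndarray, float]:
    """Label a cohort with ``rule``.

    Returns ``(labels, prevalence)``.  With ``label_noise == 0`` the result is
    deterministic; otherwise each label is flipped independently with
    probability ``label_noise`` using ``seed``.
    """
    if isinstance(records, Cohort):
        n_codes = records.config.n_codes
        records = records.records
    if n_codes is not None:
        bad = [c for c in rule.oracle_codes if not (0 <= c < n_codes)]
        if bad:
            raise ConfigurationError(
                f"rule {rule.rule_id!r} references out-of-vocabulary codes {bad}"
            )
    oracle = _oracle_matrix(rule, records)
    pos = {c: i for i, c in enumerate(rule.oracle_codes)}
    hidden = np.asarray([rec.hidden_flag for rec in records], dtype=bool)
    labels = np.zeros(len(records), dtype=bool)
    for cl in rule.clauses:
        ok = np.ones(len(records), dtype=bool)
        for c in cl.require_present:
            ok &= oracle[:, pos[c]]
        for c in cl.require_absent:
            ok &= ~oracle[:, pos[c]]
        if cl.require_hidden:
            ok &= hidden
        labels |= ok
    if rule.label_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
        flip = rng.random(len(records)) < rule.label_noise
        labels = labels ^ flip
    labels = labels.astype(np.int8)
    return labels, float(labels.mean()) if len(records) else 0.0


def oracle_signature(rule: PhenotypeRule, record: PatientRecord) -> str:
    """Binary string, digit i = 1 iff ``rule.oracle_codes[i]`` is in the record.

    Latent/hidden flags are unobserved and never enter the signature.
    """
    return "".join("1" if c in record.codes else "0" for c in rule.oracle_codes)


def oracle_signatures(
    rule: PhenotypeRule, records: Sequence[PatientRecord] | Cohort
) -> list[str]:
    """Vectorized :func:`oracle_signature` over a cohort."""
    if isinstance(records, Cohort):
        records = records.records
    oracle = _oracle_matrix(rule, records)
    digits = np.where(oracle, "1", "0")
    return ["".join(row) for row in digits]


def satisfying_signatures(rule: PhenotypeRule, ignore_hidden: bool = True) -> set[str]:
    """Enumerate the oracle signatures that satisfy the rule (n_oracle <= 20).

    With ``ignore_hidden`` (default), clauses requiring the hidden qualifier
    are treated as satisfiable, i.e. the set describes which *observable*
    combinations can qualify.
    """
    k = rule.n_oracle
    if k > 20:
        raise ConfigurationError("signature enumeration limited to n_oracle <= 20")
    pos = {c: i for i, c in enumerate(rule.oracle_codes)}
    out = set()
    for bits in range(2 ** k):
        sig = format(bits, f"0{k}b")
        present = {rule.oracle_codes[i] for i in range(k) if sig[i] == "1"}
        for cl in rule.clauses:
            if cl.require_hidden and not ignore_hidden:
                continue
            if cl.require_present <= present and not (cl.require_absent & present):
                out.add(sig)
                break
    return out


def make_complexity_controlled_rule(
    n_oracle: int,
    n_satisfying_combinations: int,
    seed: int = 0,
    oracle_codes: Sequence[int] | None = None,
    rule_id: str | None = None,
    require_hidden: bool = False,
    label_noise: float = 0.0,
) -> PhenotypeRule:
    """A rule whose satisfying signature set has exactly
    ``n_satisfying_combinations`` members, drawn uniformly without replacement
    from the ``2**n_oracle`` possibilities.

    Each satisfying signature becomes one complete-assignment clause, so the
    satisfying set is exact by construction.  Useful for studying phenotype
    complexity causally: the number of satisfying combinations is the dial.
    """
    if n_oracle < 1 or n_oracle > 20:
        raise ConfigurationError("n_oracle must lie in [1, 20]")
    total = 2 ** n_oracle
    if not (1 <= n_satisfying_combinations <= total):
        raise ConfigurationError(
            f"n_satisfying_combinations must lie in [1, {total}], "
            f"got {n_satisfying_combinations}"
        )
    if oracle_codes is None:
        oracle_codes = tuple(range(n_oracle))
    else:
        oracle_codes = tuple(int(c) for c in oracle_codes)
        if len(oracle_codes) != n_oracle:
            raise ConfigurationError("oracle_codes length must equal n_oracle")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(19,)))
    chosen = rng.choice(total, size=n_satisfying_combinations, replace=False)
    clauses = []
    for bits in sorted(int(b) for b in chosen):
        sig = format(bits, f"0{n_oracle}b")
        present = frozenset(oracle_codes[i] for i in range(n_oracle) if sig[i] == "1")
        absent = frozenset(oracle_codes[i] for i in range(n_oracle) if sig[i] == "0")
        clauses.append(Clause(present, absent, require_hidden))
    return PhenotypeRule(
        rule_id=rule_id or f"ccr_{n_oracle}o_{n_satisfying_combinations}s_{seed}",
        oracle_codes=oracle_codes,
        clauses=tuple(clauses),
        label_noise=label_noise,
    )
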