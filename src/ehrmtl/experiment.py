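"""Comparison protocol: per-split grid search for STNN/MTNN at each
auxiliary-set size, the logistic-regression baseline, best-by-validation
selection, pairwise MTNN-STNN differences, and hyperparameter-sensitivity
summaries.

Model selection is disciplined: test AUPRC is computed for every run, but
"optimal" always means the run with the best *validation* AUPRC; every
selection is logged in an audit trail.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EhrMtlError
from .features import SplitSpec, build_feature_matrix, stratified_splits
from .metrics import auprc
from .models import (
    DEFAULT_LAMBDA_GRID,
    HyperParams,
    TrainConfig,
    train_l1_logreg,
    train_mtnn,
    train_stnn,
)
from .rules import PhenotypeRule, apply_rule
from .synthetic import Cohort, PhecodeGroup, derive_phecode_labels, sample_auxiliary_tasks

_FAMILY_CODE = {"STNN": 0, "MTNN": 1, "LR": 2}


@dataclass
class RunResult:
    """One trained configuration on one split."""

    split_id: int
    family: str
    aux_set_size: int
    n_hidden_layers: int | None
    hidden_size: int | None
    learning_rate: float | None
    lam: float | None
    seed: int
    val_auprc: float
    test_auprc: float
    best_epoch: int | None
    status: str = "ok"
    message: str = ""


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and an integer key."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _slice(X, idx):
    return X[idx]


def grid_search(
    family: str,
    X,
    y_target: np.ndarray,
    split: SplitSpec,
    aux_labels: np.ndarray | None = None,
    hp_grid: Sequence[HyperParams] | None = None,
    tc: TrainConfig | None = None,
    master_seed: int = 0,
    aux_set_size: int = 0,
    mtnn_task_weighting: str = "uniform",
) -> list[RunResult]:
    """Train one model per grid point on a split; never selects on test.

    ``mtnn_task_weighting`` is ``"uniform"`` (every task contributes equally
    to the loss) or ``"target_balanced"`` (the target carries half the loss
    and the auxiliaries share the other half, so the target's effective
    optimization does not slow down as tasks are added).

    A grid point that raises a package error is recorded with
    ``status="failed"`` rather than silently dropped.
    """
    if mtnn_task_weighting not in ("uniform", "target_balanced"):
        raise ValueError(f"unknown task weighting {mtnn_task_weighting!r}")
    if family not in ("STNN", "MTNN"):
        raise ValueError(f"grid_search handles neural families, got {family!r}")
    if family == "MTNN" and (aux_labels is None or aux_labels.shape[1] < 1):
        raise EhrMtlError("MTNN grid search needs a non-empty auxiliary label matrix")
    hp_grid = list(hp_grid) if hp_grid is not None else HyperParams.grid()
    tc = tc or TrainConfig()
    y = np.asarray(y_target).ravel()
    results = []
    for gi, hp in enumerate(hp_grid):
        seed = derive_seed(
            master_seed, split.split_id, _FAMILY_CODE[family], aux_set_size, gi
        )
        run_tc = TrainConfig(
            max_epochs=tc.max_epochs,
            adam_beta1=tc.adam_beta1,
            adam_beta2=tc.adam_beta2,
            batch_size=tc.batch_size,
            seed=seed,
        )
        base = dict(
            split_id=split.split_id,
            family=family,
            aux_set_size=aux_set_size,
            n_hidden_layers=hp.n_hidden_layers,
            hidden_size=hp.hidden_size,
            learning_rate=hp.learning_rate,
            lam=None,
            seed=seed,
        )
        try:
            if family == "STNN":
                model = train_stnn(
                    _slice(X, split.train_idx), y[split.train_idx],
                    _slice(X, split.val_idx), y[split.val_idx], hp, run_tc,
                )
            else:
                K = aux_labels.shape[1]
                weights = None
                if mtnn_task_weighting == "target_balanced":
                    weights = [1.0 / K] * K
                model = train_mtnn(
                    _slice(X, split.train_idx), y[split.train_idx],
                    aux_labels[split.train_idx],
                    _slice(X, split.val_idx), y[split.val_idx], hp, run_tc,
                    aux_loss_weights=weights,
                )
            test_scores = model.predict_scores(_slice(X, split.test_idx))
            results.append(
                RunResult(
                    **base,
                    val_auprc=model.val_auprc,
                    test_auprc=auprc(y[split.test_idx], test_scores),
                    best_epoch=model.best_epoch,
                )
            )
        except EhrMtlError as exc:
            results.append(
                RunResult(
                    **base,
                    val_auprc=float("nan"),
                    test_auprc=float("nan"),
                    best_epoch=None,
                    status="failed",
                    message=str(exc),
                )
            )
    return results


def _selection_key(r: RunResult) -> tuple:
    # best validation AUPRC; ties -> fewer layers, smaller width, lower lr
    return (
        -r.val_auprc,
        r.n_hidden_layers or 0,
        r.hidden_size or 0,
        r.learning_rate or 0.0,
    )


def select_best(results: Sequence[RunResult]) -> RunResult:
    """Argmax over validation AUPRC among successful runs."""
    ok = [r for r in results if r.status == "ok" and np.isfinite(r.val_auprc)]
    if not ok:
        raise EhrMtlError("no successful runs to select from")
    return min(ok, key=_selection_key)


def sensitivity_summary(results: Sequence[RunResult] | pd.DataFrame) -> pd.DataFrame:
    """Per (split, family, aux size): spread (max-min) and IQR of validation
    and test AUPRC across the grid."""
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(
        [asdict(r) for r in results]
    )
    df = df[df["status"] == "ok"]
    rows = []
    for (split_id, family, aux_size), g in df.groupby(
        ["split_id", "family", "aux_set_size"]
    ):
        if len(g) < 2:
            continue
        rows.append(
            {
                "split_id": split_id,
                "family": family,
                "aux_set_size": aux_size,
                "n_runs": len(g),
                "val_spread": g["val_auprc"].max() - g["val_auprc"].min(),
                "test_spread": g["test_auprc"].max() - g["test_auprc"].min(),
                "val_iqr": np.subtract(*np.percentile(g["val_auprc"], [75, 25])),
                "test_iqr": np.subtract(*np.percentile(g["test_auprc"], [75, 25])),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProtocolResult:
    """Everything a full protocol run produces."""

    runs: pd.DataFrame
    best: pd.DataFrame
    pairwise: pd.DataFrame
    sensitivity: pd.DataFrame
    aux_sets: dict[int, list[int]]
    selection_audit: list[dict]
    manifest: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(outdir / "runs.csv", index=False)
        self.best.to_csv(outdir / "best.csv", index=False)
        self.pairwise.to_csv(outdir / "pairwise.csv", index=False)
        self.sensitivity.to_csv(outdir / "sensitivity.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "manifest": self.manifest,
                    "aux_sets": {str(k): v for k, v in self.aux_sets.items()},
                    "selection_audit": self.selection_audit,
                },
                fh,
                indent=2,
                default=str,
            )


def run_full_protocol(
    cohort: Cohort,
    rule: PhenotypeRule,
    groups: Sequence[PhecodeGroup],
    aux_sizes: Sequence[int] = (5, 10, 20),
    n_splits: int = 10,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    hp_grid: Sequence[HyperParams] | None = None,
    tc: TrainConfig | None = None,
    lambda_grid: Sequence[float] | None = None,
    prevalence_band: tuple[float, float] = (0.0008, 0.0295),
    master_seed: int = 0,
    mtnn_task_weighting: str = "uniform",
) -> ProtocolResult:
    """Run the full comparison: per split, an STNN grid, an MTNN grid per
    auxiliary-set size (nested phecode sets), and the LR baseline; then
    assemble best-by-validation test AUPRCs and pairwise MTNN-STNN
    differences."""
    hp_grid = list(hp_grid) if hp_grid is not None else HyperParams.grid()
    tc = tc or TrainConfig()
    aux_sizes = sorted(int(s) for s in aux_sizes)

    y, prevalence = apply_rule(rule, cohort, seed=derive_seed(master_seed, 101))
    fm = build_feature_matrix(cohort)
    X = fm.values.astype(np.float64)

    group_labels = derive_phecode_labels(cohort, list(groups))
    aux_sets = sample_auxiliary_tasks(
        group_labels, prevalence_band[0], prevalence_band[1], aux_sizes,
        seed=derive_seed(master_seed, 103),
    )
    splits = stratified_splits(
        y, n_splits=n_splits, fractions=fractions,
        master_seed=derive_seed(master_seed, 107),
    )

    all_runs: list[RunResult] = []
    best_rows = []
    audit = []
    for split in splits:
        per_family: dict[tuple[str, int], list[RunResult]] = {}
        per_family[("STNN", 0)] = grid_search(
            "STNN", X, y, split, hp_grid=hp_grid, tc=tc, master_seed=master_seed
        )
        for s in aux_sizes:
            aux = group_labels[:, aux_sets[s]]
            per_family[("MTNN", s)] = grid_search(
                "MTNN", X, y, split, aux_labels=aux, hp_grid=hp_grid, tc=tc,
                master_seed=master_seed, aux_set_size=s,
                mtnn_task_weighting=mtnn_task_weighting,
            )
        # LR baseline (single fit over the lambda path)
        lr_model = train_l1_logreg(
            X[split.train_idx], y[split.train_idx],
            X[split.val_idx], y[split.val_idx],
            lambda_grid=lambda_grid,
        )
        lr_run = RunResult(
            split_id=split.split_id,
            family="LR",
            aux_set_size=0,
            n_hidden_layers=None,
            hidden_size=None,
            learning_rate=None,
            lam=lr_model.lam,
            seed=0,
            val_auprc=lr_model.val_auprc,
            test_auprc=auprc(
                y[split.test_idx], lr_model.predict_scores(X[split.test_idx])
            ),
            best_epoch=None,
        )
        per_family[("LR", 0)] = [lr_run]

        for (family, s), results in per_family.items():
            all_runs.extend(results)
            best = select_best(results) if family != "LR" else lr_run
            best_rows.append(
                {
                    "split_id": split.split_id,
                    "family": family,
                    "aux_set_size": s,
                    "val_auprc": best.val_auprc,
                    "test_auprc": best.test_auprc,
                    "seed": best.seed,
                }
            )
            audit.append(
                {
                    "split_id": split.split_id,
                    "family": family,
                    "aux_set_size": s,
                    "criterion": "val_auprc",
                    "chosen_seed": best.seed,
                    "chosen_val_auprc": best.val_auprc,
                    "n_candidates": len(results),
                    "n_failed": sum(r.status != "ok" for r in results),
                }
            )

    runs_df = pd.DataFrame([asdict(r) for r in all_runs])
    best_df = pd.DataFrame(best_rows)

    pairwise_rows = []
    for s in aux_sizes:
        for split in splits:
            sid = split.split_id
            mt = best_df.query(
                "family == 'MTNN' and aux_set_size == @s and split_id == @sid"
            )["test_auprc"].iloc[0]
            st = best_df.query("family == 'STNN' and split_id == @sid")[
                "test_auprc"
            ].iloc[0]
            pairwise_rows.append(
                {
                    "split_id": sid,
                    "aux_set_size": s,
                    "mtnn_test_auprc": mt,
                    "stnn_test_auprc": st,
                    "mtnn_minus_stnn": mt - st,
                }
            )
    pairwise_df = pd.DataFrame(pairwise_rows)

    manifest = {
        "rule_id": rule.rule_id,
        "target_prevalence": prevalence,
        "n_patients": len(cohort),
        "n_codes": cohort.config.n_codes,
        "n_features": fm.shape[1],
        "n_splits": n_splits,
        "fractions": list(fractions),
        "aux_sizes": aux_sizes,
        "prevalence_band": list(prevalence_band),
        "hp_grid": [
            {
                "n_hidden_layers": h.n_hidden_layers,
                "hidden_size": h.hidden_size,
                "learning_rate": h.learning_rate,
            }
            for h in hp_grid
        ],
        "train_config": {
            "max_epochs": tc.max_epochs,
            "adam_beta1": tc.adam_beta1,
            "adam_beta2": tc.adam_beta2,
            "batch_size": tc.batch_size,
        },
        "lambda_grid": [float(l) for l in (lambda_grid or DEFAULT_LAMBDA_GRID)],
        "master_seed": master_seed,
        "mtnn_task_weighting": mtnn_task_weighting,
        "auprc_estimator": "average_precision_step_interpolated",
        "selection_rule": "argmax validation AUPRC; ties -> fewer layers, "
        "smaller width, lower learning rate",
    }
    return ProtocolResult(
        runs=runs_df,
        best=best_df,
        pairwise=pairwise_df,
        sensitivity=sensitivity_summary(all_runs),
        aux_sets=aux_sets,
        selection_audit=audit,
        manifest=manifest,
    )
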