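"""Performance evaluation: per-sample ROC and power/specificity sweeps.

The sweeps mirror the supplementary evaluation protocols: draw many
replicate perturbations of one axis (sample count of the target dataset,
signature size at fixed up/down proportion, or up/down composition at
fixed size), run the full score + enrichment path against the compendium
background each time, and report the fraction of replicates whose
dataset-level p-value falls below each threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from sigsearch.compendium import NormalizedCompendium
from sigsearch.enrichment import rank_datasets
from sigsearch.sa_score import categorize_scores, score_compendium, score_dataset
from sigsearch.signature import Signature, subsample_signature
from sigsearch.synthetic import SyntheticSpec, simulate_compendium, subset_samples

__all__ = ["RocResult", "SweepResult", "roc_from_scores", "power_sweep"]

SWEEP_AXES = ("sample_size", "signature_size", "composition")
DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001)


class RocResult(NamedTuple):
    """ROC curve (fpr, tpr, thresholds) and its trapezoid area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_scores(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC over score thresholds; ties grouped; area by trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"labels must contain exactly two classes, got {classes.tolist()}"
        )
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


@dataclass
class SweepResult:
    """Long-format sensitivity table for one sweep.

    ``table`` columns: axis, setting, test, threshold, sensitivity,
    replicates, seed — one row per (setting, test, threshold).
    """

    axis: str
    grid: tuple
    replicates: int
    seed: int
    thresholds: tuple
    table: pd.DataFrame = field(repr=False, default=None)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _enrichment_p(
    scores: pd.DataFrame, target: str, q_threshold: float, fisher_mode: str, seed: int
) -> tuple[float, float]:
    table = rank_datasets(
        categorize_scores(scores, q_threshold=q_threshold),
        q_threshold=q_threshold,
        fisher_mode=fisher_mode,
        seed=seed,
    )
    row = table.loc[table["dataset_id"] == target]
    if row.empty:
        return 1.0, 1.0
    return float(row["fisher_p"].iloc[0]), float(row["ks_p"].iloc[0])


def _validate_grid(
    axis: str,
    grid: Sequence,
    comp_size: int,
    sig: Signature,
    composition_total: int | None,
) -> None:
    if axis == "sample_size":
        bad = [g for g in grid if not 2 <= int(g) <= comp_size]
        if bad:
            raise ValueError(
                f"sample sizes {bad} outside [2, {comp_size}] for target dataset"
            )
    elif axis == "signature_size":
        frac = sig.n_up / sig.n_total
        for g in grid:
            subsample_signature(sig, int(g), frac, seed=0)  # raises if infeasible
    elif axis == "composition":
        if composition_total is None:
            raise ValueError("composition axis requires composition_total")
        for g in grid:
            subsample_signature(sig, composition_total, float(g), seed=0)
    else:
        raise ValueError(f"axis must be one of {SWEEP_AXES}, got {axis!r}")


def power_sweep(
    axis: str,
    grid: Sequence,
    base_spec: SyntheticSpec,
    sig: Signature,
    replicates: int = 200,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    q_threshold: float = 0.1,
    min_per_set: int = 2,
    fisher_mode: str = "exact_2x3",
    composition_total: int | None = None,
    renormalize_subsets: bool = True,
) -> SweepResult:
    """Sensitivity of both enrichment tests along one perturbation axis.

    ``base_spec`` must plant an effect in exactly one dataset — the sweep
    target.  For the ``sample_size`` axis the target dataset is re-drawn
    as a random subset each replicate (background datasets' scores are
    computed once); for the ``signature_size`` and ``composition`` axes
    the signature is re-drawn each replicate and the full compendium is
    rescored, since every score depends on the signature.
    """
    if len(base_spec.perturbed_datasets) != 1:
        raise ValueError("power_sweep needs exactly one perturbed dataset")
    target_idx = next(iter(base_spec.perturbed_datasets))
    target_id = f"D{target_idx:03d}"
    comp = simulate_compendium(base_spec)
    target_ds = comp[target_id]
    _validate_grid(axis, grid, target_ds.n_samples, sig, composition_total)
    thresholds = tuple(thresholds)
    master = np.random.SeedSequence(seed)
    setting_seeds = master.spawn(len(grid))

    if axis == "sample_size":
        others = NormalizedCompendium(
            datasets={k: v for k, v in comp.datasets.items() if k != target_id}
        )
        other_scores = score_compendium(others, sig, min_per_set=min_per_set)

    records = []
    for gi, setting in enumerate(grid):
        child_seeds = setting_seeds[gi].generate_state(replicates * 2).reshape(-1, 2)
        fisher_hits = np.zeros(len(thresholds))
        ks_hits = np.zeros(len(thresholds))
        for r in range(replicates):
            s_draw, s_mc = int(child_seeds[r, 0]), int(child_seeds[r, 1])
            if axis == "sample_size":
                sub = subset_samples(
                    target_ds, int(setting), seed=s_draw, renormalize=renormalize_subsets
                )
                scores = pd.concat(
                    [other_scores, score_dataset(sub, sig, min_per_set=min_per_set)],
                    ignore_index=True,
                )
            else:
                if axis == "signature_size":
                    sig_r = subsample_signature(
                        sig, int(setting), sig.n_up / sig.n_total, seed=s_draw
                    )
                else:
                    sig_r = subsample_signature(
                        sig, composition_total, float(setting), seed=s_draw
                    )
                scores = score_compendium(comp, sig_r, min_per_set=min_per_set)
            fisher_p, ks_p = _enrichment_p(
                scores, target_id, q_threshold, fisher_mode, seed=s_mc
            )
            fisher_hits += np.asarray(thresholds) > fisher_p
            ks_hits += np.asarray(thresholds) > ks_p
        for test, hits in (("fisher", fisher_hits), ("ks", ks_hits)):
            for t, h in zip(thresholds, hits):
                records.append(
                    {
                        "axis": axis,
                        "setting": setting,
                        "test": test,
                        "threshold": t,
                        "sensitivity": h / replicates,
                        "replicates": replicates,
                        "seed": seed,
                    }
                )
    return SweepResult(
        axis=axis,
        grid=tuple(grid),
        replicates=replicates,
        seed=seed,
        thresholds=thresholds,
        table=pd.DataFrame.from_records(records),
    )
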