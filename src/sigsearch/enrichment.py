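"""Dataset-level enrichment tests against the compendium background.

Two routes decide whether a dataset's SA-score distribution deviates from
the pooled background of all scored samples:

* a two-sample, two-sided Kolmogorov-Smirnov test on the raw SA scores;
* an exact Fisher test (Freeman-Halton, 2x3) on the per-sample
  significance categories (sig_positive / sig_negative / not_significant),
  dataset row vs rest-of-compendium row, with one override: a dataset
  whose proportion of not_significant samples exceeds the background's is
  assigned p = 1 outright (it cannot be enriched in signature-associated
  samples).

The background includes the tested dataset's own samples; this slightly
biases toward the null and is the documented reading of "all samples in
all datasets".  q-values are Benjamini-Hochberg across datasets, applied
separately to the K-S and Fisher p-value vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from sigsearch.sa_score import NOT_SIGNIFICANT, SIG_NEGATIVE, SIG_POSITIVE

__all__ = [
    "DatasetEnrichment",
    "ks_enrichment",
    "fisher_enrichment",
    "rank_datasets",
    "write_enrichment_table",
    "ENRICHMENT_COLUMNS",
]

logger = logging.getLogger("sigsearch")

ENRICHMENT_COLUMNS = [
    "dataset_id",
    "n_samples_scored",
    "n_sig_pos",
    "n_sig_neg",
    "n_ns",
    "ks_p",
    "ks_q",
    "fisher_p",
    "fisher_q",
    "direction",
]

FISHER_MODES = ("exact_2x3", "collapse_2x2", "monte_carlo")


@dataclass
class DatasetEnrichment:
    """Enrichment result for one dataset.

    ``counts`` and ``background_counts`` are (sig_positive, sig_negative,
    not_significant) triples; ``direction`` summarizes which tail
    dominates within the dataset.
    """

    dataset_id: str
    n_samples_scored: int
    counts: tuple
    background_counts: tuple
    ks_p: float
    fisher_p: float
    ks_q: float = float("nan")
    fisher_q: float = float("nan")
    direction: str = "mixed"


def ks_enrichment(
    dataset_scores: Sequence[float], background_scores: Sequence[float]
) -> float:
    """Two-sample, two-sided K-S p-value: dataset SA scores vs background."""
    dataset_scores = np.asarray(dataset_scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if dataset_scores.size == 0 or background_scores.size == 0:
        raise ValueError("K-S enrichment requires non-empty score vectors")
    return float(
        stats.ks_2samp(dataset_scores, background_scores, alternative="two-sided").pvalue
    )


def _log_table_prob(table_row1: np.ndarray, col_sums: np.ndarray, r1: int) -> np.ndarray:
    """Log multivariate-hypergeometric probability of 2xK tables.

    ``table_row1``: (..., K) counts in the first row; margins fixed at
    row sum ``r1`` and column sums ``col_sums``.
    """
    n = int(col_sums.sum())
    a = np.asarray(table_row1, dtype=float)
    c = np.asarray(col_sums, dtype=float)
    return (
        gammaln(c + 1).sum()
        + gammaln(r1 + 1)
        + gammaln(n - r1 + 1)
        - gammaln(n + 1)
        - gammaln(a + 1).sum(axis=-1)
        - gammaln(c - a + 1).sum(axis=-1)
    )


def _freeman_halton_2x3(row1: np.ndarray, col_sums: np.ndarray) -> float:
    """Exact p for a 2x3 table by probability-ordering enumeration.

    Enumerates all tables with the observed margins; p is the total
    probability of tables no more probable than the observed one.
    """
    r1 = int(row1.sum())
    log_obs = _log_table_prob(row1, col_sums, r1)
    a_max = min(r1, int(col_sums[0]))
    tables = []
    for a in range(a_max + 1):
        b_lo = max(0, r1 - a - int(col_sums[2]))
        b_hi = min(r1 - a, int(col_sums[1]))
        for b in range(b_lo, b_hi + 1):
            tables.append((a, b, r1 - a - b))
    logp = _log_table_prob(np.array(tables), col_sums, r1)
    # tolerance guards against ties lost to floating point
    keep = logp <= log_obs + 1e-9
    total = np.exp(logp[keep]).sum()
    return float(min(1.0, total))


def _n_tables_2x3(r1: int, col_sums: np.ndarray) -> int:
    count = 0
    for a in range(min(r1, int(col_sums[0])) + 1):
        b_lo = max(0, r1 - a - int(col_sums[2]))
        b_hi = min(r1 - a, int(col_sums[1]))
        count += max(0, b_hi - b_lo + 1)
    return count


def fisher_enrichment(
    dataset_counts: Sequence[int],
    background_counts: Sequence[int],
    mode: str = "exact_2x3",
    max_enumeration: int = 10_000_000,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Exact p for the dataset-vs-rest 2x3 category table, with override.

    Parameters
    ----------
    dataset_counts, background_counts
        (sig_positive, sig_negative, not_significant) for the dataset and
        for ALL scored samples (the background includes the dataset).
    mode
        ``exact_2x3`` — Freeman-Halton enumeration, falling back to
        Monte-Carlo when the table space exceeds ``max_enumeration``;
        ``collapse_2x2`` — collapse the two significant categories and
        run a classical 2x2 Fisher exact test; ``monte_carlo`` — always
        estimate by >= ``n_draws`` seeded table draws.

    Override: if the dataset's proportion of not_significant samples
    strictly exceeds the background's, p is 1 exactly.
    """
    d = np.asarray(dataset_counts, dtype=int)
    bg = np.asarray(background_counts, dtype=int)
    if d.shape != (3,) or bg.shape != (3,):
        raise ValueError("counts must be 3-vectors (pos, neg, not_significant)")
    if (d < 0).any() or (bg < d).any():
        raise ValueError(
            f"inconsistent margins: dataset {d.tolist()} vs background {bg.tolist()}"
        )
    if mode not in FISHER_MODES:
        raise ValueError(f"unknown fisher mode {mode!r}; choose from {FISHER_MODES}")
    n_d, n_bg = int(d.sum()), int(bg.sum())
    if n_d == 0:
        raise ValueError("dataset has no scored samples")
    # a dataset with MORE non-significant samples than the background rate
    # cannot be enriched in signature-associated samples
    if d[2] * n_bg > bg[2] * n_d:
        return 1.0
    rest = bg - d
    if rest.sum() == 0:
        return 1.0  # dataset IS the whole background: no contrast possible
    if mode == "collapse_2x2":
        table = np.array(
            [[d[0] + d[1], d[2]], [rest[0] + rest[1], rest[2]]]
        )
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if mode == "exact_2x3" and _n_tables_2x3(n_d, bg) <= max_enumeration:
        return _freeman_halton_2x3(d, bg)
    # Monte-Carlo under fixed margins (multivariate hypergeometric rows)
    rng = np.random.default_rng(seed)
    log_obs = _log_table_prob(d, bg, n_d)
    draws = rng.multivariate_hypergeometric(bg, n_d, size=max(n_draws, 100_000))
    logp = _log_table_prob(draws, bg, n_d)
    hits = int((logp <= log_obs + 1e-9).sum())
    return float((hits + 1) / (len(draws) + 1))


def _counts(categories: pd.Series) -> tuple:
    vc = categories.value_counts()
    return (
        int(vc.get(SIG_POSITIVE, 0)),
        int(vc.get(SIG_NEGATIVE, 0)),
        int(vc.get(NOT_SIGNIFICANT, 0)),
    )


def rank_datasets(
    scores: pd.DataFrame,
    q_threshold: float = 0.1,
    fisher_mode: str = "exact_2x3",
    tests: str = "both",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dataset enrichment table, FDR-corrected and sorted.

    ``scores`` is a categorized score table (see
    :func:`sigsearch.sa_score.categorize_scores`).  Datasets whose every
    score is undefined are omitted and logged.  Output is sorted
    ascending by ks_q, then fisher_q, then dataset_id (when only one test
    is run its q-value drives the sort).
    """
    if tests not in {"both", "ks", "fisher"}:
        raise ValueError(f"tests must be 'both', 'ks' or 'fisher', got {tests!r}")
    defined = scores[scores["defined"].fillna(False).astype(bool)]
    skipped = sorted(set(scores["dataset_id"]) - set(defined["dataset_id"]))
    for ds_id in skipped:
        logger.warning("dataset %s: all scores undefined; skipped", ds_id)
    if defined.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    background_sa = defined["SA"].to_numpy(dtype=float)
    background_counts = _counts(defined["category"])
    rows = []
    for ds_id, grp in defined.groupby("dataset_id", sort=True):
        counts = _counts(grp["category"])
        ks_p = (
            ks_enrichment(grp["SA"].to_numpy(dtype=float), background_sa)
            if tests in {"both", "ks"}
            else np.nan
        )
        fisher_p = (
            fisher_enrichment(
                counts, background_counts, mode=fisher_mode, seed=seed
            )
            if tests in {"both", "fisher"}
            else np.nan
        )
        if counts[0] > counts[1]:
            direction = "positive"
        elif counts[1] > counts[0]:
            direction = "negative"
        else:
            direction = "mixed"
        rows.append(
            DatasetEnrichment(
                dataset_id=ds_id,
                n_samples_scored=len(grp),
                counts=counts,
                background_counts=background_counts,
                ks_p=ks_p,
                fisher_p=fisher_p,
                direction=direction,
            )
        )
    table = pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in rows],
            "n_samples_scored": [r.n_samples_scored for r in rows],
            "n_sig_pos": [r.counts[0] for r in rows],
            "n_sig_neg": [r.counts[1] for r in rows],
            "n_ns": [r.counts[2] for r in rows],
            "ks_p": [r.ks_p for r in rows],
            "fisher_p": [r.fisher_p for r in rows],
            "direction": [r.direction for r in rows],
        }
    )
    table["ks_q"] = (
        multipletests(table["ks_p"].to_numpy(), method="fdr_bh")[1]
        if tests in {"both", "ks"}
        else np.nan
    )
    table["fisher_q"] = (
        multipletests(table["fisher_p"].to_numpy(), method="fdr_bh")[1]
        if tests in {"both", "fisher"}
        else np.nan
    )
    sort_cols = (
        ["ks_q", "fisher_q", "dataset_id"]
        if tests in {"both", "ks"}
        else ["fisher_q", "dataset_id"]
    )
    table = table.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    return table[ENRICHMENT_COLUMNS]


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
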