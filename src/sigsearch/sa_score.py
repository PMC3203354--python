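"""Per-sample signature association (SA) scores.

For one sample, the z-normalized values of the signature genes present on
the dataset's platform are pooled and midranked; a Wilcoxon rank-sum
statistic W is computed from the ranks of the "up" genes and standardized
by the mean and standard deviation of its null distribution:

    W  = sum(r_up) - n_up (n_up + 1) / 2
    mu = n_up n_down / 2
    sigma = sqrt( n_up n_down (n_up + n_down + 1) / 12 )
    SA = (W - mu) / sigma

Positive SA: the sample's up genes outrank its down genes.  The SA score
is referred to a t distribution with n_up + n_down - 2 degrees of freedom
for two-sided p-values; per-sample q-values are Benjamini-Hochberg over
all defined scores pooled across the whole compendium, and samples with
q <= threshold (default 0.1) are categorized significantly positive or
negative by the sign of SA.

Ties get midranks but sigma keeps the untied closed form (no tie
correction) — z-normalized continuous data make ties rare and this is a
deliberate fidelity choice.  No continuity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sigsearch.compendium import ExpressionDataset, NormalizedCompendium
from sigsearch.signature import Signature

__all__ = [
    "SampleScore",
    "compute_w",
    "sa_from_w",
    "sa_pvalue",
    "score_sample",
    "score_dataset",
    "score_compendium",
    "categorize_scores",
    "write_score_table",
    "SIG_POSITIVE",
    "SIG_NEGATIVE",
    "NOT_SIGNIFICANT",
]

SIG_POSITIVE = "sig_positive"
SIG_NEGATIVE = "sig_negative"
NOT_SIGNIFICANT = "not_significant"

SCORE_COLUMNS = [
    "sample_id",
    "dataset_id",
    "n_up_used",
    "n_down_used",
    "W",
    "SA",
    "p",
    "q",
    "category",
    "defined",
]


@dataclass
class SampleScore:
    """SA score for one sample, with provenance and significance fields.

    ``defined`` is False when too few signature genes were present on the
    dataset's platform; such scores carry NaN statistics and are excluded
    from background and enrichment rather than imputed.
    """

    sample_id: str
    dataset_id: str
    n_up_used: int
    n_down_used: int
    w: float
    sa: float
    p: float
    q: float = math.nan
    category: str | None = None
    defined: bool = True


def compute_w(ranks_up: Iterable[float], n_up: int, n_down: int) -> float:
    """Rank-sum statistic W from the midranks of the "up" genes.

    ``ranks_up`` must be the midranks of the up genes within the pooled
    (up + down) values; W ranges from 0 to n_up * n_down.
    """
    if n_up < 1 or n_down < 1:
        raise ValueError(
            f"score undefined: need n_up >= 1 and n_down >= 1 "
            f"(got {n_up}, {n_down})"
        )
    ranks_up = np.asarray(list(ranks_up), dtype=float)
    if ranks_up.size != n_up:
        raise ValueError(f"expected {n_up} up ranks, got {ranks_up.size}")
    return float(ranks_up.sum() - n_up * (n_up + 1) / 2.0)


def sa_from_w(w: float, n_up: int, n_down: int) -> float:
    """Standardize W by its null mean and standard deviation.

    Antisymmetric under swapping the up and down sets.
    """
    if n_up < 1 or n_down < 1:
        raise ValueError(
            f"score undefined: need n_up >= 1 and n_down >= 1 "
            f"(got {n_up}, {n_down})"
        )
    mu = n_up * n_down / 2.0
    sigma = math.sqrt(n_up * n_down * (n_up + n_down + 1) / 12.0)
    return (w - mu) / sigma


def sa_pvalue(sa: float, n_up: int, n_down: int) -> float:
    """Two-sided tail probability of |sa| under t(n_up + n_down - 2)."""
    df = n_up + n_down - 2
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(min(1.0, 2.0 * stats.t.sf(abs(sa), df)))


def _effective_sets(ds: ExpressionDataset, sig: Signature) -> tuple[list, list]:
    present = set(map(str, ds.values.index))
    up = sorted(g for g in sig.up if g in present)
    down = sorted(g for g in sig.down if g in present)
    return up, down


def score_sample(
    ds: ExpressionDataset,
    sample_id: str,
    sig: Signature,
    min_per_set: int = 2,
) -> SampleScore:
    """SA score for one sample of a z-normalized dataset.

    The signature is intersected with the dataset's genes; if either
    effective set has fewer than ``min_per_set`` members the score is
    returned flagged undefined (not an exception — a platform-coverage
    condition, not a usage error).
    """
    if sample_id not in ds.values.columns:
        raise KeyError(
            f"sample {sample_id!r} not in dataset {ds.dataset_id!r}"
        )
    up, down = _effective_sets(ds, sig)
    if len(up) < min_per_set or len(down) < min_per_set:
        return SampleScore(
            sample_id=sample_id,
            dataset_id=ds.dataset_id,
            n_up_used=len(up),
            n_down_used=len(down),
            w=math.nan,
            sa=math.nan,
            p=math.nan,
            defined=False,
        )
    pooled = ds.values.loc[up + down, sample_id].to_numpy(dtype=float)
    ranks = stats.rankdata(pooled)  # midranks
    w = compute_w(ranks[: len(up)], len(up), len(down))
    sa = sa_from_w(w, len(up), len(down))
    return SampleScore(
        sample_id=sample_id,
        dataset_id=ds.dataset_id,
        n_up_used=len(up),
        n_down_used=len(down),
        w=w,
        sa=sa,
        p=sa_pvalue(sa, len(up), len(down)),
    )


def score_dataset(
    ds: ExpressionDataset, sig: Signature, min_per_set: int = 2
) -> pd.DataFrame:
    """SA scores for every sample of ``ds`` (vectorized), as a DataFrame.

    Columns follow ``SCORE_COLUMNS``; q and category are left unfilled
    (they are compendium-level quantities, see :func:`categorize_scores`).
    """
    up, down = _effective_sets(ds, sig)
    n_up, n_down = len(up), len(down)
    n = ds.n_samples
    base = {
        "sample_id": ds.samples,
        "dataset_id": ds.dataset_id,
        "n_up_used": n_up,
        "n_down_used": n_down,
    }
    if n_up < min_per_set or n_down < min_per_set:
        return pd.DataFrame(
            {
                **base,
                "W": np.nan,
                "SA": np.nan,
                "p": np.nan,
                "q": np.nan,
                "category": None,
                "defined": False,
            },
            columns=SCORE_COLUMNS,
        )
    pooled = ds.values.loc[up + down].to_numpy(dtype=float)
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n_up].sum(axis=0) - n_up * (n_up + 1) / 2.0
    mu = n_up * n_down / 2.0
    sigma = math.sqrt(n_up * n_down * (n_up + n_down + 1) / 12.0)
    sa = (w - mu) / sigma
    df_t = n_up + n_down - 2
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(sa), df_t))
    return pd.DataFrame(
        {
            **base,
            "W": w,
            "SA": sa,
            "p": p,
            "q": np.nan,
            "category": None,
            "defined": True,
        },
        columns=SCORE_COLUMNS,
    )


def score_compendium(
    comp: NormalizedCompendium, sig: Signature, min_per_set: int = 2
) -> pd.DataFrame:
    """Concatenated :func:`score_dataset` tables for every dataset."""
    frames = [score_dataset(ds, sig, min_per_set=min_per_set) for ds in comp]
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def categorize_scores(scores: pd.DataFrame, q_threshold: float = 0.1) -> pd.DataFrame:
    """Fill q (BH-FDR) and significance category on a score table.

    BH is applied over all defined scores pooled across the whole
    compendium — every dataset is later compared against all samples in
    all datasets, so the multiplicity pool is the full compendium.
    """
    scores = scores.copy()
    defined = scores["defined"].fillna(False).astype(bool)
    scores["q"] = np.nan
    scores["category"] = None
    if defined.any():
        pvals = scores.loc[defined, "p"].to_numpy(dtype=float)
        q = multipletests(pvals, method="fdr_bh")[1]
        scores.loc[defined, "q"] = q
        sa = scores.loc[defined, "SA"].to_numpy(dtype=float)
        cat = np.where(
            (q <= q_threshold) & (sa > 0),
            SIG_POSITIVE,
            np.where((q <= q_threshold) & (sa < 0), SIG_NEGATIVE, NOT_SIGNIFICANT),
        )
        scores.loc[defined, "category"] = cat
    return scores


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample score table as TSV (undefined rows keep NA)."""
    out = scores.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
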