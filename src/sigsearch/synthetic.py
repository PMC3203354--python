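"""Synthetic compendia: null data, planted effects, shuffles, subsets.

Null datasets are i.i.d. standard normal matrices, per-gene z-normalized.
Planted effects add +effect_size to the signature's up genes and
-effect_size to its down genes in a chosen fraction of samples BEFORE
normalization — so the realized post-normalization shift depends on the
affected fraction (effect_size is nominal, not the realized z-shift).

All generators are bit-reproducible: each dataset gets its own generator
stream derived from the master seed and the dataset index, so datasets
can be generated independently (or in parallel) with identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from sigsearch.compendium import ExpressionDataset, NormalizedCompendium, znormalize
from sigsearch.signature import Signature

__all__ = [
    "SyntheticSpec",
    "gene_namespace",
    "simulate_compendium",
    "shuffle_genes",
    "subset_samples",
]

_FILLER_PREFIX = "NULLG"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic compendium.

    ``dataset_sizes[i]`` is the sample count of dataset ``i`` (named
    ``D000``, ``D001``, ...); indices in ``perturbed_datasets`` receive
    the planted up/down shift in ``round(affected_fraction * n)`` of
    their samples.
    """

    n_genes: int
    dataset_sizes: tuple
    sig: Signature
    effect_size: float = 0.0
    affected_fraction: float = 0.0
    perturbed_datasets: frozenset = field(default_factory=frozenset)
    seed: int = 0
    platform_id: str = "SIM"

    def __post_init__(self) -> None:
        object.__setattr__(self, "dataset_sizes", tuple(int(n) for n in self.dataset_sizes))
        object.__setattr__(
            self, "perturbed_datasets", frozenset(int(i) for i in self.perturbed_datasets)
        )
        if self.n_genes < 1 or any(n < 2 for n in self.dataset_sizes):
            raise ValueError(
                "n_genes must be >= 1 and every dataset needs >= 2 samples"
            )
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError(
                f"affected_fraction must be in [0, 1], got {self.affected_fraction}"
            )
        if not math.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        bad = [i for i in self.perturbed_datasets if not 0 <= i < len(self.dataset_sizes)]
        if bad:
            raise ValueError(f"perturbed dataset indices out of range: {bad}")
        if self.sig.n_total > self.n_genes:
            raise ValueError(
                f"signature has {self.sig.n_total} genes but namespace only "
                f"{self.n_genes}"
            )


def gene_namespace(spec: SyntheticSpec) -> list:
    """Gene identifiers: signature genes first, then numbered fillers."""
    genes = sorted(spec.sig.up) + sorted(spec.sig.down)
    n_filler = spec.n_genes - len(genes)
    genes += [f"{_FILLER_PREFIX}{i:05d}" for i in range(n_filler)]
    return genes


def _dataset_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_compendium(spec: SyntheticSpec) -> NormalizedCompendium:
    """Draw the compendium described by ``spec`` (z-normalized output)."""
    genes = gene_namespace(spec)
    missing = spec.sig.genes() - set(genes)
    if missing:
        raise ValueError(
            "signature gene(s) outside generated namespace: "
            + ", ".join(sorted(missing))
        )
    up_rows = np.arange(spec.sig.n_up)
    down_rows = np.arange(spec.sig.n_up, spec.sig.n_total)
    comp = NormalizedCompendium()
    for i, n in enumerate(spec.dataset_sizes):
        rng = _dataset_rng(spec.seed, i)
        x = rng.standard_normal((spec.n_genes, n))
        if i in spec.perturbed_datasets and spec.effect_size != 0.0:
            n_affected = int(math.floor(spec.affected_fraction * n + 0.5))
            if n_affected > 0:
                affected = rng.choice(n, size=n_affected, replace=False)
                x[np.ix_(up_rows, affected)] += spec.effect_size
                x[np.ix_(down_rows, affected)] -= spec.effect_size
        ds = ExpressionDataset(
            dataset_id=f"D{i:03d}",
            platform_id=spec.platform_id,
            values=pd.DataFrame(x, index=genes, columns=[f"D{i:03d}_S{j:03d}" for j in range(n)]),
        )
        comp.add(znormalize(ds))
    return comp


def shuffle_genes(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Permute each gene row independently across samples.

    Destroys between-gene coordination (and hence any planted signature
    signal) while conserving every row's value multiset.
    """
    rng = np.random.default_rng(seed)
    x = ds.values.to_numpy(dtype=float).copy()
    for row in x:
        rng.shuffle(row)
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        platform_id=ds.platform_id,
        values=pd.DataFrame(x, index=ds.values.index, columns=ds.values.columns),
    )


def subset_samples(
    ds: ExpressionDataset, n: int, seed: int, renormalize: bool = True
) -> ExpressionDataset:
    """Uniform without-replacement subset of ``n`` samples.

    By default the subset is re-z-normalized within itself, matching how
    a smaller dataset would have been normalized at intake; pass
    ``renormalize=False`` to keep the full-set z-scores (sensitivity
    analysis of that reading).
    """
    if not 2 <= n <= ds.n_samples:
        raise ValueError(
            f"subset size must be in [2, {ds.n_samples}], got {n}"
        )
    rng = np.random.default_rng(seed)
    cols = rng.choice(ds.n_samples, size=n, replace=False)
    cols.sort()
    sub = ExpressionDataset(
        dataset_id=ds.dataset_id,
        platform_id=ds.platform_id,
        values=ds.values.iloc[:, cols].copy(),
    )
    return znormalize(sub) if renormalize else sub
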