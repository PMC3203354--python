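"""Expression-dataset containers and within-dataset z-score normalization.

A compendium is a collection of datasets (GEO "series"-like units); each
dataset is a genes x samples matrix normalized independently of the
others, per gene, to mean 0 / sd 1 across that dataset's samples.  SA
ranks are only comparable within such a normalization block, so each
(dataset, platform) pair forms its own block and blocks are never merged
across platforms.

Matrix files are tab-delimited: first column gene_id, header row of
sample ids.  A compendium on disk is a manifest TSV with columns
``dataset_id``, ``platform_id``, ``path``, ``already_normalized`` plus
one matrix file per dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "NormalizedCompendium",
    "znormalize",
    "read_matrix",
    "write_matrix",
    "load_compendium",
    "save_compendium",
]

logger = logging.getLogger("sigsearch")

MANIFEST_COLUMNS = ["dataset_id", "platform_id", "path", "already_normalized"]


@dataclass
class ExpressionDataset:
    """One dataset's genes x samples matrix with identity metadata.

    ``values`` is a pandas DataFrame indexed by gene identifier with one
    column per sample identifier.  Gene and sample identifiers must be
    unique; values must be finite (missing values are a load-time policy,
    see :func:`read_matrix`).
    """

    dataset_id: str
    platform_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate gene identifiers: "
                + ", ".join(map(str, dupes[:5]))
            )
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate sample identifiers: "
                + ", ".join(map(str, dupes[:5]))
            )
        if self.values.size and not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(
                f"dataset {self.dataset_id!r}: non-finite values present"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def znormalize(ds: ExpressionDataset, ddof: int = 1) -> ExpressionDataset:
    """Z-score each gene row to mean 0 / sd 1 across the dataset's samples.

    The divisor is the sample standard deviation (``ddof=1``); rows with
    zero variance map to all-zero rows rather than NaN, so a gene constant
    within a dataset contributes only mid-rank information downstream.

    Raises
    ------
    ValueError
        For single-sample datasets (a one-sample dataset carries no
        relative-expression information).
    """
    if ds.n_samples < 2:
        raise ValueError(
            f"dataset {ds.dataset_id!r}: z-score normalization requires >= 2 "
            f"samples, got {ds.n_samples}"
        )
    x = ds.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    out = np.zeros_like(x)
    nonzero = sd[:, 0] > 0
    out[nonzero] = (x[nonzero] - mean[nonzero]) / sd[nonzero]
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        platform_id=ds.platform_id,
        values=pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns),
    )


def read_matrix(path: str | Path, dataset_id: str = "?") -> pd.DataFrame:
    """Read a tab-delimited genes x samples matrix.

    Rows containing any missing value are dropped with a logged warning
    (imputation would invent data; upstream summarization pipelines
    produce complete matrices).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dataset %s: dropping %d gene row(s) with missing values",
            dataset_id,
            int(incomplete.sum()),
        )
        df = df.loc[~incomplete]
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class NormalizedCompendium:
    """Collection of per-dataset z-normalized matrices.

    ``datasets`` maps dataset_id to :class:`ExpressionDataset`; the gene
    namespace is the union across datasets — genes absent from a dataset
    are simply absent, never imputed.
    """

    datasets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, ds in self.datasets.items():
            if key != ds.dataset_id:
                raise ValueError(
                    f"manifest key {key!r} != dataset_id {ds.dataset_id!r}"
                )

    def __iter__(self) -> Iterator[ExpressionDataset]:
        return iter(self.datasets.values())

    def __len__(self) -> int:
        return len(self.datasets)

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        return self.datasets[dataset_id]

    def add(self, ds: ExpressionDataset) -> None:
        if ds.dataset_id in self.datasets:
            raise ValueError(f"duplicate dataset_id: {ds.dataset_id!r}")
        self.datasets[ds.dataset_id] = ds

    def replace(self, ds: ExpressionDataset) -> "NormalizedCompendium":
        """New compendium with dataset ``ds.dataset_id`` swapped for ``ds``."""
        if ds.dataset_id not in self.datasets:
            raise KeyError(ds.dataset_id)
        new = dict(self.datasets)
        new[ds.dataset_id] = ds
        return NormalizedCompendium(datasets=new)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.datasets)

    @property
    def n_samples(self) -> int:
        return sum(ds.n_samples for ds in self)

    def gene_namespace(self) -> frozenset:
        out: set[str] = set()
        for ds in self:
            out.update(ds.values.index)
        return frozenset(out)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": [ds.dataset_id for ds in self],
                "platform_id": [ds.platform_id for ds in self],
                "n_genes": [ds.n_genes for ds in self],
                "n_samples": [ds.n_samples for ds in self],
            }
        )


def load_compendium(manifest_path: str | Path) -> NormalizedCompendium:
    """Load a compendium from a manifest TSV; z-normalize where flagged.

    The manifest needs columns ``dataset_id``, ``platform_id``, ``path``
    and ``already_normalized`` (boolean-ish).  Matrix paths are resolved
    relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    man = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ValueError(
            f"manifest {manifest_path}: missing column(s): {', '.join(missing)}"
        )
    if man["dataset_id"].duplicated().any():
        dupes = man.loc[man["dataset_id"].duplicated(), "dataset_id"].unique()
        raise ValueError(
            f"manifest {manifest_path}: duplicate dataset_id(s): "
            + ", ".join(dupes)
        )
    comp = NormalizedCompendium()
    for row in man.itertuples(index=False):
        matrix_path = Path(row.path)
        if not matrix_path.is_absolute():
            matrix_path = manifest_path.parent / matrix_path
        try:
            values = read_matrix(matrix_path, dataset_id=row.dataset_id)
        except Exception as exc:
            raise ValueError(
                f"manifest {manifest_path}: cannot read matrix for dataset "
                f"{row.dataset_id!r} at {matrix_path}: {exc}"
            ) from exc
        ds = ExpressionDataset(
            dataset_id=row.dataset_id, platform_id=row.platform_id, values=values
        )
        flag = str(row.already_normalized).strip().lower()
        if flag not in {"true", "false", "1", "0", "yes", "no"}:
            raise ValueError(
                f"manifest {manifest_path}: dataset {row.dataset_id!r}: "
                f"already_normalized must be boolean, got {row.already_normalized!r}"
            )
        if flag in {"false", "0", "no"}:
            ds = znormalize(ds)
        comp.add(ds)
    return comp


def save_compendium(comp: NormalizedCompendium, out_dir: str | Path) -> Path:
    """Write per-dataset matrix TSVs plus a manifest; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in comp:
        fname = f"{ds.dataset_id}.tsv"
        write_matrix(ds.values, out_dir / fname)
        rows.append(
            {
                "dataset_id": ds.dataset_id,
                "platform_id": ds.platform_id,
                "path": fname,
                "already_normalized": True,
            }
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest_path, sep="\t", index=False
    )
    return manifest_path
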