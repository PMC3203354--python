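"""Query-signature containers and IO.

A query signature is a named pair of disjoint gene-identifier sets: genes
coordinately induced ("up") and repressed ("down") under some reference
perturbation.  Identifiers are opaque text (typically Entrez Gene IDs);
no translation between namespaces is attempted.

Two file formats are supported:

``two_column``
    Tab-delimited rows of ``gene_id<TAB>direction`` with direction in
    {``up``, ``down``}; an optional header row ``gene<TAB>direction``.
``gmt_pair``
    Two standard GMT records named ``<name>_UP`` and ``<name>_DOWN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Signature",
    "SignatureError",
    "parse_signature",
    "write_signature",
    "subsample_signature",
]


class SignatureError(ValueError):
    """Raised for invalid signature content (parse or validation failure)."""


def _clean(gene: str) -> str:
    # strip surrounding whitespace, preserve case: Entrez IDs are numeric
    # strings and symbol case is meaningful in some namespaces
    return gene.strip()


@dataclass(frozen=True)
class Signature:
    """Disjoint, non-empty "up" and "down" gene-identifier sets.

    Parameters
    ----------
    name
        Text label for the signature.
    up, down
        Gene identifiers coordinately induced / repressed by the
        reference perturbation.  Any iterable of strings; stored as
        frozensets after whitespace stripping.

    Raises
    ------
    SignatureError
        If either set is empty or the two sets intersect.
    """

    name: str
    up: frozenset = field(default_factory=frozenset)
    down: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        up = frozenset(_clean(g) for g in self.up)
        down = frozenset(_clean(g) for g in self.down)
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        if not up or not down:
            raise SignatureError(
                f"signature {self.name!r}: both 'up' and 'down' sets must be "
                f"non-empty (got |up|={len(up)}, |down|={len(down)})"
            )
        overlap = up & down
        if overlap:
            raise SignatureError(
                f"signature {self.name!r}: gene(s) listed in both directions: "
                + ", ".join(sorted(overlap))
            )

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down)

    def genes(self) -> frozenset:
        return self.up | self.down


_DIRECTIONS = {"up": "up", "down": "down"}


def _parse_two_column(path: Path, name: str) -> Signature:
    up: set[str] = set()
    down: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                raise SignatureError(
                    f"{path}:{lineno}: expected 'gene<TAB>direction', got {line!r}"
                )
            gene, direction = parts[0], parts[1].lower()
            if lineno == 1 and gene.lower() == "gene" and direction == "direction":
                continue  # header row
            if direction not in _DIRECTIONS:
                raise SignatureError(
                    f"{path}:{lineno}: unknown direction token {parts[1]!r} "
                    f"(expected 'up' or 'down')"
                )
            gene = _clean(gene)
            target = up if direction == "up" else down
            other = down if direction == "up" else up
            if gene in other:
                raise SignatureError(
                    f"{path}: gene {gene!r} listed in both directions"
                )
            target.add(gene)
    if not up or not down:
        raise SignatureError(
            f"{path}: signature must contain at least one 'up' and one "
            f"'down' gene (got {len(up)} up, {len(down)} down)"
        )
    return Signature(name=name, up=frozenset(up), down=frozenset(down))


def _parse_gmt_pair(path: Path, name: str | None) -> Signature:
    records: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SignatureError(
                    f"{path}:{lineno}: GMT record needs name, description and "
                    f"at least one member"
                )
            records[parts[0].strip()] = [_clean(g) for g in parts[2:] if g.strip()]
    ups = {k[: -len("_UP")]: v for k, v in records.items() if k.endswith("_UP")}
    downs = {k[: -len("_DOWN")]: v for k, v in records.items() if k.endswith("_DOWN")}
    common = set(ups) & set(downs)
    if name is not None:
        common &= {name}
    if len(common) != 1:
        raise SignatureError(
            f"{path}: expected exactly one matching <name>_UP / <name>_DOWN "
            f"record pair, found {sorted(common) or 'none'}"
        )
    sig_name = common.pop()
    up = set(ups[sig_name])
    down = set(downs[sig_name])
    overlap = up & down
    if overlap:
        raise SignatureError(
            f"{path}: gene(s) listed in both directions: "
            + ", ".join(sorted(overlap))
        )
    return Signature(name=sig_name, up=frozenset(up), down=frozenset(down))


def parse_signature(
    path: str | Path, format: str = "two_column", name: str | None = None
) -> Signature:
    """Read a signature file and return a validated :class:`Signature`.

    Parameters
    ----------
    path
        Signature file.
    format
        ``"two_column"`` or ``"gmt_pair"`` (see module docstring).
    name
        Label for the signature.  Defaults to the file stem for
        ``two_column``; for ``gmt_pair`` the GMT record prefix is used and
        ``name``, if given, selects among multiple pairs.

    Duplicate (gene, direction) rows collapse to a single entry; a gene
    appearing in both directions raises :class:`SignatureError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature file not found: {path}")
    if format == "two_column":
        return _parse_two_column(path, name or path.stem)
    if format == "gmt_pair":
        return _parse_gmt_pair(path, name)
    raise ValueError(f"unknown signature format: {format!r}")


def write_signature(sig: Signature, path: str | Path, format: str = "two_column") -> None:
    """Write ``sig`` to ``path`` in the given format (inverse of parsing)."""
    path = Path(path)
    if format == "two_column":
        with open(path, "w") as fh:
            fh.write("gene\tdirection\n")
            for gene in sorted(sig.up):
                fh.write(f"{gene}\tup\n")
            for gene in sorted(sig.down):
                fh.write(f"{gene}\tdown\n")
    elif format == "gmt_pair":
        with open(path, "w") as fh:
            fh.write("\t".join([f"{sig.name}_UP", "na", *sorted(sig.up)]) + "\n")
            fh.write("\t".join([f"{sig.name}_DOWN", "na", *sorted(sig.down)]) + "\n")
    else:
        raise ValueError(f"unknown signature format: {format!r}")


def _round_half_away(x: float) -> int:
    """Round half away from zero (fixed here for reproducibility)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def subsample_signature(
    sig: Signature, n_total: int, up_fraction: float, seed: int
) -> Signature:
    """Draw a smaller signature uniformly without replacement.

    Exactly ``round(n_total * up_fraction)`` up genes (round half away
    from zero) and the remaining ``n_total - that`` down genes are drawn.
    Identical ``(sig, n_total, up_fraction, seed)`` give identical output.

    Raises
    ------
    SignatureError
        If either requested count is zero or exceeds the available genes.
    """
    if not 0.0 < up_fraction < 1.0:
        raise SignatureError(f"up_fraction must be in (0, 1), got {up_fraction}")
    n_up = _round_half_away(n_total * up_fraction)
    n_down = n_total - n_up
    if n_up < 1 or n_down < 1:
        raise SignatureError(
            f"infeasible subsample: n_total={n_total}, up_fraction={up_fraction} "
            f"gives {n_up} up / {n_down} down; both must be >= 1"
        )
    if n_up > sig.n_up or n_down > sig.n_down:
        raise SignatureError(
            f"requested {n_up} up / {n_down} down but signature {sig.name!r} "
            f"has only {sig.n_up} up / {sig.n_down} down"
        )
    rng = np.random.default_rng(seed)
    up = rng.choice(sorted(sig.up), size=n_up, replace=False)
    down = rng.choice(sorted(sig.down), size=n_down, replace=False)
    return Signature(
        name=f"{sig.name}|sub{n_total}u{n_up}",
        up=frozenset(up.tolist()),
        down=frozenset(down.tolist()),
    )
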