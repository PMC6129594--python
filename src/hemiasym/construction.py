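"""Build hemispheric networks from whole-brain connectivity matrices.

A whole-brain structural connectome is given as two square symmetric
matrices over the parcellation nodes: streamline counts (fiber number,
FN) and fractional-anisotropy weights (FA, in [0, 1]).  An edge is
retained only when its fiber number strictly exceeds a count threshold
(default 3), which suppresses spurious tractography connections; the
surviving FA values are the edge weights.  Inter-hemispheric
connections are then discarded, leaving one weighted network per
hemisphere whose node order follows the parcellation.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationScheme",
    "HemisphericNetwork",
    "SubjectConnectome",
    "apply_fn_threshold",
    "split_hemispheres",
    "construct_subject_networks",
    "default_parcellation",
    "DEFAULT_FN_THRESHOLD",
]

DEFAULT_FN_THRESHOLD = 3
SYMMETRY_TOL = 1e-8


def _check_square_symmetric(m: np.ndarray, what: str, tol: float = SYMMETRY_TOL) -> None:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{what} must be square, got shape {m.shape}")
    # exact-equality fast path; fall back to tolerance comparison
    if not np.array_equal(m, m.T) and not np.allclose(m, m.T, atol=tol, rtol=0.0):
        raise ValueError(f"{what} is asymmetric beyond tolerance {tol}")


@dataclass(frozen=True)
class ParcellationScheme:
    """Node index / region name / hemisphere mapping for a parcellation.

    ``table`` has columns ``index``, ``name``, ``abbrev``, ``hemisphere``
    ordered by matrix position.  Left and right hemispheres must contain
    the same number of regions, and the k-th left region is treated as
    homotopic to the k-th right region (the AAL atlas pairs names
    exactly, in alternating L/R order).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"index", "name", "abbrev", "hemisphere"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"parcellation missing columns: {sorted(missing)}")
        if not (t["index"].to_numpy() == np.arange(len(t))).all():
            raise ValueError("parcellation node indices must be contiguous from 0")
        if not set(t["hemisphere"]) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        left = t[t["hemisphere"] == "L"]
        right = t[t["hemisphere"] == "R"]
        if len(left) != len(right):
            raise ValueError(
                f"unequal hemisphere sizes: {len(left)} L vs {len(right)} R"
            )
        for hemi, sub in (("L", left), ("R", right)):
            if sub["abbrev"].duplicated().any():
                dups = sub.loc[sub["abbrev"].duplicated(), "abbrev"].tolist()
                raise ValueError(f"duplicate abbreviations in hemisphere {hemi}: {dups}")
        if list(left["abbrev"]) != list(right["abbrev"]):
            raise ValueError(
                "left and right abbreviation sequences differ; homotopic "
                "pairing by position requires matching order"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def n_per_hemisphere(self) -> int:
        return self.n_nodes // 2

    def indices(self, hemisphere: str) -> np.ndarray:
        """Matrix positions of one hemisphere's nodes, in parcellation order."""
        mask = self.table["hemisphere"].to_numpy() == hemisphere
        return self.table["index"].to_numpy()[mask]

    def labels(self, hemisphere: str) -> list[str]:
        mask = self.table["hemisphere"].to_numpy() == hemisphere
        return self.table.loc[mask, "abbrev"].tolist()

    @classmethod
    def from_tsv(cls, path) -> "ParcellationScheme":
        table = pd.read_csv(path, sep="\t")
        return cls(table.reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def synthetic(cls, n_per_hemisphere: int) -> "ParcellationScheme":
        """Generic alternating-L/R parcellation for simulated cohorts."""
        rows = []
        for k in range(n_per_hemisphere):
            for j, hemi in enumerate(("L", "R")):
                rows.append(
                    {
                        "index": 2 * k + j,
                        "name": f"Region {k + 1:02d}",
                        "abbrev": f"R{k + 1:02d}",
                        "hemisphere": hemi,
                    }
                )
        return cls(pd.DataFrame(rows))


@functools.lru_cache(maxsize=1)
def default_parcellation() -> ParcellationScheme:
    """The packaged 90-region AAL scheme (45 regions per hemisphere)."""
    ref = importlib.resources.files("hemiasym.data").joinpath("aal90.tsv")
    with importlib.resources.as_file(ref) as path:
        return ParcellationScheme.from_tsv(path)


@dataclass
class SubjectConnectome:
    """One subject's whole-brain fiber-count and FA matrices."""

    subject_id: str
    fn: np.ndarray
    fa: np.ndarray

    def validate(self) -> None:
        _check_square_symmetric(self.fn, f"{self.subject_id} FN matrix")
        _check_square_symmetric(self.fa, f"{self.subject_id} FA matrix")
        if self.fn.shape != self.fa.shape:
            raise ValueError(
                f"{self.subject_id}: FN shape {self.fn.shape} != FA shape {self.fa.shape}"
            )
        if np.any(np.diag(self.fa) != 0) or np.any(np.diag(self.fn) != 0):
            raise ValueError(f"{self.subject_id}: nonzero diagonal")
        if self.fa.min() < 0 or self.fa.max() > 1:
            raise ValueError(f"{self.subject_id}: FA values outside [0, 1]")
        if np.any((self.fa > 0) & (self.fn <= 0)):
            raise ValueError(f"{self.subject_id}: FA support exceeds FN support")


@dataclass
class HemisphericNetwork:
    """A weighted intra-hemispheric network (FA adjacency).

    ``node_labels`` are region abbreviations in parcellation order; the
    L and R networks of one subject share the same label sequence so
    position k pairs homotopic regions.
    """

    hemisphere: str
    adjacency: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        _check_square_symmetric(self.adjacency, f"{self.hemisphere} adjacency")
        if self.adjacency.shape[0] != len(self.node_labels):
            raise ValueError("adjacency size does not match node_labels")
        if self.adjacency.min() < 0 or self.adjacency.max() > 1:
            raise ValueError("FA weights must lie in [0, 1]")
        np.fill_diagonal(self.adjacency, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


def apply_fn_threshold(
    fn: np.ndarray, fa: np.ndarray, threshold: int = DEFAULT_FN_THRESHOLD
) -> np.ndarray:
    """Keep an FA edge only where the fiber number strictly exceeds ``threshold``.

    The comparison is strict: with the default threshold of 3, an edge
    supported by exactly 3 streamlines is removed.
    """
    fn = np.asarray(fn)
    fa = np.asarray(fa, dtype=float)
    _check_square_symmetric(fn, "FN matrix")
    _check_square_symmetric(fa, "FA matrix")
    if fn.shape != fa.shape:
        raise ValueError(f"FN shape {fn.shape} != FA shape {fa.shape}")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    out = np.where(fn > threshold, fa, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def split_hemispheres(
    adjacency: np.ndarray, parcellation: ParcellationScheme
) -> tuple[HemisphericNetwork, HemisphericNetwork]:
    """Drop inter-hemispheric edges and return the two hemispheric networks."""
    adjacency = np.asarray(adjacency, dtype=float)
    _check_square_symmetric(adjacency, "whole-brain adjacency")
    if adjacency.shape[0] != parcellation.n_nodes:
        raise ValueError(
            f"matrix dimension {adjacency.shape[0]} != parcellation size "
            f"{parcellation.n_nodes}"
        )
    out = []
    for hemi in ("L", "R"):
        idx = parcellation.indices(hemi)
        block = adjacency[np.ix_(idx, idx)]
        out.append(
            HemisphericNetwork(
                hemisphere=hemi,
                adjacency=block,
                node_labels=parcellation.labels(hemi),
            )
        )
    return out[0], out[1]


def construct_subject_networks(
    connectome: SubjectConnectome,
    parcellation: ParcellationScheme,
    threshold: int = DEFAULT_FN_THRESHOLD,
) -> tuple[HemisphericNetwork, HemisphericNetwork]:
    """Threshold by fiber number, then split into L and R networks.

    Thresholding and splitting commute (both act entrywise / blockwise),
    so the order is a convention, not a choice with consequences.
    """
    connectome.validate()
    kept = apply_fn_threshold(connectome.fn, connectome.fa, threshold)
    return split_hemispheres(kept, parcellation)
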