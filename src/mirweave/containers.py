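"""In-memory containers for the pipeline's core data.

Counts live in a thin :class:`CountMatrix` wrapper around a pandas
DataFrame (features x samples, integer); gene sets in
:class:`GeneSetCollection`; predicted miRNA->gene interactions in
:class:`TargetCompendium`. Results (differential-expression tables,
enrichment tables) are plain DataFrames with documented columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CountMatrix:
    """Integer count matrix, features x samples.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts with unique feature index and
        unique sample columns.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample column sums."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"CountMatrix({g} features x {s} samples)"


#: Required metadata columns; `group` must contain the two study arms.
METADATA_COLUMNS = ("group", "Sex", "Age", "PMI", "pH", "RIN")
GROUP_CASE = "case"
GROUP_CONTROL = "control"


def validate_metadata(meta: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Check a sample-metadata table (one row per sample, indexed by id)."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    groups = set(meta["group"])
    if not {GROUP_CASE, GROUP_CONTROL} <= groups:
        raise ValueError(f"metadata must contain both 'case' and 'control' samples, got {sorted(groups)}")
    if sample_ids is not None:
        absent = [s for s in sample_ids if s not in meta.index]
        if absent:
            raise ValueError(f"samples missing from metadata: {absent[:5]}")
    return meta


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)
        self.descriptions = {n: self.descriptions.get(n, "") for n in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def restricted_to(self, universe) -> "GeneSetCollection":
        """Intersect every set with `universe`, dropping emptied sets."""
        uni = frozenset(universe)
        kept = {n: s & uni for n, s in self.sets.items() if s & uni}
        return GeneSetCollection(kept, {n: self.descriptions[n] for n in kept})


@dataclass
class TargetCompendium:
    """Predicted miRNA -> target-gene interactions (miRDB-style)."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            if len(genes) == 0:
                raise ValueError(f"miRNA {mirna!r} has no predicted targets")
            self.targets[mirna] = frozenset(genes)

    @property
    def universe(self) -> frozenset[str]:
        """All genes appearing as a predicted target of any miRNA."""
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return frozenset(out)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, genes in self.targets.items() for g in genes}

    def __len__(self) -> int:
        return len(self.targets)
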