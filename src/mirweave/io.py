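"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV (feature-id column plus one column per sample),
metadata as CSV, gene sets as MSigDB-dialect GMT, the target compendium
as a two-column miRNA<TAB>gene TSV, and networks as edge-list TSV and
Cytoscape SIF. All writers produce byte-stable output for a given
input, so identical runs diff clean.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, TargetCompendium, validate_metadata

FLOAT_FORMAT = "%.10g"


def read_counts(path) -> CountMatrix:
    """Read a features x samples TSV of integer counts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature id(s) {dupes[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for i, row in enumerate(df.itertuples(), start=2):
            for v in row[1:]:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(f"{path}: non-numeric count at line {i}") from None
    frac = values.astype(float) - np.round(values.astype(float))
    if np.abs(frac).max() > 0:
        bad_row = int(np.argwhere(np.abs(frac) > 0)[0][0])
        raise ValueError(f"{path}: non-integer count at line {bad_row + 2}")
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, index_label="sample_id", float_format=FLOAT_FORMAT, lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """MSigDB GMT dialect: name, description, then tab-separated members."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


def read_compendium(path) -> TargetCompendium:
    """Two-column miRNA<TAB>gene TSV (no header)."""
    targets: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected exactly 2 tab-separated fields")
            mirna, gene = fields
            if (mirna, gene) in seen:
                continue
            seen.add((mirna, gene))
            targets.setdefault(mirna, set()).add(gene)
    return TargetCompendium({m: frozenset(g) for m, g in targets.items()})


def write_compendium(compendium: TargetCompendium, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(compendium.targets):
            for gene in sorted(compendium.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def write_term_annotation(annotation: dict, path) -> None:
    """pathway<TAB>term TSV, one row per (pathway, term)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for pathway in sorted(annotation):
            for term in sorted(annotation[pathway]):
                fh.write(f"{pathway}\t{term}\n")


def read_term_annotation(path) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected pathway<TAB>term")
            out.setdefault(fields[0], set()).add(fields[1])
    return {k: frozenset(v) for k, v in out.items()}


def write_table(df: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    """Generic TSV table writer with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path, sep="\t", index=index, index_label=index_label,
        float_format=FLOAT_FORMAT, lineterminator="\n",
    )


def write_network_sif(edges, path, relation: str = "targets") -> None:
    """Cytoscape SIF: source<TAB>relation<TAB>target per edge."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for mirna, gene in sorted(edges):
            fh.write(f"{mirna}\t{relation}\t{gene}\n")


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
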