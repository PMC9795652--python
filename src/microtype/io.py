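"""Readers and writers for the on-disk formats the pipeline touches.

Feature tables live on disk in the classic QIIME dialect — features in
rows, samples in columns, optional trailing ``taxonomy`` column — and are
transposed to samples × features in memory.  Trees are newick (scikit-bio),
metadata is CSV, networks go out as GraphML, run manifests as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .core import FeatureTable, ParseError, SampleMetadata, ValidationError, detect_relative

log = logging.getLogger("microtype")

TAXONOMY_COLUMNS = ("taxonomy", "Taxonomy", "Consensus Lineage")


def read_feature_table(path: str | Path, level: str) -> FeatureTable:
    """Read a TSV feature table (features × samples on disk).

    The header row holds sample ids; the first column holds feature ids.
    A trailing taxonomy column (named ``taxonomy``) is split off into the
    table's taxonomy mapping.  Counts vs proportions are detected from row
    sums after transposition.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: malformed table: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: table has no sample columns")

    taxonomy = None
    for col in TAXONOMY_COLUMNS:
        if col in df.columns:
            taxonomy = df[col].astype(str).to_dict()
            df = df.drop(columns=[col])
            break

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated feature id(s): {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated sample id(s): {dups}")

    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance value: {exc}") from exc
    if (values.to_numpy() < 0).any():
        i, j = np.argwhere(values.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative value at feature {values.index[i]!r}, sample {values.columns[j]!r}"
        )

    wide = values.T  # samples × features in memory
    wide.index.name = None
    wide.columns.name = None
    log.info("read %s: %d samples × %d features (transposed from disk layout)",
             path.name, wide.shape[0], wide.shape[1])
    return FeatureTable(wide, level=level, taxonomy=taxonomy, is_relative=detect_relative(wide))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write back in the on-disk dialect (features × samples)."""
    df = table.data.T.copy()
    if table.taxonomy:
        df["taxonomy"] = [table.taxonomy.get(f, "") for f in df.index]
    df.index.name = "#FeatureID"
    df.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    path = Path(path)
    try:
        tree = skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:
        raise ParseError(f"{path}: newick parse error: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(f"{path}: negative branch length at {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        log.warning("%s: %d branches had no length; set to 0", path.name, n_missing)
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, index_col=0)
    if "yfas_diagnosis" in df.columns:
        df["yfas_diagnosis"] = df["yfas_diagnosis"].astype(bool)
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path: str | Path) -> None:
    out = md.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest: seed, thresholds, package versions."""
    import microtype

    payload = {"microtype_version": microtype.__version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def check_shared_samples(*tables_and_names) -> list[str]:
    """Assert all inputs cover the same sample set; return the shared order.

    Accepts (object, name) pairs where object exposes ``sample_ids``.
    """
    ref_obj, ref_name = tables_and_names[0]
    ref = list(ref_obj.sample_ids)
    for obj, name in tables_and_names[1:]:
        got = set(obj.sample_ids)
        if got != set(ref):
            diff = sorted(got ^ set(ref))
            raise ValidationError(
                f"sample ids differ between {ref_name} and {name}; symmetric difference: {diff}"
            )
    return ref
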