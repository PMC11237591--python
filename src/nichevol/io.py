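"""TSV / Newick / GraphML input-output.

Count tables are written taxa-rows x sample-columns with the first column
holding the zOTU id; metadata is one row per sample (sample, habitat, park,
x, y).  Trees go through dendropy as Newick.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import networkx as nx
import pandas as pd

from .containers import CommunityTable, GroundTruth


def write_table(table: CommunityTable, counts_path, meta_path) -> None:
    out = table.counts.copy()
    out.index.name = "zotu_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.meta.copy()
    meta.index.name = "sample"
    meta.to_csv(meta_path, sep="\t")


def read_table(counts_path, meta_path) -> CommunityTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta.index = meta.index.astype(str)
    return CommunityTable(counts, meta)


def write_ground_truth(truth: GroundTruth, path) -> None:
    df = truth.preferences.copy()
    df.insert(0, "label", truth.labels)
    if truth.home_park is not None:
        df["home_park"] = truth.home_park
    df.index.name = "zotu_id"
    df.to_csv(path, sep="\t")


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    labels = df["label"]
    home = df["home_park"] if "home_park" in df.columns else None
    prefs = df.drop(columns=[c for c in ("label", "home_park") if c in df.columns])
    return GroundTruth(labels=labels, preferences=prefs, home_park=home)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
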