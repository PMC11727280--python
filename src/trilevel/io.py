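"""TSV / config I/O for datasets, structure maps and labels."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structure import HierarchicalStructure
from .synthetic import Dataset

__all__ = [
    "column_names",
    "write_dataset",
    "read_matrix",
    "read_outcome",
    "write_structure_map",
    "read_structure_map",
    "write_labels",
    "read_labels",
    "load_config",
]


def column_names(structure: HierarchicalStructure) -> list[str]:
    """Header names ``cluster{c}_gene{g}_omics{o}`` in column order."""
    names = [""] * structure.p
    for g in range(structure.G):
        c = structure.cluster_of_gene[g]
        for o, col in enumerate(structure.columns_of_gene[g]):
            names[col] = f"cluster{c}_gene{g}_omics{o}"
    return names


def write_dataset(dataset: Dataset, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>_X.tsv``, ``<prefix>_y.tsv`` and the sidecar
    structure map ``<prefix>_structure.tsv``."""
    prefix = Path(prefix)
    paths = {
        "X": prefix.with_name(prefix.name + "_X.tsv"),
        "y": prefix.with_name(prefix.name + "_y.tsv"),
        "structure": prefix.with_name(prefix.name + "_structure.tsv"),
    }
    pd.DataFrame(dataset.X, columns=column_names(dataset.structure)).to_csv(
        paths["X"], sep="\t", index=False
    )
    pd.DataFrame({"y": dataset.y}).to_csv(paths["y"], sep="\t", index=False)
    write_structure_map(dataset.structure, paths["structure"])
    return paths


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def read_outcome(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").iloc[:, 0].to_numpy(dtype=int)


def write_structure_map(structure: HierarchicalStructure,
                        path: str | Path) -> None:
    rows = []
    for g in range(structure.G):
        for o, col in enumerate(structure.columns_of_gene[g]):
            rows.append({
                "column_index": int(col),
                "cluster": int(structure.cluster_of_gene[g]),
                "gene": int(g),
                "omics_type": int(o),
            })
    pd.DataFrame(rows).sort_values("column_index").to_csv(
        path, sep="\t", index=False
    )


def read_structure_map(path: str | Path) -> HierarchicalStructure:
    df = pd.read_csv(path, sep="\t").sort_values(["gene", "omics_type"])
    genes = df["gene"].unique()
    n0 = int(df.groupby("gene").size().iloc[0])
    G = genes.size
    cols = df["column_index"].to_numpy(dtype=np.intp).reshape(G, n0)
    cl = df.groupby("gene")["cluster"].first().to_numpy(dtype=np.intp)
    return HierarchicalStructure(
        n0=n0, cluster_of_gene=cl, columns_of_gene=cols,
        n_clusters=int(cl.max() + 1),
    )


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"gene": np.arange(len(labels)),
                  "cluster": np.asarray(labels, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("gene")
    return df["cluster"].to_numpy(dtype=np.intp)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        return json.loads(text)
    return yaml.safe_load(text)
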