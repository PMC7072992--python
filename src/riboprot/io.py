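"""TSV and newick I/O for the analysis containers.

All on-disk formats are plain text: square TSV distance matrices, gene ×
sample counts TSV with a separate metadata TSV and gene-length TSV, synteny
blocks as (species, position, gene, strand) TSV, and newick trees with
bootstrap supports as internal-node labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .expression import CountsMatrix
from .wgd import SyntenyBlock

PathLike = Union[str, Path]

__all__ = [
    "read_distance_matrix",
    "write_distance_matrix",
    "read_counts",
    "write_counts",
    "read_sample_meta",
    "read_gene_lengths",
    "read_synteny_blocks",
    "write_tree",
    "read_tree",
]


def read_distance_matrix(path: PathLike) -> DistanceMatrix:
    """Square TSV (labels in first row and column) -> DistanceMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)))


def write_distance_matrix(dm: DistanceMatrix, path: PathLike) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_counts(counts_path: PathLike, library_sizes_path: PathLike) -> CountsMatrix:
    """Genes × samples counts TSV plus a (sample_id, library_size) TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lib = pd.read_csv(library_sizes_path, sep="\t", index_col=0).iloc[:, 0]
    return CountsMatrix(counts=counts, library_sizes=lib)


def write_counts(cm: CountsMatrix, counts_path: PathLike, library_sizes_path: PathLike) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.library_sizes.rename("library_size").to_csv(library_sizes_path, sep="\t")


def read_sample_meta(path: PathLike) -> pd.DataFrame:
    """Sample metadata TSV indexed by sample_id (stage/genotype or tissue)."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_gene_lengths(path: PathLike) -> pd.Series:
    """Two-column (gene, length_bp) TSV -> Series of lengths."""
    return pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]


def read_synteny_blocks(path: PathLike, focal_gene: str) -> dict[str, SyntenyBlock]:
    """Synteny TSV (species, position, gene, strand) -> one block per species."""
    df = pd.read_csv(path, sep="\t")
    blocks = {}
    for species, sub in df.groupby("species", sort=False):
        ordered = sub.sort_values("position")
        blocks[species] = SyntenyBlock(
            species=str(species),
            focal_gene=focal_gene,
            genes=list(zip(ordered["gene"], ordered["strand"])),
        )
    return blocks


def write_tree(tree: TreeNode, path: PathLike) -> None:
    """Write newick, exposing bootstrap supports as internal-node labels."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None and node.name is None:
            node.name = f"{support:g}"
    clone.write(str(path), format="newick")


def read_tree(path: PathLike) -> TreeNode:
    """Read newick; numeric internal-node labels become ``support`` values."""
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
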