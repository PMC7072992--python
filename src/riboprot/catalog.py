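"""Cytoplasmic ribosomal protein (RP) gene catalog.

Models the 92-gene RP catalog of Nile tilapia (*Oreochromis niloticus*):
one record per gene with its linkage-group assignment, exon count, gene
length and protein length, plus the summary statistics and paralog-family
partition used throughout the genomic-distribution analysis.

Gene names follow the field's nomenclature for duplicated RP genes:
``RPS27-1a`` is read as base name ``RPS27``, an older whole-genome-
duplication split indexed ``-1``/``-2``, and a younger split indexed by a
trailing lowercase ``a``/``b``. Trailing uppercase letters (``RPS27A``,
``RPL13A`` ...) are part of the canonical protein name, never a duplicate
index.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "RPGene",
    "RPCatalog",
    "ParalogFamily",
    "CatalogSummary",
    "parse_catalog",
    "load_tilapia_catalog",
    "summarize_catalog",
    "lg_distribution",
    "paralog_families",
    "split_gene_name",
]

#: Table 1 column order expected in input TSVs.
TABLE_COLUMNS = [
    "Gene",
    "AccessionNumber",
    "Chromosome Location",
    "Exon Count",
    "Gene Length (bp)",
    "Protein Length (aa)",
]

# Suffix grammar: optional "-<digits>" (older WGD split) then optional
# trailing lowercase a/b (younger split). Uppercase trailing letters stay
# part of the base name.
_NAME_RE = re.compile(r"^(?P<base>.+?)(?:-(?P<two_r>\d+))?(?P<three_r>[ab])?$")


@dataclass(frozen=True)
class RPGene:
    """One catalog row: a single ribosomal protein gene."""

    name: str
    accession_label: str
    linkage_group: str
    exon_count: int
    gene_length_bp: int
    protein_length_aa: int

    @property
    def subunit(self) -> str:
        """'small' for RPS*/RPSA genes, 'large' for RPL*/RPLP* genes."""
        if self.name.startswith("RPS") or self.name == "RPSA":
            return "small"
        if self.name.startswith("RPL"):
            return "large"
        raise ValueError(f"cannot infer ribosomal subunit from name {self.name!r}")

    def __post_init__(self):
        if self.exon_count < 1:
            raise ValueError(f"{self.name}: exon_count must be >= 1")
        if self.gene_length_bp < 1 or self.protein_length_aa < 1:
            raise ValueError(f"{self.name}: lengths must be positive")
        if self.gene_length_bp < self.protein_length_aa:
            raise ValueError(
                f"{self.name}: gene length {self.gene_length_bp} bp shorter than "
                f"protein length {self.protein_length_aa} aa"
            )


@dataclass
class RPCatalog:
    """Ordered, name-indexed collection of :class:`RPGene`."""

    genes: list[RPGene]
    species_label: str = "Oreochromis niloticus"

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty catalog")
        names = [g.name for g in self.genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene name(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, name: str) -> RPGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Gene": [g.name for g in self.genes],
                "AccessionNumber": [g.accession_label for g in self.genes],
                "Chromosome Location": [g.linkage_group for g in self.genes],
                "Exon Count": [g.exon_count for g in self.genes],
                "Gene Length (bp)": [g.gene_length_bp for g in self.genes],
                "Protein Length (aa)": [g.protein_length_aa for g in self.genes],
            }
        )


@dataclass(frozen=True)
class ParalogFamily:
    """All catalog genes sharing one base name (singletons included)."""

    base_name: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CatalogSummary:
    """Printed-precision summary of a catalog (lengths in kb to 2 decimals,
    mean exon count to 1 decimal, matching the reporting convention)."""

    n_genes: int
    n_small: int
    n_large: int
    mean_gene_length_kb: float
    mean_exon_count: float
    max_length_gene: str
    max_length_kb: float
    min_length_gene: str
    min_length_kb: float
    max_exon_genes: list[str]
    max_exon_count: int
    min_exon_genes: list[str]
    min_exon_count: int
    lg_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["lg_counts"] = dict(self.lg_counts)
        return d


def split_gene_name(name: str) -> tuple[str, str | None, str | None]:
    """Split an RP gene name into (base, older-split index, younger-split index).

    >>> split_gene_name("RPS27-1a")
    ('RPS27', '1', 'a')
    >>> split_gene_name("RPS27A")
    ('RPS27A', None, None)
    """
    m = _NAME_RE.match(name)
    if m is None:  # regex accepts any non-empty string; guard anyway
        return name, None, None
    return m.group("base"), m.group("two_r"), m.group("three_r")


def parse_catalog(
    table: Union[str, Path, io.IOBase], species_label: str = "Oreochromis niloticus"
) -> RPCatalog:
    """Parse a six-column catalog TSV (Table-1 layout) into an :class:`RPCatalog`.

    Whitespace inside accession labels is normalized (the printed table
    contains ``LOC 100691103``). Duplicate gene names and non-numeric
    count/length fields are hard errors.
    """
    if isinstance(table, (str, Path)) and "\t" not in str(table):
        df = pd.read_csv(table, sep="\t", dtype=str)
    else:  # raw text or buffer
        buf = io.StringIO(table) if isinstance(table, str) else table
        df = pd.read_csv(buf, sep="\t", dtype=str)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog table missing column(s): {missing}")
    if df.empty:
        raise ValueError("empty catalog")

    genes = []
    for i, row in df.iterrows():
        name = str(row["Gene"]).strip()
        numeric = {}
        for col in TABLE_COLUMNS[3:]:
            try:
                numeric[col] = int(str(row[col]).replace(",", "").strip())
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i + 1} ({name}): non-numeric value {row[col]!r} in {col!r}"
                ) from None
        genes.append(
            RPGene(
                name=name,
                accession_label=re.sub(r"\s+", "", str(row["AccessionNumber"])),
                linkage_group=str(row["Chromosome Location"]).strip(),
                exon_count=numeric["Exon Count"],
                gene_length_bp=numeric["Gene Length (bp)"],
                protein_length_aa=numeric["Protein Length (aa)"],
            )
        )
    return RPCatalog(genes=genes, species_label=species_label)


def load_tilapia_catalog() -> RPCatalog:
    """Load the packaged 92-gene Nile tilapia RP catalog."""
    ref = resources.files("riboprot.data").joinpath("tilapia_rp_table1.tsv")
    with resources.as_file(ref) as path:
        return parse_catalog(path)


def summarize_catalog(catalog: RPCatalog) -> CatalogSummary:
    """Compute the genomic-distribution summary of a catalog."""
    df = catalog.to_frame()
    lengths = df["Gene Length (bp)"]
    exons = df["Exon Count"]
    lg_counts = df["Chromosome Location"].value_counts().to_dict()
    n_small = sum(g.subunit == "small" for g in catalog)
    imax, imin = int(lengths.idxmax()), int(lengths.idxmin())
    return CatalogSummary(
        n_genes=len(catalog),
        n_small=n_small,
        n_large=len(catalog) - n_small,
        mean_gene_length_kb=round(float(lengths.mean()) / 1000.0, 2),
        mean_exon_count=round(float(exons.mean()), 1),
        max_length_gene=df.loc[imax, "Gene"],
        max_length_kb=round(int(lengths.max()) / 1000.0, 2),
        min_length_gene=df.loc[imin, "Gene"],
        min_length_kb=round(int(lengths.min()) / 1000.0, 2),
        max_exon_genes=sorted(df.loc[exons == exons.max(), "Gene"]),
        max_exon_count=int(exons.max()),
        min_exon_genes=sorted(df.loc[exons == exons.min(), "Gene"]),
        min_exon_count=int(exons.min()),
        lg_counts=lg_counts,
    )


def lg_distribution(catalog: RPCatalog) -> "OrderedDict[str, list[str]]":
    """Map each linkage group to the genes it carries (a partition of the catalog)."""
    out: OrderedDict[str, list[str]] = OrderedDict()
    for g in catalog:
        if not g.linkage_group:
            raise ValueError(f"{g.name}: empty linkage group")
        out.setdefault(g.linkage_group, []).append(g.name)
    return out


def paralog_families(catalog: RPCatalog) -> list[ParalogFamily]:
    """Partition the catalog into paralog families by base gene name.

    Genes whose names carry no duplicate suffix form singleton families.
    A name the grammar cannot split is kept as its own singleton family
    with a warning rather than dropped.
    """
    groups: OrderedDict[str, list[str]] = OrderedDict()
    for g in catalog:
        try:
            base, _, _ = split_gene_name(g.name)
        except Exception:  # pragma: no cover - grammar accepts all strings
            warnings.warn(f"unparseable gene name {g.name!r}; kept as singleton")
            base = g.name
        groups.setdefault(base, []).append(g.name)
    return [ParalogFamily(base_name=b, members=tuple(m)) for b, m in groups.items()]
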