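"""Reading and writing the tabular formats the pipeline consumes.

Formats handled here:

* per-condition abundance tables (TSV: ``gene_id`` column plus one column
  per replicate),
* orthogroup maps in the ``Orthogroups.tsv`` dialect emitted by orthology
  inference tools (tab-separated, first column ``Orthogroup``, one column
  per condition, comma-separated gene lists, empty cell = absent),
* plain-text gene-ID lists (one ID per line).

Gene IDs are opaque, case-sensitive strings; no accession normalization
is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MODALITIES = ("mrna", "protein")


@dataclass
class AbundanceTable:
    """Raw (or normalized) per-replicate gene abundances for one condition."""

    condition_id: str
    modality: str
    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_replicates), non-negative
    replicate_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise FormatError(f"duplicate gene ID {dup!r} in condition {self.condition_id}")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise FormatError(
                f"values shape {self.values.shape} inconsistent with {len(self.gene_ids)} genes"
            )
        if self.values.shape[1] != len(self.replicate_ids):
            raise FormatError(
                f"{self.values.shape[1]} value columns but {len(self.replicate_ids)} replicate IDs"
            )
        if self.n_replicates < 2:
            raise FormatError(f"need >= 2 replicates, got {self.n_replicates}")
        if not np.all(np.isfinite(self.values)):
            g, r = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(f"non-finite value at gene {self.gene_ids[g]!r}, replicate {self.replicate_ids[r]!r}")
        if np.any(self.values < 0):
            g, r = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value {self.values[g, r]} at gene {self.gene_ids[g]!r}, "
                f"replicate {self.replicate_ids[r]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.replicate_ids)


@dataclass
class OrthologMap:
    """Orthogroup -> condition -> member gene IDs."""

    groups: dict[str, dict[str, list[str]]]
    condition_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.condition_ids:
            conds: list[str] = []
            for members in self.groups.values():
                for c in members:
                    if c not in conds:
                        conds.append(c)
            self.condition_ids = conds
        # a gene may belong to at most one orthogroup per condition
        self._gene_to_group: dict[str, dict[str, str]] = {c: {} for c in self.condition_ids}
        for og, members in self.groups.items():
            for cond, genes in members.items():
                table = self._gene_to_group.setdefault(cond, {})
                for g in genes:
                    if g in table:
                        raise FormatError(
                            f"gene {g!r} assigned to both {table[g]!r} and {og!r} in condition {cond}"
                        )
                    table[g] = og

    def coverage(self, orthogroup: str) -> set[str]:
        """Conditions in which the orthogroup has at least one gene."""
        return {c for c, genes in self.groups[orthogroup].items() if genes}

    def single_copy(self, orthogroup: str, condition: str) -> bool:
        return len(self.groups[orthogroup].get(condition, [])) == 1

    def gene(self, orthogroup: str, condition: str) -> str:
        """The single gene of a single-copy (orthogroup, condition) entry."""
        genes = self.groups[orthogroup].get(condition, [])
        if len(genes) != 1:
            raise FormatError(f"{orthogroup} is not single-copy in {condition} ({len(genes)} genes)")
        return genes[0]

    def group_of(self, gene_id: str, condition: str) -> str | None:
        return self._gene_to_group.get(condition, {}).get(gene_id)

    def single_copy_groups(self, conditions: Iterable[str]) -> list[str]:
        """Orthogroups that are present and single-copy in every listed condition."""
        conds = list(conditions)
        return [
            og for og in sorted(self.groups)
            if all(self.single_copy(og, c) for c in conds)
        ]


def read_abundance_table(path: str | Path, condition_id: str, modality: str) -> AbundanceTable:
    """Read a genes x replicates TSV; the header row names replicates."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: fewer than 2 replicate columns")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    replicate_ids = [str(c) for c in df.columns[1:]]
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
    return AbundanceTable(condition_id, modality, gene_ids, values, replicate_ids)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as TSV with full-precision decimal representation."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(table.replicate_ids) + "\n")
        for gid, row in zip(table.gene_ids, table.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_orthogroups(path: str | Path, condition_ids: Sequence[str]) -> OrthologMap:
    """Parse an ``Orthogroups.tsv``-dialect file.

    Both ``", "`` and bare ``","`` separators are accepted inside cells.
    The header's condition columns must match ``condition_ids``
    (order-insensitive); empty cells mean the orthogroup is absent from
    that condition.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = [str(c) for c in df.columns[1:]]
    unknown = [c for c in header if c not in set(condition_ids)]
    if unknown:
        raise FormatError(f"{path}: unknown condition column(s) {unknown}")
    missing = [c for c in condition_ids if c not in set(header)]
    if missing:
        raise FormatError(f"{path}: missing condition column(s) {missing}")
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = str(row.iloc[0])
        if og in groups:
            raise FormatError(f"{path}: duplicate orthogroup ID {og!r}")
        members: dict[str, list[str]] = {}
        for cond in header:
            cell = str(row[cond]).strip()
            if not cell:
                continue
            members[cond] = [g.strip() for g in cell.split(",") if g.strip()]
        groups[og] = members
    return OrthologMap(groups, condition_ids=list(condition_ids))


def write_orthogroups(omap: OrthologMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(omap.condition_ids) + "\n")
        for og in sorted(omap.groups):
            cells = [", ".join(omap.groups[og].get(c, [])) for c in omap.condition_ids]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read one gene ID per line; blank lines ignored, duplicates reported."""
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                ids.append(line)
    unique = set(ids)
    dropped = len(ids) - len(unique)
    if dropped:
        logger.warning("%s: dropped %d duplicate gene ID(s)", path, dropped)
    if not unique:
        logger.warning("%s: empty gene list", path)
    return unique


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")
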