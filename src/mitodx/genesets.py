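"""Gene list I/O and the three-way hub-gene intersection funnel."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GeneSet", "GeneSetError", "read_gene_list", "intersect_hub"]


class GeneSetError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free list of gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cleaned, seen = [], set()
        for g in self.genes:
            g = str(g).strip()
            if not g:
                raise GeneSetError(f"gene set {self.name!r} contains an empty symbol")
            if g not in seen:
                seen.add(g)
                cleaned.append(g)
        object.__setattr__(self, "genes", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


def read_gene_list(path: str | Path, format: str | None = None):
    """Read a gene list from a one-column TSV or a GMT file.

    TSV: one symbol per line (a leading ``symbol`` header row is skipped);
    extra columns are ignored. Returns one :class:`GeneSet`. GMT: each row
    ``name <tab> description <tab> gene...``; returns a list of GeneSets.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if format not in ("tsv", "gmt"):
        raise GeneSetError(f"unknown gene list format {format!r}")
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise GeneSetError(f"empty gene list file: {path}")
    if format == "tsv":
        symbols = [ln.split("\t")[0].strip() for ln in lines]
        if symbols and symbols[0].lower() in ("symbol", "gene", "gene_symbol"):
            symbols = symbols[1:]
        if not symbols:
            raise GeneSetError(f"no gene symbols in {path}")
        return GeneSet(name=path.stem, genes=tuple(symbols))
    sets = []
    for i, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) < 3:
            raise GeneSetError(f"{path}:{i}: GMT row has {len(fields)} fields, need >= 3")
        sets.append(GeneSet(name=fields[0].strip(), genes=tuple(fields[2:])))
    return sets


def intersect_hub(
    degs: GeneSet, module_genes: GeneSet, mito: GeneSet
) -> tuple[GeneSet, dict[str, int]]:
    """Three-way intersection: DEGs ∩ key-module genes ∩ mitochondrial genes.

    Returns the sorted hub gene set and the exclusive counts of all seven
    regions of the three-set Venn diagram, keyed by membership pattern
    (``"deg"``, ``"deg&module"``, ``"deg&module&mito"``, ...).
    """
    a, b, c = degs.as_set(), module_genes.as_set(), mito.as_set()
    hub = sorted((a & b) & c)
    venn = {
        "deg": len(a - b - c),
        "module": len(b - a - c),
        "mito": len(c - a - b),
        "deg&module": len((a & b) - c),
        "deg&mito": len((a & c) - b),
        "module&mito": len((b & c) - a),
        "deg&module&mito": len(a & b & c),
    }
    if not hub:
        warnings.warn("hub intersection is empty", stacklevel=2)
    return GeneSet(name="hub", genes=tuple(hub)), venn
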