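"""Multi-omic intersection cascade nominating stabilized, pathway-annotated proteins.

The cascade has four stages:

1. Proteins significantly more abundant under treatment in *both* proteome
   cell lines (log2FC > 0 and FDR q < 0.05 in each) — candidate stabilized
   proteins.
2. Genes *not* transcriptionally upregulated (log2FC < 0.5 in *all*
   transcriptome cell lines) — rules out abundance gains explained by
   expression.
3. Stage-1 proteins whose gene is in the stage-2 list.
4. Stage-3 proteins whose gene belongs to the union of the supplied pathway
   gene sets (e.g. the KEGG signal-transduction pathways).

All thresholds use strict inequalities; boundary values are excluded.
The subset chain stage4 ⊆ stage3 ⊆ stage1 holds by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._exceptions import SchemaError

__all__ = [
    "PathwayCollection",
    "NominationResult",
    "read_gmt",
    "write_gmt",
    "filter_stabilized_proteins",
    "filter_nonupregulated_genes",
    "nominate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets (typically from a GMT file) and their union."""

    sets: dict

    @property
    def union(self) -> set:
        out: set = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: one set per line, name TAB description TAB genes..."""
    sets: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"GMT line {line_no}: need name, description, >=1 gene")
        sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise SchemaError(f"GMT file {path} contains no gene sets")
    return PathwayCollection(sets=sets)


def write_gmt(sets: dict, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class NominationResult:
    """Stage lists and counts of the intersection cascade."""

    stage1_proteins: list
    stage2_genes: list
    stage3_proteins: list
    stage4_proteins: list
    n_unmapped: int = 0
    pathway_union_size: int = 0

    @property
    def counts(self) -> dict:
        return {
            "stage1": len(self.stage1_proteins),
            "stage2": len(self.stage2_genes),
            "stage3": len(self.stage3_proteins),
            "stage4": len(self.stage4_proteins),
        }

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "stage1_proteins": list(self.stage1_proteins),
            "stage2_genes": list(self.stage2_genes),
            "stage3_proteins": list(self.stage3_proteins),
            "stage4_proteins": list(self.stage4_proteins),
            "n_unmapped": self.n_unmapped,
            "pathway_union_size": self.pathway_union_size,
        }


def _require(table: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {', '.join(missing)}")


def filter_stabilized_proteins(
    proteins: pd.DataFrame,
    lines: tuple[str, str] = ("A1336", "A2780"),
    q_max: float = 0.05,
) -> list[str]:
    """Proteins with log2FC > 0 AND q < q_max in both named cell lines.

    Expects columns protein_id plus log2fc_<line> and q_<line> per line.
    """
    cols = [f"log2fc_{ln}" for ln in lines] + [f"q_{ln}" for ln in lines]
    _require(proteins, ["protein_id", *cols], "protein")
    keep = pd.Series(True, index=proteins.index)
    for ln in lines:
        keep &= (proteins[f"log2fc_{ln}"] > 0) & (proteins[f"q_{ln}"] < q_max)
    return proteins.loc[keep, "protein_id"].tolist()


def filter_nonupregulated_genes(
    genes: pd.DataFrame,
    lines: tuple[str, ...] = ("A1336", "A2780", "SKOV3"),
    fc_max: float = 0.5,
) -> list[str]:
    """Genes with log2FC < fc_max (strict) in ALL named cell lines."""
    cols = [f"log2fc_{ln}" for ln in lines]
    _require(genes, ["gene_id", *cols], "gene")
    keep = pd.Series(True, index=genes.index)
    for ln in lines:
        keep &= genes[f"log2fc_{ln}"] < fc_max
    return genes.loc[keep, "gene_id"].tolist()


def nominate(
    stage1: list[str],
    stage2: list[str],
    pathways: PathwayCollection,
    mapping: dict,
    gene_universe: set | None = None,
    missing_gene_passes: bool = False,
) -> NominationResult:
    """Run the intersection cascade from pre-filtered stage lists.

    ``mapping`` is protein_id -> gene_id; stage-1 proteins without a mapping
    are excluded with a logged count rather than guessed.  Genes absent from
    the transcriptome (not in ``gene_universe``) are conservatively treated
    as failing the non-upregulation filter; pass ``missing_gene_passes=True``
    together with the universe to flip that.
    """
    if len(pathways) == 0:
        raise SchemaError("pathway collection is empty")

    mapped, unmapped = [], 0
    for pid in stage1:
        if pid in mapping:
            mapped.append(pid)
        else:
            unmapped += 1
    if unmapped:
        logger.warning("%d stage-1 protein(s) had no gene mapping and were excluded",
                       unmapped)

    stage2_set = set(stage2)
    if missing_gene_passes and gene_universe is not None:
        universe = set(gene_universe)
        stage3 = [p for p in mapped
                  if mapping[p] in stage2_set or mapping[p] not in universe]
    else:
        stage3 = [p for p in mapped if mapping[p] in stage2_set]

    union = pathways.union
    stage4 = [p for p in stage3 if mapping[p] in union]
    return NominationResult(
        stage1_proteins=list(stage1),
        stage2_genes=list(stage2),
        stage3_proteins=stage3,
        stage4_proteins=stage4,
        n_unmapped=unmapped,
        pathway_union_size=len(union),
    )
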