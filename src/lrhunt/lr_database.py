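"""Ligand-receptor pair annotations: loading, filtering, ortholog mapping.

Works with any curated LR database exported as a table with one ligand and
one receptor gene symbol per row (two-column CSV/TSV, or a CellPhoneDB-style
CSV via configurable column names). Multi-subunit complexes are not
modelled: rows whose ligand or receptor field encodes a complex (contains a
separator such as "_" or ",") are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "LRPairTable",
    "load_lr_pairs",
    "filter_to_expressed",
    "map_orthologs",
    "load_ortholog_mapping",
]


@dataclass
class LRPairTable:
    """Deduplicated single-gene ligand-receptor pairs.

    ``report`` counts rows dropped on the way in (complexes, empties,
    duplicates, unmapped symbols), keyed by reason.
    """

    pairs: list[tuple[str, str]]
    source_tag: str = ""
    report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError("gene symbols must be non-empty")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("pairs must be unique")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ligands(self) -> list[str]:
        seen: dict[str, None] = {}
        for lig, _ in self.pairs:
            seen.setdefault(lig)
        return list(seen)

    @property
    def receptors(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, rec in self.pairs:
            seen.setdefault(rec)
        return list(seen)


_FORMAT_COLUMNS = {
    "two_column_csv": ("ligand", "receptor"),
    "cellphonedb_csv": ("partner_a", "partner_b"),
}


def _normalize_case(symbol: str, mode: str | None) -> str:
    if mode is None:
        return symbol
    if mode == "upper":
        return symbol.upper()
    if mode == "lower":
        return symbol.lower()
    raise ValueError(f"unknown case normalization {mode!r}")


def load_lr_pairs(
    path: str | Path,
    format: str = "two_column_csv",
    ligand_col: str | None = None,
    receptor_col: str | None = None,
    complex_separators: tuple[str, ...] = ("_", ","),
    case_normalization: str | None = None,
    source_tag: str | None = None,
) -> LRPairTable:
    """Load an LR pair table from a delimited file.

    The delimiter is sniffed from the extension (.tsv/.txt -> tab, else
    comma). Column names default per ``format`` and can be overridden. Rows
    encoding multi-subunit complexes are dropped and counted in the report,
    as are empty-symbol rows and duplicates. Case normalization (none by
    default — symbol case conveys species) is applied once, here.
    """
    path = Path(path)
    if format not in _FORMAT_COLUMNS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMAT_COLUMNS)}")
    lcol, rcol = _FORMAT_COLUMNS[format]
    lcol = ligand_col or lcol
    rcol = receptor_col or rcol
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in (lcol, rcol) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing expected column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )
    report = {"complex": 0, "empty": 0, "duplicate": 0}
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lig, rec in zip(df[lcol], df[rcol]):
        lig = "" if pd.isna(lig) else str(lig).strip()
        rec = "" if pd.isna(rec) else str(rec).strip()
        if not lig or not rec:
            report["empty"] += 1
            continue
        if any(s in lig or s in rec for s in complex_separators):
            report["complex"] += 1
            continue
        lig = _normalize_case(lig, case_normalization)
        rec = _normalize_case(rec, case_normalization)
        if (lig, rec) in seen:
            report["duplicate"] += 1
            continue
        seen.add((lig, rec))
        pairs.append((lig, rec))
    if not pairs:
        raise ValueError(f"{path}: no usable ligand-receptor pairs after filtering")
    return LRPairTable(pairs=pairs, source_tag=source_tag or str(path), report=report)


def filter_to_expressed(
    pairs: LRPairTable, ligand_genes: set[str], receptor_genes: set[str]
) -> LRPairTable:
    """Restrict to pairs whose ligand and receptor are both measured."""
    if not ligand_genes or not receptor_genes:
        raise ValueError("gene sets must be non-empty")
    kept = [
        (lig, rec)
        for lig, rec in pairs.pairs
        if lig in ligand_genes and rec in receptor_genes
    ]
    if not kept:
        raise ValueError(
            "no ligand-receptor pair has both genes expressed; cannot proceed"
        )
    report = dict(pairs.report)
    report["not_expressed"] = len(pairs) - len(kept)
    return LRPairTable(pairs=kept, source_tag=pairs.source_tag, report=report)


def load_ortholog_mapping(
    path: str | Path, header: bool = True
) -> list[tuple[str, str]]:
    """Read a from<TAB>to symbol mapping TSV (set header=False if absent)."""
    df = pd.read_csv(
        Path(path), sep="\t", dtype=str, header=0 if header else None
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping must have two columns (from, to)")
    return [
        (str(a).strip(), str(b).strip())
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
        if not (pd.isna(a) or pd.isna(b))
    ]


def map_orthologs(
    pairs: LRPairTable, mapping: list[tuple[str, str]] | dict[str, str]
) -> LRPairTable:
    """Map both sides of every pair through an ortholog symbol table.

    Pairs with an unmapped ligand or receptor are dropped and counted.
    One-to-many mappings expand combinatorially (one output pair per target
    combination); results are deduplicated preserving first appearance.
    """
    if isinstance(mapping, dict):
        items = list(mapping.items())
    else:
        items = list(mapping)
    if not items:
        raise ValueError("ortholog mapping is empty")
    table: dict[str, list[str]] = {}
    for src, dst in items:
        table.setdefault(src, [])
        if dst not in table[src]:
            table[src].append(dst)
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for lig, rec in pairs.pairs:
        if lig not in table or rec not in table:
            dropped += 1
            continue
        for new_lig in table[lig]:
            for new_rec in table[rec]:
                if (new_lig, new_rec) not in seen:
                    seen.add((new_lig, new_rec))
                    out.append((new_lig, new_rec))
    if not out:
        raise ValueError("no pairs survived ortholog mapping")
    report = dict(pairs.report)
    report["unmapped"] = dropped
    return LRPairTable(pairs=out, source_tag=pairs.source_tag, report=report)
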