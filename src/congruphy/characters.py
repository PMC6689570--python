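"""Character matrices: NEXUS/FASTA input, partitions, subsampling, merging.

A matrix holds taxa x characters cells.  Each cell is either a frozenset of
state symbols (singleton = observed state, larger = polymorphism/uncertainty),
the MISSING sentinel (``?``), or the INAPPLICABLE sentinel (``-`` in
morphological columns).  Columns carry a partition tag: ``morphology``,
``dna`` or ``indel``.  All characters are treated as unordered.

Missing and inapplicable cells are scored identically by the parsimony
engine (they contribute the full column alphabet), but the distinction is
preserved so that hypothetical-ancestor export can keep inapplicability
coded as such.  A gap in a DNA column is recorded as MISSING; a gap in a
morphology column as INAPPLICABLE.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

MORPHOLOGY = "morphology"
DNA = "dna"
INDEL = "indel"
PARTITION_TAGS = (MORPHOLOGY, DNA, INDEL)


class _Sentinel:
    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __repr__(self) -> str:
        return self.name

    def __deepcopy__(self, memo):  # sentinels stay singletons
        return self


MISSING = _Sentinel("MISSING")
INAPPLICABLE = _Sentinel("INAPPLICABLE")

Cell = object  # frozenset[str] | MISSING | INAPPLICABLE


class MatrixError(ValueError):
    """Invalid character-matrix input or operation."""


@dataclass
class CharacterMatrix:
    """Rectangular taxa x characters table of state sets with partition tags."""

    taxa: list[str]
    cells: list[list[Cell]]  # row-major: cells[i][j] for taxon i, column j
    partitions: list[str]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon labels")
        for row in self.cells:
            if len(row) != len(self.partitions):
                raise MatrixError(
                    f"ragged matrix: row length {len(row)} != "
                    f"{len(self.partitions)} columns"
                )
        if len(self.cells) != len(self.taxa):
            raise MatrixError("row count does not match taxon count")
        bad = set(self.partitions) - set(PARTITION_TAGS)
        if bad:
            raise MatrixError(f"unknown partition tag(s): {sorted(bad)}")

    # -- basic properties ------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.partitions)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise MatrixError(f"taxon {label!r} not in matrix") from None

    def partition_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tag in self.partitions:
            out[tag] = out.get(tag, 0) + 1
        return out

    def columns_with_tags(self, tags: Iterable[str] | str) -> list[int]:
        if isinstance(tags, str):
            tags = (tags,)
        tags = set(tags)
        return [j for j, tag in enumerate(self.partitions) if tag in tags]

    def column_alphabet(self, j: int) -> list[str]:
        """Sorted observed state symbols of column ``j``."""
        states: set[str] = set()
        for row in self.cells:
            cell = row[j]
            if isinstance(cell, frozenset):
                states |= cell
        return sorted(states)

    # -- slicing ---------------------------------------------------------------

    def select_columns(self, cols: Sequence[int]) -> "CharacterMatrix":
        return CharacterMatrix(
            list(self.taxa),
            [[row[j] for j in cols] for row in self.cells],
            [self.partitions[j] for j in cols],
        )

    def select_taxa(self, labels: Iterable[str]) -> "CharacterMatrix":
        labels = set(labels)
        missing = labels - set(self.taxa)
        if missing:
            raise MatrixError(f"taxa not in matrix: {sorted(missing)}")
        keep = [i for i, t in enumerate(self.taxa) if t in labels]
        return CharacterMatrix(
            [self.taxa[i] for i in keep],
            [list(self.cells[i]) for i in keep],
            list(self.partitions),
        )

    def add_rows(self, other: "CharacterMatrix") -> "CharacterMatrix":
        """Append the taxa of ``other`` (same columns/partitions required)."""
        if other.partitions != self.partitions:
            raise MatrixError("row append requires identical columns")
        return CharacterMatrix(
            self.taxa + other.taxa,
            [list(r) for r in self.cells] + [list(r) for r in other.cells],
            list(self.partitions),
        )

    # -- export ----------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        def fmt(cell: Cell) -> str:
            if cell is MISSING:
                return "?"
            if cell is INAPPLICABLE:
                return "-"
            if len(cell) == 1:
                return next(iter(cell))
            return "{" + "".join(sorted(cell)) + "}"

        return pd.DataFrame(
            [[fmt(c) for c in row] for row in self.cells],
            index=self.taxa,
            columns=[f"{tag}_{j}" for j, tag in enumerate(self.partitions)],
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf)


# ---------------------------------------------------------------------------
# NEXUS / FASTA input (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def _convert_dendropy_matrix(dm, tag: str) -> CharacterMatrix:
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    n_chars = None
    for taxon in dm:
        seq = dm[taxon]
        row: list[Cell] = []
        for sc in seq:
            symbol = sc.symbol
            if symbol == "?":
                row.append(MISSING)
            elif symbol == "-":
                row.append(INAPPLICABLE if tag == MORPHOLOGY else MISSING)
            else:
                members = frozenset(
                    s.symbol for s in sc.fundamental_states if s.symbol != "-"
                )
                if not members:
                    row.append(MISSING)
                else:
                    row.append(members)
        if n_chars is None:
            n_chars = len(row)
        taxa.append(taxon.label)
        rows.append(row)
    if n_chars is None:
        raise MatrixError("empty character matrix")
    return CharacterMatrix(taxa, rows, [tag] * n_chars)


def _infer_tag(dm) -> str:
    if isinstance(dm, dendropy.DnaCharacterMatrix):
        return DNA
    return MORPHOLOGY


def read_matrix(
    text: str,
    schema: str = "nexus",
    partitions: str | Sequence[str] | None = None,
) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS file (interleaved or sequential).

    ``partitions`` assigns a tag to each character block in file order (a
    single string applies to all blocks); left as ``None``, DNA blocks are
    tagged ``dna`` and standard blocks ``morphology``.  Multiple blocks are
    concatenated column-wise over the union of their taxa (absent taxa filled
    MISSING), which is how fossils lacking molecular data join a combined
    matrix.
    """
    try:
        ds = dendropy.DataSet.get(data=text, schema=schema)
    except Exception as exc:
        raise MatrixError(f"cannot parse {schema} matrix: {exc}") from exc
    if not ds.char_matrices:
        raise MatrixError("no character matrix found in input")
    if isinstance(partitions, str):
        partitions = [partitions] * len(ds.char_matrices)
    parts = []
    for i, dm in enumerate(ds.char_matrices):
        tag = partitions[i] if partitions is not None else _infer_tag(dm)
        parts.append(_convert_dendropy_matrix(dm, tag))
    return combine_partitions(parts)


def read_fasta(text: str, tag: str = DNA) -> CharacterMatrix:
    """Convenience FASTA (DNA) reader."""
    try:
        dm = dendropy.DnaCharacterMatrix.get(data=text, schema="fasta")
    except Exception as exc:
        raise MatrixError(f"cannot parse FASTA: {exc}") from exc
    return _convert_dendropy_matrix(dm, tag)


def write_nexus(m: CharacterMatrix) -> str:
    """Serialize as NEXUS, one CHARACTERS block per partition tag."""

    def fmt(cell: Cell) -> str:
        if cell is MISSING:
            return "?"
        if cell is INAPPLICABLE:
            return "-"
        syms = sorted(cell)
        return syms[0] if len(syms) == 1 else "{" + "".join(syms) + "}"

    def fmt_taxon(label: str) -> str:
        return f"'{label}'" if (" " in label or "'" in label) else label

    out = io.StringIO()
    out.write("#NEXUS\n\n")
    out.write("BEGIN TAXA;\n")
    out.write(f"    DIMENSIONS NTAX={m.n_taxa};\n    TAXLABELS\n")
    for t in m.taxa:
        out.write(f"        {fmt_taxon(t)}\n")
    out.write("    ;\nEND;\n")
    for tag in PARTITION_TAGS:
        cols = m.columns_with_tags(tag)
        if not cols:
            continue
        sub = m.select_columns(cols)
        symbols = sorted({s for j in range(sub.n_chars) for s in sub.column_alphabet(j)})
        datatype = "DNA" if tag == DNA else "STANDARD"
        out.write(f"\nBEGIN CHARACTERS;\n    TITLE {tag};\n")
        out.write(f"    DIMENSIONS NCHAR={sub.n_chars};\n")
        out.write(f"    FORMAT DATATYPE={datatype} MISSING=? GAP=-")
        if datatype == "STANDARD":
            out.write(f' SYMBOLS="{"".join(symbols)}"')
        out.write(";\n    MATRIX\n")
        width = max(len(fmt_taxon(t)) for t in sub.taxa) + 2
        for t, row in zip(sub.taxa, sub.cells):
            out.write(f"        {fmt_taxon(t):<{width}}{''.join(fmt(c) for c in row)}\n")
        out.write("    ;\nEND;\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Subsampling and merging
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def subsample_sites(
    m: CharacterMatrix,
    tags: Iterable[str] | str,
    fraction: float,
    seed: int | np.random.Generator,
) -> CharacterMatrix:
    """Draw ``round(fraction * n_tagged)`` tagged columns without replacement.

    Columns carrying other tags are dropped; selected columns keep their
    original order, so ``fraction=1.0`` is the identity on the tagged
    partition.  The count rounds half up.  Deterministic given ``seed``.
    """
    if not (0 < fraction <= 1):
        raise MatrixError(f"fraction must be in (0, 1], got {fraction}")
    cols = m.columns_with_tags(tags)
    if not cols:
        raise MatrixError(f"no columns tagged {tags!r}")
    k = _round_half_up(fraction * len(cols))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(cols), size=k, replace=False)
    keep = [cols[i] for i in sorted(chosen)]
    return m.select_columns(keep)


def combine_partitions(parts: Sequence[CharacterMatrix]) -> CharacterMatrix:
    """Column-wise merge over the union of taxa.

    Taxa present in one part but absent in another are filled MISSING across
    the absent part's columns — this is how morphology-only fossils join a
    combined morphology+DNA matrix.
    """
    if not parts:
        raise MatrixError("nothing to combine")
    taxa: list[str] = []
    for p in parts:
        for t in p.taxa:
            if t not in taxa:
                taxa.append(t)
    cells: list[list[Cell]] = [[] for _ in taxa]
    partitions: list[str] = []
    for p in parts:
        idx = {t: i for i, t in enumerate(p.taxa)}
        for i, t in enumerate(taxa):
            if t in idx:
                cells[i].extend(p.cells[idx[t]])
            else:
                cells[i].extend([MISSING] * p.n_chars)
        partitions.extend(p.partitions)
    return CharacterMatrix(taxa, cells, partitions)
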