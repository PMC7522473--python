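"""Readers/writers for the external formats the pipeline touches.

Coordinates are 1-based inclusive throughout (GFF3 convention). Protein
sequences travel inside the annotation table so that a genome is fully
self-contained; below-detection concentrations are kept as an explicit
flag plus the detection limit, never coerced to zero.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Gene",
    "GenomeRecord",
    "MutantTableRow",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "read_panel",
    "write_panel",
    "load_mutant_table",
]

VALID_STRANDS = frozenset({"+", "-"})


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class Gene:
    """One annotated protein-coding gene.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on
    ``contig``; ``protein`` is the translated product.
    """

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.locus_tag}: coordinates are 1-based")
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"gene {self.locus_tag}: strand {self.strand!r} not in {{+,-}}"
            )
        if not self.protein:
            raise ValueError(f"gene {self.locus_tag}: empty protein sequence")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """An annotated genome: ordered genes plus species/niche labels.

    ``contigs`` optionally maps contig name to its nucleotide sequence,
    which is required for 5'-UTR extraction but not for homology search.
    """

    genome_id: str
    species: str = ""
    niche: str = ""
    genes: list[Gene] = field(default_factory=list)
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig, g.start))

    def gene(self, locus_tag: str) -> Gene:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(f"locus {locus_tag!r} not found in genome {self.genome_id}")


@dataclass(frozen=True)
class MutantTableRow:
    """One row of the roseoflavin-resistant mutant table.

    ``below_detection`` marks concentrations reported as "< limit"; the
    numeric field then holds the detection limit itself.
    """

    mutant_id: str
    position: int | None
    wt_base: str | None
    mut_base: str | None
    riboflavin_ng_per_ml: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.riboflavin_ng_per_ml < 0:
            raise ValueError("concentration must be non-negative")
        if self.wt_base is not None and self.wt_base == self.mut_base:
            raise ValueError("mutant row with wt_base == mut_base")


def read_fasta(path: str | Path | io.TextIOBase) -> list[tuple[str, str]]:
    """Parse a (possibly line-wrapped) multi-record FASTA file.

    Returns ``(id, sequence)`` pairs in file order with sequences
    upper-cased. A sequence line before the first header is a
    :class:`ParseError` naming the line number.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path)
        close = True
    records: list[tuple[str, list[str]]] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                records.append((header, []))
            else:
                if not records:
                    raise ParseError(
                        f"line {lineno}: sequence data before first FASTA header"
                    )
                records[-1][1].append(line.upper())
    finally:
        if close:
            handle.close()
    return [(name, "".join(chunks)) for name, chunks in records]


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_ANNOT_COLS = ["locus_tag", "contig", "start", "end", "strand", "protein"]


def read_annotations(path: str | Path) -> list[Gene]:
    """Read a gene-annotation TSV into validated :class:`Gene` objects.

    Expected tab-separated columns: locus_tag, contig, start, end,
    strand, protein. Rows are returned sorted by (contig, start).
    Coordinate or strand violations raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    genes = [
        Gene(
            locus_tag=row.locus_tag,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            protein=row.protein,
        )
        for row in df.itertuples(index=False)
    ]
    return sorted(genes, key=lambda g: (g.contig, g.start))


def write_annotations(genes: Sequence[Gene], path: str | Path) -> None:
    pd.DataFrame(
        [
            (g.locus_tag, g.contig, g.start, g.end, g.strand, g.protein)
            for g in genes
        ],
        columns=_ANNOT_COLS,
    ).to_csv(path, sep="\t", index=False)


_PANEL_COLS = ["genome_id", "species", "niche"] + _ANNOT_COLS


def write_panel(panel: Sequence[GenomeRecord], path: str | Path) -> None:
    """Write a genome panel as one flat annotation TSV."""
    rows = [
        (g.genome_id, g.species, g.niche, gn.locus_tag, gn.contig, gn.start,
         gn.end, gn.strand, gn.protein)
        for g in panel
        for gn in g.genes
    ]
    pd.DataFrame(rows, columns=_PANEL_COLS).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[GenomeRecord]:
    """Read a flat panel TSV back into :class:`GenomeRecord` objects."""
    df = pd.read_csv(path, sep="\t", dtype={"strand": str, "protein": str})
    missing = [c for c in _PANEL_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing panel columns {missing}")
    panel = []
    for gid, sub in df.groupby("genome_id", sort=True):
        genes = [
            Gene(
                locus_tag=r.locus_tag,
                contig=r.contig,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                protein=r.protein,
            )
            for r in sub.itertuples(index=False)
        ]
        panel.append(
            GenomeRecord(
                genome_id=str(gid),
                species=str(sub["species"].iloc[0]),
                niche=str(sub["niche"].iloc[0]),
                genes=genes,
            )
        )
    return panel


def load_mutant_table() -> list[MutantTableRow]:
    """Load the packaged riboswitch-mutant table (7 mutants + WT).

    The wild-type row carries a below-detection flag with the 0.2
    ng mL^-1 limit of the microbiological assay.
    """
    ref = resources.files("riboscreen").joinpath("data/riboswitch_mutants.tsv")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:  # pragma: no cover
        raise RuntimeError("packaged mutant table fixture is missing") from exc
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    if df.shape[1] != 5 or df.shape[0] != 8:
        raise RuntimeError("packaged mutant table fixture is corrupted")
    rows: list[MutantTableRow] = []
    for rec in df.itertuples(index=False):
        mutant_id, pos, wt, mut, conc = (str(v).strip() for v in rec)
        below = conc.startswith("<")
        value = float(conc.lstrip("<").strip())
        if math.isnan(value):  # pragma: no cover
            raise RuntimeError("packaged mutant table fixture is corrupted")
        rows.append(
            MutantTableRow(
                mutant_id=mutant_id,
                position=None if pos == "-" else int(pos),
                wt_base=None if wt == "-" else wt,
                mut_base=None if mut == "-" else mut,
                riboflavin_ng_per_ml=value,
                below_detection=below,
            )
        )
    return rows
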