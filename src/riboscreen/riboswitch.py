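"""FMN riboswitch detection and mutant characterization.

The FMN riboswitch sits in the 5'-UTR upstream of ribD and switches the
rib operon off when flavin is abundant. Its regulatory elements are
scanned as literal DNA motifs: the antiterminator (AntiT, TTCAGGGC)
whose formation permits transcription, and the two anti-antiterminator
elements (Anti-antiT, CATCTTC and GAAGATG) whose pairing in the
FMN-bound state allows premature termination. Point mutations found in
roseoflavin-resistant overproducer strains are mapped onto these
elements and classified as transitions or transversions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeRecord

__all__ = [
    "RiboswitchModel",
    "MotifHit",
    "Mutation",
    "RiboswitchAnnotation",
    "extract_utr",
    "scan_motifs",
    "map_mutations",
    "classify_mutation",
    "conservation_profile",
    "reverse_complement",
]

DNA = frozenset("ACGT")
PURINES = frozenset("AG")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RiboswitchModel:
    """Literal-motif model of the FMN riboswitch regulatory elements."""

    utr_length: int = 500
    antiterminator: str = "TTCAGGGC"
    anti_antiterminators: tuple[str, ...] = ("CATCTTC", "GAAGATG")
    mismatch_tolerance: int = 0

    def __post_init__(self) -> None:
        for motif in (self.antiterminator, *self.anti_antiterminators):
            if not motif or set(motif) - DNA:
                raise ValueError(f"motif {motif!r} is not a DNA string")

    @property
    def motifs(self) -> dict[str, str]:
        out = {"antiterminator": self.antiterminator}
        for i, m in enumerate(self.anti_antiterminators, start=1):
            out[f"anti-antiterminator-{i}"] = m
        return out


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start`` is 1-based within the UTR."""

    motif: str
    sequence: str
    start: int
    mismatches: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    @property
    def region(self) -> str:
        # collapse numbered anti-antiterminator copies to the element name
        return self.motif.rsplit("-", 1)[0] if self.motif.startswith(
            "anti-antiterminator"
        ) else self.motif


@dataclass(frozen=True)
class Mutation:
    """A point substitution within the riboswitch, 1-based."""

    position: int
    wt_base: str
    mut_base: str
    region: str = ""
    mutation_class: str = ""

    def __post_init__(self) -> None:
        if self.wt_base == self.mut_base:
            raise ValueError("wt and mutant base are identical")
        for b in (self.wt_base, self.mut_base):
            if b not in DNA:
                raise ValueError(f"{b!r} is not a DNA base")


@dataclass
class RiboswitchAnnotation:
    """A 5'-UTR with its located motifs and any mapped mutations."""

    utr: str
    motif_hits: list[MotifHit] = field(default_factory=list)
    mutations: list[Mutation] = field(default_factory=list)

    def region_at(self, position: int) -> str:
        if not 1 <= position <= len(self.utr):
            raise ValueError(
                f"position {position} outside UTR of length {len(self.utr)}"
            )
        for hit in self.motif_hits:
            if hit.start <= position <= hit.end:
                return hit.region
        return "other"


def extract_utr(
    genome: GenomeRecord, target_locus: str, length: int = 500
) -> str:
    """The ``length`` bases immediately 5' of a gene, on its coding strand.

    For a + strand gene this is the genomic window left of ``start``;
    for a - strand gene, the reverse complement of the window right of
    ``end``. Truncated (with a warning) where the contig ends.
    """
    gene = genome.gene(target_locus)
    contig = genome.contigs.get(gene.contig)
    if contig is None:
        raise KeyError(
            f"contig sequence {gene.contig!r} unavailable in genome "
            f"{genome.genome_id}"
        )
    if gene.strand == "+":
        lo = max(gene.start - length, 1)
        utr = contig[lo - 1 : gene.start - 1]
    else:
        hi = min(gene.end + length, len(contig))
        utr = reverse_complement(contig[gene.end : hi])
    if len(utr) < length:
        warnings.warn(
            f"5'-UTR of {target_locus} truncated to {len(utr)} nt at contig edge",
            stacklevel=2,
        )
    return utr.upper()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_motifs(
    utr: str, model: RiboswitchModel | None = None
) -> list[MotifHit]:
    """Locate every model motif in a UTR (given strand only).

    Exact occurrences are reported first; if the model's mismatch
    tolerance is positive, a fallback pass admits occurrences with up to
    that many mismatches. Hits are sorted by (mismatches, position).
    """
    model = model or RiboswitchModel()
    utr = utr.upper()
    if set(utr) - DNA:
        raise ValueError("UTR contains non-ACGT characters")
    hits: list[MotifHit] = []
    for name, motif in model.motifs.items():
        exact: list[MotifHit] = []
        fuzzy: list[MotifHit] = []
        for i in range(len(utr) - len(motif) + 1):
            window = utr[i : i + len(motif)]
            mm = _hamming(window, motif)
            if mm == 0:
                exact.append(MotifHit(name, motif, i + 1, 0))
            elif mm <= model.mismatch_tolerance:
                fuzzy.append(MotifHit(name, window, i + 1, mm))
        hits.extend(exact if exact else fuzzy)
    return sorted(hits, key=lambda h: (h.mismatches, h.start, h.motif))


def map_mutations(wt_riboswitch: str, variant: str) -> list[Mutation]:
    """Positions and base changes distinguishing a variant from the WT.

    Variants are point mutants, so the sequences must have equal length
    (no indels); one :class:`Mutation` is reported per differing
    position, 1-based from the riboswitch origin.
    """
    wt, var = wt_riboswitch.upper(), variant.upper()
    if len(wt) != len(var):
        raise ValueError(
            f"length mismatch ({len(wt)} vs {len(var)}); indels are out of scope"
        )
    return [
        Mutation(position=i + 1, wt_base=a, mut_base=b)
        for i, (a, b) in enumerate(zip(wt, var))
        if a != b
    ]


def classify_mutation(
    mutation: Mutation, annotation: RiboswitchAnnotation
) -> Mutation:
    """Fill in the regulatory region and transition/transversion class."""
    region = annotation.region_at(mutation.position)
    is_transition = (mutation.wt_base in PURINES) == (mutation.mut_base in PURINES)
    return replace(
        mutation,
        region=region,
        mutation_class="transition" if is_transition else "transversion",
    )


def conservation_profile(aligned_utrs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Per-column base frequencies and information content in bits.

    Expects pre-aligned, equal-length sequences. Frequencies are
    normalised over non-gap characters; IC = 2 - H (Shannon, log2).
    All-gap columns get IC 0 and ``all_gap`` True.
    """
    if len(aligned_utrs) < 2:
        raise ValueError("need at least two aligned sequences")
    seqs = [s.upper() for _, s in aligned_utrs]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must have equal length")
    length = len(seqs[0])
    records = []
    for col in range(length):
        bases = [s[col] for s in seqs if s[col] in DNA]
        row: dict[str, float | int | bool] = {"column": col + 1}
        if not bases:
            row.update({b: 0.0 for b in "ACGT"})
            row["IC_bits"] = 0.0
            row["all_gap"] = True
        else:
            freqs = {b: bases.count(b) / len(bases) for b in "ACGT"}
            entropy = -sum(
                p * math.log2(p) for p in freqs.values() if p > 0
            )
            row.update(freqs)
            row["IC_bits"] = 2.0 - entropy
            row["all_gap"] = False
        records.append(row)
    df = pd.DataFrame.from_records(records)
    df["IC_bits"] = np.clip(df["IC_bits"], 0.0, 2.0)
    return df
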