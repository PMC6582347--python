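"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`GenomeSeq`, :class:`ParticleRecord`, :class:`ExpressionTable` and
:class:`Pfm`.  Genomic coordinates are 1-based and inclusive on the Watson
reference strand; dyad-relative coordinates are signed integers with the dyad
at 0.

Tag totals in particle tables may be stored in either *genomic* orientation
(upstream = lower coordinate) or *gene* orientation (upstream = towards the
promoter).  In-memory :class:`ParticleRecord` objects are always gene-oriented:
the reader flips upstream/downstream for Crick-strand genes when the table is
genomic (the default), because every analysis in this package is
gene-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomeSeq",
    "ParticleRecord",
    "ExpressionTable",
    "Pfm",
    "HISTONES",
    "SIDES",
    "PARTICLE_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_particle_table",
    "write_particle_table",
    "read_expression_table",
    "read_meme_motifs",
    "write_meme_motifs",
]

HISTONES = ("H2A", "H2B", "H3", "H4")
SIDES = ("upstream", "downstream")
ALPHABET = "ACGT"

PARTICLE_COLUMNS = [
    "gene_id", "chrom", "strand", "gene_index", "dyad",
    "h2a_up", "h2a_down", "h2b_up", "h2b_down",
    "h3_up", "h3_down", "h4_up", "h4_down",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Genome sequence

@dataclass
class GenomeSeq:
    """A genome as a mapping from sequence name to uppercase DNA string."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("genome contains no sequences")
        clean: dict[str, str] = {}
        for name, seq in self.records.items():
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains non-DNA characters {sorted(bad)}"
                )
            clean[name] = seq
        self.records = clean

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the substring [start, end], 1-based inclusive, Watson strand."""
        seq = self.records[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"window [{start}, {end}] out of bounds for {chrom} (length {len(seq)})"
            )
        return seq[start - 1:end]


def read_fasta(path: str | Path) -> GenomeSeq:
    """Read a FASTA file into a :class:`GenomeSeq` (lowercase accepted)."""
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FormatError(f"{path}: not FASTA, first record line is {first!r}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: sequence {rec.id!r} is empty")
        records[rec.id] = str(rec.seq)
    return GenomeSeq(records)


def write_fasta(genome: GenomeSeq, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in genome.records.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Particle tables

@dataclass
class ParticleRecord:
    """One nucleosomal particle with per-histone tag totals on both sides.

    ``tags`` maps ``(histone, side)`` with histone in ``HISTONES`` and side in
    ``SIDES`` to a non-negative real tag total; sides are in *gene* direction.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" (Watson) or "-" (Crick)
    gene_index: int  # 1, 2 or 3: the +1/+2/+3 particle
    dyad: int  # 1-based genomic coordinate
    tags: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.gene_index not in (1, 2, 3):
            raise FormatError(f"gene_index must be 1, 2 or 3, got {self.gene_index}")
        if self.dyad < 1:
            raise FormatError(f"dyad must be >= 1, got {self.dyad}")
        for key, val in self.tags.items():
            if val < 0:
                raise FormatError(f"negative tag total {val} for {key}")

    def tag(self, histone: str, side: str) -> float:
        return self.tags[(histone, side)]


def _row_to_record(row: pd.Series, orientation: str) -> ParticleRecord:
    strand = str(row["strand"])
    tags: dict[tuple[str, str], float] = {}
    for hist in HISTONES:
        up = float(row[f"{hist.lower()}_up"])
        down = float(row[f"{hist.lower()}_down"])
        if orientation == "genomic" and strand == "-":
            up, down = down, up
        tags[(hist, "upstream")] = up
        tags[(hist, "downstream")] = down
    return ParticleRecord(
        gene_id=str(row["gene_id"]),
        chrom=str(row["chrom"]),
        strand=strand,
        gene_index=int(row["gene_index"]),
        dyad=int(row["dyad"]),
        tags=tags,
    )


def read_particle_table(
    path: str | Path, orientation: str = "genomic"
) -> list[ParticleRecord]:
    """Read a TSV particle table into gene-oriented :class:`ParticleRecord` s.

    ``orientation`` declares the convention of the ``*_up``/``*_down`` columns
    on disk: ``"genomic"`` (default; flipped for Crick genes on load) or
    ``"gene"`` (already gene-oriented).  Tag totals may be depth-normalized
    reals; the reader accepts either raw or normalized counts.
    """
    if orientation not in ("genomic", "gene"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    tag_cols = PARTICLE_COLUMNS[5:]
    if (df[tag_cols] < 0).any().any():
        bad = int((df[tag_cols] < 0).any(axis=1).idxmax())
        raise FormatError(f"{path}: negative tag total in row {bad}")
    bad_strand = ~df["strand"].astype(str).isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"{path}: strand must be + or -, got "
            f"{df.loc[bad_strand.idxmax(), 'strand']!r}"
        )
    return [_row_to_record(row, orientation) for _, row in df.iterrows()]


def particles_to_frame(
    particles: list[ParticleRecord], orientation: str = "genomic"
) -> pd.DataFrame:
    """Tabulate records; inverse of the reader's orientation conversion."""
    rows = []
    for p in particles:
        row: dict[str, object] = {
            "gene_id": p.gene_id, "chrom": p.chrom, "strand": p.strand,
            "gene_index": p.gene_index, "dyad": p.dyad,
        }
        for hist in HISTONES:
            up = p.tags[(hist, "upstream")]
            down = p.tags[(hist, "downstream")]
            if orientation == "genomic" and p.strand == "-":
                up, down = down, up
            row[f"{hist.lower()}_up"] = up
            row[f"{hist.lower()}_down"] = down
        rows.append(row)
    return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)


def write_particle_table(
    particles: list[ParticleRecord],
    path: str | Path,
    orientation: str = "genomic",
    header_comment: str | None = None,
) -> None:
    from . import __version__

    df = particles_to_frame(particles, orientation)
    with open(path, "w") as fh:
        fh.write(f"# hexorient {__version__} particle table; orientation={orientation}\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression groups

@dataclass
class ExpressionTable:
    """gene_id -> ordinal expression-group label."""

    groups: dict[str, str]
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in self.levels}
        if bad:
            raise FormatError(f"labels {sorted(bad)} not in declared levels {self.levels}")

    def __getitem__(self, gene_id: str) -> str:
        return self.groups[gene_id]


def read_expression_table(
    path: str | Path, levels: tuple[str, ...] | None = None
) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    groups = dict(zip(df["gene_id"].astype(str), df["group"].astype(str)))
    if levels is None:
        levels = tuple(sorted(set(groups.values())))
    return ExpressionTable(groups, levels)


# ---------------------------------------------------------------------------
# Motifs (MEME minimal text format)

@dataclass
class Pfm:
    """Position frequency matrix over {A, C, G, T}."""

    name: str
    probs: np.ndarray  # shape (width, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise FormatError(f"motif {self.name!r}: probs must be (width, 4)")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9) or np.any(self.probs < 0):
            raise FormatError(f"motif {self.name!r}: rows must be probabilities summing to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def read_meme_motifs(path: str | Path) -> list[Pfm]:
    """Parse motifs from MEME minimal text format.

    Letter-probability rows off by at most 1e-6 from unit sum are
    renormalized; larger deviations raise a :class:`FormatError` naming the
    offending line.  Built by hand because the strict-validation semantics
    (tolerance, line-numbered errors) are part of this reader's contract.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    motifs: list[Pfm] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{i + 1}: MOTIF line without a name")
            name = parts[1]
            # advance to the letter-probability matrix header
            j = i + 1
            while j < n and not lines[j].strip().startswith("letter-probability matrix"):
                if lines[j].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}:{i + 1}: motif {name!r} has no matrix")
                j += 1
            if j == n:
                raise FormatError(f"{path}:{i + 1}: motif {name!r} has no matrix")
            header = lines[j].strip()
            width = None
            toks = header.replace("=", " = ").split()
            for k, tok in enumerate(toks):
                if tok == "w" and k + 2 < len(toks) and toks[k + 1] == "=":
                    width = int(toks[k + 2])
            rows: list[list[float]] = []
            j += 1
            while j < n:
                row_line = lines[j].strip()
                if not row_line or not _is_number_row(row_line):
                    break
                vals = [float(x) for x in row_line.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{j + 1}: expected 4 probabilities, got {len(vals)}")
                s = sum(vals)
                if abs(s - 1.0) > 1e-6:
                    raise FormatError(f"{path}:{j + 1}: probabilities sum to {s:.8f}, not 1")
                rows.append([v / s for v in vals])
                j += 1
            if width is not None and width != len(rows):
                raise FormatError(
                    f"{path}:{i + 1}: motif {name!r} declares w={width} but has {len(rows)} rows"
                )
            if not rows:
                raise FormatError(f"{path}:{i + 1}: motif {name!r} has an empty matrix")
            motifs.append(Pfm(name, np.array(rows)))
            i = j
        else:
            i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def _is_number_row(line: str) -> bool:
    try:
        [float(x) for x in line.split()]
        return True
    except ValueError:
        return False


def write_meme_motifs(motifs: list[Pfm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.probs:
                fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")
            fh.write("\n")
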