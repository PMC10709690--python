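"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are held internally as 0-based, half-open
``[start, end)`` intervals, matching the BED ecosystem.  Printed coordinate
tables that mirror genome-browser display (conserved non-coding sequence
tables) are 1-based inclusive and converted on read; the original printed
coordinates remain recoverable via :meth:`GenomicInterval.printed_start` /
:meth:`GenomicInterval.printed_end`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "GeneModel",
    "FragmentRecord",
    "Pwm",
    "PeakSet",
    "InsertionTrack",
    "CountMatrix",
    "SampleDesign",
    "CONDITIONS",
    "GENOTYPES",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_narrowpeak",
    "write_bed",
    "read_cns_table",
    "read_gene_models",
    "write_gene_models",
    "fragments_to_insertions",
    "read_pwm",
    "write_pwm",
    "write_bedgraph",
]

CONDITIONS = ("Medium", "IL12", "IL12_IL27", "IL27")
GENOTYPES = ("flox", "cre")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded and scored."""

    contig: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.contig}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    @property
    def printed_start(self) -> int:
        """1-based inclusive start, as a genome browser would print it."""
        return self.start + 1

    @property
    def printed_end(self) -> int:
        """1-based inclusive end (equals the half-open end)."""
        return self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-derived transcription start site."""

    gene_id: str
    contig: str
    body_start: int
    body_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.body_start >= self.body_end:
            raise ValueError(f"{self.gene_id}: body_start >= body_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end - 1

    def window(self, margin: int = 3000) -> GenomicInterval:
        """Gene body extended by ``margin`` bp on both sides (clipped at 0)."""
        return GenomicInterval(
            self.contig, max(0, self.body_start - margin), self.body_end + margin,
            strand=self.strand, label=self.gene_id,
        )


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced ATAC fragment (both Tn5 insertion events of a read pair)."""

    contig: str
    frag_start: int
    frag_end: int

    def __post_init__(self) -> None:
        if self.frag_start >= self.frag_end:
            raise ValueError("frag_start must be < frag_end")

    @property
    def span(self) -> int:
        return self.frag_end - self.frag_start


@dataclass(frozen=True)
class Pwm:
    """A position probability matrix over ACGT with a background model."""

    motif_id: str
    matrix: np.ndarray  # L x 4, rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError("PWM must have length >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if np.any(m <= 0):
            raise ValueError("PWM entries must be positive (apply a pseudocount)")
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


@dataclass
class PeakSet:
    """An ordered collection of genomic intervals (ATAC/ChIP peaks, motif
    hits, conserved non-coding elements)."""

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.intervals, key=lambda iv: (iv.contig, iv.start, iv.end)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [iv.contig for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
            }
        )


@dataclass
class InsertionTrack:
    """Per-base Tn5 insertion counts over one or more contigs."""

    tracks: dict[str, np.ndarray]
    n_discarded: int = 0  # insertion events falling outside contig bounds

    def total(self) -> int:
        return int(sum(t.sum() for t in self.tracks.values()))

    def contig(self, name: str) -> np.ndarray:
        return self.tracks[name]

    def __add__(self, other: "InsertionTrack") -> "InsertionTrack":
        if set(self.tracks) != set(other.tracks):
            raise ValueError("tracks cover different contigs")
        return InsertionTrack(
            {c: self.tracks[c] + other.tracks[c] for c in self.tracks},
            self.n_discarded + other.n_discarded,
        )


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if np.any(c < 0):
            raise FormatError("negative counts")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise FormatError("non-integer counts")
            c = np.round(c).astype(np.int64)
        self.counts = c.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class SampleDesign:
    """Experimental design: condition, day, genotype and replicate per sample."""

    table: pd.DataFrame  # index = sample_id; columns condition, day, genotype, replicate

    REQUIRED = ("condition", "day", "genotype", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"design missing columns: {missing}")
        if t.index.has_duplicates:
            raise FormatError("duplicate sample ids in design")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown conditions: {sorted(bad_cond)}")
        bad_geno = set(t["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise FormatError(f"unknown genotypes: {sorted(bad_geno)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return t[name].to_numpy()

    def samples_where(self, **kwargs) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for key, value in kwargs.items():
            mask &= self.table[key] == value
        return list(self.table.index[mask])

    def validate_against(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples absent from design: {sorted(missing)}")


# ---------------------------------------------------------------------------
# counts + design
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, design_path: str | Path) -> tuple[CountMatrix, SampleDesign]:
    """Read a gene x sample count TSV and its design TSV as a validated pair.

    The count file has a header row of sample ids and gene ids in the first
    column.  Every sample must have exactly one design row; negative or
    non-integer counts are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if np.any(values < 0):
        raise FormatError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: non-integer counts")
    cm = CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                     values.astype(np.int64))
    design = read_design(design_path)
    design.validate_against(cm)
    return cm, design


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> SampleDesign:
    t = pd.read_csv(path, sep="\t", index_col=0)
    return SampleDesign(t)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path, max_q: float | None = None) -> PeakSet:
    """Read a narrowPeak (BED6+4) or plain BED3+ file into a :class:`PeakSet`.

    Intervals are taken as half-open 0-based as in BED.  The score column is
    preserved when present.  With ``max_q`` set, narrowPeak records whose
    ``-log10(qValue)`` column implies q >= ``max_q`` are dropped (peak-caller
    significance filtering at read time).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            if max_q is not None and len(fields) >= 9:
                neglog_q = float(fields[8])
                if neglog_q >= 0 and 10 ** (-neglog_q) >= max_q:
                    continue
            intervals.append(GenomicInterval(contig, start, end, strand, score, label))
    return PeakSet(intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            score = "." if iv.score is None else f"{iv.score:g}"
            label = iv.label if iv.label is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{label}\t{score}\t{iv.strand}\n")


def read_cns_table(path: str | Path) -> PeakSet:
    """Read a conserved non-coding sequence coordinate table.

    Expected columns: Gene, Chromosome, start, end, CNS.  Coordinates are
    1-based inclusive as printed in genome-browser style tables and are
    converted to internal 0-based half-open; each interval is labelled
    ``<gene>:CNS<cns>``.
    """
    t = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in t.columns}
    for needed in ("gene", "chromosome", "start", "end", "cns"):
        if needed not in cols:
            raise FormatError(f"{path}: missing column {needed!r}")
    intervals = []
    for _, row in t.iterrows():
        gene = str(row[cols["gene"]]).strip().strip("*")
        contig = str(row[cols["chromosome"]]).strip()
        if not contig.startswith("chr"):
            contig = "chr" + contig
        try:
            start1 = int(row[cols["start"]])
            end1 = int(row[cols["end"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric coordinates for {gene}") from exc
        cns = str(row[cols["cns"]]).strip()
        intervals.append(
            GenomicInterval(contig, start1 - 1, end1, label=f"{gene}:CNS{cns}")
        )
    return PeakSet(intervals)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene bodies from a BED6-style file (name column = gene id)."""
    genes = []
    for iv in read_narrowpeak(path):
        if iv.label is None:
            raise FormatError(f"{path}: gene record without a name")
        if iv.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {iv.label} without strand")
        genes.append(GeneModel(iv.label, iv.contig, iv.start, iv.end, iv.strand))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.body_start}\t{g.body_end}\t{g.gene_id}\t.\t{g.strand}\n")


# ---------------------------------------------------------------------------
# fragments -> insertion track
# ---------------------------------------------------------------------------


def fragments_to_insertions(
    frags: Iterable[FragmentRecord],
    contig_lengths: dict[str, int],
    max_span: int = 99,
    shift_plus: int = 4,
    shift_minus: int = -5,
) -> InsertionTrack:
    """Convert ATAC fragments to a per-base Tn5 insertion track.

    Each retained fragment contributes two insertion events: the 5' end
    shifted by ``shift_plus`` and the rightmost base (``frag_end - 1``)
    shifted by ``shift_minus``, the conventional +4/-5 transposase-dimer
    correction.  Fragments spanning more than ``max_span`` bp are excluded
    (they straddle nucleosomes rather than a single accessible site).
    Events shifted outside the contig are discarded and counted.
    """
    tracks = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    discarded = 0
    for frag in frags:
        if frag.contig not in tracks:
            raise KeyError(f"fragment on unknown contig {frag.contig!r}")
        if frag.span > max_span:
            continue
        length = contig_lengths[frag.contig]
        for pos in (frag.frag_start + shift_plus, frag.frag_end - 1 + shift_minus):
            if 0 <= pos < length:
                tracks[frag.contig][pos] += 1
            else:
                discarded += 1
    if discarded:
        warnings.warn(f"{discarded} shifted insertion events fell outside contigs")
    return InsertionTrack(tracks, n_discarded=discarded)


def write_bedgraph(track: InsertionTrack, path: str | Path) -> None:
    """Export an insertion track as bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for contig in sorted(track.tracks):
            values = track.tracks[contig]
            nz = np.flatnonzero(values)
            if nz.size == 0:
                continue
            # merge consecutive equal-value runs
            run_start = nz[0]
            prev = nz[0]
            for pos in nz[1:]:
                if pos == prev + 1 and values[pos] == values[run_start]:
                    prev = pos
                    continue
                fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{values[run_start]}\n")
                run_start = prev = pos
            fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{values[run_start]}\n")


def read_bedgraph(path: str | Path, contig_lengths: dict[str, int]) -> InsertionTrack:
    tracks = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end, value = line.split("\t")
            if contig not in tracks:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig}")
            tracks[contig][int(start):int(end)] += int(float(value))
    return InsertionTrack(tracks)


# ---------------------------------------------------------------------------
# position weight matrices (MEME-minimal text)
# ---------------------------------------------------------------------------


def read_pwm(path_or_buffer: str | Path | io.TextIOBase, pseudocount: float = 1e-4) -> list[Pwm]:
    """Read motifs from a MEME-minimal text file.

    Each probability row is renormalized after adding ``pseudocount`` so all
    entries are strictly positive (log-odds scores stay finite).
    """
    if isinstance(path_or_buffer, io.TextIOBase):
        lines = path_or_buffer.read().splitlines()
        where = "<buffer>"
    else:
        where = str(path_or_buffer)
        lines = Path(path_or_buffer).read_text().splitlines()

    background = np.full(4, 0.25)
    motifs: list[Pwm] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip() if "=" in line else ""
            if alpha and alpha.upper() != "ACGT":
                raise FormatError(f"{where}: unsupported alphabet {alpha!r}")
            i += 1
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freq.get(b, 0.25) for b in _BASES])
            background = background / background.sum()
            i += 1
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            # skip to the letter-probability header (or straight to numbers)
            while i < n and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip() and lines[i].split()[0].replace(".", "", 1).replace("-", "", 1).isdigit():
                    break
                i += 1
            if i < n and lines[i].strip().startswith("letter-probability"):
                i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            matrix = np.asarray(rows, dtype=float)
            if matrix.size == 0:
                raise FormatError(f"{where}: motif {motif_id} has no probability rows")
            if matrix.shape[1] != 4:
                raise FormatError(f"{where}: motif {motif_id} rows must have 4 columns")
            sums = matrix.sum(axis=1)
            if np.any(sums <= 0):
                raise FormatError(f"{where}: motif {motif_id} has a zero-sum row")
            matrix = matrix + pseudocount
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            motifs.append(Pwm(motif_id, matrix, background))
        else:
            i += 1
    return motifs


def write_pwm(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
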