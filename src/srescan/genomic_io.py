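"""Genomic file I/O and coordinate arithmetic.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; 1-based formats (wiggle fixedStep) are converted on read.  Sequences
are lower-case ``atcg`` with every ambiguity code collapsed to ``n``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .encode import reverse_complement


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class CoordinateError(ValueError):
    """An interval falls outside its chromosome."""


class PromoterBoundsError(CoordinateError):
    """A promoter would extend past a chromosome edge (rejected, not clipped)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A ChIP peak: an interval plus the TF label and any extra table columns."""

    interval: GenomicInterval
    tf_label: str = ""
    attrs: tuple = ()

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass(frozen=True)
class TranscriptRecord:
    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start: interval start on '+', interval end on '-'."""
        return self.interval.start if self.strand == "+" else self.interval.end


@dataclass
class ConservationTrack:
    """Per-base conservation scores (phyloP-like; negative = accelerated).

    Covers ``[offset, offset + len(scores))``; positions outside coverage and
    gaps inside it return the missing marker (NaN by default).
    """

    chrom: str
    offset: int
    scores: np.ndarray
    missing: float = float("nan")

    def slice(self, start: int, end: int) -> np.ndarray:
        """Scores over ``[start, end)``, missing marker where uncovered."""
        out = np.full(end - start, self.missing, dtype=float)
        lo = max(start, self.offset)
        hi = min(end, self.offset + len(self.scores))
        if lo < hi:
            out[lo - start : hi - start] = self.scores[lo - self.offset : hi - self.offset]
        return out


_NON_ACGT = re.compile(r"[^acgt]")


def _clean_sequence(raw: str) -> str:
    return _NON_ACGT.sub("n", raw.lower())


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into ``{header token: lowercase sequence}``.

    Sequences are lower-cased and any letter outside ``acgt`` becomes ``n``.
    Records are keyed by the header token before the first whitespace.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected a '>' header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = _clean_sequence(str(record.seq))
    return genome


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path, width: int = 60) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    """Strand-aware subsequence: ``[start, end)``, reverse-complemented on '-'."""
    if interval.chrom not in genome:
        raise CoordinateError(f"unknown chromosome {interval.chrom!r}")
    chrom_seq = genome[interval.chrom]
    if interval.start < 0 or interval.end > len(chrom_seq):
        raise CoordinateError(
            f"interval {interval.chrom}:[{interval.start},{interval.end}) outside "
            f"chromosome of length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end]
    return reverse_complement(seq) if interval.strand == "-" else seq


def promoter_interval(transcript: TranscriptRecord, length: int = 500) -> GenomicInterval:
    """The ``length`` bases immediately upstream of the TSS, 5'->3' toward it.

    '+' transcript starting at ``s`` -> ``[s - length, s, +)``.  '-' transcript
    ending at ``e`` -> ``[e, e + length, -)``: extraction reverse-complements,
    so both strands read in transcription direction toward the TSS.
    Promoters running past the chromosome start are rejected (never clipped)
    so every promoter has exactly ``length`` bases.
    """
    iv = transcript.interval
    if iv.strand == "+":
        if iv.start - length < 0:
            raise PromoterBoundsError(
                f"promoter of {transcript.gene_id} underflows chromosome start "
                f"(TSS at {iv.start}, need {length} upstream bases)"
            )
        return GenomicInterval(iv.chrom, iv.start - length, iv.start, "+")
    return GenomicInterval(iv.chrom, iv.end, iv.end + length, "-")


def deduplicate_transcripts(transcripts: list[TranscriptRecord]) -> list[TranscriptRecord]:
    """One transcript per gene_id: keep the one whose TSS is most upstream
    (5'-most in transcription direction), i.e. the outermost promoter."""
    best: dict[str, TranscriptRecord] = {}
    for t in transcripts:
        prev = best.get(t.gene_id)
        if prev is None:
            best[t.gene_id] = t
            continue
        if t.strand == "+":
            if t.tss < prev.tss:
                best[t.gene_id] = t
        else:
            if t.tss > prev.tss:
                best[t.gene_id] = t
    return sorted(best.values(), key=lambda t: (t.interval.chrom, t.interval.start))


def read_peaks(path, tf_label: str = "") -> list[Peak]:
    """Read a BED3+/narrowPeak-like TSV of peaks, sorted by (chrom, start).

    Rows with ``end <= start`` are dropped; a single warning reports how many.
    Extra columns ride along unparsed in ``Peak.attrs``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise ValueError(f"{path}: peak table needs at least 3 columns (chrom, start, end)")
    bad = df[1].astype(int) >= df[2].astype(int)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} peak row(s) with end <= start")
        df = df[~bad]
    peaks = [
        Peak(
            GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
            tf_label=tf_label,
            attrs=tuple(row[3:]),
        )
        for row in df.itertuples(index=False)
    ]
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def write_peaks(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            extra = "".join(f"\t{a}" for a in p.attrs)
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}{extra}\n")


def read_transcripts_bed(path) -> list[TranscriptRecord]:
    """Read transcripts from BED6 (name column = gene id, column 6 = strand)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 6:
        raise ValueError(f"{path}: transcript BED needs 6 columns (through strand)")
    return [
        TranscriptRecord(
            gene_id=str(row[3]),
            interval=GenomicInterval(str(row[0]), int(row[1]), int(row[2]), str(row[5])),
        )
        for row in df.itertuples(index=False)
    ]


def write_transcripts_bed(transcripts: list[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.gene_id}\t0\t{iv.strand}\n")


_FIXEDSTEP = re.compile(r"fixedStep\s+chrom=(\S+)\s+start=(\d+)(?:\s+step=(\d+))?(?:\s+span=(\d+))?")


def read_wiggle(path) -> dict[str, ConservationTrack]:
    """Read a fixedStep wiggle (1-based start, converted to 0-based offsets).

    Multiple blocks for one chromosome are merged into a single track with
    NaN in uncovered gaps.  Only step=1/span=1 tracks are supported — the
    per-base resolution phyloP is distributed at.
    """
    blocks: dict[str, list[tuple[int, list[float]]]] = {}
    current: list[float] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            m = _FIXEDSTEP.match(line)
            if m:
                chrom, start1 = m.group(1), int(m.group(2))
                step = int(m.group(3) or 1)
                span = int(m.group(4) or 1)
                if step != 1 or span != 1:
                    raise ValueError(f"{path}: line {lineno}: only step=1 span=1 supported")
                current = []
                blocks.setdefault(chrom, []).append((start1 - 1, current))
            else:
                if current is None:
                    raise ValueError(f"{path}: line {lineno}: value before fixedStep header")
                current.append(float(line))
    return {chrom: _merge_blocks(chrom, blist) for chrom, blist in blocks.items()}


def read_bedgraph(path) -> dict[str, ConservationTrack]:
    """Read a bedGraph (0-based half-open) into per-chromosome tracks."""
    blocks: dict[str, list[tuple[int, list[float]]]] = {}
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return {}
    for row in df.itertuples(index=False):
        chrom, start, end, value = str(row[0]), int(row[1]), int(row[2]), float(row[3])
        blocks.setdefault(chrom, []).append((start, [value] * (end - start)))
    return {chrom: _merge_blocks(chrom, blist) for chrom, blist in blocks.items()}


def _merge_blocks(chrom: str, blist: list[tuple[int, list[float]]]) -> ConservationTrack:
    offset = min(start for start, _ in blist)
    end = max(start + len(vals) for start, vals in blist)
    scores = np.full(end - offset, np.nan)
    for start, vals in blist:
        scores[start - offset : start - offset + len(vals)] = vals
    return ConservationTrack(chrom=chrom, offset=offset, scores=scores)


def write_wiggle(tracks: dict[str, ConservationTrack], path) -> None:
    with open(path, "w") as fh:
        for chrom, track in tracks.items():
            fh.write(f"fixedStep chrom={chrom} start={track.offset + 1} step=1\n")
            fh.write("\n".join(f"{v:.4f}" for v in track.scores) + "\n")
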