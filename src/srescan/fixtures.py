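"""Self-contained synthetic inputs with the statistical structure the
pipeline assumes.

The generator builds a mini-genome of uniform random sequence with planted
SRE-like and CCAAT (NF-Y) motif instances arranged as couples at a bounded
spacing, ChIP-like peak tables over them (plus motif-free control peaks), a
smooth phyloP-like conservation track that peaks on the planted motifs, a
transcriptome whose positive genes carry a planted couple inside the 500-bp
promoter, and GO annotations with one designated term enriched in positive
genes.  Every planted instance is recorded in a first-class truth table so
recovery properties are assertable without re-deriving ground truth.

Defaults: the SRE-1 consensus ``atcaccccac`` and the CCAAT box ``ccaat`` are
the canonical literature motifs; couple spacing defaults to 5-25 bp — the
tight arrangement typical of sterol-responsive promoters, well inside the
250-bp pairing cap, and short enough that a complete couple is guaranteed to
sit intact inside at least three consecutive 100-bp scan windows at the
20-bp scan step, which is the regime the consecutive-window call rule is
designed for.  All outputs are pure functions of the config (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encode import reverse_complement
from .genomic_io import (
    ConservationTrack,
    GenomicInterval,
    Peak,
    TranscriptRecord,
    write_fasta,
    write_peaks,
    write_transcripts_bed,
    write_wiggle,
)

_BASES = np.frombuffer(b"atcg", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureConfig:
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_positive_pairs: int = 60        # ChIP-supported couples, training material
    n_control_peaks: int = 200
    sre_motif: str = "atcaccccac"
    nfy_motif: str = "ccaat"
    sp1_motif: str = "gggcgg"
    pair_spacing: tuple[int, int] = (5, 25)    # bp between SRE end and NFY start
    motif_mutation_rate: float = 0.05
    peak_jitter: int = 10
    peak_halfwidth: int = 25
    n_genes: int = 200
    positive_gene_fraction: float = 0.3
    go_n_terms: int = 20
    go_genes_per_term: int = 25
    go_enriched_positive_fraction: float = 0.8
    promoter_length: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        if not set(self.sre_motif + self.nfy_motif + self.sp1_motif) <= set("atcg"):
            raise ValueError("motifs must be over {a,t,c,g}")
        lo, hi = self.pair_spacing
        if not 0 <= lo <= hi < 250:
            raise ValueError("pair spacing range must sit within [0, 250)")
        for frac in (self.motif_mutation_rate, self.positive_gene_fraction,
                     self.go_enriched_positive_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class Fixture:
    config: FixtureConfig
    genome: dict[str, str]
    truth: pd.DataFrame          # chrom, kind, start, end, pair_id, context, gene_id
    sre_peaks: list[Peak]
    nfy_peaks: list[Peak]
    control_peaks: list[Peak]
    conservation: dict[str, ConservationTrack]
    transcripts: list[TranscriptRecord]
    annotations: dict[str, set[str]]
    term_names: dict[str, str]
    gene_truth: dict[str, bool]          # gene -> promoter carries a planted couple
    enriched_term: str
    expected_counts: dict[str, tuple[int, int]]  # term -> (pos_in, n_in) from truth


def _rng(config: FixtureConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stage])


def _mutate_motif(motif: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(motif.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        cur = int(np.where(_BASES == arr[i])[0][0])
        arr[i] = _BASES[(cur + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode()


class _Occupancy:
    """Per-chromosome reservation of planted regions (with a safety margin)."""

    def __init__(self, margin: int = 300):
        self.margin = margin
        self.taken: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        return all(
            end + self.margin <= s or start - self.margin >= e
            for s, e in self.taken.get(chrom, [])
        )

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.taken.setdefault(chrom, []).append((start, end))

    def sample_position(
        self, chrom: str, span: int, lo: int, hi: int, rng: np.random.Generator,
        max_tries: int = 2000,
    ) -> int:
        for _ in range(max_tries):
            pos = int(rng.integers(lo, hi - span))
            if self.free(chrom, pos, pos + span):
                self.reserve(chrom, pos, pos + span)
                return pos
        raise RuntimeError(f"could not place a span of {span} bp on {chrom}; genome too crowded")


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _plant_pair(
    seq: np.ndarray,
    pos: int,
    config: FixtureConfig,
    rng: np.random.Generator,
    revcomp: bool = False,
) -> tuple[tuple[int, int], tuple[int, int], int]:
    """Plant SRE + spacer + NFY at pos; returns (sre span, nfy span, total span)."""
    spacing = int(rng.integers(config.pair_spacing[0], config.pair_spacing[1] + 1))
    sre = _mutate_motif(config.sre_motif, config.motif_mutation_rate, rng)
    nfy = _mutate_motif(config.nfy_motif, config.motif_mutation_rate, rng)
    cassette = sre + "" .join(
        chr(_BASES[i]) for i in rng.integers(0, 4, size=spacing)
    ) + nfy
    span = len(cassette)
    if revcomp:
        _plant(seq, pos, reverse_complement(cassette))
        # reverse-complementing flips the order: the NFY copy leads, SRE trails
        sre_span = (pos + len(nfy) + spacing, pos + span)
        nfy_span = (pos, pos + len(nfy))
    else:
        _plant(seq, pos, cassette)
        sre_span = (pos, pos + len(sre))
        nfy_span = (pos + len(sre) + spacing, pos + span)
    return sre_span, nfy_span, span


def make_genome(config: FixtureConfig = FixtureConfig()):
    """Random background with ChIP-style planted couples; returns
    (genome arrays, truth rows, occupancy) for downstream stages."""
    rng = _rng(config, 1)
    genome = {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=config.chrom_length)].copy()
        for i in range(config.n_chromosomes)
    }
    occupancy = _Occupancy()
    truth_rows: list[dict] = []
    chroms = sorted(genome)
    max_span = len(config.sre_motif) + config.pair_spacing[1] + len(config.nfy_motif)
    for pair_id in range(config.n_positive_pairs):
        chrom = chroms[pair_id % len(chroms)]
        pos = occupancy.sample_position(
            chrom, max_span, 600, config.chrom_length - 1200, rng
        )
        sre_span, nfy_span, _ = _plant_pair(genome[chrom], pos, config, rng)
        for kind, (s, e) in (("sre", sre_span), ("nfy", nfy_span)):
            truth_rows.append(
                dict(chrom=chrom, kind=kind, start=s, end=e,
                     pair_id=pair_id, context="chip", gene_id="")
            )
    return genome, truth_rows, occupancy


def make_transcriptome_and_go(genome, truth_rows, occupancy, config: FixtureConfig):
    """Place genes (planting couples in the promoters of positive genes) and
    assemble GO groups with one designated enriched term.

    Mutates the genome arrays in place (promoter planting) and appends
    promoter-context rows to the truth.  Minus-strand genes carry the
    reverse-complemented cassette on the template side, so promoter
    extraction recovers it in forward orientation.
    """
    rng = _rng(config, 2)
    chroms = sorted(genome)
    n_pos = round(config.n_genes * config.positive_gene_fraction)
    transcripts: list[TranscriptRecord] = []
    gene_truth: dict[str, bool] = {}
    gene_len = 1000
    L = config.promoter_length
    max_span = len(config.sre_motif) + config.pair_spacing[1] + len(config.nfy_motif)
    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        chrom = chroms[g % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        # reserve promoter + body in one block
        block = L + gene_len
        pos = occupancy.sample_position(chrom, block, 600, config.chrom_length - 1200, rng)
        if strand == "+":
            tss = pos + L
            interval = GenomicInterval(chrom, tss, tss + gene_len, "+")
            prom_start = tss - L
        else:
            tss = pos + gene_len
            interval = GenomicInterval(chrom, pos, tss, "-")
            prom_start = tss  # promoter is [tss, tss + L) on '-'
        transcripts.append(TranscriptRecord(gene_id=gene_id, interval=interval))
        positive = g < n_pos
        gene_truth[gene_id] = positive
        if positive:
            # keep the cassette comfortably inside the promoter
            offset = int(rng.integers(60, L - max_span - 60))
            gpos = prom_start + offset
            sre_span, nfy_span, _ = _plant_pair(
                genome[chrom], gpos, config, rng, revcomp=(strand == "-")
            )
            for kind, (s, e) in (("sre", sre_span), ("nfy", nfy_span)):
                truth_rows.append(
                    dict(chrom=chrom, kind=kind, start=s, end=e,
                         pair_id=-1, context="promoter", gene_id=gene_id)
                )
    # --- GO groups -----------------------------------------------------
    gene_ids = [t.gene_id for t in transcripts]
    positives = [g for g in gene_ids if gene_truth[g]]
    negatives = [g for g in gene_ids if not gene_truth[g]]
    annotations: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    expected: dict[str, tuple[int, int]] = {}
    enriched_term = "GO:0000001"
    for t in range(config.go_n_terms):
        term = f"GO:{t + 1:07d}"
        term_names[term] = (
            "designated enriched process" if term == enriched_term else f"background process {t}"
        )
        k = min(config.go_genes_per_term, len(gene_ids))
        if term == enriched_term:
            k_pos = min(round(k * config.go_enriched_positive_fraction), len(positives))
            k_neg = min(k - k_pos, len(negatives))
            chosen = list(rng.choice(positives, size=k_pos, replace=False)) + list(
                rng.choice(negatives, size=k_neg, replace=False)
            )
        else:
            chosen = list(rng.choice(gene_ids, size=k, replace=False))
        for g in chosen:
            annotations.setdefault(g, set()).add(term)
        expected[term] = (sum(gene_truth[g] for g in chosen), len(chosen))
    return transcripts, annotations, term_names, gene_truth, enriched_term, expected


def make_peaks(truth: pd.DataFrame, config: FixtureConfig):
    """ChIP-style peak tables: one peak per chip-context planted motif
    (center jittered <= peak_jitter) plus motif-free control peaks whose
    centers are rejected within 250 bp of any planted motif."""
    rng = _rng(config, 3)
    sre_peaks, nfy_peaks = [], []
    motif_centers: dict[str, list[int]] = {}
    for row in truth.itertuples(index=False):
        center = (row.start + row.end) // 2
        motif_centers.setdefault(row.chrom, []).append(center)
        if row.context != "chip":
            continue
        jitter = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
        c = center + jitter
        peak = Peak(
            GenomicInterval(row.chrom, c - config.peak_halfwidth, c + config.peak_halfwidth),
            tf_label=row.kind.upper(),
        )
        (sre_peaks if row.kind == "sre" else nfy_peaks).append(peak)
    centers_sorted = {c: np.sort(np.asarray(v)) for c, v in motif_centers.items()}
    chroms = sorted({row.chrom for row in truth.itertuples(index=False)}) or ["chr1"]
    controls: list[Peak] = []
    tries = 0
    while len(controls) < config.n_control_peaks and tries < 200 * config.n_control_peaks:
        tries += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        c = int(rng.integers(600, config.chrom_length - 600))
        centers = centers_sorted.get(chrom)
        if centers is not None and len(centers):
            i = int(np.searchsorted(centers, c))
            near = min(abs(int(centers[j]) - c) for j in (i - 1, i) if 0 <= j < len(centers))
            if near < 250:
                continue
        controls.append(
            Peak(
                GenomicInterval(chrom, c - config.peak_halfwidth, c + config.peak_halfwidth),
                tf_label="CTRL",
            )
        )
    key = lambda p: (p.interval.chrom, p.interval.start)
    return sorted(sre_peaks, key=key), sorted(nfy_peaks, key=key), sorted(controls, key=key)


def make_conservation(truth: pd.DataFrame, config: FixtureConfig) -> dict[str, ConservationTrack]:
    """phyloP-like tracks: N(0,1) background, planted motif bases shifted +3."""
    rng = _rng(config, 4)
    tracks = {}
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        scores = rng.normal(0.0, 1.0, size=config.chrom_length)
        for row in truth.itertuples(index=False):
            if row.chrom == chrom:
                scores[row.start : row.end] += 3.0
        tracks[chrom] = ConservationTrack(chrom=chrom, offset=0, scores=scores)
    return tracks


def make_fixture(config: FixtureConfig = FixtureConfig()) -> Fixture:
    """Run every generation stage and bundle the results with their truth."""
    genome_arrays, truth_rows, occupancy = make_genome(config)
    (transcripts, annotations, term_names, gene_truth,
     enriched_term, expected) = make_transcriptome_and_go(
        genome_arrays, truth_rows, occupancy, config
    )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "kind", "start", "end", "pair_id", "context", "gene_id"]
    )
    sre_peaks, nfy_peaks, control_peaks = make_peaks(truth, config)
    conservation = make_conservation(truth, config)
    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}
    return Fixture(
        config=config,
        genome=genome,
        truth=truth,
        sre_peaks=sre_peaks,
        nfy_peaks=nfy_peaks,
        control_peaks=control_peaks,
        conservation=conservation,
        transcripts=transcripts,
        annotations=annotations,
        term_names=term_names,
        gene_truth=gene_truth,
        enriched_term=enriched_term,
        expected_counts=expected,
    )


def write_fixture_dir(fixture: Fixture, outdir) -> None:
    """Write every fixture artifact in its standard on-disk format."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.genome, outdir / "genome.fa")
    write_peaks(fixture.sre_peaks, outdir / "sre_peaks.tsv")
    write_peaks(fixture.nfy_peaks, outdir / "nfy_peaks.tsv")
    write_peaks(fixture.control_peaks, outdir / "control_peaks.tsv")
    write_wiggle(fixture.conservation, outdir / "conservation.wig")
    write_transcripts_bed(fixture.transcripts, outdir / "transcripts.bed")
    with open(outdir / "go_annotations.tsv", "w") as fh:
        for gene, terms in sorted(fixture.annotations.items()):
            for term in sorted(terms):
                fh.write(f"{gene}\t{term}\tP\n")
    with open(outdir / "go_term_names.tsv", "w") as fh:
        for term, name in sorted(fixture.term_names.items()):
            fh.write(f"{term}\t{name}\n")
    fixture.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in fixture.config.__dict__.items()
        },
        "enriched_term": fixture.enriched_term,
        "gene_truth": fixture.gene_truth,
        "files": [
            "genome.fa", "sre_peaks.tsv", "nfy_peaks.tsv", "control_peaks.tsv",
            "conservation.wig", "transcripts.bed", "go_annotations.tsv",
            "go_term_names.tsv", "truth.tsv",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
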