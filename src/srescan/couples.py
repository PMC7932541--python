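"""Pairing of SRE ChIP peaks with nearby NF-Y peaks and training-window assembly.

An SRE peak joins the positive set when an NF-Y peak center lies within
``max_pair_distance`` (default 250 bp) of its own center; the nearest NF-Y is
kept, one couple per SRE peak.  Each couple yields a 100-bp training window
spanning -50..+50 around the SRE peak center on the forward strand.  Negative
windows come from control peaks whose centers are at least
``max_pair_distance`` away from every SRE and NF-Y center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomicInterval, Peak

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairingConfig:
    max_pair_distance: int = 250  # center-to-center, bp
    flank: int = 50               # each side of the SRE peak center

    def __post_init__(self):
        if self.max_pair_distance <= 0 or self.flank <= 0:
            raise ValueError("max_pair_distance and flank must be positive")


@dataclass(frozen=True)
class PeakPair:
    sre: GenomicInterval
    nfy: GenomicInterval
    distance: int

    def __post_init__(self):
        if self.sre.chrom != self.nfy.chrom:
            raise ValueError("paired peaks must share a chromosome")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass(frozen=True)
class LabeledSequence:
    """A 100-base window with its class label and provenance.

    ``copy_index`` 0 marks a seed window; augmented copies count from 1 and
    record which positions were mutated.
    """

    sequence: str
    label: int
    source_id: str
    chrom: str = ""
    start: int = -1
    end: int = -1
    copy_index: int = 0
    mutated_positions: tuple[int, ...] = ()


def _centers_by_chrom(peaks: list[Peak]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for p in peaks:
        out.setdefault(p.interval.chrom, []).append(p.center)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


def _is_sorted(peaks: list[Peak]) -> bool:
    keys = [(p.interval.chrom, p.interval.start) for p in peaks]
    return keys == sorted(keys)


def find_couples(
    sre_peaks: list[Peak],
    nfy_peaks: list[Peak],
    config: PairingConfig = PairingConfig(),
) -> list[PeakPair]:
    """One couple per SRE peak that has an NF-Y center closer than the cap.

    Proximity is center-to-center; among several candidates the nearest NF-Y
    wins (ties to the leftmost).
    """
    for name, peaks in (("SRE", sre_peaks), ("NFY", nfy_peaks)):
        if not _is_sorted(peaks):
            warnings.warn(f"{name} peaks were not sorted by (chrom, start); sorting internally")
    sre_sorted = sorted(sre_peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    nfy_centers = _centers_by_chrom(nfy_peaks)
    pairs: list[PeakPair] = []
    for sre in sre_sorted:
        centers = nfy_centers.get(sre.interval.chrom)
        if centers is None or len(centers) == 0:
            continue
        c = sre.center
        i = int(np.searchsorted(centers, c))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(centers):
                d = abs(int(centers[j]) - c)
                if best is None or d < best[0]:
                    best = (d, int(centers[j]))
        if best is not None and best[0] < config.max_pair_distance:
            d, nc = best
            pairs.append(
                PeakPair(
                    sre=sre.interval,
                    nfy=GenomicInterval(sre.interval.chrom, nc, nc + 1),
                    distance=d,
                )
            )
    return pairs


def pair_window(
    pair: PeakPair,
    genome: dict[str, str],
    config: PairingConfig = PairingConfig(),
) -> LabeledSequence | None:
    """The positive ±flank window around the SRE peak center (forward strand).

    Returns None when the window would run off the chromosome; callers count
    the skips.
    """
    center = pair.sre.center
    start, end = center - config.flank, center + config.flank
    chrom_seq = genome.get(pair.sre.chrom)
    if chrom_seq is None or start < 0 or end > len(chrom_seq):
        return None
    return LabeledSequence(
        sequence=chrom_seq[start:end],
        label=1,
        source_id=f"{pair.sre.chrom}:{center}",
        chrom=pair.sre.chrom,
        start=start,
        end=end,
    )


def positive_windows(
    pairs: list[PeakPair],
    genome: dict[str, str],
    config: PairingConfig = PairingConfig(),
) -> list[LabeledSequence]:
    out, skipped = [], 0
    for pair in pairs:
        w = pair_window(pair, genome, config)
        if w is None:
            skipped += 1
        else:
            out.append(w)
    if skipped:
        logger.info("skipped %d positive window(s) outside chromosome bounds", skipped)
    return out


def build_negative_set(
    control_peaks: list[Peak],
    sre_peaks: list[Peak],
    nfy_peaks: list[Peak],
    genome: dict[str, str],
    config: PairingConfig = PairingConfig(),
) -> list[LabeledSequence]:
    """±flank windows around control centers far from every SRE/NF-Y center.

    A control peak is kept only when its center is >= max_pair_distance away
    from all SRE and NF-Y peak centers, so negatives carry no positive-class
    signal.
    """
    tf_centers = _centers_by_chrom(sre_peaks + nfy_peaks)
    out, skipped = [], 0
    for ctrl in control_peaks:
        c = ctrl.center
        centers = tf_centers.get(ctrl.interval.chrom)
        if centers is not None and len(centers):
            i = int(np.searchsorted(centers, c))
            near = min(
                abs(int(centers[j]) - c) for j in (i - 1, i) if 0 <= j < len(centers)
            )
            if near < config.max_pair_distance:
                continue
        start, end = c - config.flank, c + config.flank
        chrom_seq = genome.get(ctrl.interval.chrom)
        if chrom_seq is None or start < 0 or end > len(chrom_seq):
            skipped += 1
            continue
        out.append(
            LabeledSequence(
                sequence=chrom_seq[start:end],
                label=0,
                source_id=f"{ctrl.interval.chrom}:{c}",
                chrom=ctrl.interval.chrom,
                start=start,
                end=end,
            )
        )
    if skipped:
        logger.info("skipped %d control window(s) outside chromosome bounds", skipped)
    return out


def write_windows_fasta(windows: list[LabeledSequence], path) -> None:
    """Windows as FASTA; header = origin coordinates, label and copy index."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f">{w.source_id}|label={w.label}|copy={w.copy_index}\n{w.sequence}\n"
            )
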