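"""Sliding-window promoter scanning and occlusion saliency.

A 500-bp promoter is scanned with 100-bp windows at a 20-bp step (21 windows
at offsets 0, 20, ..., 400); each window's probability comes from the trained
classifier.  A promoter is called positive when at least ``call_run_length``
(default 3) *consecutive* windows each exceed ``call_threshold`` (default
0.9, strict).  An alternative reading — the run's mean exceeding the
threshold — is available via ``run_rule="mean"`` but is off by default.

Occlusion localizes the bases driving a prediction: for a 100-bp window the
probability is recomputed 100 times with one base zeroed per pass, giving a
loss vector (intact minus occluded probability; positive loss = the base
supports the call).  Zeroing kills BOTH copies of the base — row ``i`` and
its mirror row ``199 - i`` of the strand-doubled matrix — otherwise the base
leaks back in through the reverse-complement half.  The promoter-level
profile averages the loss vectors of high-probability windows taken at a
5-bp step (81 windows), mapped back to promoter coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn import SREClassifier
from .encode import WINDOW_LENGTH, encode_batch, encode_window
from .genomic_io import GenomicInterval


@dataclass(frozen=True)
class ScanConfig:
    promoter_length: int = 500
    window: int = 100
    scan_step: int = 20
    occlusion_step: int = 5
    call_run_length: int = 3
    call_threshold: float = 0.9
    run_rule: str = "each"  # "each": every window in the run > threshold; "mean": run mean > threshold

    def __post_init__(self):
        if self.window > self.promoter_length:
            raise ValueError("window must not exceed promoter_length")
        span = self.promoter_length - self.window
        if span % self.scan_step or span % self.occlusion_step:
            raise ValueError("steps must divide the scan span evenly")
        if not 0 < self.call_threshold < 1:
            raise ValueError("call_threshold must be in (0, 1)")
        if self.run_rule not in ("each", "mean"):
            raise ValueError("run_rule must be 'each' or 'mean'")


@dataclass
class ScanProfile:
    gene_id: str
    offsets: np.ndarray        # window starts in promoter coordinates
    probabilities: np.ndarray
    positive: bool
    run_start: int = -1        # window indices of the best qualifying run
    run_end: int = -1


@dataclass
class OcclusionProfile:
    gene_id: str
    mean_loss: np.ndarray      # per promoter base; NaN where no window qualifies
    n_windows: np.ndarray      # contributing qualifying windows per base


def window_promoter(seq: str, config: ScanConfig = ScanConfig()) -> list[tuple[int, str]]:
    """(offset, window) pairs at the scan step; 21 windows for 500/100/20."""
    if len(seq) != config.promoter_length:
        raise ValueError(
            f"promoter must be exactly {config.promoter_length} bases, got {len(seq)}"
        )
    return [
        (off, seq[off : off + config.window])
        for off in range(0, config.promoter_length - config.window + 1, config.scan_step)
    ]


def call_positive(
    probabilities: np.ndarray, config: ScanConfig = ScanConfig()
) -> tuple[bool, tuple[int, int]]:
    """Apply the consecutive-window rule; returns (call, best run bounds).

    Under the default rule a qualifying run is >= call_run_length consecutive
    windows each strictly above call_threshold; the longest such run is
    reported (first one on ties).  Bounds are (-1, -1) for a negative call.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    best = (-1, -1)
    if config.run_rule == "each":
        above = p > config.call_threshold
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                if j - i + 1 >= config.call_run_length and j - i > best[1] - best[0]:
                    best = (i, j)
                i = j + 1
            else:
                i += 1
    else:  # longest run whose mean exceeds the threshold
        n = len(p)
        for i in range(n):
            for j in range(i + config.call_run_length - 1, n):
                if p[i : j + 1].mean() > config.call_threshold and j - i > best[1] - best[0]:
                    best = (i, j)
    return best != (-1, -1), best


def scan_promoter(
    model: SREClassifier,
    seq: str,
    config: ScanConfig = ScanConfig(),
    gene_id: str = "",
) -> ScanProfile:
    """Probability per window plus the SRE-NFY call for one promoter."""
    windows = window_promoter(seq, config)
    offsets = np.array([off for off, _ in windows])
    probs = model.predict_proba(encode_batch([w for _, w in windows]))
    positive, (run_start, run_end) = call_positive(probs, config)
    return ScanProfile(
        gene_id=gene_id,
        offsets=offsets,
        probabilities=probs,
        positive=positive,
        run_start=run_start,
        run_end=run_end,
    )


def occlude_window(model: SREClassifier, window: str) -> np.ndarray:
    """Per-base probability loss for one 100-bp window.

    ``loss[i] = p(intact) - p(base i zeroed)``; both the forward row and its
    reverse-complement mirror are zeroed, so the base is truly absent.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"occlusion window must be {WINDOW_LENGTH} bases, got {len(window)}")
    intact = encode_window(window)
    batch = np.repeat(intact[None], WINDOW_LENGTH + 1, axis=0)
    for i in range(WINDOW_LENGTH):
        batch[i + 1, i, :] = 0.0
        batch[i + 1, 2 * WINDOW_LENGTH - 1 - i, :] = 0.0
    probs = model.predict_proba(batch)
    return probs[0] - probs[1:]


def averaged_occlusion(
    model: SREClassifier,
    seq: str,
    config: ScanConfig = ScanConfig(),
    gene_id: str = "",
) -> OcclusionProfile:
    """Base-wise mean occlusion loss over the promoter.

    Windows are taken at ``occlusion_step`` (81 windows for 500/100/5); only
    those whose intact probability exceeds ``call_threshold`` contribute —
    the "best" windows, where the model actually sees a site.  Their loss
    vectors are mapped to promoter coordinates and averaged per base.  The
    result does not depend on window enumeration order.
    """
    if len(seq) != config.promoter_length:
        raise ValueError(
            f"promoter must be exactly {config.promoter_length} bases, got {len(seq)}"
        )
    offsets = list(range(0, config.promoter_length - config.window + 1, config.occlusion_step))
    windows = [seq[off : off + config.window] for off in offsets]
    intact_probs = model.predict_proba(encode_batch(windows))
    total = np.zeros(config.promoter_length)
    counts = np.zeros(config.promoter_length, dtype=int)
    for off, window, p0 in zip(offsets, windows, intact_probs):
        if p0 > config.call_threshold:
            loss = occlude_window(model, window)
            total[off : off + config.window] += loss
            counts[off : off + config.window] += 1
    with np.errstate(invalid="ignore"):
        mean_loss = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return OcclusionProfile(gene_id=gene_id, mean_loss=mean_loss, n_windows=counts)


def scan_to_rows(profile: ScanProfile, promoter: GenomicInterval | None = None) -> list[dict]:
    """Flatten a ScanProfile for TSV output, with genomic positions if known.

    Promoter offset o maps to genome coordinate ``start + o`` on '+' and
    ``end - o - window`` on '-' (the promoter string is already written
    5'->3' toward the TSS).
    """
    rows = []
    for i, (off, prob) in enumerate(zip(profile.offsets, profile.probabilities)):
        if promoter is None:
            genome_pos = ""
        elif promoter.strand == "+":
            genome_pos = promoter.start + int(off)
        else:
            genome_pos = promoter.end - int(off) - 100
        rows.append(
            {
                "gene_id": profile.gene_id,
                "offset": int(off),
                "genomic_position": genome_pos,
                "probability": float(prob),
                "call": int(profile.positive),
                "run_start": profile.run_start,
                "run_end": profile.run_end,
                "in_run": int(profile.run_start <= i <= profile.run_end)
                if profile.positive
                else 0,
            }
        )
    return rows


def called_region_bed_row(
    profile: ScanProfile, promoter: GenomicInterval, config: ScanConfig = ScanConfig()
) -> tuple | None:
    """Genome-coordinate BED row for the called run, strand-aware; None if negative."""
    if not profile.positive:
        return None
    off_lo = int(profile.offsets[profile.run_start])
    off_hi = int(profile.offsets[profile.run_end]) + config.window
    if promoter.strand == "+":
        start, end = promoter.start + off_lo, promoter.start + off_hi
    else:
        start, end = promoter.end - off_hi, promoter.end - off_lo
    return (promoter.chrom, start, end, profile.gene_id, 0, promoter.strand)
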