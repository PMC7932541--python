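"""Conservation-weighted data augmentation of the positive training windows.

Each 100-bp seed window is copied ``copies_per_seed`` times; every copy gets
exactly ``mutations_per_copy`` point mutations at positions drawn by
roulette-wheel selection with wheel slices proportional to the *inverse* of
the per-base phylogenetic score, so strongly conserved bases (high phyloP)
are rarely touched and the planted regulatory grammar survives augmentation.

phyloP can be negative (accelerated sites), so the raw reciprocal is shifted:

    w_i = 1 / (s_i - min(s) + epsilon)

which keeps every slice positive and strictly decreasing in the score.
Positions are drawn *without* replacement — sequential wheel spins with the
chosen slice removed and the wheel renormalized — implemented via the
equivalent exponential race (the k smallest of E_i / w_i, E_i ~ Exp(1)),
which vectorizes over copies.  The replacement base is uniform over the three
alternatives, so every mutation changes the base; ``n`` positions are never
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .couples import LabeledSequence

_BASES = np.frombuffer(b"atcg", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"atcg"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class AugmentConfig:
    mutations_per_copy: int = 20
    copies_per_seed: int = 100
    epsilon: float = 0.1
    train_fraction: float = 0.75  # the 3:1 train:validation split
    rng_seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.copies_per_seed < 0 or self.mutations_per_copy < 0:
            raise ValueError("counts must be non-negative")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def mutation_weights(scores: np.ndarray, epsilon: float = 0.1) -> np.ndarray:
    """Per-position selection probabilities, inverse to conservation.

    Missing scores must be imputed (to 0) beforehand; an all-missing track
    degrades to uniform weights with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).all():
        warnings.warn("conservation track entirely missing; using uniform mutation weights")
        scores = np.zeros_like(scores)
    scores = np.where(np.isnan(scores), 0.0, scores)
    raw = 1.0 / (scores - scores.min() + epsilon)
    return raw / raw.sum()


def _draw_positions(
    weights: np.ndarray, k: int, eligible: np.ndarray, rng: np.random.Generator, n_copies: int
) -> list[np.ndarray]:
    """Weighted sampling without replacement, one draw set per copy.

    Exponential-race form of sequential renormalized roulette-wheel spins:
    position i is taken iff E_i / w_i ranks among the k smallest.
    """
    w = np.where(eligible, weights, 0.0)
    n_eligible = int(eligible.sum())
    kk = min(k, n_eligible)
    if kk < k:
        warnings.warn(
            f"only {n_eligible} eligible positions for {k} requested mutations; mutating all"
        )
    if kk == 0:
        return [np.empty(0, dtype=np.int64) for _ in range(n_copies)]
    keys = rng.standard_exponential((n_copies, len(w)))
    with np.errstate(divide="ignore"):
        keys = keys / w  # ineligible -> inf, never selected
    picked = np.argpartition(keys, kk - 1, axis=1)[:, :kk]
    return [np.sort(row) for row in picked]


def mutate_copy(
    seq: str,
    weights: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, ...]]:
    """One mutated copy: (sequence, sorted mutated positions)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    eligible = _BASE_INDEX[arr] >= 0
    (positions,) = _draw_positions(weights, config.mutations_per_copy, eligible, rng, 1)
    _apply_mutations(arr, positions, rng)
    return arr.tobytes().decode("ascii"), tuple(int(p) for p in positions)


def _apply_mutations(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    if len(positions) == 0:
        return
    cur = _BASE_INDEX[arr[positions]]
    # uniform over the 3 alternatives: shift by 1..3 mod 4
    alt = (cur + rng.integers(1, 4, size=len(positions))) % 4
    arr[positions] = _BASES[alt]


def augment_set(
    seeds: list[LabeledSequence],
    tracks: list[np.ndarray],
    config: AugmentConfig = AugmentConfig(),
) -> list[LabeledSequence]:
    """Originals plus ``copies_per_seed`` mutated copies of every seed.

    ``tracks[i]`` is the per-base conservation slice for ``seeds[i]`` (same
    length as the window).  Output size is ``|seeds| * (1 + copies_per_seed)``
    and is a pure function of (seeds, tracks, config).
    """
    if len(seeds) != len(tracks):
        raise ValueError(f"{len(seeds)} seeds but {len(tracks)} conservation tracks")
    rng = np.random.default_rng(config.rng_seed)
    out: list[LabeledSequence] = []
    for seed, track in zip(seeds, tracks):
        track = np.asarray(track, dtype=float)
        if len(track) != len(seed.sequence):
            raise ValueError(
                f"seed {seed.source_id}: track length {len(track)} != "
                f"sequence length {len(seed.sequence)}"
            )
        out.append(seed)
        if config.copies_per_seed == 0:
            continue
        weights = mutation_weights(track, config.epsilon)
        arr0 = np.frombuffer(seed.sequence.encode("ascii"), dtype=np.uint8)
        eligible = _BASE_INDEX[arr0] >= 0
        draws = _draw_positions(
            weights, config.mutations_per_copy, eligible, rng, config.copies_per_seed
        )
        for copy_idx, positions in enumerate(draws, start=1):
            arr = arr0.copy()
            _apply_mutations(arr, positions, rng)
            out.append(
                LabeledSequence(
                    sequence=arr.tobytes().decode("ascii"),
                    label=seed.label,
                    source_id=seed.source_id,
                    chrom=seed.chrom,
                    start=seed.start,
                    end=seed.end,
                    copy_index=copy_idx,
                    mutated_positions=tuple(int(p) for p in positions),
                )
            )
    return out


def split_train_val(
    samples: list[LabeledSequence],
    config: AugmentConfig = AugmentConfig(),
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Random stratified split (default 3:1), shuffled, seed-reproducible.

    Stratifying by label keeps validation accuracy a stable early-stopping
    signal; within each label the assignment is a random permutation.
    """
    if not samples:
        raise ValueError("cannot split an empty sample list")
    rng = np.random.default_rng(config.rng_seed)
    train: list[LabeledSequence] = []
    val: list[LabeledSequence] = []
    for label in sorted({s.label for s in samples}):
        group = [s for s in samples if s.label == label]
        order = rng.permutation(len(group))
        n_train = round(len(group) * config.train_fraction)
        for rank, idx in enumerate(order):
            (train if rank < n_train else val).append(group[idx])
    rng.shuffle(train)
    rng.shuffle(val)
    return train, val


def sequential_roulette_oracle(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Literal sequential roulette wheel: spin, remove the slice, renormalize.

    Reference sampler used by tests to validate the vectorized
    exponential-race implementation; O(k n) per call.
    """
    w = np.asarray(weights, dtype=float).copy()
    picked = []
    for _ in range(min(k, int((w > 0).sum()))):
        p = w / w.sum()
        i = int(rng.choice(len(w), p=p))
        picked.append(i)
        w[i] = 0.0
    return np.sort(np.asarray(picked, dtype=np.int64))
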