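"""Seeded generator of RNA sequences with ground-truth structures.

Structures are built by a stochastic stem–loop grammar rather than by
thermodynamic sampling: each RNA alternates unpaired exterior linkers
with i-fragments whose outermost helix closes the whole fragment, so
the exterior-loop labels of the generated structure are exact by
construction.  Fragment interiors recurse into hairpins, internal
loops/bulges and two-way multiloops (minimum helix 2 bp, hairpin loops
of at least 3 nt); optionally one crossing pair per fragment emulates a
pseudoknot.  Sequences are sampled so paired positions are complementary
under a configurable GC/AU/GU composition, while unpaired positions
follow region-specific GC fractions — exterior linkers GC-depleted
relative to fragment loops, the compositional contrast the labeler
learns from.

A per-base label-noise knob produces "coarse" training variants with
flipped labels, standing in for structure corpora of uncertain
accuracy, next to noise-free "accurate" variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exterior import label_exterior
from .labeler import WindowDataset
from .struct_io import SecondaryStructure
from .windows import build_labels, encode_window_set, make_windows

__all__ = ["SynthParams", "generate_structure", "generate_corpus", "generate_dataset"]

#: Shortest fragment the grammar can close: 2 bp helix + 3 nt hairpin.
MIN_FRAGMENT = 7

#: Fragment-count distribution shaped like real corpora: most RNAs hold
#: one or two i-fragments and ~17% more than two (up to 10).
DEFAULT_FRAGMENT_COUNT_PROBS = {
    1: 0.55,
    2: 0.28,
    3: 0.07,
    4: 0.04,
    5: 0.025,
    6: 0.015,
    7: 0.009,
    8: 0.006,
    9: 0.003,
    10: 0.002,
}


@dataclass
class SynthParams:
    """Knobs of the structure generator.

    ``n_fragments`` may be an int, an inclusive ``(lo, hi)`` range, or a
    ``{count: prob}`` distribution.  Fragment lengths are lognormal
    (``fragment_length_mean`` nt on the natural scale, default 129 —
    the corpus-average i-fragment length the generator emulates);
    linker lengths are geometric with the given mean, internal linkers
    at least 1 nt.  ``pair_probs`` gives GC/AU/GU weights for paired
    positions; ``exterior_gc`` and ``fragment_gc`` set the unpaired
    G+C fraction per region.  ``label_noise`` is the per-base flip rate
    applied to coarse dataset variants.
    """

    n_fragments: object = None  # default: DEFAULT_FRAGMENT_COUNT_PROBS
    fragment_length_mean: float = 129.0
    fragment_length_sigma: float = 0.7
    fragment_length_max: int = 1100
    linker_length_mean: float = 10.0
    helix_extend_prob: float = 0.7
    branch_prob: float = 0.35
    pair_probs: dict = field(default_factory=lambda: {"GC": 0.5, "AU": 0.4, "GU": 0.1})
    exterior_gc: float = 0.2
    fragment_gc: float = 0.6
    pseudoknot_prob: float = 0.1
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.pair_probs.values())
        if total <= 0:
            raise ValueError("pair_probs must have positive mass")
        self.pair_probs = {k: v / total for k, v in self.pair_probs.items()}
        for name in ("exterior_gc", "fragment_gc", "pseudoknot_prob", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _sample_fragment_count(params: SynthParams, rng: np.random.Generator) -> int:
    spec = params.n_fragments
    if spec is None:
        spec = DEFAULT_FRAGMENT_COUNT_PROBS
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    if isinstance(spec, dict):
        counts = sorted(spec)
        probs = np.asarray([spec[c] for c in counts], dtype=float)
        return int(rng.choice(counts, p=probs / probs.sum()))
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _sample_fragment_length(params: SynthParams, rng: np.random.Generator) -> int:
    mu = np.log(params.fragment_length_mean) - params.fragment_length_sigma**2 / 2
    length = int(round(np.exp(rng.normal(mu, params.fragment_length_sigma))))
    return int(np.clip(length, MIN_FRAGMENT, params.fragment_length_max))


def _sample_linker_length(params: SynthParams, rng: np.random.Generator, terminal: bool) -> int:
    p = 1.0 / max(params.linker_length_mean, 1.0)
    length = int(rng.geometric(p))
    return length - 1 if terminal else length  # terminal linkers may be empty


def _build_fragment_pairs(
    n: int, params: SynthParams, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Nested stem–loop pairs on local coordinates 0..n-1.

    The outermost helix always closes (0, n-1) so the whole region is
    non-exterior; interiors recurse into hairpins, internal loops and
    two-way branches subject to helix >= 2 and hairpin >= 3.
    """
    if n < MIN_FRAGMENT:
        raise ValueError(
            f"fragment of {n} nt infeasible: minimum is {MIN_FRAGMENT} "
            "(2 bp helix + 3 nt hairpin)"
        )
    pairs: set[tuple[int, int]] = set()

    def stem(i: int, j: int) -> None:
        avail = j - i + 1
        max_h = (avail - 3) // 2
        h = 2
        while h < max_h and rng.random() < params.helix_extend_prob:
            h += 1
        for d in range(h):
            pairs.add((i + d, j - d))
        ii, jj = i + h, j - h  # interior, inclusive
        rem = jj - ii + 1
        if rem >= 2 * MIN_FRAGMENT + 1 and rng.random() < params.branch_prob:
            # two-way multiloop: child stems separated by unpaired gaps
            slack = rem - 2 * MIN_FRAGMENT
            g0 = int(rng.integers(0, slack + 1))
            slack -= g0
            g1 = int(rng.integers(1, slack + 1)) if slack >= 1 else 0
            slack -= g1
            extra0 = int(rng.integers(0, slack + 1))
            child0 = MIN_FRAGMENT + extra0
            child1 = rem - g0 - g1 - child0 - (slack - extra0)
            a = ii + g0
            stem(a, a + child0 - 1)
            b = a + child0 + g1
            stem(b, b + child1 - 1)
        elif rem >= MIN_FRAGMENT + 2 and rng.random() < 0.8:
            # internal loop / bulge, then a continuing stem
            slack = rem - MIN_FRAGMENT
            l = int(rng.integers(0, min(slack, 6) + 1))
            r = int(rng.integers(0 if l else 1, min(slack - l, 6) + 1))
            if l + r == 0 or rem - l - r < MIN_FRAGMENT:
                return  # leave interior as a (large) hairpin loop
            stem(ii + l, jj - r)
        # else: hairpin loop (interior left unpaired)

    stem(0, n - 1)

    if rng.random() < params.pseudoknot_prob:
        _try_add_pseudoknot(n, pairs, rng)
    return pairs


def _try_add_pseudoknot(n: int, pairs: set[tuple[int, int]], rng: np.random.Generator) -> None:
    """Add one crossing pair between unpaired loop positions, if possible."""
    paired = {k for p in pairs for k in p}
    unpaired = [k for k in range(n) if k not in paired]
    for _ in range(20):
        if len(unpaired) < 2:
            return
        u, v = sorted(rng.choice(len(unpaired), size=2, replace=False))
        u, v = unpaired[u], unpaired[v]
        if v - u <= 3:
            continue
        crosses = any(a < u < b < v or u < a < v < b for a, b in pairs)
        if crosses:
            pairs.add((u, v))
            return


_GC = ("G", "C")
_AU = ("A", "U")


def _sample_pair_bases(params: SynthParams, rng: np.random.Generator) -> tuple[str, str]:
    kind = rng.choice(["GC", "AU", "GU"], p=[params.pair_probs.get(k, 0.0) for k in ("GC", "AU", "GU")])
    a, b = {"GC": ("G", "C"), "AU": ("A", "U"), "GU": ("G", "U")}[kind]
    return (a, b) if rng.random() < 0.5 else (b, a)


def _sample_unpaired_base(gc: float, rng: np.random.Generator) -> str:
    if rng.random() < gc:
        return _GC[int(rng.random() < 0.5)]
    return _AU[int(rng.random() < 0.5)]


def generate_structure(
    params: SynthParams, seed: int | np.random.Generator | None = 0, name: str = ""
) -> tuple[SecondaryStructure, np.ndarray]:
    """One synthetic RNA: alternating exterior linkers and i-fragments.

    Returns the structure and its exact exterior-loop label vector
    (``labels == label_exterior(structure)`` by construction).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = _sample_fragment_count(params, rng)
    segments: list[tuple[str, int]] = []  # ("linker"|"fragment", length)
    lead = _sample_linker_length(params, rng, terminal=True)
    if k == 0 and lead == 0:
        lead = max(int(round(params.linker_length_mean)), 1)
    if lead:
        segments.append(("linker", lead))
    for fi in range(k):
        segments.append(("fragment", _sample_fragment_length(params, rng)))
        if fi < k - 1:
            segments.append(("linker", _sample_linker_length(params, rng, terminal=False)))
    tail = _sample_linker_length(params, rng, terminal=True)
    if tail:
        segments.append(("linker", tail))

    n = sum(length for _, length in segments)
    pairs: set[tuple[int, int]] = set()
    region_exterior = np.zeros(n, dtype=bool)
    offset = 0
    for kind, length in segments:
        if kind == "fragment":
            for i, j in _build_fragment_pairs(length, params, rng):
                pairs.add((i + offset, j + offset))
        else:
            region_exterior[offset : offset + length] = True
        offset += length

    chars = [""] * n
    for i, j in sorted(pairs):
        if chars[i] or chars[j]:  # base already set by another pair (triple-free grammar)
            continue
        chars[i], chars[j] = _sample_pair_bases(params, rng)
    for pos in range(n):
        if not chars[pos]:
            gc = params.exterior_gc if region_exterior[pos] else params.fragment_gc
            chars[pos] = _sample_unpaired_base(gc, rng)

    structure = SecondaryStructure("".join(chars), pairs, name)
    labels = label_exterior(structure)
    return structure, labels


def generate_corpus(
    n: int, params: SynthParams, seed: int = 0, name_prefix: str = "synth"
) -> list[tuple[SecondaryStructure, np.ndarray]]:
    """n independent structures from one seeded stream."""
    rng = np.random.default_rng(seed)
    return [
        generate_structure(params, rng, name=f"{name_prefix}_{k}") for k in range(n)
    ]


def _flip_labels(
    y: np.ndarray, mask: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate == 0.0:
        return y.copy()
    flips = (rng.random(y.shape) < rate) & (mask > 0)
    return np.where(flips, 1 - y, y).astype(y.dtype)


def generate_dataset(
    n: int,
    params: SynthParams,
    split: Sequence[float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    window_length: int = 200,
    step: int | None = None,
) -> dict[str, dict[str, WindowDataset]]:
    """Windowed, encoded, labeled train/val/test datasets.

    RNAs (not windows) are split disjointly by the given fractions.
    Returns ``{"accurate": {...}, "coarse": {...}}`` where the coarse
    variant has ``params.label_noise`` of its real-base labels flipped
    (train and validation splits only; test labels stay clean so both
    variants are scored against the truth).
    """
    if abs(sum(split) - 1.0) > 1e-9 or len(split) != 3:
        raise ValueError("split must be three fractions summing to 1")
    n_train = int(round(n * split[0]))
    n_val = int(round(n * split[1]))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for split {tuple(split)}")
    corpus = generate_corpus(n, params, seed=seed)
    noise_rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))

    bounds = {
        "train": slice(0, n_train),
        "val": slice(n_train, n_train + n_val),
        "test": slice(n_train + n_val, n),
    }
    accurate: dict[str, WindowDataset] = {}
    coarse: dict[str, WindowDataset] = {}
    for part, sl in bounds.items():
        xs, ys, ms = [], [], []
        for structure, _ in corpus[sl]:
            ws = make_windows(structure.sequence, L=window_length, step=step)
            x, _ = encode_window_set(ws)
            y, m = build_labels(structure, ws)
            xs.append(x)
            ys.append(y)
            ms.append(m)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        m = np.concatenate(ms)
        accurate[part] = WindowDataset(x, y, m)
        if part == "test":
            coarse[part] = WindowDataset(x, y.copy(), m)
        else:
            coarse[part] = WindowDataset(
                x, _flip_labels(y, m, params.label_noise, noise_rng), m
            )
    return {"accurate": accurate, "coarse": coarse}
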