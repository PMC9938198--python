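"""Exterior-loop labeling, i-fragment partitioning, and assembly.

A base belongs to an *exterior loop* when it is unpaired and not
located between two paired bases — i.e. no pair ``(i, j)`` exists with
``i < k < j``.  Bases in non-canonical pairs, base triples, and
pseudoknots all count as paired, and their closed intervals count as
cover.  *Independent fragments* (i-fragments) are the maximal
contiguous runs of non-exterior bases; by construction every base pair
lies entirely inside a single i-fragment, so fragments can be folded
independently and their substructures reassembled losslessly.

Labeling is implemented as interval-union coverage: position ``k`` is
exterior iff it is outside the union of closed intervals ``[i, j]``
over all pairs.  Endpoints of a pair are paired, interior positions are
"between two paired bases", and positions outside every interval are
unpaired dangling/linker bases — the three cases of the definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .struct_io import SecondaryStructure, StructureError

__all__ = [
    "label_exterior",
    "partition_ifragments",
    "extract_substructure",
    "assemble",
    "fragment_stats",
    "context_composition",
    "IFragment",
    "FragmentStats",
    "labels_to_tsv",
    "exterior_runs_to_bed",
]


@dataclass
class IFragment:
    """A maximal non-exterior run, in parent coordinates.

    ``start`` is 0-based inclusive, ``end`` exclusive.  ``substructure``
    (when present) is in local coordinates 0..end-start.
    """

    start: int
    end: int
    sequence: str
    substructure: Optional[SecondaryStructure] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad fragment bounds [{self.start},{self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length != end - start")

    def __len__(self) -> int:
        return self.end - self.start


def label_exterior(structure: SecondaryStructure) -> np.ndarray:
    """Per-base exterior-loop labels (1 = exterior) for a structure.

    Position ``k`` is labeled 1 iff it participates in no pair and no
    pair ``(i, j)`` has ``i < k < j``; equivalently, iff ``k`` lies
    outside the union of closed pair intervals.
    """
    n = len(structure.sequence)
    covered = np.zeros(n, dtype=bool)
    for i, j in structure.pairs:
        covered[i : j + 1] = True
    return (~covered).astype(np.int8)


def partition_ifragments(
    sequence: str, labels: Sequence[int]
) -> list[IFragment]:
    """Maximal runs of non-exterior (label 0) positions, in order.

    A fully exterior RNA yields an empty list: an unpaired RNA has no
    independent fragments to fold.
    """
    labels = np.asarray(labels)
    if len(labels) != len(sequence):
        raise ValueError(
            f"labels length {len(labels)} != sequence length {len(sequence)}"
        )
    fragments: list[IFragment] = []
    n = len(sequence)
    k = 0
    while k < n:
        if labels[k] == 0:
            start = k
            while k < n and labels[k] == 0:
                k += 1
            fragments.append(IFragment(start, k, sequence[start:k]))
        else:
            k += 1
    return fragments


def extract_substructure(
    structure: SecondaryStructure, fragment: IFragment
) -> SecondaryStructure:
    """Local-coordinate substructure of one i-fragment.

    Keeps exactly the pairs with both ends in ``[start, end)`` shifted
    by ``-start``.  For fragments derived from true exterior labels no
    pair can straddle a boundary (the closed interval of a pair is
    entirely non-exterior); a straddling pair indicates inconsistent
    inputs and raises.
    """
    start, end = fragment.start, fragment.end
    local: set[tuple[int, int]] = set()
    for i, j in structure.pairs:
        inside_i = start <= i < end
        inside_j = start <= j < end
        if inside_i != inside_j:
            raise StructureError(
                f"pair ({i},{j}) straddles fragment [{start},{end}) — "
                "labels inconsistent with structure"
            )
        if inside_i and inside_j:
            local.add((i - start, j - start))
    return SecondaryStructure(fragment.sequence, local, structure.name)


def assemble(
    n: int, fragments: Iterable[IFragment], sequence: str | None = None
) -> SecondaryStructure:
    """Shift fragment substructures back to parent coordinates and merge.

    Positions outside every fragment stay unpaired.  If ``sequence`` is
    omitted, fragment sequences are placed on an ``A`` background (the
    pairs, not the linker sequence, are the object of interest).
    """
    frags = sorted(fragments, key=lambda f: f.start)
    prev_end = 0
    for f in frags:
        if f.start < prev_end:
            raise ValueError(
                f"overlapping fragments at [{f.start},{f.end})"
            )
        if f.end > n:
            raise ValueError(f"fragment [{f.start},{f.end}) exceeds length {n}")
        prev_end = f.end
    if sequence is None:
        chars = ["A"] * n
        for f in frags:
            chars[f.start : f.end] = f.sequence
        sequence = "".join(chars)
    elif len(sequence) != n:
        raise ValueError("sequence length != n")
    pairs: set[tuple[int, int]] = set()
    for f in frags:
        if f.substructure is None:
            continue
        if len(f.substructure.sequence) != len(f):
            raise StructureError(
                "fragment substructure length mismatches fragment"
            )
        for i, j in f.substructure.pairs:
            pairs.add((i + f.start, j + f.start))
    return SecondaryStructure(sequence, pairs)


# ---------------------------------------------------------------------------
# corpus statistics


@dataclass
class FragmentStats:
    """Descriptive statistics of i-fragments over a structure corpus.

    ``correlations`` maps a description to ``(r, p)`` Pearson tuples, or
    to ``None`` when a variable is degenerate (zero variance), in which
    case the correlation is undefined rather than NaN.
    """

    per_rna: pd.DataFrame
    fragment_lengths: np.ndarray
    mean_fragment_length: float
    correlations: dict[str, Optional[tuple[float, float]]] = field(
        default_factory=dict
    )


def _pearson_or_none(x, y) -> Optional[tuple[float, float]]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fragment_stats(structures: Sequence[SecondaryStructure]) -> FragmentStats:
    """Per-RNA and corpus-level i-fragment statistics.

    Reports, per RNA: length, fragment count, mean fragment length; and
    over the corpus: the pooled fragment-length distribution plus the
    Pearson correlations between RNA length and fragment count, fragment
    length and parent RNA length, and fragment count and fragment
    length.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures for corpus statistics")
    rows = []
    frag_lengths: list[int] = []
    frag_parent_len: list[int] = []
    frag_parent_count: list[int] = []
    for s in structures:
        frags = partition_ifragments(s.sequence, label_exterior(s))
        lens = [len(f) for f in frags]
        rows.append(
            {
                "name": s.name,
                "length": len(s.sequence),
                "n_fragments": len(frags),
                "mean_fragment_length": float(np.mean(lens)) if lens else np.nan,
            }
        )
        frag_lengths.extend(lens)
        frag_parent_len.extend([len(s.sequence)] * len(lens))
        frag_parent_count.extend([len(frags)] * len(lens))
    per_rna = pd.DataFrame(rows)
    frag_lengths_arr = np.asarray(frag_lengths)
    correlations = {
        "rna_length_vs_fragment_count": _pearson_or_none(
            per_rna["length"], per_rna["n_fragments"]
        ),
        "fragment_length_vs_rna_length": _pearson_or_none(
            frag_lengths_arr, frag_parent_len
        ),
        "fragment_count_vs_fragment_length": _pearson_or_none(
            frag_parent_count, frag_lengths_arr
        ),
    }
    return FragmentStats(
        per_rna=per_rna,
        fragment_lengths=frag_lengths_arr,
        mean_fragment_length=(
            float(frag_lengths_arr.mean()) if len(frag_lengths_arr) else float("nan")
        ),
        correlations=correlations,
    )


def context_composition(
    structures: Sequence[SecondaryStructure],
    window: int = 31,
    per_class: int = 2000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Base composition around exterior vs non-exterior centers.

    Samples ``per_class`` odd-length windows centered on exterior-loop
    bases and the same number centered on non-exterior bases (centers at
    least ``window // 2`` from both sequence ends), then compares the
    A/C/G/U frequencies of the two groups with a two-proportion z-test
    per base.  Exterior loops being depleted in G and C relative to
    fragments is the compositional signal a sequence-only labeler can
    exploit.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    rng = np.random.default_rng(seed)
    ext_centers: list[tuple[int, int]] = []
    non_centers: list[tuple[int, int]] = []
    for si, s in enumerate(structures):
        labels = label_exterior(s)
        for k in range(half, len(s.sequence) - half):
            (ext_centers if labels[k] else non_centers).append((si, k))
    if len(ext_centers) < per_class or len(non_centers) < per_class:
        raise ValueError(
            f"corpus too small: {len(ext_centers)} exterior and "
            f"{len(non_centers)} non-exterior candidate centers for "
            f"per_class={per_class}"
        )
    counts = {}
    for group, centers in (("exterior", ext_centers), ("non_exterior", non_centers)):
        chosen = rng.choice(len(centers), size=per_class, replace=False)
        tally = {b: 0 for b in "ACGU"}
        for ci in chosen:
            si, k = centers[ci]
            for b in structures[si].sequence[k - half : k + half + 1]:
                tally[b] += 1
        counts[group] = tally
    total = {g: sum(c.values()) for g, c in counts.items()}
    rows = []
    for b in "ACGU":
        x1, n1 = counts["exterior"][b], total["exterior"]
        x2, n2 = counts["non_exterior"][b], total["non_exterior"]
        p1, p2 = x1 / n1, x2 / n2
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (p1 - p2) / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {"base": b, "freq_exterior": p1, "freq_non_exterior": p2, "z": z, "p": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# label serialization


def labels_to_tsv(name: str, sequence: str, labels: Sequence[int]) -> str:
    """TSV serialization: name, 1-based position, base, label."""
    lines = ["name\tposition\tbase\tlabel"]
    for k, (b, lab) in enumerate(zip(sequence, labels), start=1):
        lines.append(f"{name}\t{k}\t{b}\t{int(lab)}")
    return "\n".join(lines) + "\n"


def exterior_runs_to_bed(name: str, labels: Sequence[int]) -> str:
    """BED3 intervals (0-based half-open) of exterior-loop runs."""
    labels = np.asarray(labels)
    lines = []
    k = 0
    while k < len(labels):
        if labels[k] == 1:
            start = k
            while k < len(labels) and labels[k] == 1:
                k += 1
            lines.append(f"{name}\t{start}\t{k}")
        else:
            k += 1
    return "\n".join(lines) + ("\n" if lines else "")
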