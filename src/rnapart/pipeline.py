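"""Partition -> per-fragment fold -> assemble, with a pluggable predictor.

The divide-and-conquer premise: exterior-loop bases split an RNA into
independent fragments whose pairs never cross fragment boundaries, so
each fragment can be folded on its own and the substructures assembled
directly into the full-length structure.  Any callable from an RNA
sequence to a :class:`~rnapart.struct_io.SecondaryStructure` of equal
length can serve as the fragment predictor; a built-in Nussinov
maximum-pairing folder keeps the pipeline self-contained and
deterministic, and a subprocess adapter shows how external folding
engines plug in.
"""

from __future__ import annotations

import subprocess
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .exterior import label_exterior, partition_ifragments, assemble
from .labeler import LabelerEnsemble, predict_labels
from .metrics import compute_metrics, pair_confusion
from .struct_io import SecondaryStructure, parse_dotbracket

__all__ = [
    "FragmentPredictor",
    "nussinov_fold",
    "NussinovPredictor",
    "CommandLinePredictor",
    "partition_predict_assemble",
    "evaluate_with_without",
]

#: Contract: sequence in, equal-length structure out, pairs within bounds.
FragmentPredictor = Callable[[str], SecondaryStructure]

CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def nussinov_fold(
    sequence: str,
    min_loop: int = 3,
    allowed_pairs: frozenset = CANONICAL_PAIRS,
) -> SecondaryStructure:
    """Maximum-cardinality nested pairing by dynamic programming.

    ``N[i][j]`` is the maximum number of pairs in ``sequence[i..j]``
    with hairpin loops of at least ``min_loop`` unpaired bases.  The
    recurrence either leaves ``j`` unpaired or pairs it with some
    ``k``; ties break deterministically, preferring ``j`` unpaired and
    then the smallest ``k``.
    """
    seq = sequence.strip().upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid base(s) {sorted(bad)!r} in sequence")
    n = len(seq)
    N = np.zeros((n, n), dtype=np.int32)
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            pairable[i, j] = (seq[i], seq[j]) in allowed_pairs

    def candidates(i: int, j: int) -> np.ndarray:
        ks = np.flatnonzero(pairable[i : j - min_loop, j]) + i
        return ks

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i, j - 1]  # j unpaired
            ks = candidates(i, j)
            if len(ks):
                left = np.where(ks > i, N[i, np.maximum(ks - 1, i)], 0)
                left[ks == i] = 0
                inner = N[np.minimum(ks + 1, j - 1), j - 1]
                inner[ks + 1 > j - 1] = 0
                vals = left + inner + 1
                m = int(vals.max())
                if m > best:
                    best = m
            N[i, j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if N[i, j] == N[i, j - 1]:  # prefer j unpaired on ties
            stack.append((i, j - 1))
            continue
        for k in candidates(i, j):  # smallest k first
            left = N[i, k - 1] if k > i else 0
            inner = N[k + 1, j - 1] if k + 1 <= j - 1 else 0
            if left + inner + 1 == N[i, j]:
                pairs.add((int(k), int(j)))
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                break
    return SecondaryStructure(seq, pairs)


class NussinovPredictor:
    """Deterministic built-in fragment predictor (maximum pairing)."""

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def __call__(self, sequence: str) -> SecondaryStructure:
        return nussinov_fold(sequence, min_loop=self.min_loop)


class CommandLinePredictor:
    """Adapter for external folding engines via a subprocess.

    The command receives the RNA sequence on stdin and must print a
    dot-bracket line (optionally preceded by the sequence) on stdout —
    the convention of ``RNAfold --noPS``-style tools.  Shipped as an
    integration example; nothing in the package requires an external
    engine.
    """

    def __init__(self, command: Sequence[str]):
        self.command = list(command)

    def __call__(self, sequence: str) -> SecondaryStructure:
        proc = subprocess.run(
            self.command,
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = [ln.split()[0] for ln in proc.stdout.splitlines() if ln.strip()]
        brackets = [ln for ln in lines if set(ln) <= set(".()[]{}<>AaBb") and len(ln) == len(sequence)]
        if not brackets:
            raise ValueError(
                f"no dot-bracket line of length {len(sequence)} in output of {self.command}"
            )
        return parse_dotbracket(f"{sequence}\n{brackets[-1]}")


def partition_predict_assemble(
    sequence: str,
    labeler_or_labels,
    predictor: FragmentPredictor,
    threshold: float = 0.5,
) -> SecondaryStructure:
    """Predict exterior labels, fold each i-fragment, assemble.

    ``labeler_or_labels`` is either a trained :class:`LabelerEnsemble`
    or a precomputed per-base label vector (oracle mode).  Exterior
    bases are unpaired in the output; with an all-zero label vector the
    result equals ``predictor(sequence)`` exactly.
    """
    if isinstance(labeler_or_labels, LabelerEnsemble):
        probs = labeler_or_labels.predict_sequence(sequence)
        labels = predict_labels(probs, threshold)
    else:
        labels = np.asarray(labeler_or_labels)
        if len(labels) != len(sequence):
            raise ValueError("label vector length != sequence length")
    fragments = partition_ifragments(sequence, labels)
    for frag in fragments:
        sub = predictor(frag.sequence)
        if len(sub.sequence) != len(frag):
            raise ValueError(
                f"predictor returned length {len(sub.sequence)} for a "
                f"{len(frag)}-base fragment"
            )
        frag.substructure = sub
    return assemble(len(sequence), fragments, sequence=sequence)


def _sign_permutation_p(diffs: np.ndarray, n_perm: int = 2000, seed: int = 0) -> float:
    """Two-sided permutation sign test on paired differences."""
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = abs(nz.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(nz)))
    null = np.abs((signs * nz).mean(axis=1))
    return float((np.sum(null >= obs - 1e-15) + 1) / (n_perm + 1))


def evaluate_with_without(
    corpus: Sequence[SecondaryStructure],
    labeler: Optional[LabelerEnsemble],
    predictor: FragmentPredictor,
    threshold: float = 0.5,
    length_bins: Sequence[int] = (0, 100, 200, 400, 800, 10**9),
    seed: int = 0,
) -> dict:
    """Pair-level metrics of a predictor with vs without partitioning.

    For every reference structure the predictor folds the whole
    sequence ("without") and the partition/assemble pipeline folds the
    fragments ("with"; ``labeler=None`` uses oracle labels from the
    reference structure).  Returns a per-RNA table, paired-difference
    summary with a permutation sign-test p-value, and per-length-bin
    mean F1.
    """
    if not corpus:
        raise ValueError("empty corpus")
    rows = []
    for s in corpus:
        without = predictor(s.sequence)
        if labeler is None:
            labels = label_exterior(s)
            with_ = partition_predict_assemble(s.sequence, labels, predictor, threshold)
        else:
            with_ = partition_predict_assemble(s.sequence, labeler, predictor, threshold)
        rep_wo = compute_metrics(pair_confusion(without, s)).as_dict()
        rep_wi = compute_metrics(pair_confusion(with_, s)).as_dict()
        row = {"name": s.name, "length": len(s.sequence)}
        for key in ("SEN", "PRE", "ACC", "MCC", "F1"):
            row[f"{key}_without"] = rep_wo[key]
            row[f"{key}_with"] = rep_wi[key]
        rows.append(row)
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["F1_with", "F1_without"])
    diffs = (defined["F1_with"] - defined["F1_without"]).to_numpy()
    summary = {
        "n": len(table),
        "mean_F1_without": float(defined["F1_without"].mean()) if len(defined) else None,
        "mean_F1_with": float(defined["F1_with"].mean()) if len(defined) else None,
        "mean_F1_diff": float(diffs.mean()) if len(diffs) else None,
        "p_sign_test": _sign_permutation_p(diffs, seed=seed) if len(diffs) else None,
    }
    table["length_bin"] = pd.cut(table["length"], bins=list(length_bins), right=False)
    by_len = (
        table.groupby("length_bin", observed=True)[["F1_without", "F1_with"]]
        .mean()
        .reset_index()
    )
    return {"per_rna": table, "summary": summary, "by_length": by_len}
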