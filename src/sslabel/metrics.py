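"""Evaluation metrics: per-residue Q accuracy and the Sov fragment-overlap
score.

Q_m is the percentage of residues whose predicted state matches the true
state.  Sov rewards contiguous agreement: for every pair of same-state
overlapping segments (S1 true, S2 predicted),

    term = (minov + sigma) / maxov * len(S1)
    sigma = min(maxov - minov, minov, len(S1) // 2, len(S2) // 2)

where minov is the length of the actual overlap and maxov the extent of
the union of the two segments, and

    Sov = 100 * (sum of terms) / N.

The primary (default) variant takes N as the total number of residues in
the sequence; the ``"sov99"`` variant instead normalizes by the sum of
len(S1) over paired segments plus len(S1) over true segments with no
same-state overlap partner (the 1999 redefinition), for comparison with
other tools.  The default variant gives no credit for unmatched true
segments and can therefore score below published SOV'99 values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .seq_io import LabelSequence

LabelsLike = Union[LabelSequence, str]

__all__ = ["Segment", "q_accuracy", "per_class_recall", "extract_segments", "sov"]


@dataclass(frozen=True)
class Segment:
    """A maximal same-state run; 1-based inclusive residue indices."""

    state: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _labels_str(y: LabelsLike) -> str:
    return y.labels if isinstance(y, LabelSequence) else y


def q_accuracy(y_true: LabelsLike, y_pred: LabelsLike) -> float:
    """Percentage of positions with matching state (Q3/Q8)."""
    t, p = _labels_str(y_true), _labels_str(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    if len(t) == 0:
        raise ValueError("empty sequences")
    matches = sum(a == b for a, b in zip(t, p))
    return 100.0 * matches / len(t)


def per_class_recall(y_true: LabelsLike, y_pred: LabelsLike) -> Dict[str, float]:
    """Per-state recall (percent of true-state residues predicted as such)."""
    t, p = _labels_str(y_true), _labels_str(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    out: Dict[str, float] = {}
    for state in sorted(set(t)):
        total = sum(a == state for a in t)
        hit = sum(a == state and a == b for a, b in zip(t, p))
        out[state] = 100.0 * hit / total
    return out


def extract_segments(y: LabelsLike) -> List[Segment]:
    """Ordered maximal same-state runs covering every position once."""
    s = _labels_str(y)
    segments: List[Segment] = []
    if not s:
        return segments
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            segments.append(Segment(state=s[start], start=start + 1, end=i))
            start = i
    return segments


def _overlap_terms(s1: Segment, s2: Segment) -> Tuple[int, int, int]:
    """(minov, maxov, sigma) for an overlapping same-state pair."""
    minov = min(s1.end, s2.end) - max(s1.start, s2.start) + 1
    maxov = max(s1.end, s2.end) - min(s1.start, s2.start) + 1
    sigma = min(maxov - minov, minov, s1.length // 2, s2.length // 2)
    return minov, maxov, sigma


def sov(y_true: LabelsLike, y_pred: LabelsLike, variant: str = "literal") -> float:
    """Segment-overlap score (percentage).

    ``variant="literal"`` (default) normalizes by the total residue
    count N; ``variant="sov99"`` normalizes by the SOV'99 segment-based
    denominator.  Both use the same per-pair numerator term.
    """
    t, p = _labels_str(y_true), _labels_str(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    if variant not in ("literal", "sov99"):
        raise ValueError(f"unknown Sov variant {variant!r}")
    if len(t) == 0:
        raise ValueError("empty sequences")
    num, denom = _sov_terms(t, p, variant)
    return 100.0 * num / denom if denom > 0 else 0.0


def _sov_terms(t: str, p: str, variant: str) -> Tuple[float, float]:
    """Numerator and denominator of the Sov ratio for one sequence."""
    true_segs = extract_segments(t)
    pred_by_state: Dict[str, List[Segment]] = {}
    for seg in extract_segments(p):
        pred_by_state.setdefault(seg.state, []).append(seg)

    num = 0.0
    seg_denom = 0.0  # SOV'99 normalizer
    for s1 in true_segs:
        partners = [
            s2
            for s2 in pred_by_state.get(s1.state, [])
            if s2.start <= s1.end and s2.end >= s1.start
        ]
        if not partners:
            seg_denom += s1.length
            continue
        for s2 in partners:
            minov, maxov, sigma = _overlap_terms(s1, s2)
            num += (minov + sigma) / maxov * s1.length
            seg_denom += s1.length
    denom = float(len(t)) if variant == "literal" else seg_denom
    return num, denom


def dataset_sov(
    pairs: Sequence[Tuple[LabelsLike, LabelsLike]], variant: str = "literal"
) -> Tuple[float, float]:
    """Corpus-level Sov: (micro, macro).

    Micro pools numerator/denominator over all proteins (N = total
    residues for the literal variant); macro is the unweighted mean of
    per-protein scores.
    """
    nums, denoms, per_protein = [], [], []
    for y_true, y_pred in pairs:
        t, p = _labels_str(y_true), _labels_str(y_pred)
        n, d = _sov_terms(t, p, variant)
        nums.append(n)
        denoms.append(d)
        per_protein.append(100.0 * n / d if d > 0 else 0.0)
    total_d = sum(denoms)
    micro = 100.0 * sum(nums) / total_d if total_d > 0 else 0.0
    macro = float(np.mean(per_protein)) if per_protein else 0.0
    return micro, macro
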