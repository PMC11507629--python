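"""Synthetic corpora with the statistical structure the labeler exploits.

Labels follow a first-order Markov chain over the secondary-structure
alphabet, so same-state runs have geometric lengths (mean 1/(1 - p_stay));
the default three-state chain has strong diagonals and a forbidden
helix-to-sheet transition, giving the CRF transition matrix real
structure to learn.  Per-residue feature vectors stand in for PLM
embeddings: row t is the class mean of the underlying label plus
isotropic Gaussian noise, optionally smoothed along the chain to mimic
local context.  Class means are placed on orthogonal axes, so the
position-wise Bayes accuracy is controlled by the separation/noise
ratio.

Residue strings are uniform random amino acids: the generator couples
features to labels directly and makes no claim of realistic amino-acid
composition.  Everything is reproducible from the spec's seed, and
``write_corpus`` emits the same FASTA/label/HDF5-cache files the I/O
layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alphabets import SS3, SS8, LabelAlphabet
from .encoding import write_embedding_cache
from .seq_io import STANDARD_AA, LabelSequence, ResidueSequence, write_fasta, write_labels

__all__ = [
    "SyntheticSpec", "CorpusRecord", "default_ss3_spec", "default_ss8_spec",
    "sample_labels", "sample_features", "generate_corpus", "write_corpus",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic label/feature distribution."""

    alphabet: LabelAlphabet
    label_transition: np.ndarray  # (K, K) row-stochastic
    label_init: np.ndarray        # (K,) simplex
    class_means: np.ndarray       # (K, D)
    noise_sd: float = 1.0
    length_range: Tuple[int, int] = (40, 60)
    n_sequences: int = 200
    seed: int = 0
    smooth: bool = False          # width-3 moving average over feature rows

    def __post_init__(self) -> None:
        K = self.alphabet.size
        T = np.asarray(self.label_transition, dtype=np.float64)
        pi = np.asarray(self.label_init, dtype=np.float64)
        object.__setattr__(self, "label_transition", T)
        object.__setattr__(self, "label_init", pi)
        object.__setattr__(
            self, "class_means", np.asarray(self.class_means, dtype=np.float64)
        )
        if T.shape != (K, K):
            raise ValueError(f"transition matrix must be {K}x{K}")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(T < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if pi.shape != (K,) or not np.isclose(pi.sum(), 1.0, atol=1e-12):
            raise ValueError("label_init must be a length-K simplex vector")
        if self.class_means.shape[0] != K:
            raise ValueError("class_means must have one row per state")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")

    @property
    def feature_dim(self) -> int:
        return self.class_means.shape[1]


@dataclass(frozen=True)
class CorpusRecord:
    """A sequence with optional true labels and per-residue features.

    The container the pipeline trains/predicts on; labels may be absent
    for prediction-only inputs and features absent under PLM ablation.
    """

    seq: ResidueSequence
    labels: Optional[LabelSequence] = None
    features: Optional[np.ndarray] = None  # (L, D)


def _orthogonal_means(K: int, dim: int, separation: float) -> np.ndarray:
    """Class means on orthogonal coordinate axes at the given norm."""
    if dim < K:
        raise ValueError("feature_dim must be >= number of states")
    means = np.zeros((K, dim))
    means[np.arange(K), np.arange(K)] = separation
    return means


def default_ss3_spec(
    n_sequences: int = 200,
    length_range: Tuple[int, int] = (40, 60),
    feature_dim: int = 64,
    separation: float = 2.3,
    noise_sd: float = 1.0,
    p_stay: float = 0.85,
    seed: int = 0,
) -> SyntheticSpec:
    """Three-state corpus with strong diagonals and a forbidden H->E move.

    At the defaults the two-class Gaussian overlap gives a position-wise
    Bayes ceiling around 0.90 (means separated by ``separation * sqrt(2)``
    at unit noise), leaving the Markov run structure several points of
    headroom for a decoder that uses transitions.
    """
    rest = 1.0 - p_stay
    # state order H, E, C; H->E is structurally forbidden
    T = np.array(
        [
            [p_stay, 0.0, rest],
            [rest / 3.0, p_stay, 2.0 * rest / 3.0],
            [rest / 2.0, rest / 2.0, p_stay],
        ]
    )
    return SyntheticSpec(
        alphabet=SS3,
        label_transition=T,
        label_init=np.full(3, 1.0 / 3.0),
        class_means=_orthogonal_means(3, feature_dim, separation),
        noise_sd=noise_sd,
        length_range=length_range,
        n_sequences=n_sequences,
        seed=seed,
    )


def default_ss8_spec(
    n_sequences: int = 200,
    length_range: Tuple[int, int] = (40, 60),
    feature_dim: int = 64,
    separation: float = 2.6,
    noise_sd: float = 1.0,
    p_stay: float = 0.8,
    seed: int = 0,
) -> SyntheticSpec:
    """Eight-state corpus with forbidden-transition structure.

    Helix states never jump straight into strand states (and vice versa)
    without passing through a coil-like state, mimicking the grammar a
    transition matrix can learn from real assignments.
    """
    K = SS8.size
    helix = {"H", "G", "I"}
    strand = {"E", "B"}
    T = np.zeros((K, K))
    for a_idx, a in enumerate(SS8.states):
        allowed = []
        for b_idx, b in enumerate(SS8.states):
            if b_idx == a_idx:
                continue
            if (a in helix and b in strand) or (a in strand and b in helix):
                continue
            allowed.append(b_idx)
        T[a_idx, a_idx] = p_stay
        T[a_idx, allowed] = (1.0 - p_stay) / len(allowed)
    return SyntheticSpec(
        alphabet=SS8,
        label_transition=T,
        label_init=np.full(K, 1.0 / K),
        class_means=_orthogonal_means(K, feature_dim, separation),
        noise_sd=noise_sd,
        length_range=length_range,
        n_sequences=n_sequences,
        seed=seed,
    )


def sample_labels(spec: SyntheticSpec) -> List[LabelSequence]:
    """Draw label sequences as first-order Markov chains (seeded)."""
    rng = np.random.default_rng(spec.seed)
    K = spec.alphabet.size
    out = []
    lo, hi = spec.length_range
    for _ in range(spec.n_sequences):
        L = int(rng.integers(lo, hi + 1))
        states = np.empty(L, dtype=np.intp)
        states[0] = rng.choice(K, p=spec.label_init)
        for t in range(1, L):
            states[t] = rng.choice(K, p=spec.label_transition[states[t - 1]])
        out.append(
            LabelSequence(spec.alphabet, "".join(spec.alphabet.symbol(s) for s in states))
        )
    return out


def sample_features(
    labels: Sequence[LabelSequence], spec: SyntheticSpec
) -> List[np.ndarray]:
    """Label-coupled Gaussian feature rows for each label sequence (seeded).

    Row t is ``class_means[y_t] + N(0, noise_sd^2 I)``; with
    ``spec.smooth`` a width-3 moving average is applied along the chain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out = []
    for lab in labels:
        idx = np.asarray(lab.indices(), dtype=np.intp)
        mat = spec.class_means[idx] + spec.noise_sd * rng.standard_normal(
            (len(lab), spec.feature_dim)
        )
        if spec.smooth and len(lab) >= 3:
            sm = mat.copy()
            sm[1:-1] = (mat[:-2] + mat[1:-1] + mat[2:]) / 3.0
            mat = sm
        out.append(mat)
    return out


def generate_corpus(spec: SyntheticSpec, id_prefix: str = "syn") -> List[CorpusRecord]:
    """Full corpus: random residue strings + Markov labels + features."""
    labels = sample_labels(spec)
    features = sample_features(labels, spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    aa = np.array(list(STANDARD_AA))
    records = []
    for i, (lab, feat) in enumerate(zip(labels, features)):
        residues = "".join(rng.choice(aa, size=len(lab)))
        records.append(
            CorpusRecord(
                seq=ResidueSequence(id=f"{id_prefix}{i:04d}", residues=residues),
                labels=lab,
                features=feat,
            )
        )
    return records


def write_corpus(
    records: Sequence[CorpusRecord], outdir: str, prefix: str = "corpus"
) -> dict:
    """Write FASTA + label file + embedding cache; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / f"{prefix}.fasta"),
        "labels": str(outdir / f"{prefix}.labels"),
        "embeddings": str(outdir / f"{prefix}.embeddings.h5"),
    }
    write_fasta(paths["fasta"], [r.seq for r in records])
    write_labels(paths["labels"], [(r.seq.id, r.labels) for r in records])
    write_embedding_cache(
        paths["embeddings"], {r.seq.id: r.features for r in records}
    )
    return paths
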