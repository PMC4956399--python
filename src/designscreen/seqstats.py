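"""Sequence-profile statistics for variant sets.

Position frequency profiles, per-position information content in bits (as
drawn by sequence-logo tools), Jensen-Shannon divergence between profiles,
mean divergence from a reference (wild-type) sequence, and PCA of one-hot
encoded sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .codons import AA_ALPHABET, AA_INDEX, validate_protein

__all__ = [
    "SequenceProfile",
    "build_profile",
    "information_content",
    "js_divergence",
    "divergence_from_reference",
    "onehot_encode",
    "onehot_pca",
]

LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class SequenceProfile:
    """Per-position amino-acid frequency matrix (window_length x 20)."""

    matrix: np.ndarray
    n_sequences: int
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if (self.matrix < 0).any():
            raise ValueError("profile entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("profile rows must sum to 1")

    @property
    def window_length(self) -> int:
        return self.matrix.shape[0]


def _index_matrix(sequences: list[str]) -> np.ndarray:
    length = len(sequences[0])
    out = np.empty((len(sequences), length), dtype=np.int8)
    for i, seq in enumerate(sequences):
        if len(seq) != length:
            raise ValueError(
                f"sequence {i} has length {len(seq)}, expected {length}: {seq!r}"
            )
        validate_protein(seq, name=f"sequence {i}")
        out[i] = [AA_INDEX[a] for a in seq]
    return out


def build_profile(sequences: list[str], pseudocount: float = 0.0) -> SequenceProfile:
    """Per-position frequencies: (count + pc) / (n + 20 * pc)."""
    if not sequences:
        raise ValueError("no sequences given")
    idx = _index_matrix(sequences)
    n, length = idx.shape
    counts = np.zeros((length, 20))
    for j in range(length):
        counts[j] = np.bincount(idx[:, j], minlength=20)
    freq = (counts + pseudocount) / (n + 20.0 * pseudocount)
    return SequenceProfile(freq, n, pseudocount)


def _entropy_bits(rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, rows * np.log2(rows), 0.0)
    return -terms.sum(axis=1)


def information_content(
    profile: SequenceProfile, small_sample_correction: bool = False
) -> np.ndarray:
    """Bits per position: log2(20) minus the Shannon entropy of the row.

    ``small_sample_correction`` subtracts the usual 19/(2 ln2 n) logo
    correction (clipped at zero); it is off by default.
    """
    ic = LOG2_20 - _entropy_bits(profile.matrix)
    if small_sample_correction:
        ic = ic - 19.0 / (2.0 * np.log(2.0) * profile.n_sequences)
    return np.clip(ic, 0.0, LOG2_20)


def js_divergence(
    p: SequenceProfile, q: SequenceProfile
) -> tuple[np.ndarray, float]:
    """Per-position Jensen-Shannon divergence in bits, plus its mean.

    JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m the midpoint distribution;
    base-2 logs bound it by 1 bit. Zeros follow the 0*log(0) = 0 convention.
    """
    if p.window_length != q.window_length:
        raise ValueError("profiles have different window lengths")
    m = 0.5 * (p.matrix + q.matrix)
    jsd = _entropy_bits(m) - 0.5 * (_entropy_bits(p.matrix) + _entropy_bits(q.matrix))
    jsd = np.clip(jsd, 0.0, 1.0)
    return jsd, float(jsd.mean())


def divergence_from_reference(sequences: list[str], reference: str) -> float:
    """Mean percent of window positions differing from the reference."""
    validate_protein(reference, name="reference")
    idx = _index_matrix(sequences)
    if idx.shape[1] != len(reference):
        raise ValueError("sequences and reference have different lengths")
    ref = np.array([AA_INDEX[a] for a in reference], dtype=np.int8)
    return float((idx != ref).mean() * 100.0)


def onehot_encode(sequences: list[str]) -> np.ndarray:
    """(n, window_length*20) binary one-hot matrix, alphabetical aa order."""
    idx = _index_matrix(sequences)
    n, length = idx.shape
    out = np.zeros((n, length * 20))
    out[np.arange(n)[:, None], np.arange(length) * 20 + idx] = 1.0
    return out


def onehot_pca(
    sequences: list[str],
    n_components: int = 2,
    fit_set: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of one-hot encoded sequences (mean-centred, unscaled).

    Components are fitted on ``fit_set`` when given, otherwise on
    ``sequences`` themselves; the sequences are then projected. Returns
    (projections, explained-variance fractions). ``n_components`` beyond
    what the fit set supports is truncated with a warning.
    """
    x = onehot_encode(sequences)
    x_fit = onehot_encode(fit_set) if fit_set is not None else x
    max_comp = min(x_fit.shape)
    if n_components > max_comp:
        warnings.warn(f"n_components truncated from {n_components} to {max_comp}", stacklevel=2)
        n_components = max_comp
    pca = PCA(n_components=n_components)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance fit sets
        pca.fit(x_fit)
        ratio = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
        return pca.transform(x), ratio
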