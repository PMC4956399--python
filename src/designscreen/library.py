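"""Designed-library accounting and naive (NNK) library simulation.

Covers the bookkeeping around a designed protein-variant library: the size of
the untruncated sequence landscape, the design budget, top-K selection of
unique variants per design strategy, reverse translation of protein windows
to oligonucleotides, and a biased degenerate-codon (NNK) simulator of naive
combinatorial libraries together with its closed-form per-position
amino-acid distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import (
    AA_ALPHABET,
    CODON_AA_FLAT,
    DEGENERATE,
    MOST_FREQUENT_CODON,
    NT_ALPHABET,
    NT_INDEX,
    STOP_CHAR,
    SYNONYMOUS_CODONS,
    translate,
    validate_protein,
)

__all__ = [
    "VariantRecord",
    "NaiveLibrarySpec",
    "landscape_size",
    "design_budget",
    "select_top_candidates",
    "reverse_translate",
    "simulate_nnk_library",
    "expected_aa_frequency",
    "read_candidates_tsv",
    "write_candidates_tsv",
    "write_variants_fasta",
]


@dataclass(frozen=True)
class VariantRecord:
    """One designed variant: a fixed-length window sequence plus provenance.

    ``score`` follows the energy convention of design software: lower is
    better.
    """

    id: str
    window_seq: str
    strategy: str
    score: float
    backbone_id: str | None = None

    def __post_init__(self) -> None:
        validate_protein(self.window_seq, name=f"variant {self.id}")


@dataclass(frozen=True)
class NaiveLibrarySpec:
    """Parameters of a wild-type-biased degenerate-codon naive library.

    Each codon position of the wild-type nucleotide sequence is randomized
    under a degenerate scheme (default NNK: N = A/C/G/T at codon positions 1
    and 2, K = G/T at position 3), except that with probability ``wt_bias``
    the wild-type base is kept unchanged — the bias branch applies even when
    the wild-type base is outside the scheme's allowed set at that slot.
    """

    wt_nt: str
    scheme: str = "NNK"
    wt_bias: float = 0.70
    n_sequences: int = 1_000_000
    n_replicates: int = 10
    stop_policy: str = "discard"  # or "keep-flagged"

    def __post_init__(self) -> None:
        if len(self.wt_nt) % 3 != 0:
            raise ValueError("wt_nt length must be divisible by 3")
        if not set(self.wt_nt) <= set(NT_ALPHABET):
            raise ValueError("wt_nt must use unambiguous bases A/C/G/T")
        if not 0.0 <= self.wt_bias <= 1.0:
            raise ValueError("wt_bias must lie in [0, 1]")
        if len(self.scheme) != 3 or any(c not in DEGENERATE for c in self.scheme):
            raise ValueError(f"scheme must be a 3-letter degenerate codon, got {self.scheme!r}")
        if self.stop_policy not in ("discard", "keep-flagged"):
            raise ValueError(f"unknown stop_policy {self.stop_policy!r}")

    @property
    def window_length(self) -> int:
        return len(self.wt_nt) // 3

    def allowed_bases(self, slot: int) -> str:
        """Allowed bases of the degenerate scheme at codon slot 0, 1 or 2."""
        return DEGENERATE[self.scheme[slot]]


def landscape_size(n_positions: int, alphabet_size: int) -> int:
    """Exact number of sequences over ``n_positions`` with the given alphabet.

    Computed with arbitrary-precision integers, so e.g. an 18-residue protein
    window gives 20**18 = 262,144,000,000,000,000,000,000 (about 2.6e23)
    without floating-point overflow.
    """
    if n_positions < 0 or alphabet_size < 1:
        raise ValueError("n_positions must be >= 0 and alphabet_size >= 1")
    return int(alphabet_size) ** int(n_positions)


def design_budget(n_backbones: int, n_designs_per_backbone: int) -> int:
    """Total designed models: backbones times designs per backbone."""
    if n_backbones < 0 or n_designs_per_backbone < 0:
        raise ValueError("arguments must be non-negative")
    return int(n_backbones) * int(n_designs_per_backbone)


def select_top_candidates(
    records: list[VariantRecord], k_per_strategy: int
) -> list[VariantRecord]:
    """Best-scoring ``k`` unique variants per strategy, globally deduplicated.

    A window sequence appearing in several records is assigned to the record
    where it scores best (ties broken by strategy label then id, for
    determinism); within each strategy the k best-scoring unique sequences
    are kept, with score ties at the cutoff broken by lexicographic window
    sequence. Because losing duplicates are removed before the per-strategy
    cut, the next-best unique sequence backfills automatically. If a strategy
    holds fewer than k unique sequences a warning is emitted and the partial
    result returned. Output is sorted by (strategy, score).
    """
    if k_per_strategy < 0:
        raise ValueError("k_per_strategy must be >= 0")
    if k_per_strategy == 0 or not records:
        return []

    best: dict[str, VariantRecord] = {}
    for rec in records:
        cur = best.get(rec.window_seq)
        if cur is None or (rec.score, rec.strategy, rec.id) < (cur.score, cur.strategy, cur.id):
            best[rec.window_seq] = rec

    by_strategy: dict[str, list[VariantRecord]] = {}
    for rec in records:  # preserve first-seen strategy order
        by_strategy.setdefault(rec.strategy, [])
    for rec in best.values():
        by_strategy[rec.strategy].append(rec)

    out: list[VariantRecord] = []
    for strategy, pool in by_strategy.items():
        pool.sort(key=lambda r: (r.score, r.window_seq))
        if len(pool) < k_per_strategy:
            warnings.warn(
                f"strategy {strategy!r} has only {len(pool)} unique sequences "
                f"(requested {k_per_strategy})",
                stacklevel=2,
            )
        out.extend(pool[:k_per_strategy])
    out.sort(key=lambda r: (r.strategy, r.score, r.window_seq))
    return out


def reverse_translate(
    window_seq: str,
    codon_choice: str = "most-frequent",
    seed: int | None = None,
) -> str:
    """Back-translate a protein window into an in-frame nucleotide string.

    ``codon_choice`` is ``"most-frequent"`` (fixed per-amino-acid table,
    byte-reproducible) or ``"random"`` (seeded uniform draw among synonymous
    codons). The result always translates back to ``window_seq`` under the
    standard genetic code.
    """
    validate_protein(window_seq)
    if codon_choice == "most-frequent":
        return "".join(MOST_FREQUENT_CODON[aa] for aa in window_seq)
    if codon_choice == "random":
        rng = np.random.default_rng(seed)
        return "".join(
            SYNONYMOUS_CODONS[aa][rng.integers(len(SYNONYMOUS_CODONS[aa]))]
            for aa in window_seq
        )
    raise ValueError(f"unknown codon_choice {codon_choice!r}")


def _sample_aa_matrix(spec: NaiveLibrarySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` windows as an (n, window_length) array of aa/stop chars."""
    length = len(spec.wt_nt)
    wt = np.array([NT_INDEX[b] for b in spec.wt_nt], dtype=np.int8)
    # Per nucleotide slot: keep the wild-type base with prob wt_bias, else
    # draw uniformly from the scheme's allowed set for that codon slot.
    keep = rng.random((n, length)) < spec.wt_bias
    bases = np.empty((n, length), dtype=np.int8)
    bases[:] = wt[None, :]
    for slot in range(3):
        allowed = np.array([NT_INDEX[b] for b in spec.allowed_bases(slot)], dtype=np.int8)
        cols = np.arange(slot, length, 3)
        rand = allowed[rng.integers(0, len(allowed), size=(n, len(cols)))]
        sub = bases[:, cols]
        sub[~keep[:, cols]] = rand[~keep[:, cols]]
        bases[:, cols] = sub
    codon_idx = (
        16 * bases[:, 0::3].astype(np.int32)
        + 4 * bases[:, 1::3].astype(np.int32)
        + bases[:, 2::3].astype(np.int32)
    )
    return CODON_AA_FLAT[codon_idx]


def _rows_to_strings(aa: np.ndarray) -> list[str]:
    joined = aa.view(f"U{aa.shape[1]}").ravel()
    return joined.tolist()


def simulate_nnk_library(spec: NaiveLibrarySpec, seed: int) -> list[list[str]]:
    """Simulate replicate sets of naive-library protein windows.

    Returns ``spec.n_replicates`` independent lists of ``spec.n_sequences``
    amino-acid strings. Under ``stop_policy="discard"`` any window containing
    a stop codon is discarded and redrawn, so set sizes are exact; under
    ``"keep-flagged"`` stop codons appear as ``*`` in the output.
    """
    rng = np.random.default_rng(seed)
    replicates: list[list[str]] = []
    for _ in range(spec.n_replicates):
        aa = _sample_aa_matrix(spec, spec.n_sequences, rng)
        if spec.stop_policy == "discard":
            bad = (aa == STOP_CHAR).any(axis=1)
            while bad.any():
                aa[bad] = _sample_aa_matrix(spec, int(bad.sum()), rng)
                bad = (aa == STOP_CHAR).any(axis=1)
        replicates.append(_rows_to_strings(aa))
    return replicates


def write_candidates_tsv(records: list[VariantRecord], path: str) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "strategy": [r.strategy for r in records],
            "window_seq": [r.window_seq for r in records],
            "score": [r.score for r in records],
            "backbone_id": [r.backbone_id or "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        VariantRecord(
            id=str(row.id),
            window_seq=str(row.window_seq),
            strategy=str(row.strategy),
            score=float(row.score),
            backbone_id=str(row.backbone_id) or None,
        )
        for row in df.itertuples()
    ]


def write_variants_fasta(records: list[VariantRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} strategy={r.strategy} score={r.score:.4f}\n{r.window_seq}\n")


def expected_aa_frequency(spec: NaiveLibrarySpec, position: int) -> tuple[pd.Series, float]:
    """Exact amino-acid distribution at one window position (0-based).

    Marginalizes the per-base mixture (``wt_bias`` on the wild-type base,
    the remainder uniform over the scheme's allowed set) over the 64 codons.
    Returns a 20-entry frequency Series plus the stop-codon mass; the Series
    and stop mass together sum to 1.
    """
    if not 0 <= position < spec.window_length:
        raise ValueError(f"position {position} outside window of length {spec.window_length}")
    probs = np.zeros(20)
    stop = 0.0
    slot_dists = []
    for slot in range(3):
        wt_base = spec.wt_nt[3 * position + slot]
        allowed = spec.allowed_bases(slot)
        dist = {b: 0.0 for b in NT_ALPHABET}
        dist[wt_base] += spec.wt_bias
        for b in allowed:
            dist[b] += (1.0 - spec.wt_bias) / len(allowed)
        slot_dists.append(dist)
    for i, b1 in enumerate(NT_ALPHABET):
        for b2 in NT_ALPHABET:
            for b3 in NT_ALPHABET:
                p = slot_dists[0][b1] * slot_dists[1][b2] * slot_dists[2][b3]
                if p == 0.0:
                    continue
                aa = CODON_AA_FLAT[16 * i + 4 * NT_INDEX[b2] + NT_INDEX[b3]]
                if aa == STOP_CHAR:
                    stop += p
                else:
                    probs[AA_ALPHABET.index(aa)] += p
    return pd.Series(probs, index=list(AA_ALPHABET)), float(stop)
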