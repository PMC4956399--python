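"""Seeded synthetic-data generators for the whole screening pipeline.

Everything downstream — library selection, selection-count simulation, read
QC, profile statistics, the read-count surrogate and structural rescoring —
can be exercised on data produced here, with no external downloads. The
generators emulate a designed protein-variant screen:

* a ground-truth affinity landscape over an 18-residue window, additive per
  position so that closed-form oracles are exact;
* design candidates from several "strategies", each sampling its own
  perturbed Boltzmann distribution over the landscape so strategy profiles
  occupy distinct sequence regions;
* selection read counts whose expected log10 value decreases affinely with
  the affinity score (tighter binders get more reads), with
  negative-binomial overdispersion;
* single-end FASTQ reads with substitution errors and Phred strings;
* jittered two-chain complex ensembles for structural analytics;
* four-parameter-logistic dose-response curves.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import AA_ALPHABET, AA_INDEX, NT_ALPHABET, validate_protein
from .library import VariantRecord
from .readqc import DEFAULT_TEMPLATE, ReadCountTable, ReadTemplate
from .structscore import Atom, StructureModel

__all__ = [
    "CountModel",
    "GroundTruth",
    "DoseResponseCurve",
    "PhredModel",
    "DEFAULT_WT_WINDOW",
    "make_ground_truth",
    "simulate_design_candidates",
    "simulate_selection_counts",
    "expected_log10_counts",
    "simulate_reads",
    "simulate_structures",
    "simulate_dose_response",
]

#: Human ubiquitin residues 54-71, the designed window emulated throughout.
DEFAULT_WT_WINDOW = "RTLSDYNIQKESTLHLVL"


@dataclass(frozen=True)
class CountModel:
    """Affine link from affinity score to expected log10 read count.

    Expected log10 count decreases with the affinity score at ``slope``
    (per selection round); ``overdispersion`` is the negative-binomial
    dispersion (variance = mu + overdispersion * mu^2; 0 means Poisson).
    """

    slope: float = 0.15
    overdispersion: float = 0.3


@dataclass(frozen=True)
class GroundTruth:
    """Additive per-position affinity landscape over the designed window.

    ``energy[i, j]`` is the contribution of amino acid j (alphabetical
    order) at window position i; lower total = tighter binding. Hotspots
    are substitutions constructed to lower the wild-type affinity by a fixed
    effect size, emulating the critical interface mutations that selection
    experiments recover.
    """

    window_start: int
    window_length: int
    wt_aa: str
    energy: np.ndarray
    hotspots: tuple[tuple[int, str, float], ...]
    count_model: CountModel
    seed: int

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if len(self.wt_aa) != self.window_length:
            raise ValueError("wt_aa length must equal window_length")
        validate_protein(self.wt_aa, name="wt_aa")
        if self.energy.shape != (self.window_length, 20):
            raise ValueError("energy must be (window_length, 20)")
        if not np.isfinite(self.energy).all():
            raise ValueError("energy entries must be finite")

    def affinity(self, seq: str) -> float:
        """Additive affinity score of one window sequence (lower = tighter)."""
        if len(seq) != self.window_length:
            raise ValueError("sequence length mismatch")
        idx = [AA_INDEX[a] for a in seq]
        return float(self.energy[np.arange(self.window_length), idx].sum())

    def affinities(self, seqs: list[str]) -> np.ndarray:
        return np.array([self.affinity(s) for s in seqs])

    def reference_binder(self) -> str:
        """Wild type with all hotspot substitutions applied — the emulation
        of a previously characterized tight binder used for calibration."""
        seq = list(self.wt_aa)
        for pos, aa, _ in self.hotspots:
            seq[pos] = aa
        return "".join(seq)


def make_ground_truth(
    seed: int,
    n_hotspots: int = 3,
    effect_size: float = 2.0,
    window_start: int = 54,
    window_length: int = 18,
    wt_aa: str = DEFAULT_WT_WINDOW,
    energy_scale: float = 1.0,
    wt_favor: float = 3.0,
    count_model: CountModel = CountModel(),
) -> GroundTruth:
    """Draw a seeded additive landscape with planted hotspot substitutions.

    The wild-type residue at each position gets an energy bonus drawn
    uniformly from [0, 2*wt_favor] below the random background: strongly
    conserved positions coexist with tolerant ones, so Boltzmann-sampled
    designs retain roughly half the wild-type residues while the best of
    them bind tighter than wild type — the regime real designed binder
    sets sit in. Each hotspot is a (position, favored amino acid, effect) triple with
    the favored residue differing from wild type and its energy set exactly
    ``effect_size`` below the wild-type residue's energy at that position,
    so ``affinity(wt with hotspot applied) == affinity(wt) - effect_size``.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if n_hotspots > window_length:
        raise ValueError("n_hotspots cannot exceed window_length")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if len(wt_aa) != window_length:
        wt_aa = wt_aa[:window_length] if len(wt_aa) > window_length else None
        if wt_aa is None:
            raise ValueError("wt_aa shorter than window_length")
    rng = np.random.default_rng(seed)
    energy = rng.normal(0.0, energy_scale, size=(window_length, 20))
    bonuses = rng.uniform(0.0, 2.0 * wt_favor, size=window_length)
    for pos in range(window_length):
        energy[pos, AA_INDEX[wt_aa[pos]]] -= bonuses[pos]
    positions = rng.choice(window_length, size=n_hotspots, replace=False)
    hotspots: list[tuple[int, str, float]] = []
    for pos in sorted(int(p) for p in positions):
        wt_idx = AA_INDEX[wt_aa[pos]]
        choices = [i for i in range(20) if i != wt_idx]
        fav = int(rng.choice(choices))
        energy[pos, fav] = energy[pos, wt_idx] - effect_size
        hotspots.append((pos, AA_ALPHABET[fav], effect_size))
    return GroundTruth(
        window_start=window_start,
        window_length=window_length,
        wt_aa=wt_aa,
        energy=energy,
        hotspots=tuple(hotspots),
        count_model=count_model,
        seed=seed,
    )


def simulate_design_candidates(
    gt: GroundTruth,
    strategies: list[str],
    n_per_strategy: int,
    bias: float | dict[str, float] = 1.0,
    seed: int = 0,
    strategy_spread: float = 0.75,
    score_noise: float = 0.5,
) -> list[VariantRecord]:
    """Sample strategy-labeled design candidates from the landscape.

    Each strategy perturbs the landscape with its own Gaussian offset of
    scale ``strategy_spread`` (so different strategies prefer measurably
    different sequence regions) and samples per-position residues from the
    Boltzmann distribution exp(-E/T) at temperature ``bias`` (scalar or
    per-strategy mapping; T -> 0 collapses onto the optimum sequence of the
    strategy's effective landscape). The design score is the true affinity
    plus Gaussian noise of scale ``score_noise``.
    """
    if not strategies:
        raise ValueError("strategy list is empty")
    if n_per_strategy < 1:
        raise ValueError("n_per_strategy must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    for strategy in strategies:
        temp = bias[strategy] if isinstance(bias, dict) else float(bias)
        eff = gt.energy + rng.normal(0.0, strategy_spread, size=gt.energy.shape)
        if temp <= 0:
            aa_idx = np.tile(eff.argmin(axis=1), (n_per_strategy, 1))
        else:
            logits = -eff / temp
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            cum = probs.cumsum(axis=1)
            u = rng.random((n_per_strategy, gt.window_length))
            aa_idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        aa_arr = np.array(list(AA_ALPHABET), dtype="U1")[aa_idx]
        seqs = aa_arr.view(f"U{gt.window_length}").ravel().tolist()
        noise = rng.normal(0.0, score_noise, size=n_per_strategy)
        for i, (s, eps) in enumerate(zip(seqs, noise)):
            records.append(
                VariantRecord(
                    id=f"{strategy}_{i:06d}",
                    window_seq=s,
                    strategy=strategy,
                    score=gt.affinity(s) + float(eps),
                    backbone_id=f"{strategy}_bb{i // 25:04d}",
                )
            )
    return records


def _expected_counts(
    seqs: list[str], gt: GroundTruth, rounds: int, depth: int
) -> np.ndarray:
    aff = gt.affinities(seqs)
    logw = -gt.count_model.slope * rounds * aff
    logw -= logw.max()
    w = 10.0**logw
    return depth * w / w.sum()


def expected_log10_counts(
    library: list[VariantRecord], gt: GroundTruth, rounds: int, depth: int
) -> np.ndarray:
    """Noise-free expected log10 counts; affine and decreasing in affinity."""
    mu = _expected_counts([r.window_seq for r in library], gt, rounds, depth)
    return np.log10(mu)


def simulate_selection_counts(
    library: list[VariantRecord],
    gt: GroundTruth,
    rounds: int = 4,
    depth: int = 100_000,
    seed: int = 0,
    channel: str | None = None,
) -> ReadCountTable:
    """Draw overdispersed per-variant read counts after ``rounds`` selections.

    The expected count of a variant is proportional to
    10**(-slope * rounds * affinity), normalized to the sequencing depth, so
    the expected log10 count is affine and decreasing in the affinity score
    with a slope proportional to the number of rounds. Counts are
    negative-binomial (gamma-Poisson mixture) with the ground truth's
    overdispersion; overdispersion 0 gives Poisson counts.
    """
    if rounds < 1 or depth < 1:
        raise ValueError("rounds and depth must be >= 1")
    channel = channel or f"phage_r{rounds}"
    if not library:
        return ReadCountTable.from_counts({}, channel, 0)
    rng = np.random.default_rng(seed)
    seqs = [r.window_seq for r in library]
    mu = _expected_counts(seqs, gt, rounds, depth)
    phi = gt.count_model.overdispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    counts = rng.poisson(lam)
    table = {s: int(c) for s, c in zip(seqs, counts) if c > 0}
    return ReadCountTable.from_counts(table, channel, 0)


@dataclass(frozen=True)
class PhredModel:
    """Quality-string model: clean bases score high, error bases score low."""

    q_high: int = 38
    q_low: int = 12


def simulate_reads(
    table: ReadCountTable,
    oligo_map: dict[str, str],
    error_rate: float = 0.0,
    phred_model: PhredModel = PhredModel(),
    seed: int = 0,
    template: ReadTemplate = DEFAULT_TEMPLATE,
    channel: str | None = None,
) -> list[SeqRecord]:
    """Emit one FASTQ record per counted read of each variant.

    Reads are single-end: left anchor + variant oligo + right anchor.
    Substitution errors are introduced independently per base at
    ``error_rate``; positions that received an error are marked with the low
    Phred score of the model, all others with the high score, so the quality
    string is consistent with where the errors lie. A variant missing from
    ``oligo_map`` raises ``KeyError`` naming it.
    """
    if channel is None:
        if len(table.channels) != 1:
            raise ValueError("channel must be given for multi-channel tables")
        channel = table.channels[0]
    counts = table.counts(channel)
    for variant in counts.index:
        if variant not in oligo_map:
            raise KeyError(f"no oligo for variant {variant!r}")
    rng = np.random.default_rng(seed)
    nt = np.array(list(NT_ALPHABET), dtype="U1")
    nt_idx = {b: i for i, b in enumerate(NT_ALPHABET)}
    reads: list[SeqRecord] = []
    serial = 0
    for variant, count in counts.items():
        full = template.left_anchor + oligo_map[variant] + template.right_anchor
        base_idx = np.array([nt_idx[b] for b in full], dtype=np.int8)
        for _ in range(int(count)):
            idx = base_idx.copy()
            errors = rng.random(len(idx)) < error_rate
            if errors.any():
                # substitute to one of the three other bases
                shift = rng.integers(1, 4, size=int(errors.sum()))
                idx[errors] = (idx[errors] + shift) % 4
            quals = np.where(errors, phred_model.q_low, phred_model.q_high)
            rec = SeqRecord(
                Seq("".join(nt[idx])),
                id=f"read_{serial:07d}",
                description=f"channel={channel}",
            )
            rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
            reads.append(rec)
            serial += 1
    return reads


def _reference_complex(n_residues: int) -> StructureModel:
    """Toy two-chain complex: variant strand (chain A) facing partner (B)."""
    atoms: list[Atom] = []

    def add_res(chain: str, rn: int, x0: float, y0: float, sc_dir: float) -> None:
        resname = "ALA"
        atoms.extend(
            [
                Atom(chain, rn, resname, "N", x0 - 1.2, y0, 0.0, "N"),
                Atom(chain, rn, resname, "CA", x0, y0, 0.0, "C"),
                Atom(chain, rn, resname, "C", x0 + 1.2, y0, 0.3, "C"),
                Atom(chain, rn, resname, "O", x0 + 1.2, y0, 1.5, "O"),
                Atom(chain, rn, resname, "CB", x0, y0 + 1.5 * sc_dir, 0.5, "C"),
            ]
        )

    for i in range(n_residues):
        add_res("A", i + 1, 3.8 * i, 0.0, +1.0)
    n_partner = max(4, n_residues // 2)
    for i in range(n_partner):
        add_res("B", i + 1, 3.8 * i + 1.9, 6.0, -1.0)
    return StructureModel(atoms, "ref")


def simulate_structures(
    n_models: int,
    n_residues: int = 18,
    displacement_sd: float = 0.5,
    seed: int = 0,
) -> list[StructureModel]:
    """Jittered backbone ensemble around a toy two-chain reference complex.

    Model 0 is the reference itself. Each further model applies smooth
    (sequence-coherent) Gaussian per-residue displacement whose 3-D
    magnitude has root-mean-square ``displacement_sd`` (A), applied to all
    atoms of a residue, followed by a random rigid rotation and translation
    — which superposition removes, so the Kabsch RMSD to the reference
    reflects only the jitter and is of order ``displacement_sd``.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    ref = _reference_complex(n_residues)
    residues = sorted({(a.chain, a.resnum) for a in ref.atoms})
    res_of_atom = np.array([residues.index((a.chain, a.resnum)) for a in ref.atoms])
    # 3-point smoothing kernel, L2-normalized so the marginal sd is preserved
    kernel = np.array([0.5, 1.0, 0.5])
    kernel = kernel / np.sqrt((kernel**2).sum())
    per_axis_sd = displacement_sd / np.sqrt(3.0)

    models = [ref.with_coords(ref.coords(), model_id="model_0000")]
    for m in range(1, n_models):
        disp = rng.normal(0.0, per_axis_sd, size=(len(residues), 3))
        for axis in range(3):
            disp[:, axis] = np.convolve(disp[:, axis], kernel, mode="same")
        coords = ref.coords() + disp[res_of_atom]
        rot = Rotation.from_rotvec(rng.normal(0.0, 1.0, size=3))
        coords = rot.apply(coords) + rng.normal(0.0, 5.0, size=3)
        models.append(ref.with_coords(coords, model_id=f"model_{m:04d}"))
    return models


@dataclass(frozen=True)
class DoseResponseCurve:
    """Noisy four-parameter-logistic inhibition curve with known truth."""

    concentrations: np.ndarray  # molar, strictly increasing
    response: np.ndarray  # fraction activity
    truth_ic50: float
    truth_hill: float

    def __post_init__(self) -> None:
        if not (np.diff(self.concentrations) > 0).all():
            raise ValueError("concentrations must be strictly increasing")
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    concentrations: np.ndarray | list[float] | None = None,
    seed: int = 0,
    bottom: float = 0.0,
    top: float = 1.0,
) -> DoseResponseCurve:
    """Sample activity = bottom + (top-bottom)/(1+(c/ic50)^hill) + noise.

    Concentrations default to 11 log-spaced points over three decades either
    side of the true IC50. At c = ic50 the noise-free response is exactly
    the midpoint (top+bottom)/2.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if concentrations is None:
        concentrations = np.geomspace(ic50 * 1e-3, ic50 * 1e3, 11)
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    response = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=conc.shape)
    return DoseResponseCurve(conc, response, float(ic50), float(hill))
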