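"""Read-count surrogate models and affinity extrapolation.

The central idea: after several selection rounds, a variant's deep
sequencing read count is a surrogate for its binding affinity. This module
trains an ensemble of random-forest regressors to predict log10 read count
from the window sequence — positives are the selected variants with their
observed counts, and each forest draws its own fresh set of uniform-random
negative sequences assigned a pseudo-count of 1e-10 (log10 target -10).
Hyperparameters (terminal node size, variables per split) are chosen by
grid search under class-balanced five-fold cross-validation scored by
Spearman rank correlation. Predictions are the median over the ensemble; a
calibrated threshold (the prediction for a known tight binder) turns them
into hit calls, from which hit-rate enrichment of a designed library over
naive replicate libraries is computed. The module also carries the two
affinity-calibration fits: the log-count vs IC50 line used to extrapolate
an IC50 bound, and the four-parameter-logistic dose-response fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.ensemble import RandomForestRegressor

from .codons import AA_ALPHABET, AA_INDEX
from .synthetic import DoseResponseCurve

__all__ = [
    "SurrogateEnsemble",
    "EnrichmentReport",
    "LineFit",
    "FourPLFit",
    "FitError",
    "encode",
    "decode",
    "encode_many",
    "random_sequences",
    "train",
    "predict",
    "calibrate_threshold",
    "classify",
    "enrichment",
    "fit_count_affinity_line",
    "fit_4pl",
    "DEFAULT_GRID",
]

NEGATIVE_PSEUDO_COUNT = 1e-10
NEGATIVE_TARGET = float(np.log10(NEGATIVE_PSEUDO_COUNT))  # -10
DEFAULT_GRID = ((3, 5, 9), (3, 7, 12))  # node sizes x variables per split


def encode(window_seq: str) -> np.ndarray:
    """One-hot feature vector (window_length * 20) for one window."""
    vec = np.zeros(len(window_seq) * 20)
    for i, aa in enumerate(window_seq):
        if aa not in AA_INDEX:
            raise ValueError(f"invalid residue {aa!r} in {window_seq!r}")
        vec[i * 20 + AA_INDEX[aa]] = 1.0
    return vec


def decode(vec: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    if len(vec) % 20 != 0:
        raise ValueError("vector length must be a multiple of 20")
    blocks = np.asarray(vec).reshape(-1, 20)
    if not np.allclose(blocks.sum(axis=1), 1.0):
        raise ValueError("not a valid one-hot encoding")
    return "".join(AA_ALPHABET[j] for j in blocks.argmax(axis=1))


def encode_many(sequences: list[str]) -> np.ndarray:
    return np.array([encode(s) for s in sequences])


def random_sequences(n: int, window_length: int, rng: np.random.Generator) -> list[str]:
    """Uniform-random windows over the 20 natural amino acids."""
    idx = rng.integers(0, 20, size=(n, window_length))
    aa = np.array(list(AA_ALPHABET), dtype="U1")[idx]
    return aa.view(f"U{window_length}").ravel().tolist()


@dataclass
class SurrogateEnsemble:
    """Bag of fitted forests plus encoding spec and calibrated threshold."""

    models: list[RandomForestRegressor]
    window_length: int
    node_size: int
    vars_per_split: int
    seed_base: int
    negative_pseudo_count: float = NEGATIVE_PSEUDO_COUNT
    threshold: float | None = None
    cv_table: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.models)


def _balanced_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle indices 0..n-1 into ``folds`` near-equal chunks."""
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def train(
    positives: list[tuple[str, float]],
    n_models: int = 100,
    folds: int = 5,
    grid: tuple[tuple[int, ...], tuple[int, ...]] = DEFAULT_GRID,
    seed: int = 0,
    n_trees: int = 100,
) -> SurrogateEnsemble:
    """Fit the surrogate ensemble on (window sequence, read count) positives.

    Targets are log10(count); every forest pairs the positives with a fresh
    equal-size draw of uniform-random negative sequences at target -10
    (log10 of the 1e-10 pseudo-count). The (node size, variables per split)
    pair is chosen by grid search maximizing the mean Spearman correlation
    under ``folds``-fold cross-validation with class-balanced folds; ties go
    to the first grid point in row-major order. A single-point grid skips no
    machinery but warns that there is nothing to search.
    """
    if len(positives) < folds:
        raise ValueError(f"need at least {folds} positives")
    node_sizes, mtries = grid
    if len(node_sizes) * len(mtries) == 1:
        warnings.warn("degenerate 1-point grid: fitting without search", stacklevel=2)
    rng = np.random.default_rng(seed)
    window_length = len(positives[0][0])

    pos_x = encode_many([s for s, _ in positives])
    pos_y = np.log10([c for _, c in positives])
    n = len(positives)

    # one negative draw shared across the CV search
    cv_neg = random_sequences(n, window_length, rng)
    neg_x = encode_many(cv_neg)
    neg_y = np.full(n, NEGATIVE_TARGET)
    pos_folds = _balanced_folds(n, folds, rng)
    neg_folds = _balanced_folds(n, folds, rng)

    cv_table: dict[tuple[int, int], float] = {}
    best: tuple[float, tuple[int, int]] | None = None
    for ns in node_sizes:
        for mtry in mtries:
            scores = []
            for f in range(folds):
                te_p, te_n = pos_folds[f], neg_folds[f]
                tr_p = np.setdiff1d(np.arange(n), te_p)
                tr_n = np.setdiff1d(np.arange(n), te_n)
                x_tr = np.vstack([pos_x[tr_p], neg_x[tr_n]])
                y_tr = np.concatenate([pos_y[tr_p], neg_y[tr_n]])
                x_te = np.vstack([pos_x[te_p], neg_x[te_n]])
                y_te = np.concatenate([pos_y[te_p], neg_y[te_n]])
                model = RandomForestRegressor(
                    n_estimators=n_trees,
                    min_samples_leaf=ns,
                    max_features=mtry,
                    random_state=int(rng.integers(2**31)),
                )
                model.fit(x_tr, y_tr)
                scores.append(_spearman(model.predict(x_te), y_te))
            mean = float(np.mean(scores))
            cv_table[(ns, mtry)] = mean
            if best is None or mean > best[0]:
                best = (mean, (ns, mtry))
    assert best is not None
    node_size, vars_per_split = best[1]

    seed_base = int(rng.integers(2**31))
    models = []
    for m in range(n_models):
        model_rng = np.random.default_rng(seed_base + m)
        neg = random_sequences(n, window_length, model_rng)
        x = np.vstack([pos_x, encode_many(neg)])
        y = np.concatenate([pos_y, np.full(n, NEGATIVE_TARGET)])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=node_size,
            max_features=vars_per_split,
            random_state=seed_base + m,
        )
        forest.fit(x, y)
        models.append(forest)
    return SurrogateEnsemble(
        models=models,
        window_length=window_length,
        node_size=node_size,
        vars_per_split=vars_per_split,
        seed_base=seed_base,
        cv_table=cv_table,
    )


def predict(ens: SurrogateEnsemble, sequences: list[str]) -> np.ndarray:
    """Median predicted log10 count across the ensemble, per sequence."""
    if not ens.models:
        raise RuntimeError("ensemble has no fitted models")
    x = encode_many(sequences)
    preds = np.stack([m.predict(x) for m in ens.models])
    return np.median(preds, axis=0)


def calibrate_threshold(ens: SurrogateEnsemble, reference_seq: str) -> float:
    """Set the hit threshold to the ensemble prediction for a reference binder."""
    th = float(predict(ens, [reference_seq])[0])
    ens.threshold = th
    return th


def classify(
    ens: SurrogateEnsemble, sequences: list[str], threshold: float | None = None
) -> np.ndarray:
    """Boolean hit calls: predicted log10 count >= threshold (inclusive)."""
    th = threshold if threshold is not None else ens.threshold
    if th is None:
        raise RuntimeError("threshold not calibrated")
    return predict(ens, sequences) >= th


@dataclass(frozen=True)
class EnrichmentReport:
    """Hit-rate comparison of designed strategy sets against naive replicates."""

    designed_fractions: dict[str, float]
    naive_fractions: tuple[float, ...]
    enrichment: dict[str, float]
    threshold: float
    naive_sd: float
    infinite: bool = False


def enrichment(
    ens: SurrogateEnsemble,
    designed: dict[str, list[str]],
    naive: list[list[str]],
    threshold: float | None = None,
) -> EnrichmentReport:
    """Per-strategy enrichment factor of designed hit rates over naive ones.

    Hit fraction of a set = (#predictions >= threshold) / set size;
    enrichment per strategy = designed fraction / mean naive fraction, so
    the factor is independent of library sizes. If no naive replicate has
    any hit, the factors are reported infinite and flagged.
    """
    th = threshold if threshold is not None else ens.threshold
    if th is None:
        raise RuntimeError("threshold not calibrated")
    naive_fracs = tuple(
        float(np.mean(predict(ens, reps) >= th)) for reps in naive
    )
    designed_fracs = {
        label: float(np.mean(predict(ens, seqs) >= th)) for label, seqs in designed.items()
    }
    mean_naive = float(np.mean(naive_fracs)) if naive_fracs else 0.0
    infinite = mean_naive == 0.0
    factors = {
        label: (float("inf") if infinite else frac / mean_naive)
        for label, frac in designed_fracs.items()
    }
    return EnrichmentReport(
        designed_fractions=designed_fracs,
        naive_fractions=naive_fracs,
        enrichment=factors,
        threshold=float(th),
        naive_sd=float(np.std(naive_fracs)) if naive_fracs else float("nan"),
        infinite=infinite,
    )


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class LineFit:
    """Least-squares line linking log10 read count to IC50."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    scale: str  # "log" (log10 IC50) or "linear"

    def extrapolate(self, log10_count: float) -> float:
        """IC50 implied by the line at the given log10 read count."""
        y = self.slope * log10_count + self.intercept
        return float(10.0**y) if self.scale == "log" else float(y)


def fit_count_affinity_line(
    points: list[tuple[float, float]], scale: str = "log"
) -> LineFit:
    """Fit IC50 against log10 read count by simple linear regression.

    ``points`` are (log10 count, IC50) pairs. With ``scale="log"`` (default,
    matching log-scaled dose-response plots) the response is log10(IC50);
    ``"linear"`` regresses the raw IC50. The Pearson correlation is computed
    on the fitted scale. ``extrapolate`` inverts the transform, giving the
    IC50 bound implied at any log count.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    ic50 = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise FitError("constant log-count values: line undefined")
    y = np.log10(ic50) if scale == "log" else ic50
    res = stats.linregress(x, y)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        scale=scale,
    )


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    residuals: np.ndarray

    def response_at(self, c: np.ndarray | float) -> np.ndarray | float:
        return _four_pl(np.asarray(c, dtype=float), self.bottom, self.top, self.hill, self.ic50)


def _four_pl(c: np.ndarray, bottom: float, top: float, hill: float, ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_4pl(curve: DoseResponseCurve) -> FourPLFit:
    """Nonlinear least-squares fit of the four-parameter logistic.

    response = bottom + (top - bottom) / (1 + (c/IC50)^hill), with IC50
    constrained positive. A flat response (no transition to fit) or
    optimizer failure raises :class:`FitError` carrying the residuals.
    """
    c = curve.concentrations
    y = curve.response
    if len(c) < 5:
        raise ValueError("need at least 5 concentration points")
    if np.ptp(y) < 1e-9:
        raise FitError("flat response: IC50 unidentifiable")
    mid = 0.5 * (y.max() + y.min())
    ic50_guess = float(c[np.argmin(np.abs(y - mid))])
    p0 = [float(y.min()), float(y.max()), 1.0, ic50_guess]
    bounds = ([-np.inf, -np.inf, -50.0, 1e-300], [np.inf, np.inf, 50.0, np.inf])
    try:
        popt, _ = optimize.curve_fit(_four_pl, c, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        resid = y - _four_pl(c, *p0)
        raise FitError(f"4PL fit did not converge: {exc}; residuals {resid}") from exc
    resid = y - _four_pl(c, *popt)
    return FourPLFit(
        bottom=float(popt[0]), top=float(popt[1]), hill=float(popt[2]),
        ic50=float(popt[3]), residuals=resid,
    )
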