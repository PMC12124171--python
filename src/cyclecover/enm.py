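"""Presence-background maximum-entropy niche models.

The model is the standard Gibbs density over background cells,
``P(cell) = exp(η(x)) / Z`` with ``η(x) = Σ_j β_j f_j(x)``, fitted by
maximizing the mean presence log-probability minus an L1 penalty
``Σ_j λ_j |β_j|`` (the maxnet formulation of MaxEnt).  Feature classes are
the classic L/Q/H/P/T transforms of min–max standardized covariates.
Candidate models (feature-class combination × regularization multiplier)
are scored by held-out AUC on a two-level spatial checkerboard partition
(four bins) that reduces spatial autocorrelation between training and
testing points, and the winner is refit on all data.  Continuous
suitability uses the cloglog transform; binary range maps come from the
threshold maximizing sensitivity + specificity (max SSS).

Penalties follow the Maxent convention λ_j = multiplier × s_class(j) ×
sd_j / √m (sd over background, m presences) with per-class base scalars
L/Q/P = 1.0, H = 0.5, T = 2.0.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid import ClimateStack, Grid
from .occurrences import Season, SeasonalOccurrenceSet

FEATURE_CLASS_PENALTY = {"L": 1.0, "Q": 1.0, "P": 1.0, "H": 0.5, "T": 2.0}
DEFAULT_COMBOS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")
DEFAULT_MULTIPLIERS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


class ConvergenceError(RuntimeError):
    """Raised when the penalized likelihood optimizer fails to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# -- configuration ---------------------------------------------------------

@dataclass(frozen=True)
class PredictorConfig:
    """Collinearity screen: drop layers until all pairwise |r| ≤ r_max."""

    r_max: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.r_max < 1):
            raise ValueError("r_max must be in (0, 1)")


@dataclass(frozen=True)
class BackgroundConfig:
    """Background sampling: up to ``n_background`` cells drawn uniformly from
    the valid cells within ``buffer_km`` of any occurrence (fewer when the
    buffered region is small).  Presence cells are excluded by default."""

    n_background: int = 10_000
    buffer_km: float = 100.0
    seed: int = 0
    exclude_presences: bool = True

    def __post_init__(self) -> None:
        if self.n_background <= 0 or self.buffer_km <= 0:
            raise ValueError("n_background and buffer_km must be positive")


@dataclass(frozen=True)
class ModelSearchConfig:
    feature_class_combos: tuple[str, ...] = DEFAULT_COMBOS
    regularization_multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    n_hinge_knots: int = 10
    n_threshold_knots: int = 10
    checkerboard_factors: tuple[int, int] = (2, 2)
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not self.feature_class_combos:
            raise ValueError("need at least one feature-class combination")
        if any(m <= 0 for m in self.regularization_multipliers):
            raise ValueError("regularization multipliers must be positive")


# -- collinearity filter ---------------------------------------------------

def collinearity_filter(stack: ClimateStack, config: PredictorConfig | None = None
                        ) -> list[str]:
    """Greedy removal of collinear layers.

    While any pair of retained layers has |Pearson r| over the valid cells
    above ``r_max``, drop — from the worst-offending pair — the layer with
    the larger mean |r| against all other retained layers (ties broken by
    layer-name order, the later name dropped).
    """
    config = config or PredictorConfig()
    names = stack.names
    if len(names) < 2:
        raise ValueError("collinearity filter needs at least two layers")
    X = np.column_stack([stack.layers[n][stack.mask] for n in names])
    corr = np.abs(np.corrcoef(X, rowvar=False))
    retained = list(range(len(names)))
    while True:
        sub = corr[np.ix_(retained, retained)]
        np.fill_diagonal(sub, 0.0)
        worst = sub.max()
        if worst <= config.r_max or len(retained) == 1:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i].sum() / (len(retained) - 1)
        mean_j = sub[j].sum() / (len(retained) - 1)
        # drop the layer more correlated with everything else; tie -> later name
        drop_local = j if (mean_j > mean_i or np.isclose(mean_i, mean_j)) else i
        retained.pop(drop_local)
    return [names[i] for i in retained]


# -- background sampling ---------------------------------------------------

def sample_background(stack: ClimateStack, occurrence_cells: np.ndarray,
                      config: BackgroundConfig | None = None) -> np.ndarray:
    """Sample background cells within a distance buffer of the occurrences.

    Candidates are valid cells whose center lies within ``buffer_km`` of any
    occurrence cell center; ``min(n_background, n_candidates)`` are drawn
    uniformly without replacement with the configured seed, so species with
    small buffered regions get fewer background points.
    """
    config = config or BackgroundConfig()
    occurrence_cells = np.asarray(occurrence_cells)
    if len(occurrence_cells) == 0:
        raise ValueError("need at least one occurrence cell")
    grid = stack.grid
    ox, oy = grid.cell_center(occurrence_cells[:, 0], occurrence_cells[:, 1])
    tree = cKDTree(np.column_stack([ox, oy]))
    cand = stack.valid_cells()
    cx, cy = grid.cell_center(cand[:, 0], cand[:, 1])
    dist, _ = tree.query(np.column_stack([cx, cy]))
    keep = dist <= config.buffer_km
    if config.exclude_presences:
        occ_flat = set(map(tuple, occurrence_cells))
        keep &= np.array([tuple(c) not in occ_flat for c in cand])
    cand = cand[keep]
    if len(cand) == 0:
        raise ValueError("no background candidates within the buffer")
    rng = np.random.default_rng(config.seed)
    n = min(config.n_background, len(cand))
    idx = rng.choice(len(cand), size=n, replace=False)
    return cand[np.sort(idx)]


# -- feature expansion -----------------------------------------------------

@dataclass
class FeatureExpansion:
    """Rebuildable description of the feature transform.

    Covariates are min–max standardized to [0,1] using the training
    background bounds (values outside are clamped and audited); classes:
    L identity, Q squares, P pairwise products, H forward/reverse hinges at
    interior knots, T step indicators at interior knots.
    """

    classes: str
    covariate_names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    hinge_knots: np.ndarray      # interior knots in (0,1)
    threshold_knots: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    feature_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self._build_description()

    def _build_description(self) -> None:
        names, tags = [], []
        covs = self.covariate_names
        for cls in self.classes:
            if cls == "L":
                names += covs
                tags += ["L"] * len(covs)
            elif cls == "Q":
                names += [f"{c}^2" for c in covs]
                tags += ["Q"] * len(covs)
            elif cls == "H":
                for c in covs:
                    for t in self.hinge_knots:
                        names += [f"hingeF({c},{t:.4f})", f"hingeR({c},{t:.4f})"]
                        tags += ["H", "H"]
            elif cls == "P":
                for a, b in itertools.combinations(covs, 2):
                    names.append(f"{a}*{b}")
                    tags.append("P")
            elif cls == "T":
                for c in covs:
                    for t in self.threshold_knots:
                        names.append(f"step({c},{t:.4f})")
                        tags.append("T")
            else:
                raise ValueError(f"unknown feature class {cls!r}")
        self.feature_names, self.feature_classes = names, tags

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, int]:
        """Feature matrix for raw covariates; returns (features, n_clamped)."""
        X = np.asarray(X, dtype=float)
        Z = (X - self.lower) / (self.upper - self.lower)
        n_clamped = int(((Z < 0) | (Z > 1)).sum())
        Z = np.clip(Z, 0.0, 1.0)
        cols: list[np.ndarray] = []
        k = Z.shape[1]
        for cls in self.classes:
            if cls == "L":
                cols.append(Z)
            elif cls == "Q":
                cols.append(Z**2)
            elif cls == "H":
                for j in range(k):
                    for t in self.hinge_knots:
                        cols.append(np.column_stack([
                            np.maximum(0.0, Z[:, j] - t) / (1.0 - t),
                            np.maximum(0.0, t - Z[:, j]) / t,
                        ]))
            elif cls == "P":
                for a, b in itertools.combinations(range(k), 2):
                    cols.append((Z[:, a] * Z[:, b])[:, None])
            elif cls == "T":
                for j in range(k):
                    for t in self.threshold_knots:
                        cols.append((Z[:, j] > t).astype(float)[:, None])
        F = np.hstack([np.atleast_2d(c) if c.ndim == 2 else c[:, None] for c in cols])
        return F, n_clamped

    def to_dict(self) -> dict:
        return {"classes": self.classes, "covariate_names": self.covariate_names,
                "lower": self.lower.tolist(), "upper": self.upper.tolist(),
                "hinge_knots": self.hinge_knots.tolist(),
                "threshold_knots": self.threshold_knots.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        return cls(classes=d["classes"], covariate_names=list(d["covariate_names"]),
                   lower=np.asarray(d["lower"]), upper=np.asarray(d["upper"]),
                   hinge_knots=np.asarray(d["hinge_knots"]),
                   threshold_knots=np.asarray(d["threshold_knots"]))


def build_features(X: np.ndarray, classes: str, covariate_names: list[str] | None = None,
                   n_hinge_knots: int = 10, n_threshold_knots: int = 10,
                   bounds: tuple[np.ndarray, np.ndarray] | None = None,
                   ) -> tuple[np.ndarray, FeatureExpansion]:
    """Build the feature matrix for (typically background) covariates.

    ``bounds`` defaults to the per-covariate min/max of ``X`` itself;
    a degenerate covariate (min == max) is an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = X.shape[1]
    covariate_names = covariate_names or [f"x{j}" for j in range(k)]
    lower, upper = bounds if bounds is not None else (X.min(axis=0), X.max(axis=0))
    if np.any(upper <= lower):
        bad = [covariate_names[j] for j in np.nonzero(upper <= lower)[0]]
        raise ValueError(f"degenerate covariates (min == max): {bad}")
    hk = np.arange(1, n_hinge_knots + 1) / (n_hinge_knots + 1)
    tk = np.arange(1, n_threshold_knots + 1) / (n_threshold_knots + 1)
    exp = FeatureExpansion(classes=classes, covariate_names=list(covariate_names),
                           lower=np.asarray(lower, dtype=float),
                           upper=np.asarray(upper, dtype=float),
                           hinge_knots=hk, threshold_knots=tk)
    F, _ = exp.transform(X)
    return F, exp


# -- penalized Gibbs likelihood --------------------------------------------

@dataclass
class MaxentFit:
    beta: np.ndarray
    log_z: float
    objective: float
    n_iter: int
    lambdas: np.ndarray


def maxent_objective(beta: np.ndarray, F_presence: np.ndarray, F_background: np.ndarray,
                     lambdas: np.ndarray) -> float:
    """Penalized negative mean presence log-likelihood (to be minimized)."""
    beta = np.asarray(beta, dtype=float)
    return float(-F_presence.mean(axis=0) @ beta + logsumexp(F_background @ beta)
                 + lambdas @ np.abs(beta))


def feature_penalties(F_background: np.ndarray, feature_classes: list[str],
                      multiplier: float, n_presences: int) -> np.ndarray:
    sd = F_background.std(axis=0)
    base = np.array([FEATURE_CLASS_PENALTY[c] for c in feature_classes])
    return multiplier * base * sd / np.sqrt(n_presences)


def fit_maxent(F_presence: np.ndarray, F_background: np.ndarray,
               multiplier: float = 1.0, feature_classes: list[str] | None = None,
               tol: float = 1e-6, max_iter: int = 10_000) -> MaxentFit:
    """Fit the L1-penalized Gibbs model by FISTA with backtracking.

    Minimizes −mean_presence(η) + log Σ_background e^η + Σ λ_j|β_j| with
    λ_j = multiplier × s_class × sd_j/√m.  Features constant over the
    background are excluded (β pinned at 0): their penalty vanishes and the
    likelihood can be unbounded along them.  Raises
    :class:`ConvergenceError` when the objective change has not dropped
    below ``tol`` within ``max_iter`` iterations.
    """
    Fp = np.atleast_2d(np.asarray(F_presence, dtype=float))
    Fb = np.atleast_2d(np.asarray(F_background, dtype=float))
    if len(Fp) == 0 or len(Fb) == 0:
        raise ValueError("need at least one presence and one background point")
    k = Fb.shape[1]
    feature_classes = feature_classes or ["L"] * k
    lam_full = feature_penalties(Fb, feature_classes, multiplier, len(Fp))
    active = Fb.std(axis=0) > 1e-12
    Fp_a, Fb_a, lam = Fp[:, active], Fb[:, active], lam_full[active]

    a = Fp_a.mean(axis=0)
    x = np.zeros(Fb_a.shape[1])
    y = x.copy()
    t_mom = 1.0
    step = 1.0

    def smooth(beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = Fb_a @ beta
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        return float(lz - a @ beta), -a + Fb_a.T @ q

    obj_prev = smooth(x)[0]  # beta = 0 -> no penalty term
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g_y, grad = smooth(y)
        while True:
            x_new = np.sign(y - step * grad) * np.maximum(
                np.abs(y - step * grad) - step * lam, 0.0)
            d = x_new - y
            g_new = smooth(x_new)[0]
            if g_new <= g_y + grad @ d + (d @ d) / (2 * step) + 1e-12:
                break
            step *= 0.5
        obj = g_new + lam @ np.abs(x_new)
        if obj > obj_prev:  # restart momentum on non-monotone step
            y = x.copy()
            t_mom = 1.0
            continue
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
        y = x_new + ((t_mom - 1) / t_new) * (x_new - x)
        x, t_mom = x_new, t_new
        if abs(obj_prev - obj) < tol:
            obj_prev = obj
            break
        obj_prev = obj
        step *= 1.2
    else:
        raise ConvergenceError(
            "maxent fit did not converge",
            {"n_iter": n_iter, "objective": obj_prev, "tol": tol,
             "n_features": int(active.sum())})

    beta = np.zeros(k)
    beta[active] = x
    return MaxentFit(beta=beta, log_z=float(logsumexp(Fb @ beta)),
                     objective=obj_prev, n_iter=n_iter, lambdas=lam_full)


# -- spatial partitioning and evaluation -----------------------------------

def checkerboard2_partition(cells: np.ndarray, grid: Grid,
                            factors: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Two-level checkerboard fold labels in {1,2,3,4} per (row, col) cell.

    The fine parity uses blocks of ``f1 × f1`` cells, the coarse parity
    blocks of ``f1·f2 × f1·f2``; the label depends only on the cell's
    position, so nearby cells share folds and spatial autocorrelation
    between train and test bins is reduced.
    """
    f1, f2 = factors
    if f1 < 2 or f2 < 2:
        raise ValueError("aggregation factors must be >= 2")
    if grid.nrows < f1 * f2 or grid.ncols < f1 * f2:
        raise ValueError("grid smaller than one coarse checkerboard block")
    cells = np.asarray(cells)
    r, c = cells[:, 0], cells[:, 1]
    fine = (r // f1 + c // f1) % 2
    coarse = (r // (f1 * f2) + c // (f1 * f2)) % 2
    return (1 + fine + 2 * coarse).astype(int)


def evaluate_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(presence score > background score), ties ½."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


# -- thresholding ----------------------------------------------------------

def max_sss_threshold(presence_scores: np.ndarray, background_scores: np.ndarray
                      ) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity over presence scores.

    Candidates are the unique presence scores τ, evaluated with the rule
    "score ≥ τ ⇒ presence" (sensitivity = fraction of presences ≥ τ,
    specificity = fraction of background < τ); ties take the smallest τ
    (maximal sensitivity).  The returned threshold τ′ is the largest
    observed score strictly below the winning τ (or the adjacent float when
    none exists) so that the conventional strict rule "value > τ′ ⇒
    presence" reproduces the same partition.  Returns (τ′, sensitivity,
    specificity).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    all_scores = np.concatenate([p, b])
    if np.unique(all_scores).size < 2:
        raise ValueError("all scores identical: no discriminating threshold")
    cand = np.unique(p)  # ascending
    sens = 1.0 - (np.searchsorted(np.sort(p), cand, side="left") / len(p))
    spec = np.searchsorted(np.sort(b), cand, side="left") / len(b)
    best = int(np.argmax(sens + spec))  # argmax returns the first (smallest τ) tie
    tau = cand[best]
    below = all_scores[all_scores < tau]
    stored = float(below.max()) if len(below) else float(np.nextafter(tau, -np.inf))
    return stored, float(sens[best]), float(spec[best])


def binarize(suitability_map: np.ndarray, presence_scores: np.ndarray,
             background_scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Binary range map via the max-SSS threshold ("value > τ′ ⇒ presence")."""
    stored, _, _ = max_sss_threshold(presence_scores, background_scores)
    return np.asarray(suitability_map) > stored, stored


# -- model container, selection and prediction -----------------------------

@dataclass
class NicheModel:
    """A fitted, selected and thresholded species–season niche model."""

    species: str
    season: Season
    expansion: FeatureExpansion
    beta: np.ndarray
    log_z: float
    entropy: float
    reg_multiplier: float
    fold_aucs: list[float]
    mean_test_auc: float
    threshold: float
    threshold_sensitivity: float
    threshold_specificity: float

    @property
    def feature_class_combo(self) -> str:
        return self.expansion.classes

    def linear_predictor(self, X_raw: np.ndarray) -> tuple[np.ndarray, int]:
        F, n_clamped = self.expansion.transform(X_raw)
        return F @ self.beta, n_clamped

    def to_json(self, path) -> None:
        d = {"species": self.species, "season": self.season.value,
             "expansion": self.expansion.to_dict(), "beta": self.beta.tolist(),
             "log_z": self.log_z, "entropy": self.entropy,
             "reg_multiplier": self.reg_multiplier, "fold_aucs": self.fold_aucs,
             "mean_test_auc": self.mean_test_auc, "threshold": self.threshold,
             "threshold_sensitivity": self.threshold_sensitivity,
             "threshold_specificity": self.threshold_specificity}
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "NicheModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(species=d["species"], season=Season(d["season"]),
                   expansion=FeatureExpansion.from_dict(d["expansion"]),
                   beta=np.asarray(d["beta"]), log_z=d["log_z"], entropy=d["entropy"],
                   reg_multiplier=d["reg_multiplier"], fold_aucs=list(d["fold_aucs"]),
                   mean_test_auc=d["mean_test_auc"], threshold=d["threshold"],
                   threshold_sensitivity=d["threshold_sensitivity"],
                   threshold_specificity=d["threshold_specificity"])


def _cloglog(eta: np.ndarray, entropy: float) -> np.ndarray:
    return -np.expm1(-np.exp(eta - entropy))


def gibbs_entropy(eta_background: np.ndarray) -> float:
    """Entropy of the normalized Gibbs distribution over background cells."""
    eta = np.asarray(eta_background, dtype=float)
    log_q = eta - logsumexp(eta)
    return float(-(np.exp(log_q) * log_q).sum())


def select_and_fit(occset: SeasonalOccurrenceSet, stack: ClimateStack,
                   background_config: BackgroundConfig | None = None,
                   search_config: ModelSearchConfig | None = None) -> NicheModel:
    """Cross-validated candidate search, refit, and thresholding.

    Every (feature combo × multiplier) candidate is scored by its mean
    held-out AUC over the four checkerboard bins (folds with no held-out
    presences or background are skipped); the best candidate — ties broken
    by fewer feature classes, then larger multiplier, preferring the
    smoother model — is refit on all data and thresholded by max SSS.
    """
    background_config = background_config or BackgroundConfig()
    search_config = search_config or ModelSearchConfig()
    grid = stack.grid
    pres_cells = np.asarray(occset.cells)
    bg_cells = sample_background(stack, pres_cells, background_config)
    Xp = stack.values_at(pres_cells)
    Xb = stack.values_at(bg_cells)
    fold_p = checkerboard2_partition(pres_cells, grid, search_config.checkerboard_factors)
    fold_b = checkerboard2_partition(bg_cells, grid, search_config.checkerboard_factors)

    results = []
    for combo in search_config.feature_class_combos:
        for mult in search_config.regularization_multipliers:
            aucs = []
            for f in (1, 2, 3, 4):
                tr_p, te_p = Xp[fold_p != f], Xp[fold_p == f]
                tr_b, te_b = Xb[fold_b != f], Xb[fold_b == f]
                if len(te_p) == 0 or len(te_b) == 0 or len(tr_p) == 0 or len(tr_b) == 0:
                    continue
                F_trb, exp_ = build_features(
                    tr_b, combo, stack.names,
                    search_config.n_hinge_knots, search_config.n_threshold_knots)
                F_trp, _ = exp_.transform(tr_p)
                fit = fit_maxent(F_trp, F_trb, mult, exp_.feature_classes,
                                 search_config.tol, search_config.max_iter)
                eta_p = exp_.transform(te_p)[0] @ fit.beta
                eta_b = exp_.transform(te_b)[0] @ fit.beta
                aucs.append(evaluate_auc(eta_p, eta_b))
            if not aucs:
                raise ValueError("no usable cross-validation fold "
                                 "(every bin lacks presences or background)")
            results.append((combo, mult, aucs, float(np.mean(aucs))))

    # maximize AUC; ties -> fewer feature classes, then larger multiplier
    combo, mult, fold_aucs, mean_auc = max(
        results, key=lambda r: (r[3], -len(r[0]), r[1]))

    F_b, expansion = build_features(Xb, combo, stack.names,
                                    search_config.n_hinge_knots,
                                    search_config.n_threshold_knots)
    F_p, _ = expansion.transform(Xp)
    fit = fit_maxent(F_p, F_b, mult, expansion.feature_classes,
                     search_config.tol, search_config.max_iter)
    eta_b = F_b @ fit.beta
    entropy = gibbs_entropy(eta_b)
    s_p = _cloglog(F_p @ fit.beta, entropy)
    s_b = _cloglog(eta_b, entropy)
    stored, sens, spec = max_sss_threshold(s_p, s_b)
    return NicheModel(species=occset.species, season=occset.season,
                      expansion=expansion, beta=fit.beta, log_z=fit.log_z,
                      entropy=entropy, reg_multiplier=mult,
                      fold_aucs=[float(a) for a in fold_aucs], mean_test_auc=mean_auc,
                      threshold=stored, threshold_sensitivity=sens,
                      threshold_specificity=spec)


def predict_suitability(model: NicheModel, stack: ClimateStack,
                        return_clamp_audit: bool = False):
    """Continuous cloglog suitability map in (0,1); NaN outside the mask.

    Covariates outside the training background range are clamped to the
    stored bounds; pass ``return_clamp_audit=True`` to also get the count of
    clamped covariate values.
    """
    cells = stack.valid_cells()
    X = stack.values_at(cells, model.expansion.covariate_names)
    eta, n_clamped = model.linear_predictor(X)
    out = np.full(stack.grid.shape, np.nan)
    out[cells[:, 0], cells[:, 1]] = _cloglog(eta, model.entropy)
    return (out, n_clamped) if return_clamp_audit else out


def binary_range_map(model: NicheModel, stack: ClimateStack) -> np.ndarray:
    """Binary range map from the stored max-SSS threshold (strict >)."""
    suit = predict_suitability(model, stack)
    return np.where(np.isnan(suit), False, suit > model.threshold)
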