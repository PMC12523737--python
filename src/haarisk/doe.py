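"""Two-level factorial screening and multi-response desirability optimization.

The screening side estimates main effects and interactions of a full 2^k
design by the classical contrast formula

    effect(term) = mean(y | contrast = +1) − mean(y | contrast = −1)
                 = (2 / N) Σ contrast · y

and flags significance either by Lenth's pseudo-standard-error (PSE) when
the factorial runs are unreplicated, or by center-point pure error when at
least two center runs are available — the data behind a Pareto chart of
standardized effects.

The optimization side fits a per-response surrogate (deterministic full
quadratic by default, or a seeded single-hidden-layer network) on coded
runs, then maximizes the Derringer–Suich overall desirability — the
geometric mean of per-response desirability transforms — on a deterministic
grid over the coded hypercube.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InsufficientDesignError

__all__ = [
    "Factor",
    "FactorialDesign",
    "EffectEntry",
    "EffectTable",
    "Goal",
    "ResponseGoal",
    "DesirabilitySpec",
    "build_full_factorial",
    "build_face_centered",
    "FactorialEffects",
    "estimate_effects",
    "desirability_single",
    "desirability",
    "DesirabilityOptimizer",
    "optimize_conditions",
]


@dataclass(frozen=True)
class Factor:
    name: str
    low: float
    high: float
    units: str = ""

    def decode(self, coded: float) -> float:
        """Coded level in [-1, 1] to natural units."""
        return (self.low + self.high) / 2 + coded * (self.high - self.low) / 2


@dataclass
class FactorialDesign:
    """Coded 2^k design, optionally with center points, plus responses.

    ``runs`` is (n_runs, k) with factorial rows in {−1, +1} and center rows
    all-zero; ``responses`` maps response name → one value per run.
    """

    factors: list[Factor]
    runs: np.ndarray
    responses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=float)
        k = len(self.factors)
        fact = self.runs[~self.is_center]
        expected = {tuple(row) for row in itertools.product((-1.0, 1.0), repeat=k)}
        got = [tuple(row) for row in fact]
        if sorted(got) != sorted(expected):
            raise InsufficientDesignError(
                f"factorial rows must be all 2^{k} sign combinations exactly once"
            )
        for name, y in self.responses.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (self.runs.shape[0],):
                raise InsufficientDesignError(
                    f"response {name!r}: need one value per run "
                    f"({self.runs.shape[0]}), got {y.shape}"
                )
            self.responses[name] = y

    @property
    def is_center(self) -> np.ndarray:
        return np.all(self.runs == 0, axis=1)

    @property
    def k(self) -> int:
        return len(self.factors)

    def response(self, name: str) -> np.ndarray:
        try:
            return self.responses[name]
        except KeyError:
            raise ComputationError(
                f"design has no response {name!r}; have {sorted(self.responses)}"
            ) from None


def build_full_factorial(factors: list[Factor], n_center: int = 0) -> FactorialDesign:
    """Standard-order full 2^k design with *n_center* appended center rows."""
    k = len(factors)
    if not 2 <= k <= 6:
        raise InsufficientDesignError(f"number of factors must be in [2, 6], got {k}")
    if n_center < 0:
        raise InsufficientDesignError("n_center must be >= 0")
    # standard (Yates) order: first factor alternates fastest
    rows = []
    for i in range(2**k):
        rows.append([1.0 if (i >> j) & 1 else -1.0 for j in range(k)])
    runs = np.array(rows, dtype=float)
    if n_center:
        runs = np.vstack([runs, np.zeros((n_center, k))])
    return FactorialDesign(list(factors), runs)


def build_face_centered(factors: list[Factor], n_center: int = 3) -> np.ndarray:
    """Face-centered 3-level composite layout: 2^k cube + 2k axial + centers.

    Returns the coded run matrix only (it is not a plain 2^k design).
    """
    k = len(factors)
    cube = np.array(
        list(itertools.product((-1.0, 1.0), repeat=k)), dtype=float
    )
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -1.0
        axial[2 * j + 1, j] = 1.0
    center = np.zeros((n_center, k))
    return np.vstack([cube, axial, center])


# ---------------------------------------------------------------------------
# effect estimation


@dataclass(frozen=True)
class EffectEntry:
    term: str
    effect: float
    standardized: float
    significant: bool


@dataclass(frozen=True)
class EffectTable:
    entries: tuple[EffectEntry, ...]
    pse: float
    margin_of_error: float
    method: str  # "lenth" or "center_pure_error"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": e.term,
                    "effect": e.effect,
                    "standardized_effect": e.standardized,
                    "margin": self.margin_of_error,
                    "significant": e.significant,
                }
                for e in self.entries
            ]
        )


def _term_labels_and_columns(design: FactorialDesign) -> tuple[list[str], np.ndarray]:
    """All 2^k − 1 contrast columns over the factorial rows, mains first."""
    fact = design.runs[~design.is_center]
    names = [f.name for f in design.factors]
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for order in range(1, design.k + 1):
        for combo in itertools.combinations(range(design.k), order):
            labels.append(":".join(names[j] for j in combo))
            cols.append(np.prod(fact[:, list(combo)], axis=1))
    return labels, np.column_stack(cols)


def lenth_pse(effects: np.ndarray) -> float:
    """Lenth's pseudo-standard-error of a set of unreplicated contrasts.

    s0 = 1.5 · median|c|; PSE = 1.5 · median of |c| restricted to
    |c| < 2.5 s0.
    """
    abs_eff = np.abs(np.asarray(effects, dtype=float))
    s0 = 1.5 * float(np.median(abs_eff))
    trimmed = abs_eff[abs_eff < 2.5 * s0]
    if trimmed.size == 0:
        return 0.0
    return 1.5 * float(np.median(trimmed))


class FactorialEffects:
    """Effect/Pareto analysis of a full 2^k design, sklearn style.

    Parameters
    ----------
    alpha : float
        Two-sided significance level for the margin of error.

    Attributes (after :meth:`fit`)
    ------------------------------
    effects_ : dict term -> effect value
    pse_ : float, the effect standard error used (Lenth PSE or pure-error SE)
    margin_ : float, |effect| threshold for significance
    table_ : EffectTable sorted by |standardized effect| descending
    """

    def __init__(self, alpha: float = 0.05) -> None:
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha}

    def set_params(self, **params) -> "FactorialEffects":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, design: FactorialDesign, response: str) -> "FactorialEffects":
        y_all = design.response(response)
        center_mask = design.is_center
        y = y_all[~center_mask]
        labels, cols = _term_labels_and_columns(design)
        n = y.size
        effects = (2.0 / n) * (cols.T @ y)

        n_center = int(center_mask.sum())
        if n_center >= 2:
            s_pe = float(np.std(y_all[center_mask], ddof=1))
            se = 2.0 * s_pe / math.sqrt(n)
            df = n_center - 1
            method = "center_pure_error"
        else:
            se = lenth_pse(effects)
            df = len(effects) / 3.0  # Lenth's nominal degrees of freedom m/3
            method = "lenth"
        margin = float(stats.t.ppf(1 - self.alpha / 2, df) * se) if se > 0 else 0.0

        entries = []
        for term, eff in zip(labels, effects):
            std = eff / se if se > 0 else math.inf if eff != 0 else 0.0
            entries.append(
                EffectEntry(
                    term=term,
                    effect=float(eff),
                    standardized=float(std),
                    significant=bool(se > 0 and abs(eff) > margin),
                )
            )
        entries.sort(key=lambda e: (-abs(e.standardized), e.term))

        self.effects_ = {term: float(eff) for term, eff in zip(labels, effects)}
        self.pse_ = float(se)
        self.margin_ = margin
        self.table_ = EffectTable(tuple(entries), float(se), margin, method)
        return self


def estimate_effects(
    design: FactorialDesign, response: str, alpha: float = 0.05
) -> EffectTable:
    """Ranked (Pareto) effect table for one response of a full 2^k design."""
    return FactorialEffects(alpha=alpha).fit(design, response).table_


# ---------------------------------------------------------------------------
# desirability


class Goal(str, enum.Enum):
    MAXIMIZE = "maximize"
    MINIMIZE = "minimize"
    TARGET = "target"


@dataclass(frozen=True)
class ResponseGoal:
    """Derringer–Suich desirability transform for one response."""

    goal: Goal
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ComputationError(
                f"desirability bounds need lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.weight <= 0:
            raise ComputationError("desirability weight must be > 0")
        if self.goal is Goal.TARGET:
            if self.target is None or not self.lower <= self.target <= self.upper:
                raise ComputationError(
                    "target goal needs a target inside [lower, upper]"
                )


DesirabilitySpec = dict[str, ResponseGoal]


def desirability_single(y: float, goal: ResponseGoal) -> float:
    """Per-response desirability d(y) ∈ [0, 1]."""
    L, U, s = goal.lower, goal.upper, goal.weight
    if goal.goal is Goal.MAXIMIZE:
        if y <= L:
            return 0.0
        if y >= U:
            return 1.0
        return ((y - L) / (U - L)) ** s
    if goal.goal is Goal.MINIMIZE:
        if y >= U:
            return 0.0
        if y <= L:
            return 1.0
        return ((U - y) / (U - L)) ** s
    T = goal.target
    if y <= L or y >= U:
        return 1.0 if y == T else 0.0
    if y == T:
        return 1.0
    if y < T:
        return ((y - L) / (T - L)) ** s
    return ((U - y) / (U - T)) ** s


def _desirability_array(values: np.ndarray, goal: ResponseGoal) -> np.ndarray:
    """Vectorized per-response desirability."""
    y = np.asarray(values, dtype=float)
    L, U, s = goal.lower, goal.upper, goal.weight
    if goal.goal is Goal.MAXIMIZE:
        ramp = np.clip((y - L) / (U - L), 0.0, 1.0) ** s
        return ramp
    if goal.goal is Goal.MINIMIZE:
        return np.clip((U - y) / (U - L), 0.0, 1.0) ** s
    T = goal.target
    left = np.clip((y - L) / (T - L), 0.0, None) if T > L else (y >= T).astype(float)
    right = np.clip((U - y) / (U - T), 0.0, None) if U > T else (y <= T).astype(float)
    d = np.where(y < T, left, right) ** s
    return np.clip(d, 0.0, 1.0)


def desirability(responses: dict[str, float], spec: DesirabilitySpec) -> float:
    """Overall desirability: geometric mean of the per-response transforms."""
    if not spec:
        raise ComputationError("empty desirability spec")
    ds = []
    for name, goal in spec.items():
        if name not in responses:
            raise ComputationError(f"response {name!r} missing for desirability spec")
        ds.append(desirability_single(responses[name], goal))
    if any(d == 0.0 for d in ds):
        return 0.0
    return float(np.exp(np.mean(np.log(ds))))


# ---------------------------------------------------------------------------
# surrogate optimization


def _quadratic_basis(X: np.ndarray) -> np.ndarray:
    """[1, x_i, x_i x_j (i<j), x_i^2] feature matrix."""
    n, k = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, j] for j in range(k))
    for i, j in itertools.combinations(range(k), 2):
        cols.append(X[:, i] * X[:, j])
    cols.extend(X[:, j] ** 2 for j in range(k))
    return np.column_stack(cols)


class _QuadraticSurrogate:
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_QuadraticSurrogate":
        B = _quadratic_basis(X)
        if X.shape[0] < B.shape[1]:
            raise InsufficientDesignError(
                f"quadratic surrogate needs >= {B.shape[1]} runs, got {X.shape[0]}"
            )
        self.coef_, *_ = np.linalg.lstsq(B, y, rcond=None)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _quadratic_basis(X) @ self.coef_


class DesirabilityOptimizer:
    """Surrogate-based multi-response optimizer over the coded hypercube.

    Fits one surrogate per response on coded runs and maximizes overall
    desirability by an exhaustive deterministic grid search (first-occurrence
    tie-break), mirroring the screen-then-optimize workflow of factorial
    method development.

    Parameters
    ----------
    surrogate : {"quadratic", "small_network"}
        ``quadratic`` — full second-order polynomial by least squares
        (deterministic); ``small_network`` — single-hidden-layer perceptron
        (8 tanh units, L-BFGS, seeded).
    resolution : int
        Grid points per factor over [-1, 1].
    seed : int or None
        Random state of the network surrogate; ignored for the quadratic.
    """

    def __init__(
        self,
        surrogate: str = "quadratic",
        resolution: int = 41,
        seed: int | None = 0,
    ) -> None:
        self.surrogate = surrogate
        self.resolution = resolution
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "surrogate": self.surrogate,
            "resolution": self.resolution,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "DesirabilityOptimizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _make_surrogate(self):
        if self.surrogate == "quadratic":
            return _QuadraticSurrogate()
        if self.surrogate == "small_network":
            from sklearn.neural_network import MLPRegressor

            return MLPRegressor(
                hidden_layer_sizes=(8,),
                activation="tanh",
                solver="lbfgs",
                max_iter=5000,
                random_state=self.seed,
            )
        raise ValueError(f"unknown surrogate {self.surrogate!r}")

    def fit(
        self, X: np.ndarray, responses: dict[str, np.ndarray] | pd.DataFrame
    ) -> "DesirabilityOptimizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InsufficientDesignError("X must be a 2-D coded run matrix")
        if isinstance(responses, pd.DataFrame):
            responses = {c: responses[c].to_numpy() for c in responses.columns}
        self.models_ = {}
        for name, y in responses.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (X.shape[0],):
                raise InsufficientDesignError(
                    f"response {name!r}: need one value per run"
                )
            self.models_[name] = self._make_surrogate().fit(X, y)
        self.n_factors_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> pd.DataFrame:
        """Surrogate predictions for each response at coded settings *X*."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return pd.DataFrame(
            {name: model.predict(X) for name, model in self.models_.items()}
        )

    def optimize(
        self, spec: DesirabilitySpec, chunk: int = 200_000
    ) -> tuple[np.ndarray, dict[str, float], float]:
        """Maximize overall desirability on the grid.

        Returns (coded optimum (k,), predicted responses there, D at optimum).
        """
        self._check_fitted()
        for name in spec:
            if name not in self.models_:
                raise ComputationError(f"no surrogate for response {name!r}")
        axis = np.linspace(-1.0, 1.0, self.resolution)
        k = self.n_factors_
        total = self.resolution**k
        best_D = -1.0
        best_x: np.ndarray | None = None
        for start in range(0, total, chunk):
            idx = np.arange(start, min(start + chunk, total))
            multi = np.stack(
                np.unravel_index(idx, (self.resolution,) * k), axis=1
            )
            block = axis[multi]
            log_d = np.zeros(block.shape[0])
            dead = np.zeros(block.shape[0], dtype=bool)
            for name, goal in spec.items():
                d = _desirability_array(self.models_[name].predict(block), goal)
                dead |= d == 0.0
                with np.errstate(divide="ignore"):
                    log_d += np.where(d > 0, np.log(np.maximum(d, 1e-300)), 0.0)
            D = np.where(dead, 0.0, np.exp(log_d / len(spec)))
            i = int(np.argmax(D))
            if D[i] > best_D:
                best_D = float(D[i])
                best_x = block[i].copy()
        assert best_x is not None
        predicted = {
            name: float(model.predict(best_x[None, :])[0])
            for name, model in self.models_.items()
        }
        return best_x, predicted, best_D

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise ComputationError("DesirabilityOptimizer is not fitted")


def optimize_conditions(
    X: np.ndarray,
    responses: dict[str, np.ndarray] | pd.DataFrame,
    spec: DesirabilitySpec,
    surrogate: str = "quadratic",
    seed: int | None = 0,
    resolution: int = 41,
) -> tuple[np.ndarray, dict[str, float], float]:
    """Fit surrogates on coded runs and return the desirability optimum."""
    opt = DesirabilityOptimizer(surrogate=surrogate, resolution=resolution, seed=seed)
    return opt.fit(X, responses).optimize(spec)
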