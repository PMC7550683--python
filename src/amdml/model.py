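"""Auto-weighted multi-view discriminative metric learning (AMDML).

The model learns a single column-orthonormal projection H shared across M
feature views, a view-weight vector Theta on the probability simplex, and a
positive constraint weight gamma trading off two terms per view:

* a Fisher discriminative term
  a_m = Tr(H^T X^m (L_G^m - L_P^m) X^m^T H) — small when same-class
  neighbours project close together and different-class neighbours far
  apart;
* a global-structure (PCA-like) term
  b_m = Tr(H^T X^m L_W X^m^T H) >= 0 — the total projected variance of
  the view.

The objective is

    J(H, Theta, gamma) = sum_m Theta_m^t (gamma^2 a_m - gamma b_m),
    s.t.  H^T H = I,  sum_m Theta_m = 1,  Theta_m >= 0,

minimised by block coordinate descent: Theta and gamma have closed-form
updates, H is the eigenvector basis of the d algebraically smallest
eigenvalues of the weighted system matrix.  The exponent t > 1 smooths the
view weights away from one-hot solutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .data import MultiViewDataset
from .graphs import ViewGraphs


class NumericalError(ArithmeticError):
    """A closed-form update hit a degenerate configuration."""


@dataclass(frozen=True)
class FitConfig:
    """All tunables of the AMDML fit.

    Parameters
    ----------
    k1, k2 : int
        Neighbour counts of the intraclass / interclass graphs.
    d : int
        Dimension of the learned metric subspace (columns of H).
    exponent_t : float
        Simplex-smoothing exponent t > 1 on the view weights.
    delta : float
        Convergence tolerance on |J(t) - J(t-1)|.
    t_max : int
        Maximum number of coordinate-descent iterations.
    epsilon_clamp : float
        Floor used when shifted per-view costs or gamma become
        non-positive.
    seed : int
        Recorded for provenance; the fit itself is deterministic.
    """

    k1: int = 5
    k2: int = 5
    d: int = 8
    exponent_t: float = 2.0
    delta: float = 1e-5
    t_max: int = 100
    epsilon_clamp: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not self.exponent_t > 1:
            raise ValueError("exponent_t must be > 1")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


def _fix_signs(H: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    H = H.copy()
    for j in range(H.shape[1]):
        i = int(np.argmax(np.abs(H[:, j])))
        if H[i, j] < 0:
            H[:, j] = -H[:, j]
    return H


def _scatter_matrices(
    dataset: MultiViewDataset, graphs: ViewGraphs
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-view D x D matrices S_m = X (L_G - L_P) X^T and C_m = X L_W X^T.

    These depend only on the data and graphs, not on (H, Theta, gamma), so
    they are cached on the graphs object.
    """
    cache = getattr(graphs, "_scatter_cache", None)
    if cache is not None and cache[0] is dataset:
        return cache[1], cache[2]
    S, C = [], []
    for m, (_, X) in enumerate(dataset.views):
        S.append(X @ (graphs.L_G[m] - graphs.L_P[m]) @ X.T)
        C.append(X @ graphs.L_W @ X.T)
    graphs._scatter_cache = (dataset, S, C)
    return S, C


def trace_terms(
    H: np.ndarray, dataset: MultiViewDataset, graphs: ViewGraphs
) -> tuple[np.ndarray, np.ndarray]:
    """Per-view Fisher traces a_m and global-structure traces b_m.

    a_m = Tr(H^T X^m (L_G^m - L_P^m) X^m^T H);
    b_m = Tr(H^T X^m L_W X^m^T H), always >= 0 since L_W is PSD.
    """
    S, C = _scatter_matrices(dataset, graphs)
    a = np.array([np.trace(H.T @ Sm @ H) for Sm in S])
    b = np.array([np.trace(H.T @ Cm @ H) for Cm in C])
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise NumericalError("non-finite trace terms")
    return a, b


def system_matrix(
    Theta: np.ndarray,
    gamma: float,
    dataset: MultiViewDataset,
    graphs: ViewGraphs,
    exponent_t: float,
) -> np.ndarray:
    """The D x D matrix A = sum_m Theta_m^t (gamma^2 S_m - gamma C_m)."""
    S, C = _scatter_matrices(dataset, graphs)
    w = np.asarray(Theta, dtype=float) ** exponent_t
    A = sum(w[m] * (gamma**2 * S[m] - gamma * C[m]) for m in range(len(S)))
    return (A + A.T) / 2.0


def solve_H(
    Theta: np.ndarray,
    gamma: float,
    dataset: MultiViewDataset,
    graphs: ViewGraphs,
    d: int,
    exponent_t: float = 2.0,
) -> np.ndarray:
    """Minimise Tr(H^T A H) over column-orthonormal H.

    Returns the orthonormal eigenvectors of the d algebraically smallest
    eigenvalues of the system matrix, columns ordered by ascending
    eigenvalue, signs fixed so the largest-magnitude component of each
    column is positive.
    """
    A = system_matrix(Theta, gamma, dataset, graphs, exponent_t)
    D = A.shape[0]
    if d > D:
        raise ValueError(f"d={d} exceeds feature dimension D={D}")
    _, vecs = eigh(A, subset_by_index=(0, d - 1))
    return _fix_signs(vecs)


def update_theta(
    H: np.ndarray,
    gamma: float,
    dataset: MultiViewDataset,
    graphs: ViewGraphs,
    exponent_t: float,
    epsilon_clamp: float = 1e-10,
) -> np.ndarray:
    """Closed-form simplex update of the view weights.

    With per-view cost c_m = gamma^2 a_m - gamma b_m, the stationary point
    of sum_m Theta_m^t c_m on the simplex is
    Theta_m = (1/c_m)^(1/(t-1)) / sum_k (1/c_k)^(1/(t-1)), valid for
    positive costs.  Non-positive costs (possible because the Fisher term
    is a difference) are shifted above zero first:
    c_m <- max(c_m - min_k c_k + eps, eps).
    """
    a, b = trace_terms(H, dataset, graphs)
    c = gamma**2 * a - gamma * b
    if np.any(c <= 0):
        c = np.maximum(c - c.min() + epsilon_clamp, epsilon_clamp)
    inv = (1.0 / c) ** (1.0 / (exponent_t - 1.0))
    total = inv.sum()
    if not np.isfinite(total) or total == 0:
        return np.full(c.size, 1.0 / c.size)
    return inv / total


def update_gamma(
    H: np.ndarray,
    Theta: np.ndarray,
    dataset: MultiViewDataset,
    graphs: ViewGraphs,
    exponent_t: float,
    epsilon_clamp: float = 1e-10,
) -> tuple[float, bool]:
    """Closed-form update gamma = sum Theta^t b / (2 sum Theta^t a).

    This is the unconstrained minimiser of J(gamma) when the weighted
    Fisher term sum_m Theta_m^t a_m is positive.  A non-positive result is
    clamped to ``epsilon_clamp``; the second return value flags clamping.
    """
    a, b = trace_terms(H, dataset, graphs)
    w = np.asarray(Theta, dtype=float) ** exponent_t
    denom = 2.0 * float(w @ a)
    if denom == 0.0:
        raise NumericalError(
            f"zero denominator in gamma update: per-view a = {a.tolist()}"
        )
    gamma = float(w @ b) / denom
    if gamma <= 0:
        return epsilon_clamp, True
    return gamma, False


def objective(
    H: np.ndarray,
    Theta: np.ndarray,
    gamma: float,
    dataset: MultiViewDataset,
    graphs: ViewGraphs,
    exponent_t: float,
) -> float:
    """J = sum_m Theta_m^t (gamma^2 a_m - gamma b_m)."""
    a, b = trace_terms(H, dataset, graphs)
    w = np.asarray(Theta, dtype=float) ** exponent_t
    J = float(w @ (gamma**2 * a - gamma * b))
    if not np.isfinite(J):
        raise NumericalError("non-finite objective")
    return J


@dataclass
class AMDMLResults:
    """Fitted AMDML parameters, diagnostics, and the transform.

    Attributes
    ----------
    H : ndarray, shape (D, d)
        Column-orthonormal projection into the learned metric space.
    theta : ndarray, shape (M,)
        View weights on the simplex.
    gamma : float
        Constraint weight between the Fisher and global-structure terms.
    objective_trace : ndarray
        J after every iteration (including the initial point).
    converged : bool
        True if |J(t) - J(t-1)| <= delta before t_max.
    clamp_events : list of (iteration, kind)
        Iterations where the Theta shift or gamma floor activated; lets
        users audit non-monotone steps of the objective.
    """

    model: "AMDML"
    H: np.ndarray
    theta: np.ndarray
    gamma: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    clamp_events: list = field(default_factory=list)
    step_trace: list = field(default_factory=list)

    @property
    def config(self) -> FitConfig:
        return self.model.config

    def transform(
        self, dataset: MultiViewDataset | None = None, mode: str = "weighted-concat"
    ) -> np.ndarray:
        """Project a dataset into the learned fused metric space.

        Per view, Y^m = H^T X^m (d x N).  Fusion modes:

        * ``weighted-concat`` (default) — stack Theta_m * Y^m over views
          into a (d*M) x N matrix; squared Euclidean distances equal
          sum_m Theta_m^2 ||H^T (x_i^m - x_j^m)||^2.
        * ``unweighted-concat`` — stack the Y^m unscaled.
        * ``weighted-mean`` — sum_m Theta_m Y^m, a d x N matrix.
        """
        if dataset is None:
            dataset = self.model.dataset
        if dataset.n_views != self.theta.size:
            raise ValueError("dataset view count differs from the fitted model")
        Y = [self.H.T @ X for _, X in dataset.views]
        if mode == "weighted-concat":
            return np.vstack([t * y for t, y in zip(self.theta, Y)])
        if mode == "unweighted-concat":
            return np.vstack(Y)
        if mode == "weighted-mean":
            return sum(t * y for t, y in zip(self.theta, Y))
        raise ValueError(f"unknown fusion mode {mode!r}")

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        cfg = self.config
        lines = [
            "AMDML fit results",
            "=" * 50,
            f"views (M):          {self.theta.size}",
            f"samples (N):        {self.model.dataset.n_samples}",
            f"feature dim (D):    {self.model.dataset.dim}",
            f"subspace dim (d):   {cfg.d}",
            f"k1 / k2:            {cfg.k1} / {cfg.k2}",
            f"exponent t:         {cfg.exponent_t}",
            f"converged:          {self.converged} ({self.n_iter} iterations)",
            f"final objective J:  {self.objective_trace[-1]:.6g}",
            f"gamma:              {self.gamma:.6g}",
            "-" * 50,
            "view weights Theta:",
        ]
        for name, t in zip(self.model.dataset.view_names, self.theta):
            lines.append(f"  {name:<16s} {t:.4f}")
        if self.clamp_events:
            lines.append(f"clamp events: {self.clamp_events}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the fitted model to a self-describing JSON text file."""
        payload = {
            "format": "amdml-model 1",
            "config": asdict(self.config),
            "H": self.H.tolist(),
            "theta": self.theta.tolist(),
            "gamma": self.gamma,
            "objective_trace": self.objective_trace.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "clamp_events": self.clamp_events,
            "view_names": self.model.dataset.view_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load(path: str | Path) -> "FrozenResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "amdml-model 1":
            raise ValueError(f"{path}: not an amdml model file")
        return FrozenResults(
            H=np.array(payload["H"]),
            theta=np.array(payload["theta"]),
            gamma=float(payload["gamma"]),
            objective_trace=np.array(payload["objective_trace"]),
            converged=bool(payload["converged"]),
            n_iter=int(payload["n_iter"]),
            clamp_events=[tuple(e) for e in payload["clamp_events"]],
            config=FitConfig(**payload["config"]),
            view_names=list(payload["view_names"]),
        )


@dataclass
class FrozenResults:
    """A deserialized fit: same transform surface, no training data attached."""

    H: np.ndarray
    theta: np.ndarray
    gamma: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    clamp_events: list
    config: FitConfig
    view_names: list[str]

    def transform(
        self, dataset: MultiViewDataset, mode: str = "weighted-concat"
    ) -> np.ndarray:
        if dataset.n_views != self.theta.size:
            raise ValueError("dataset view count differs from the fitted model")
        Y = [self.H.T @ X for _, X in dataset.views]
        if mode == "weighted-concat":
            return np.vstack([t * y for t, y in zip(self.theta, Y)])
        if mode == "unweighted-concat":
            return np.vstack(Y)
        if mode == "weighted-mean":
            return sum(t * y for t, y in zip(self.theta, Y))
        raise ValueError(f"unknown fusion mode {mode!r}")


class AMDML:
    """Auto-weighted multi-view discriminative metric learning model.

    Parameters
    ----------
    dataset : MultiViewDataset
        M feature views (D x N each) over the same N labelled samples.
    config : FitConfig, optional
        Fit tunables; defaults are sensible for D around 8-16.

    Examples
    --------
    >>> model = AMDML(dataset, FitConfig(k1=5, k2=5, d=4))
    >>> res = model.fit()
    >>> fused = res.transform()          # (d*M) x N fused features
    >>> print(res.summary())
    """

    def __init__(self, dataset: MultiViewDataset, config: FitConfig | None = None):
        if len(np.unique(dataset.labels)) < 2:
            raise ValueError("both classes must be present to fit")
        self.dataset = dataset
        self.config = config or FitConfig()
        if self.config.d > dataset.dim:
            raise ValueError(
                f"subspace dim d={self.config.d} exceeds feature dim "
                f"D={dataset.dim}"
            )
        self.graphs = ViewGraphs.build(dataset, self.config.k1, self.config.k2)

    @classmethod
    def from_views(
        cls,
        views: list[tuple[str, np.ndarray]],
        labels: np.ndarray,
        config: FitConfig | None = None,
    ) -> "AMDML":
        """Build directly from (name, D x N matrix) pairs and labels."""
        return cls(MultiViewDataset(views=views, labels=labels), config)

    def fit(self) -> AMDMLResults:
        """Run the block coordinate descent until |dJ| <= delta or t_max.

        Initialisation: uniform Theta, gamma = 1, H from the unweighted
        eigenproblem.  Each iteration updates Theta (closed form), gamma
        (closed form), then H (eigendecomposition), and records J.
        """
        cfg = self.config
        M = self.dataset.n_views
        Theta = np.full(M, 1.0 / M)
        gamma = 1.0
        H = solve_H(Theta, gamma, self.dataset, self.graphs, cfg.d, cfg.exponent_t)
        trace = [objective(H, Theta, gamma, self.dataset, self.graphs, cfg.exponent_t)]
        clamp_events: list[tuple[int, str]] = []
        # (iteration, step, exact, J) — `exact` marks steps that performed an
        # exact block minimisation (no clamp), after which J cannot increase.
        step_trace: list[tuple[int, str, bool, float]] = [
            (0, "init", True, trace[0])
        ]
        converged = False
        it = 0

        def _J(H, Theta, gamma):
            return objective(
                H, Theta, gamma, self.dataset, self.graphs, cfg.exponent_t
            )

        for it in range(1, cfg.t_max + 1):
            a, b = trace_terms(H, self.dataset, self.graphs)
            c = gamma**2 * a - gamma * b
            theta_exact = bool(np.all(c > 0))
            Theta = update_theta(
                H, gamma, self.dataset, self.graphs, cfg.exponent_t, cfg.epsilon_clamp
            )
            if not theta_exact:
                clamp_events.append((it, "theta-shift"))
            step_trace.append((it, "theta", theta_exact, _J(H, Theta, gamma)))

            gamma, clamped = update_gamma(
                H, Theta, self.dataset, self.graphs, cfg.exponent_t, cfg.epsilon_clamp
            )
            if clamped:
                clamp_events.append((it, "gamma-floor"))
            step_trace.append((it, "gamma", not clamped, _J(H, Theta, gamma)))

            H = solve_H(Theta, gamma, self.dataset, self.graphs, cfg.d, cfg.exponent_t)
            J = _J(H, Theta, gamma)
            step_trace.append((it, "H", True, J))
            trace.append(J)
            if abs(trace[-1] - trace[-2]) <= cfg.delta:
                converged = True
                break
        return AMDMLResults(
            model=self,
            H=H,
            theta=Theta,
            gamma=gamma,
            objective_trace=np.array(trace),
            converged=converged,
            n_iter=it,
            clamp_events=clamp_events,
            step_trace=step_trace,
        )
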