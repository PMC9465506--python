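"""Cormack-Jolly-Seber models on locality detection histories.

The CJS model conditions on each locality's first detection and estimates, per
decade interval, the probability Phi that an extant population persists to the
next decade and, per decade occasion, the probability p that an extant
population is recorded at least once.  Both parameters take a logit link with
one of four time structures:

====================  ==============================  ==========
structure             linear predictor                MARK name
====================  ==============================  ==========
``constant``          intercept                       ``.``
``linear``            intercept + s                   ``Time``
``quadratic``         intercept + s + s**2            ``Time^2``
``full``              one free parameter per          ``t``
                      interval / occasion
====================  ==============================  ==========

where s is the interval (or occasion) index mapped affinely onto [-1, 1] for
numerical conditioning; real-scale estimates are invariant to that choice.

Candidate models are ranked by the small-sample-corrected AIC

    AICc = -2 log L + 2K + 2K(K+1) / (n_eff - K - 1),

with effective sample size n_eff the number of release events (detections at
occasions 1..T-1), the standard capture-recapture convention.  Absolute AICc
values depend on that convention; real-scale ML estimates do not.

Indexing convention (0-based, T occasions): ``phi[k]`` is persistence over the
interval from occasion k to k+1 and ``p[k]`` is detection at the *arrival*
occasion k+1, so both vectors have length T-1 and share the index k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .records import DetectionHistorySet

__all__ = [
    "CJSModelSpec",
    "DesignMatrices",
    "CJSModel",
    "CJSResults",
    "ModelTable",
    "chi_vector",
    "cjs_loglik",
    "build_design",
    "count_parameters",
    "build_marray",
    "fit_cjs",
    "aicc",
    "akaike_weights",
    "model_selection",
    "persistence_over",
    "DEFAULT_MODEL_SET",
]

STRUCTURES = ("constant", "linear", "quadratic", "full")

_ALIASES = {
    ".": "constant",
    "time": "linear",
    "time^2": "quadratic",
    "time2": "quadratic",
    "t": "full",
}

_MARK_NAMES = {
    "constant": ".",
    "linear": "Time",
    "quadratic": "Time^2",
    "full": "t",
}

#: real-scale boundary: |logit| above this is reported as a boundary estimate
BOUNDARY_LOGIT = 15.0

_TINY = 1e-300


def _canon(structure: str) -> str:
    s = str(structure).strip()
    s = _ALIASES.get(s.lower(), s.lower())
    if s not in STRUCTURES:
        raise ValueError(
            f"unknown time structure {structure!r}; expected one of "
            f"{STRUCTURES} or MARK aliases {tuple(_ALIASES)}"
        )
    return s


@dataclass(frozen=True)
class CJSModelSpec:
    """Time structures for persistence (phi) and detection (p) at T occasions."""

    phi: str
    p: str
    T: int

    def __post_init__(self):
        object.__setattr__(self, "phi", _canon(self.phi))
        object.__setattr__(self, "p", _canon(self.p))
        if self.T < 2:
            raise ValueError("CJS needs at least two occasions")

    @property
    def name(self) -> str:
        """MARK-style model name, e.g. ``Phi(Time^2)p(t)``."""
        return f"Phi({_MARK_NAMES[self.phi]})p({_MARK_NAMES[self.p]})"


@dataclass(frozen=True)
class DesignMatrices:
    """Coefficient-to-logit maps for the two parameter vectors."""

    X_phi: np.ndarray  # (T-1, K_phi)
    X_p: np.ndarray  # (T-1, K_p)
    time_covariate: np.ndarray  # scaled index in [-1, 1], length T-1


def time_covariate(n: int) -> np.ndarray:
    """Index 0..n-1 mapped affinely onto [-1, 1] (all zeros when n == 1)."""
    if n == 1:
        return np.zeros(1)
    return -1.0 + 2.0 * np.arange(n) / (n - 1)


def _structure_matrix(structure: str, n: int) -> np.ndarray:
    s = time_covariate(n)
    if structure == "constant":
        return np.ones((n, 1))
    if structure == "linear":
        return np.column_stack([np.ones(n), s])
    if structure == "quadratic":
        return np.column_stack([np.ones(n), s, s**2])
    return np.eye(n)  # full


def build_design(spec: CJSModelSpec) -> DesignMatrices:
    """Design matrices mapping coefficients to logit(phi) and logit(p)."""
    n = spec.T - 1
    return DesignMatrices(
        X_phi=_structure_matrix(spec.phi, n),
        X_p=_structure_matrix(spec.p, n),
        time_covariate=time_covariate(n),
    )


def count_parameters(spec: CJSModelSpec) -> int:
    """Number of estimable parameters K.

    constant -> 1, linear -> 2, quadratic -> 3, full -> T-1 per parameter;
    when *both* are full the terminal persistence and detection enter the
    likelihood only through their product, so one parameter is not separately
    estimable and K is reduced by one.
    """
    per = {"constant": 1, "linear": 2, "quadratic": 3, "full": spec.T - 1}
    k = per[spec.phi] + per[spec.p]
    if spec.phi == "full" and spec.p == "full":
        k -= 1
    return k


# ---------------------------------------------------------------------------
# likelihood


def _check_probs(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1) | ~np.isfinite(x)):
        raise ValueError(f"{name} values must lie in [0, 1]")
    return x


def chi_vector(phi: Sequence[float], p: Sequence[float]) -> np.ndarray:
    """Probability chi_i that a population alive at occasion i is never
    detected at any later occasion.

    ``phi`` and ``p`` both have length T-1 (see module docstring); the result
    has length T with ``chi[T-1] = 1`` and the backward recursion

        chi_i = 1 - phi_i * (1 - (1 - p_{i+1}) * chi_{i+1}).
    """
    phi = _check_probs(phi, "phi")
    p = _check_probs(p, "p")
    if phi.shape != p.shape:
        raise ValueError("phi and p must have the same length T-1")
    T = len(phi) + 1
    chi = np.ones(T)
    for k in range(T - 2, -1, -1):
        chi[k] = 1.0 - phi[k] * (1.0 - (1.0 - p[k]) * chi[k + 1])
    return chi


def _history_matrix(histories) -> np.ndarray:
    if isinstance(histories, DetectionHistorySet):
        return histories.matrix
    Y = np.asarray(histories, dtype=np.int8)
    if Y.ndim != 2:
        raise ValueError("histories must be a 2-D 0/1 array")
    return Y


def cjs_loglik(histories, phi: Sequence[float], p: Sequence[float]) -> float:
    """Conditional-on-first-detection CJS log-likelihood.

    A history first detected at occasion f and last detected at l contributes

        prod_{i=f..l-1} phi_i * p_{i+1}^y_{i+1} * (1-p_{i+1})^(1-y_{i+1})
        * chi_l,

    the product running over the intervals between first and last detection
    and chi_l absorbing the never-seen-again tail.
    """
    Y = _history_matrix(histories)
    phi = _check_probs(phi, "phi")
    p = _check_probs(p, "p")
    T = Y.shape[1]
    if len(phi) != T - 1 or len(p) != T - 1:
        raise ValueError("phi and p must have length T-1")
    if Y.shape[0] and not Y.any(axis=1).all():
        raise ValueError("all-zero history violates conditioning on first detection")
    chi = chi_vector(phi, p)
    uniq, counts = np.unique(Y, axis=0, return_counts=True)
    total = 0.0
    for h, c in zip(uniq, counts):
        det = np.flatnonzero(h)
        f, l = det[0], det[-1]
        ll = np.log(max(chi[l], _TINY))
        for k in range(f, l):
            ll += np.log(max(phi[k], _TINY))
            if h[k + 1]:
                ll += np.log(max(p[k], _TINY))
            else:
                ll += np.log(max(1.0 - p[k], _TINY))
        total += c * ll
    return float(total)


def build_marray(histories) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduce histories to the m-array sufficient statistics.

    Returns ``(m, never, releases)`` where ``m[i, j]`` counts localities
    detected at occasion i whose next detection is occasion j (0-based,
    j > i), ``never[i]`` counts those never detected after i, and
    ``releases[i] = m[i].sum() + never[i]`` is the number of detections at
    occasion i < T-1.  The CJS likelihood is a product of multinomials over
    these cells, so the m-array is equivalent to the full history data.
    """
    Y = _history_matrix(histories)
    n, T = Y.shape
    m = np.zeros((T - 1, T), dtype=np.int64)
    never = np.zeros(T - 1, dtype=np.int64)
    for h in range(n):
        det = np.flatnonzero(Y[h])
        if det.size == 0:
            raise ValueError("all-zero history violates conditioning on first detection")
        for a, b in zip(det[:-1], det[1:]):
            m[a, b] += 1
        if det[-1] < T - 1:
            never[det[-1]] += 1
    releases = m.sum(axis=1) + never
    return m, never, releases


def _marray_loglik_grad(
    m: np.ndarray, never: np.ndarray, phi: np.ndarray, p: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood and its gradient w.r.t. (phi, p) from the m-array.

    The recapture cell probability is
    q_ij = prod_{k=i}^{j-1} phi_k * prod_{k=i}^{j-2} (1-p_k) * p_{j-1}
    (indexing per module convention) and the never-again cell is chi_i.
    """
    T = m.shape[1]
    phi = np.clip(phi, _TINY, 1.0)
    p = np.clip(p, _TINY, 1.0 - 1e-15)
    log_phi = np.log(phi)
    log_p = np.log(p)
    log_1mp = np.log1p(-p)

    ll = 0.0
    g_phi = np.zeros(T - 1)
    g_p = np.zeros(T - 1)

    # multinomial recapture cells: d(ll)/d(log phi_k) etc. are m-count sums
    for i in range(T - 1):
        for j in range(i + 1, T):
            c = m[i, j]
            if not c:
                continue
            ll += c * (
                log_phi[i:j].sum() + log_1mp[i : j - 1].sum() + log_p[j - 1]
            )
            g_phi[i:j] += c / phi[i:j]
            g_p[i : j - 1] -= c / (1.0 - p[i : j - 1])
            g_p[j - 1] += c / p[j - 1]

    # never-seen-again cells through the chi recursion (backprop)
    chi = chi_vector(phi, p)
    adj = np.zeros(T)  # d(ll)/d(chi_i)
    for i in range(T - 1):
        if never[i]:
            ll += never[i] * np.log(max(chi[i], _TINY))
            adj[i] += never[i] / max(chi[i], _TINY)
    # chi_i depends on chi_{i+1}: propagate adjoints forward in i
    for i in range(T - 1):
        a = adj[i]
        if a == 0.0:
            continue
        g_phi[i] += a * (-(1.0 - (1.0 - p[i]) * chi[i + 1]))
        g_p[i] += a * (-phi[i] * chi[i + 1])
        adj[i + 1] += a * phi[i] * (1.0 - p[i])
    return float(ll), g_phi, g_p


# ---------------------------------------------------------------------------
# model object


class CJSModel:
    """Cormack-Jolly-Seber model for a set of locality detection histories.

    Parameters
    ----------
    histories
        :class:`~cjsdecline.records.DetectionHistorySet` or (n, T) 0/1 array;
        every row must contain at least one detection.
    phi, p
        Time structure of persistence and detection: ``constant`` / ``linear``
        / ``quadratic`` / ``full`` (MARK aliases ``.``, ``Time``, ``Time^2``,
        ``t`` accepted).

    Examples
    --------
    >>> model = CJSModel(histories, phi="quadratic", p="t")
    >>> res = model.fit(seed=1)
    >>> res.phi_hat, res.aicc
    """

    def __init__(self, histories, phi: str = "constant", p: str = "constant"):
        Y = _history_matrix(histories)
        if Y.shape[0] == 0:
            raise ValueError("no detection histories")
        self.endog = Y
        self.histories = histories if isinstance(histories, DetectionHistorySet) else None
        self.spec = CJSModelSpec(phi, p, Y.shape[1])
        self.design = build_design(self.spec)
        self.m, self.never, self.releases = build_marray(Y)
        self.n_eff = int(self.releases.sum())
        self.K = count_parameters(self.spec)
        self.k_phi = self.design.X_phi.shape[1]
        self.k_p = self.design.X_p.shape[1]
        # identifiability: need at least one re-detection after a first detection
        if self.m.sum() == 0:
            warnings.warn(
                "no locality was ever re-detected after its first detection; "
                "persistence is unidentifiable",
                stacklevel=2,
            )

    @classmethod
    def from_records(cls, rs, grid=None, phi="constant", p="constant", **kwargs):
        """Build directly from a year-filtered RecordSet."""
        from .records import DEFAULT_GRID, build_detection_histories

        hist = build_detection_histories(rs, grid or DEFAULT_GRID, **kwargs)
        return cls(hist, phi=phi, p=p)

    # -- parameter mapping --------------------------------------------------
    def _split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.k_phi + self.k_p,):
            raise ValueError(
                f"beta must have length {self.k_phi + self.k_p} "
                f"({self.k_phi} phi + {self.k_p} p coefficients)"
            )
        return beta[: self.k_phi], beta[self.k_phi :]

    def real_params(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Real-scale (phi, p) vectors implied by coefficient vector beta."""
        b_phi, b_p = self._split(beta)
        return expit(self.design.X_phi @ b_phi), expit(self.design.X_p @ b_p)

    def loglike(self, beta: np.ndarray) -> float:
        phi, p = self.real_params(beta)
        ll, _, _ = _marray_loglik_grad(self.m, self.never, phi, p)
        return ll

    def score(self, beta: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood w.r.t. beta."""
        b_phi, b_p = self._split(beta)
        eta_phi = self.design.X_phi @ b_phi
        eta_p = self.design.X_p @ b_p
        phi, p = expit(eta_phi), expit(eta_p)
        _, g_phi, g_p = _marray_loglik_grad(self.m, self.never, phi, p)
        return np.concatenate(
            [
                self.design.X_phi.T @ (g_phi * phi * (1.0 - phi)),
                self.design.X_p.T @ (g_p * p * (1.0 - p)),
            ]
        )

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        start: np.ndarray | None = None,
        n_restarts: int = 5,
        seed: int | np.random.Generator = 0,
        tol: float = 1e-8,
    ) -> "CJSResults":
        """Maximise the likelihood by quasi-Newton from a zero start plus
        ``n_restarts`` seeded random starts; the best optimum is kept.

        Any non-finite estimate marks the fit non-converged rather than being
        silently reported.
        """
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        nb = self.k_phi + self.k_p
        starts = [np.zeros(nb)]
        if start is not None:
            starts.insert(0, np.asarray(start, dtype=float))
        starts += [rng.normal(scale=1.0, size=nb) for _ in range(n_restarts)]

        def neg(beta):
            ll = self.loglike(beta)
            return -ll

        def neg_grad(beta):
            return -self.score(beta)

        best = None
        any_ok = False
        for s in starts:
            try:
                res = minimize(
                    neg,
                    s,
                    jac=neg_grad,
                    method="L-BFGS-B",
                    options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
                )
            except (ValueError, FloatingPointError):  # pragma: no cover
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            any_ok = any_ok or res.success
        if best is None:  # pragma: no cover - optimizer never raises in practice
            raise RuntimeError("all optimizer starts failed")
        converged = bool(any_ok and np.all(np.isfinite(best.x)))
        return CJSResults(self, best.x, float(-best.fun), converged)


class CJSResults:
    """ML estimates, uncertainties and information criteria for a CJSModel.

    Attributes
    ----------
    params : coefficient vector on the logit scale
    phi_hat, p_hat : real-scale per-interval / per-occasion estimates
    llf : maximised log-likelihood;  m2ll = -2 llf
    K, n_eff, aicc : parameter count, effective sample size, corrected AIC
    boundary_phi, boundary_p : flags where |logit| exceeds the boundary
    """

    def __init__(self, model: CJSModel, params: np.ndarray, llf: float, converged: bool):
        self.model = model
        self.spec = model.spec
        self.params = np.asarray(params, dtype=float)
        self.llf = llf
        self.converged = converged and np.isfinite(llf)
        self.n_histories = model.endog.shape[0]
        self.n_eff = model.n_eff
        self.K = model.K
        b_phi, b_p = model._split(self.params)
        eta_phi = model.design.X_phi @ b_phi
        eta_p = model.design.X_p @ b_p
        self.phi_hat = expit(eta_phi)
        self.p_hat = expit(eta_p)
        self.boundary_phi = np.abs(eta_phi) > BOUNDARY_LOGIT
        self.boundary_p = np.abs(eta_p) > BOUNDARY_LOGIT
        # pin boundary estimates to the limit they approach
        self.phi_hat = np.where(self.boundary_phi, np.round(self.phi_hat), self.phi_hat)
        self.p_hat = np.where(self.boundary_p, np.round(self.p_hat), self.p_hat)
        self._cov = None

    @property
    def m2ll(self) -> float:
        return -2.0 * self.llf

    @property
    def minus_two_log_lik(self) -> float:
        return self.m2ll

    @property
    def aicc(self) -> float:
        return aicc(self.m2ll, self.K, self.n_eff)

    @property
    def terminal_confounded(self) -> bool:
        """True when only the product phi_{T-1} * p_T is estimable."""
        return self.spec.phi == "full" and self.spec.p == "full"

    @property
    def terminal_product(self) -> float:
        """phi_{T-1} * p_T — the estimable quantity at the terminal occasion."""
        return float(self.phi_hat[-1] * self.p_hat[-1])

    # -- uncertainty --------------------------------------------------------
    def cov_params(self) -> np.ndarray:
        """Approximate covariance of the coefficients from the numeric Hessian
        of the negative log-likelihood (delta-method quality; flagged
        approximate, boundary estimates have no meaningful SE)."""
        if self._cov is None:
            from statsmodels.tools.numdiff import approx_hess

            H = approx_hess(self.params, lambda b: -self.model.loglike(b))
            self._cov = np.linalg.pinv(H)
        return self._cov

    def _real_se(self, X: np.ndarray, real: np.ndarray, offset: int) -> np.ndarray:
        cov = self.cov_params()[offset : offset + X.shape[1], offset : offset + X.shape[1]]
        var_eta = np.einsum("ij,jk,ik->i", X, cov, X)
        var_eta = np.clip(var_eta, 0.0, None)
        return real * (1.0 - real) * np.sqrt(var_eta)

    @property
    def phi_se(self) -> np.ndarray:
        return self._real_se(self.model.design.X_phi, self.phi_hat, 0)

    @property
    def p_se(self) -> np.ndarray:
        return self._real_se(self.model.design.X_p, self.p_hat, self.model.k_phi)

    # -- reporting ----------------------------------------------------------
    def estimates_frame(self) -> pd.DataFrame:
        """Tidy (occasion, parameter, estimate, se, boundary) table."""
        grid = (
            self.model.histories.occasions if self.model.histories is not None else None
        )
        T = self.spec.T
        labels = grid.labels if grid is not None else [str(i + 1) for i in range(T)]
        rows = []
        phi_se, p_se = self.phi_se, self.p_se
        for k in range(T - 1):
            rows.append(
                ("phi", labels[k], k + 1, self.phi_hat[k], phi_se[k], bool(self.boundary_phi[k]))
            )
        for k in range(T - 1):
            rows.append(
                ("p", labels[k + 1], k + 2, self.p_hat[k], p_se[k], bool(self.boundary_p[k]))
            )
        return pd.DataFrame(
            rows, columns=["parameter", "occasion", "index", "estimate", "se", "boundary"]
        )

    def summary(self) -> str:
        lines = [
            f"CJS model {self.spec.name}  (T={self.spec.T})",
            f"  histories: {self.n_histories}   releases (n_eff): {self.n_eff}",
            f"  -2 log L: {self.m2ll:.2f}   K: {self.K}   AICc: {self.aicc:.2f}",
            f"  converged: {self.converged}",
        ]
        if self.terminal_confounded:
            lines.append(
                "  terminal phi*p confounded; estimable product "
                f"phi_(T-1)*p_T = {self.terminal_product:.3f}"
            )
        frame = self.estimates_frame()
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "T": self.spec.T,
            "K": self.K,
            "n_histories": self.n_histories,
            "n_eff": self.n_eff,
            "minus_two_log_lik": self.m2ll,
            "aicc": self.aicc,
            "converged": self.converged,
            "phi_hat": self.phi_hat.tolist(),
            "p_hat": self.p_hat.tolist(),
            "beta": self.params.tolist(),
        }


def fit_cjs(
    histories,
    spec: CJSModelSpec | tuple[str, str],
    **fit_kwargs,
) -> CJSResults:
    """Functional wrapper: build a :class:`CJSModel` and fit it."""
    if isinstance(spec, CJSModelSpec):
        phi, p = spec.phi, spec.p
    else:
        phi, p = spec
    return CJSModel(histories, phi=phi, p=p).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# information criteria and model selection


def aicc(minus_two_log_lik: float, K: int, n_eff: int) -> float:
    """Small-sample corrected AIC: -2lnL + 2K + 2K(K+1)/(n_eff - K - 1)."""
    if n_eff <= K + 1:
        raise ValueError(
            f"AICc undefined: effective sample size {n_eff} <= K + 1 = {K + 1}"
        )
    return minus_two_log_lik + 2.0 * K + 2.0 * K * (K + 1) / (n_eff - K - 1)


def akaike_weights(aicc_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Delta-AICc values and Akaike weights for a candidate set.

    Returns ``(delta, weights)`` with delta_i = AICc_i - min AICc and
    w_i = exp(-delta_i / 2) normalised to sum to one.
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.isfinite(a).any():
        raise ValueError("need at least one finite AICc value")
    delta = a - np.nanmin(a[np.isfinite(a)])
    w = np.exp(-delta / 2.0)
    w = np.where(np.isfinite(delta), w, 0.0)
    return delta, w / w.sum()


#: all 16 crossings of the four time structures, the default candidate set
DEFAULT_MODEL_SET: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in STRUCTURES for b in STRUCTURES
)


@dataclass
class ModelTable:
    """Candidate CJS models ranked by AICc (the MARK-style results table)."""

    table: pd.DataFrame
    fits: list[CJSResults] = field(default_factory=list)

    @property
    def best(self) -> CJSResults:
        name = self.table.iloc[0]["model"]
        return next(f for f in self.fits if f.spec.name == name)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        cols = ["model", "K", "minus_two_log_lik", "aicc", "delta_aicc", "weight"]
        sub = self.table[cols].copy()
        header = "| Model | Parameters | -2lnL | AICc | deltaAICc | Weight |"
        sep = "|---|---|---|---|---|---|"
        rows = [
            f"| {r.model} | {r.K} | {r.minus_two_log_lik:.2f} | {r.aicc:.2f} "
            f"| {r.delta_aicc:.2f} | {r.weight:.2f} |"
            for r in sub.itertuples(index=False)
        ]
        return "\n".join([header, sep] + rows)


def model_selection(
    histories,
    specs: Iterable[tuple[str, str] | CJSModelSpec] | None = None,
    **fit_kwargs,
) -> ModelTable:
    """Fit each candidate structure and rank by AICc.

    Ties in AICc are broken toward the smaller K.  Non-converged fits are kept
    in the table but flagged and excluded from the weight normalisation (with
    a warning).
    """
    Y = _history_matrix(histories)
    T = Y.shape[1]
    if specs is None:
        specs = DEFAULT_MODEL_SET
    fits: list[CJSResults] = []
    for spec in specs:
        if isinstance(spec, CJSModelSpec):
            if spec.T != T:
                raise ValueError(f"spec {spec.name} has T={spec.T}, data has T={T}")
            phi, p = spec.phi, spec.p
        else:
            phi, p = spec
        fits.append(CJSModel(Y, phi=phi, p=p).fit(**fit_kwargs))

    rows = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "K": [f.K for f in fits],
            "minus_two_log_lik": [f.m2ll for f in fits],
            "aicc": [f.aicc for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    ok = rows["converged"].to_numpy()
    if not ok.any():
        raise RuntimeError("no candidate model converged")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} non-converged model(s) excluded from Akaike weights",
            stacklevel=2,
        )
    delta = np.full(len(rows), np.nan)
    weight = np.full(len(rows), np.nan)
    d, w = akaike_weights(rows.loc[ok, "aicc"].to_numpy())
    delta[ok] = d
    weight[ok] = w
    rows["delta_aicc"] = delta
    rows["weight"] = weight
    order = np.lexsort((rows["K"].to_numpy(), rows["aicc"].to_numpy()))
    rows = rows.iloc[order].reset_index(drop=True)
    return ModelTable(rows, fits)


def persistence_over(phi, n_intervals: int) -> float:
    """Probability of persisting through ``n_intervals`` consecutive intervals.

    A constant phi gives phi**n; a per-interval vector gives the product of
    its first ``n_intervals`` entries.
    """
    if n_intervals < 0:
        raise ValueError("n_intervals must be >= 0")
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    _check_probs(phi_arr, "phi")
    if phi_arr.size == 1:
        return float(phi_arr[0] ** n_intervals)
    if phi_arr.size < n_intervals:
        raise ValueError(
            f"need {n_intervals} per-interval values, got {phi_arr.size}"
        )
    return float(np.prod(phi_arr[:n_intervals]))
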