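"""Common principal components analysis (CPCA) for two covariance matrices.

Flury's hierarchy compares the climatic covariance structure of two groups —
here the native and non-native realized niches — through four nested
hypotheses about size, shape and orientation:

- equality: identical eigenvectors and eigenvalues (one shared matrix);
- proportionality: same eigenvectors, eigenvalues scaled by one constant rho;
- cpc: a shared orthogonal eigenvector basis B, free eigenvalues per group;
- unrelated: each group keeps its own sample covariance.

All models are fitted by maximum likelihood under a two-group Wishart model
(group weights n1, n2), the CPC basis by the Flury–Gautschi (FG) pairwise
rotation algorithm, and the preferred model is chosen by minimum AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_geo import DomainError


class ConvergenceError(DomainError):
    pass


@dataclass
class CovModel:
    name: str  # equality | proportionality | cpc | unrelated
    log_likelihood: float
    chi_square_vs_unrelated: float
    df: int
    n_params: int
    aic: float = field(init=False)
    fitted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.log_likelihood + 2.0 * self.n_params

    def row(self) -> dict:
        return {
            "name": self.name,
            "chi2": self.chi_square_vs_unrelated,
            "df": self.df,
            "n_params": self.n_params,
            "logL": self.log_likelihood,
            "AIC": self.aic,
        }


def _check_spd(S: np.ndarray, label: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DomainError(f"{label} is not square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise DomainError(f"{label} is not symmetric")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise DomainError(f"{label} is not positive definite") from exc
    return 0.5 * (S + S.T)


def _log_likelihood(S_list, Sigma_list, n_list) -> float:
    """Two-group Wishart log-likelihood of model covariances Sigma_i."""
    ll = 0.0
    for S, Sigma, n in zip(S_list, Sigma_list, n_list):
        p = S.shape[0]
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise DomainError("model covariance not positive definite")
        ll += -0.5 * n * (logdet + np.trace(np.linalg.solve(Sigma, S)) + p * np.log(2.0 * np.pi))
    return ll


def _fit_proportionality(S1, S2, n1, n2, tol=1e-14, max_iter=2000):
    """Alternating ML for Sigma2 = rho * Sigma1 (Flury's likelihood equations)."""
    p = S1.shape[0]
    rho = 1.0
    for _ in range(max_iter):
        Sigma1 = (n1 * S1 + n2 * S2 / rho) / (n1 + n2)
        rho_new = float(np.trace(np.linalg.solve(Sigma1, S2)) / p)
        if abs(rho_new - rho) < tol * max(1.0, abs(rho)):
            rho = rho_new
            break
        rho = rho_new
    Sigma1 = (n1 * S1 + n2 * S2 / rho) / (n1 + n2)
    return Sigma1, rho


def fg_common_eigenvectors(
    S_list,
    n_list,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """FG (Flury–Gautschi) joint diagonalization.

    Minimizes sum_i n_i log det diag(B' S_i B) over orthogonal B by pairwise
    plane rotations, initialized from the eigenvectors of the pooled matrix.
    Raises :class:`ConvergenceError` (with the criterion trace) if the sweep
    limit is reached before the improvement drops below ``tol``.
    """
    p = S_list[0].shape[0]
    pooled = sum(n * S for S, n in zip(S_list, n_list)) / sum(n_list)
    _, B = np.linalg.eigh(pooled)
    trace = []

    def criterion(B):
        val = 0.0
        for S, n in zip(S_list, n_list):
            d = np.einsum("jp,jk,kp->p", B, S, B)
            val += n * np.sum(np.log(d))
        return val

    prev = criterion(B)
    trace.append(prev)
    for _ in range(max_sweeps):
        for j in range(p - 1):
            for k in range(j + 1, p):
                Q = np.eye(2)
                cols = B[:, [j, k]]
                T = [cols.T @ S @ cols for S in S_list]
                for _inner in range(50):
                    lam = [np.diag(Q.T @ t @ Q) for t in T]
                    w = [n * (l[0] - l[1]) / (l[0] * l[1]) for n, l in zip(n_list, lam)]
                    if all(abs(x) < 1e-300 for x in w):
                        break
                    M = sum(x * t for x, t in zip(w, T))
                    _, vec = np.linalg.eigh(M)
                    # rotation closest to identity, positive diagonal
                    Qn = vec if abs(vec[0, 0]) >= abs(vec[0, 1]) else vec[:, ::-1]
                    Qn = Qn * np.sign(np.diag(Qn))
                    if np.allclose(Qn, Q, atol=1e-14):
                        Q = Qn
                        break
                    Q = Qn
                B[:, [j, k]] = cols @ Q
        cur = criterion(B)
        trace.append(cur)
        if prev - cur < tol:
            return B
        prev = cur
    raise ConvergenceError(f"FG did not converge in {max_sweeps} sweeps; criterion trace tail {trace[-5:]}")


def n_parameters(name: str, p: int) -> int:
    tri = p * (p + 1) // 2
    return {
        "equality": tri,
        "proportionality": tri + 1,
        "cpc": p * (p - 1) // 2 + 2 * p,
        "unrelated": 2 * tri,
    }[name]


def fit_cpc_hierarchy(S1: np.ndarray, S2: np.ndarray, n1: int, n2: int) -> tuple[list[CovModel], CovModel]:
    """Fit the four-model hierarchy and choose by minimum AIC.

    ``n1``/``n2`` are the group sample sizes (occurrence counts after
    thinning, unless the covariances came from elsewhere). Returns the model
    list (equality, proportionality, cpc, unrelated) and the AIC-best model;
    ties break toward fewer parameters.
    """
    S1 = _check_spd(S1, "S1")
    S2 = _check_spd(S2, "S2")
    if S1.shape != S2.shape:
        raise DomainError("covariance matrices differ in size")
    p = S1.shape[0]
    if n1 <= p or n2 <= p:
        raise DomainError("sample sizes must exceed the number of variables")
    S_list, n_list = [S1, S2], [n1, n2]

    ll_unrel = _log_likelihood(S_list, S_list, n_list)

    pooled = (n1 * S1 + n2 * S2) / (n1 + n2)
    ll_eq = _log_likelihood(S_list, [pooled, pooled], n_list)

    Sig1_prop, rho = _fit_proportionality(S1, S2, n1, n2)
    ll_prop = _log_likelihood(S_list, [Sig1_prop, rho * Sig1_prop], n_list)

    B = fg_common_eigenvectors(S_list, n_list)
    lams = [np.einsum("jp,jk,kp->p", B, S, B) for S in S_list]
    Sig_cpc = [(B * lam) @ B.T for lam in lams]
    ll_cpc = _log_likelihood(S_list, Sig_cpc, n_list)

    specs = [
        ("equality", ll_eq, {"pooled": pooled}),
        ("proportionality", ll_prop, {"Sigma1": Sig1_prop, "rho": rho}),
        ("cpc", ll_cpc, {"B": B, "eigenvalues": np.vstack(lams)}),
        ("unrelated", ll_unrel, {"S1": S1, "S2": S2}),
    ]
    models = []
    for name, ll, fitted in specs:
        k = n_parameters(name, p)
        chi2 = max(0.0, 2.0 * (ll_unrel - ll))
        df = n_parameters("unrelated", p) - k
        models.append(CovModel(name=name, log_likelihood=ll, chi_square_vs_unrelated=chi2, df=df, n_params=k, fitted=fitted))
    best = min(models, key=lambda m: (round(m.aic, 9), m.n_params))
    return models, best
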