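"""Second-level parametric empirical Bayes over first-level posteriors.

Each first-level free parameter j is modeled across subject-session fits i
by a Bayesian linear model

    Ep_j^(i) = X_i · beta_j + e_i,   e_i ~ N(0, s_ij + sigma_j^2)

where ``X`` is the 4-column design (mean, group, drug, group x drug),
``s_ij`` the first-level posterior variance of parameter j in fit i, and
``sigma_j^2`` an estimated between-subject variance. With Gaussian priors
on beta the posterior and the log model evidence are analytic; the
between-subject variance is estimated by EM with a small floor. Parameters
are treated independently (diagonal across first-level parameters), which
keeps every quantity closed-form.

Effects are assessed by Bayesian model reduction: the evidence of a
reduced model that pins one beta coefficient to zero (prior variance
shrunk to ~0) is compared with the full model, giving a posterior
probability Pp = sigmoid(F_full - F_reduced) that the effect is present;
rows with Pp at or above threshold are flagged "meaningful".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignMatrix", "PebPriors", "SecondLevelResult", "build_design",
           "peb_fit", "bmr_report", "display_name", "param_block"]

COVARIATES = ("mean", "group", "drug", "group_x_drug")
SESSIONS = ("baseline", "placebo", "ketamine")

#: effect coding — centered given equal session counts per subject
GROUP_CODE = {"TRD": +0.5, "HV": -0.5}
DRUG_CODE = {"ketamine": 2.0 / 3.0, "baseline": -1.0 / 3.0,
             "placebo": -1.0 / 3.0}


@dataclass
class DesignMatrix:
    X: np.ndarray
    rows: list  # (subject_id, session)
    columns: tuple = COVARIATES
    degenerate: bool = False

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("design matrix must be n x 4")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be all ones")
        self.X = X


def build_design(subjects, sessions_per_subject=SESSIONS) -> DesignMatrix:
    """Design over subject-session rows.

    ``subjects``: sequence of (subject_id, group) with group in {TRD, HV}.
    Rows are ordered subject-major in the given order. Raises on unknown
    session labels; a group column with no variation (single-group roster)
    sets the ``degenerate`` flag and warns instead of failing.
    """
    rows, xs = [], []
    for sid, group in subjects:
        if group not in GROUP_CODE:
            raise ValueError(f"unknown group label {group!r}")
        for ses in sessions_per_subject:
            if ses not in DRUG_CODE:
                raise ValueError(f"unknown session label {ses!r}")
            g = GROUP_CODE[group]
            d = DRUG_CODE[ses]
            xs.append([1.0, g, d, g * d])
            rows.append((sid, ses))
    X = np.asarray(xs)
    degenerate = np.ptp(X[:, 1]) == 0 or np.ptp(X[:, 2]) == 0
    if degenerate:
        warnings.warn("design is rank deficient (a covariate is constant)",
                      UserWarning, stacklevel=2)
    return DesignMatrix(X=X, rows=rows, degenerate=degenerate)


@dataclass
class PebPriors:
    beta_var: float = 0.25
    between_var: float | None = None  # None -> EM estimate
    between_floor: float = 1e-6
    em_iter: int = 100
    #: undo first-level shrinkage before the second-level model, i.e. model
    #: the data-only (prior-removed) estimates; needs fits carrying their
    #: first-level prior variances
    deflate_first_level: bool = True
    max_row_var: float = 1e6
    #: joint GLS across first-level parameters using the full per-fit
    #: posterior covariance; correlated estimation errors between
    #: parameters then inform each other's effects. Falls back to the
    #: per-parameter (diagonal) model when False.
    multivariate: bool = True


@dataclass
class SecondLevelResult:
    param_names: tuple
    design: DesignMatrix
    beta: np.ndarray        # (n_params, 4) posterior means
    beta_cov: np.ndarray    # (n_params, 4, 4)
    sigma2: np.ndarray      # (n_params,) between-subject variance
    F_param: np.ndarray     # (n_params,) per-parameter log evidence
    priors: PebPriors = field(default_factory=PebPriors)
    _ys: np.ndarray | None = None     # (n_params, n_rows) first-level means
    _svar: np.ndarray | None = None   # (n_params, n_rows) first-level vars
    _mv: dict | None = None           # multivariate-mode internals

    @property
    def F_full(self) -> float:
        if self._mv is not None:
            return float(self._mv["F_full"])
        return float(self.F_param.sum())


def _evidence(y, X, svar, beta_var_diag, sigma2):
    """Evidence with a per-column prior variance vector (for reduction)."""
    d = svar + sigma2
    Vb_inv = 1.0 / beta_var_diag
    A = (X.T / d) @ X + np.diag(Vb_inv)
    Cb = np.linalg.inv(A)
    mb = Cb @ (X.T @ (y / d))
    _, logdetA = np.linalg.slogdet(A)
    logZ = -0.5 * (y @ (y / d) - mb @ A @ mb + np.sum(np.log(d))
                   + np.sum(np.log(beta_var_diag)) + logdetA
                   + y.size * np.log(2 * np.pi))
    return mb, Cb, logZ


def _em_sigma2(y, X, svar, beta_var, floor, n_iter):
    sigma2 = max(float(np.var(y) / 2), floor)
    full_var = np.full(X.shape[1], beta_var)
    for _ in range(n_iter):
        mb, Cb, _ = _evidence(y, X, svar, full_var, sigma2)
        r = y - X @ mb
        shrink = sigma2 / (svar + sigma2)
        mu_e = shrink * r
        v_e = shrink * svar
        new = max(float(np.mean(mu_e**2 + v_e)), floor)
        if abs(new - sigma2) < 1e-10 * max(sigma2, 1e-12):
            sigma2 = new
            break
        sigma2 = new
    return sigma2


def peb_fit(first_level, X: DesignMatrix, second_priors: PebPriors | None = None
            ) -> SecondLevelResult:
    """Fit the second-level Bayesian linear model to a list of FitResults.

    ``first_level`` order must match the design rows; all fits must share
    one parameter naming scheme.
    """
    pri = second_priors or PebPriors()
    if len(first_level) != X.X.shape[0]:
        raise ValueError("number of first-level fits does not match design rows")
    names = tuple(first_level[0].names)
    for f in first_level:
        if tuple(f.names) != names:
            raise ValueError("first-level fits use inconsistent parameter names")
    rank = np.linalg.matrix_rank(X.X)
    if rank < 4 and not X.degenerate:
        raise ValueError("design matrix is rank deficient")
    P = len(names)
    n = len(first_level)
    ys = np.empty((P, n))
    svar = np.empty((P, n))
    Cs = np.empty((n, P, P))
    deflate = (pri.deflate_first_level
               and all(f.prior_var is not None for f in first_level))
    for i, f in enumerate(first_level):
        ep = f.Ep
        Ci = 0.5 * (f.Cp + f.Cp.T)
        if deflate:
            # remove the first-level shrinkage prior in the full parameter
            # space: P_post = P_data + P_prior and (prior mean 0)
            # P_data mle = P_post Ep, so mle = P_data^{-1} P_post Ep.
            # Directions the data do not inform get a huge variance and
            # thus no weight at the second level.
            v0 = np.asarray(f.prior_var, dtype=float)
            P_post = np.linalg.inv(Ci)
            P_data = P_post - np.diag(1.0 / v0)
            w, V = np.linalg.eigh(0.5 * (P_data + P_data.T))
            w = np.clip(w, 1.0 / pri.max_row_var, None)
            Ci = (V / w) @ V.T
            ep = Ci @ (P_post @ ep)
        ys[:, i] = ep
        svar[:, i] = np.clip(np.diag(Ci), 1e-12, pri.max_row_var)
        Cs[i] = Ci
    sigma2 = np.empty(P)
    for j in range(P):
        sigma2[j] = (pri.between_var if pri.between_var is not None
                     else _em_sigma2(ys[j], X.X, svar[j], pri.beta_var,
                                     pri.between_floor, pri.em_iter))

    full_var = np.full(4, pri.beta_var)
    if not pri.multivariate:
        beta = np.empty((P, 4))
        beta_cov = np.empty((P, 4, 4))
        Fp = np.empty(P)
        for j in range(P):
            mb, Cb, logZ = _evidence(ys[j], X.X, svar[j], full_var,
                                     sigma2[j])
            beta[j], beta_cov[j], Fp[j] = mb, Cb, logZ
        return SecondLevelResult(param_names=names, design=X, beta=beta,
                                 beta_cov=beta_cov, sigma2=sigma2,
                                 F_param=Fp, priors=pri, _ys=ys, _svar=svar)

    # joint GLS across parameters: vec(beta) ordered covariate-major
    # (k = c * P + j), y_i = (x_i^T kron I_P) vec(beta) + eps_i with
    # eps_i ~ N(0, C_i + diag(sigma2))
    D = 4 * P
    A = np.zeros((D, D))
    b = np.zeros(D)
    K = 0.0
    for i in range(n):
        Vi = Cs[i] + np.diag(sigma2)
        sign, logdetV = np.linalg.slogdet(Vi)
        Wi = np.linalg.inv(Vi)
        yi = ys[:, i]
        xi = X.X[i]
        A += np.kron(np.outer(xi, xi), Wi)
        b += np.kron(xi, Wi @ yi)
        K += yi @ Wi @ yi + logdetV
    K += n * P * np.log(2 * np.pi)
    A += np.eye(D) / pri.beta_var
    Cbeta = np.linalg.inv(A)
    m = Cbeta @ b
    q = float(b @ m)
    _, logdetA = np.linalg.slogdet(A)
    F_full = -0.5 * (K - q + D * np.log(pri.beta_var) + logdetA)
    beta = m.reshape(4, P).T
    beta_cov = np.empty((P, 4, 4))
    for j in range(P):
        idx = [c * P + j for c in range(4)]
        beta_cov[j] = Cbeta[np.ix_(idx, idx)]
    mv = {"m": m, "Ckk": np.diag(Cbeta).copy(), "F_full": F_full, "P": P}
    return SecondLevelResult(param_names=names, design=X, beta=beta,
                             beta_cov=beta_cov, sigma2=sigma2,
                             F_param=np.full(P, np.nan), priors=pri,
                             _ys=ys, _svar=svar, _mv=mv)


# ---------------------------------------------------------------------------
# reporting


def param_block(name: str) -> str:
    if name.startswith("kappa_"):
        return "time_constants"
    if name.startswith("G:"):
        return "intrinsic"
    if name.startswith(("A_", "B:")):
        return "extrinsic"
    return "other"


_CONN_TEXT = {
    "self_ss": "inhibitory self-connection–ss",
    "self_sp": "inhibitory self-connection–sp",
    "self_ii": "inhibitory self-connection–ii",
    "self_dp": "inhibitory self-connection–dp",
    "ii_to_ss": "inhibitory connection–ii to ss",
    "ii_to_sp": "inhibitory connection–ii to sp",
    "ii_to_dp": "inhibitory connection–ii to dp",
    "ss_to_sp": "excitatory connection–ss to sp",
    "ss_to_ii": "excitatory connection–ss to ii",
    "sp_to_dp": "excitatory connection–sp to dp",
    "dp_to_ii": "excitatory connection–dp to ii",
}


def display_name(name: str) -> str:
    """Human-readable report name, e.g. kappa_nmda:Amy -> 'NMDA-Amy'."""
    if name.startswith("kappa_"):
        ch, region = name[len("kappa_"):].split(":")
        return f"{ch.upper()}-{region}"
    if name.startswith("G:"):
        _, region, conn = name.split(":")
        return f"{region}: {_CONN_TEXT.get(conn, conn)}"
    return name


def bmr_report(res: SecondLevelResult, threshold: float = 0.95) -> pd.DataFrame:
    """Tables-style report: per (parameter, covariate) effect Ep and Pp.

    Pp compares the full model evidence with a reduced model whose prior
    variance for that coefficient is shrunk to 1e-8 (effect pinned to 0).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be inside (0, 1)")
    rows = []
    pri = res.priors
    full_var = np.full(4, pri.beta_var)
    eps_var = 1e-8
    delta = 1.0 / eps_var - 1.0 / pri.beta_var
    for j, name in enumerate(res.param_names):
        if res._mv is None:
            y, sv, s2 = res._ys[j], res._svar[j], res.sigma2[j]
            _, _, logZ_full = _evidence(y, res.design.X, sv, full_var, s2)
        for c, cov in enumerate(COVARIATES):
            if res._mv is not None:
                # rank-1 Bayesian model reduction on the joint posterior
                k = c * res._mv["P"] + j
                mk = res._mv["m"][k]
                ckk = res._mv["Ckk"][k]
                dF = -0.5 * (-delta * mk ** 2 / (1 + delta * ckk)
                             + np.log(pri.beta_var / eps_var)
                             - np.log1p(delta * ckk))
            else:
                red = full_var.copy()
                red[c] = eps_var
                _, _, logZ_red = _evidence(y, res.design.X, res._svar[j],
                                           red, res.sigma2[j])
                dF = logZ_full - logZ_red
            pp = 1.0 / (1.0 + np.exp(-np.clip(dF, -700, 700)))
            rows.append({
                "block": param_block(name),
                "parameter": display_name(name),
                "param_name": name,
                "covariate": cov,
                "Ep": res.beta[j, c],
                "Pp": pp,
                "meaningful": bool(pp >= threshold),
            })
    df = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(COVARIATES)}
    df = df.sort_values(["covariate", "block", "param_name"],
                        key=lambda s: s.map(order) if s.name == "covariate" else s
                        ).reset_index(drop=True)
    return df
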