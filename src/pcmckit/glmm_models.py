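"""Binomial mixed-model registry (analyses 1-6'), dataset assembly, and fitting.

Models are logistic GLMMs with crossed random intercepts for the focal
subject and the former opponent (random slopes attempted where applicable,
dropped deterministically on non-convergence).  Fitting maximizes the
Laplace-approximate marginal likelihood; full-vs-null comparisons use
likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from . import pcmc_core
from .behavior_io import PCMCPair, Session

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODEL_IDS",
    "model_spec",
    "assemble_model_table",
    "fit_model",
    "fit_logistic_glm",
    "likelihood_ratio_test",
    "SeparationError",
]

BEHAVIOR_TYPE_LEVELS = (
    "contact_or_approach_only",  # reference level
    "vocal_only",
    "vocal_with_contact_or_approach",
)


class SeparationError(RuntimeError):
    """Response is degenerate or separated; coefficients are not estimable."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one analysis in the registry."""

    model_id: str
    response: str
    session_subset: str  # pc | pc_and_mc_all | pc_and_mc_affiliation | pc_affiliation
    roles: tuple[str, ...]
    fixed_effects: tuple[str, ...]
    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)
    random_slopes_applicable: bool = True


_REGISTRY: dict[str, ModelSpec] = {
    "M1": ModelSpec(
        model_id="M1",
        response="affiliation_with_opponent",
        session_subset="pc",
        roles=("aggressor", "victim"),
        fixed_effects=(
            "physical_aggression",
            "counter_aggression",
            "rank_difference",
            "familiarity",
        ),
    ),
    "M2": ModelSpec(
        model_id="M2",
        response="received_aggression_any",
        session_subset="pc_and_mc_all",
        roles=("aggressor", "victim"),
        fixed_effects=("is_pc",),
    ),
    "M3": ModelSpec(
        model_id="M3",
        response="received_aggression_from_opponent",
        session_subset="pc",
        roles=("victim",),
        fixed_effects=(
            "affiliation_with_opponent",
            "physical_aggression",
            "counter_aggression",
            "rank_difference",
            "familiarity",
        ),
    ),
    "M4": ModelSpec(
        model_id="M4",
        response="vocal_used_toward_partner",
        session_subset="pc_and_mc_affiliation",
        roles=("aggressor", "victim"),
        fixed_effects=("is_pc",),
    ),
    "M5": ModelSpec(
        model_id="M5",
        response="vocal_used_toward_opponent",
        session_subset="pc_affiliation",
        roles=("victim",),
        fixed_effects=(
            "physical_aggression",
            "counter_aggression",
            "rank_difference",
            "familiarity",
        ),
    ),
    "M6": ModelSpec(
        model_id="M6",
        response="received_aggression_from_opponent",
        session_subset="pc_affiliation",
        roles=("victim",),
        # counter-aggression deliberately absent: not estimable in this subset
        fixed_effects=(
            "physical_aggression",
            "rank_difference",
            "familiarity",
            "vocal_used_toward_opponent",
        ),
    ),
    "M6prime": ModelSpec(
        model_id="M6prime",
        response="received_aggression_from_opponent",
        session_subset="pc_affiliation",
        roles=("victim",),
        fixed_effects=(
            "physical_aggression",
            "rank_difference",
            "familiarity",
            "behavior_type",
        ),
        categorical={"behavior_type": BEHAVIOR_TYPE_LEVELS},
    ),
}

MODEL_IDS = tuple(_REGISTRY)


def model_spec(model_id: str) -> ModelSpec:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; known: {MODEL_IDS}") from None


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _lookup_familiarity(familiarity, a: str, b: str, when) -> float | None:
    if familiarity is None:
        return None
    if callable(familiarity):
        return familiarity(a, b, when)
    return familiarity.get((a, b))


def _session_row(
    session: Session, pair: PCMCPair, familiarity, ranks: dict[str, int]
) -> dict | None:
    subject, opponent = session.focal, session.opponent
    fam = _lookup_familiarity(familiarity, subject, opponent, session.date_time.date())
    r_subj, r_opp = ranks.get(subject), ranks.get(opponent)
    if fam is None or r_subj is None or r_opp is None:
        logger.info(
            "dropping session %s: missing %s",
            session.session_id,
            "familiarity" if fam is None else "rank",
        )
        return None
    is_pc = session.kind == "PC"
    scope = pcmc_core.OPPONENT_ONLY if is_pc else pcmc_core.ANY_PARTNER
    affil_t = pcmc_core.first_affiliation_time(session, pcmc_core.OPPONENT_ONLY)
    row = {
        "pair_id": pair.pair_id,
        "session_id": session.session_id,
        "subject": subject,
        "opponent": opponent,
        "role": session.focal_role,
        "is_pc": float(is_pc),
        "physical_aggression": float(session.conflict_physical),
        "counter_aggression": float(session.conflict_counter),
        "rank_difference": float(r_subj - r_opp),
        "familiarity": float(fam),
        "affiliation_with_opponent": float(affil_t is not None),
        "affiliation_with_partner": float(
            pcmc_core.first_affiliation_time(session, scope) is not None
        ),
        "received_aggression_any": float(pcmc_core.received_aggression_any(session)),
        "vocal_used_toward_opponent": float(
            pcmc_core.vocal_given(session, pcmc_core.OPPONENT_ONLY)
        ),
        "vocal_used_toward_partner": float(pcmc_core.vocal_given(session, scope)),
    }
    if is_pc:
        row["received_aggression_from_opponent"] = float(
            pcmc_core.aggression_exposure(session, affil_t)
        )
        bt = pcmc_core.affiliation_behavior_type(session, pcmc_core.OPPONENT_ONLY)
    else:
        row["received_aggression_from_opponent"] = float("nan")
        bt = pcmc_core.affiliation_behavior_type(session, scope)
    row["behavior_type"] = bt if bt is not None else ""
    return row


def assemble_model_table(
    pairs: list[PCMCPair],
    familiarity,
    ranks: dict[str, int],
    spec: ModelSpec,
    role: str,
) -> pd.DataFrame:
    """One analysis row per session in the spec's subset for one focal role.

    ``familiarity`` is a ``dict[(subject, opponent)] -> index`` or a callable
    ``(subject, opponent, date) -> index``; rows with an undefined covariate
    are dropped (logged), never zero-filled.
    """
    if role not in spec.roles:
        raise ValueError(f"{spec.model_id} is not defined for role {role!r}")
    rows = []
    for pair in pairs:
        if pair.focal_role != role:
            continue
        if spec.session_subset in ("pc", "pc_affiliation"):
            sessions = [pair.pc]
        else:
            sessions = [pair.pc, pair.mc]
        for s in sessions:
            row = _session_row(s, pair, familiarity, ranks)
            if row is None:
                continue
            if spec.session_subset == "pc_affiliation" and not row["affiliation_with_opponent"]:
                continue
            if spec.session_subset == "pc_and_mc_affiliation" and not row["affiliation_with_partner"]:
                continue
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and spec.response in df.columns:
        df = df[~df[spec.response].isna()].reset_index(drop=True)
    return df


def _design_matrix(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Fixed-effect design with intercept; categorical effects expand to
    treatment dummies (first level = reference).  Returns (X, column names,
    continuous-effect names usable as random slopes)."""
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    slope_candidates: list[str] = []
    for fe in spec.fixed_effects:
        if fe in spec.categorical:
            levels = spec.categorical[fe]
            observed = set(table[fe])
            unknown = observed - set(levels) - {""}
            if unknown:
                raise ValueError(f"{fe}: unexpected level(s) {sorted(unknown)}")
            for level in levels[1:]:
                cols.append((table[fe] == level).to_numpy(dtype=float))
                names.append(f"{fe}[{level}]")
        else:
            cols.append(table[fe].to_numpy(dtype=float))
            names.append(fe)
            if table[fe].nunique() > 2:
                slope_candidates.append(fe)
    return np.column_stack(cols), names, slope_candidates


# ---------------------------------------------------------------------------
# Laplace fitting engine
# ---------------------------------------------------------------------------


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _inner_mode(y, X, beta, Z, dvec, b0, max_iter=50, tol=1e-9):
    """Newton maximization of the penalized joint loglik over random effects."""
    b = b0.copy()
    xb = X @ beta

    def obj(b):
        eta = xb + Z @ b
        return _bernoulli_loglik(y, eta) - 0.5 * np.sum((b / dvec) ** 2)

    f = obj(b)
    for _ in range(max_iter):
        eta = xb + Z @ b
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = Z.T @ (y - mu) - b / dvec**2
        H = Z.T @ (w[:, None] * Z)
        H[np.diag_indices_from(H)] += 1.0 / dvec**2
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            f_new = obj(b + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        b = b + t * step
        gain, f = f_new - f, f_new
        if abs(gain) < tol:
            break
    return b, f


def _laplace_nll_factory(y, X, Z, col_term, n_terms):
    p = X.shape[1]
    cache = {"b": np.zeros(Z.shape[1]) if Z is not None else None}

    def nll(params):
        beta = params[:p]
        if Z is None or n_terms == 0:
            return -_bernoulli_loglik(y, X @ beta)
        sig = np.exp(params[p:])
        dvec = sig[col_term]
        b, _ = _inner_mode(y, X, beta, Z, dvec, cache["b"])
        cache["b"] = b
        eta = X @ beta + Z @ b
        mu = expit(eta)
        w = mu * (1.0 - mu)
        ZWZ = Z.T @ (w[:, None] * Z)
        M = dvec[:, None] * ZWZ * dvec[None, :]
        M[np.diag_indices_from(M)] += 1.0
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return 1e10
        ll = (
            _bernoulli_loglik(y, eta)
            - 0.5 * np.sum((b / dvec) ** 2)
            - 0.5 * logdet
        )
        return -ll

    return nll, cache


@dataclass
class FitResult:
    """Fitted GLMM: per-term Wald summaries plus the Laplace log-likelihood."""

    model_id: str
    role: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    random_structure: list[str]
    random_sd: dict[str, float]
    converged: bool
    notes: list[str] = field(default_factory=list)
    lrt_vs_null: tuple[float, int, float] | None = None

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p_wald(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def coefficient(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return float(self.beta[i]), float(self.se[i])

    def to_dict(self) -> dict:
        out = {
            "model_id": self.model_id,
            "role": self.role,
            "n": self.n,
            "loglik": self.loglik,
            "converged": self.converged,
            "random_structure": self.random_structure,
            "random_sd": self.random_sd,
            "notes": self.notes,
            "coefficients": [
                {
                    "term": t,
                    "beta": float(b),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                }
                for t, b, s, z, p in zip(self.terms, self.beta, self.se, self.z, self.p_wald)
            ],
        }
        if self.lrt_vs_null is not None:
            chi2, df, p = self.lrt_vs_null
            out["lrt_vs_null"] = {"chi2": chi2, "df": df, "p": p}
        return out


def _build_random_design(
    table: pd.DataFrame, structure: list[str]
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Z matrix and per-column term indices for terms like ``"subject"``
    (intercept) or ``"subject:familiarity"`` (independent random slope)."""
    if not structure:
        return None, None
    blocks, col_term = [], []
    for t_idx, term in enumerate(structure):
        factor, _, value_col = term.partition(":")
        codes, levels = pd.factorize(table[factor], sort=True)
        Zt = np.zeros((len(table), len(levels)))
        vals = table[value_col].to_numpy(dtype=float) if value_col else np.ones(len(table))
        Zt[np.arange(len(table)), codes] = vals
        blocks.append(Zt)
        col_term.extend([t_idx] * len(levels))
    return np.hstack(blocks), np.array(col_term)


def _fit_once(y, X, table, structure, x0_beta=None):
    p = X.shape[1]
    Z, col_term = _build_random_design(table, structure)
    n_terms = len(structure)
    nll, cache = _laplace_nll_factory(y, X, Z, col_term, n_terms)
    beta0 = x0_beta if x0_beta is not None else _logistic_start(y, X)
    x0 = np.concatenate([beta0, np.full(n_terms, np.log(0.5))])
    bounds = [(None, None)] * p + [(-7.0, 2.5)] * n_terms
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    beta = res.x[:p]
    sig = np.exp(res.x[p:]) if n_terms else np.empty(0)
    loglik = -res.fun

    # Wald covariance: fixed-effect block of the inverse joint Hessian
    if Z is not None and n_terms:
        dvec = sig[col_term]
        b, _ = _inner_mode(y, X, beta, Z, dvec, cache["b"])
        eta = X @ beta + Z @ b
        mu = expit(eta)
        w = mu * (1.0 - mu)
        Hbb = X.T @ (w[:, None] * X)
        Hbu = X.T @ (w[:, None] * Z)
        Huu = Z.T @ (w[:, None] * Z)
        Huu[np.diag_indices_from(Huu)] += 1.0 / dvec**2
        S = Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T)
    else:
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        S = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(S)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    converged = bool(res.success) and np.all(np.isfinite(se)) and np.max(np.abs(beta)) < 15
    return beta, se, sig, loglik, converged, res


def _logistic_start(y, X):
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = X.T @ (w[:, None] * X)
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H + 1e-8 * np.eye(X.shape[1]), g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
        np.clip(beta, -15, 15, out=beta)
    return beta


def fit_logistic_glm(y, X) -> tuple[np.ndarray, float]:
    """Plain logistic regression (no random effects): coefficients + loglik.

    This is what :func:`fit_model` reduces to when every random-effect
    variance is forced to zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = _logistic_start(y, X)
    return beta, _bernoulli_loglik(y, X @ beta)


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    role: str | None = None,
    random_slopes: bool = True,
    fixed_effects_override: tuple[str, ...] | None = None,
    force_zero_variance: bool = False,
) -> FitResult:
    """Fit one registry model on an assembled table.

    Random structure starts from intercepts for subject and opponent plus
    (when ``random_slopes``) independent subject/opponent slopes for each
    continuous fixed effect; on non-convergence slopes are dropped one at a
    time in reverse order and the final structure is recorded in ``notes``.
    """
    if table.empty:
        raise ValueError(f"{spec.model_id}: empty analysis table")
    role = role or (table["role"].iloc[0] if "role" in table else "all")
    y = table[spec.response].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError(
            f"{spec.model_id}: response {spec.response!r} is constant (n={len(y)})"
        )
    work_spec = spec
    if fixed_effects_override is not None:
        work_spec = ModelSpec(
            model_id=spec.model_id,
            response=spec.response,
            session_subset=spec.session_subset,
            roles=spec.roles,
            fixed_effects=fixed_effects_override,
            categorical={
                k: v for k, v in spec.categorical.items() if k in fixed_effects_override
            },
        )
    X, names, slope_candidates = _design_matrix(table, work_spec)

    notes: list[str] = []
    if force_zero_variance:
        structures: list[list[str]] = [[]]
    else:
        base = ["subject", "opponent"]
        slopes = []
        if random_slopes and spec.random_slopes_applicable:
            for fe in slope_candidates:
                slopes.extend([f"subject:{fe}", f"opponent:{fe}"])
        full = base + slopes
        # reduction path: drop slopes from the end, then keep intercepts only
        structures = [full[: len(base) + k] for k in range(len(slopes), -1, -1)]

    last = None
    for structure in structures:
        beta, se, sig, loglik, converged, res = _fit_once(y, X, table, structure)
        last = (beta, se, sig, loglik, converged, structure)
        if converged:
            if structure != structures[0]:
                notes.append(
                    f"random slopes reduced to {structure} after non-convergence"
                )
            break
    beta, se, sig, loglik, converged, structure = last
    if not converged:
        notes.append("fit did not converge under any random structure")
    if np.max(np.abs(beta)) >= 10:
        notes.append("possible separation: |beta| >= 10")
    return FitResult(
        model_id=spec.model_id,
        role=role,
        terms=names,
        beta=beta,
        se=se,
        loglik=loglik,
        n=len(y),
        random_structure=list(structure),
        random_sd={t: float(s) for t, s in zip(structure, sig)},
        converged=converged,
        notes=notes,
    )


def fit_null_model(
    table: pd.DataFrame, spec: ModelSpec, role: str | None = None
) -> FitResult:
    """Intercept-only model with random intercepts (the 'null' model)."""
    return fit_model(
        table, spec, role=role, random_slopes=False, fixed_effects_override=()
    )


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Full-vs-reduced LRT: ``(chi2, df, p)``.

    Requires the reduced fixed effects to be a subset of the full ones and
    both fits to use the same rows.
    """
    if full.n != reduced.n:
        raise ValueError(f"row mismatch: {full.n} vs {reduced.n}")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms are not nested in the full model")
    df = len(full.terms) - len(reduced.terms)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -1e-4:
            logger.warning("negative LRT chi2 %.3g clipped to 0", chi2)
        chi2 = 0.0
    p = 1.0 if df == 0 else float(chi2_dist.sf(chi2, df))
    return float(chi2), df, p


def fit_with_lrt(
    table: pd.DataFrame, spec: ModelSpec, role: str | None = None,
    random_slopes: bool = True,
) -> FitResult:
    """Fit the full model and attach the full-vs-null LRT."""
    full = fit_model(table, spec, role=role, random_slopes=random_slopes)
    null = fit_null_model(table, spec, role=role)
    full.lrt_vs_null = likelihood_ratio_test(full, null)
    return full
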