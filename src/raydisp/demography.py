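"""Cormack-Jolly-Seber survival, static life tables and replacement survival.

The CJS model estimates apparent survival (phi) and recapture probability
(p) from encounter histories conditioned on first capture.  Fits use the
m-array sufficient statistics and numerical maximum likelihood on the logit
scale with random restarts; models may hold phi and p constant or let them
vary by occasion (time) or by sex.  AICc uses the total number of releases
as the effective sample size.

The static life table couples age-specific adult survival with female-based
fecundity (female fledglings per female, assuming a 1:1 fledgling sex
ratio).  The Euler-Lotka relation sum_x lambda^-x l_x m_x = 1 gives the
population growth rate; solving it at lambda = 1 for the first-year
(fledgling) survival yields the value required to keep the population
constant: s0 = 1 / sum_x (prod_{i<x} phi_i) m_x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, xlogy

__all__ = [
    "CJSFit",
    "LifeTable",
    "build_encounter_histories",
    "build_marray",
    "cjs_loglik",
    "fit_cjs",
    "build_life_table",
    "solve_first_year_survival",
    "recovery_ratio",
]


@dataclass
class CJSFit:
    phi_structure: str  # 'constant' | 'time' | 'sex'
    p_structure: str
    phi: dict  # label -> estimate
    phi_se: dict
    p: dict
    p_se: dict
    log_lik: float
    n_params: int
    ess: int  # effective sample size (total releases)
    aicc: float
    converged: bool
    flags: list = field(default_factory=list)
    terminal_product: float | None = None  # phi_{K-1} * p_K when confounded


@dataclass
class LifeTable:
    ages: np.ndarray  # 1..A (first breeding age is 1)
    survivorship: np.ndarray  # l_x including first-year survival
    fecundity: np.ndarray  # m_x, female fledglings per female
    first_year_survival: float
    growth_rate: float  # lambda from Euler-Lotka; 0 flags a sterile schedule
    degenerate: bool = False


# --------------------------------------------------------------------------
# encounter histories and the m-array
# --------------------------------------------------------------------------

def build_encounter_histories(
    captures: pd.DataFrame, stage: str = "adult"
) -> tuple[np.ndarray, np.ndarray, list]:
    """Binary detection matrix over the observed span of years.

    Returns ``(histories, sexes, years)``: histories is (n_individuals,
    n_occasions) over consecutive calendar years; individuals without any
    record at the requested stage are dropped.
    """
    rec = captures[captures["stage"] == stage]
    if len(rec) == 0:
        raise ValueError(f"no {stage!r} records")
    years = list(range(int(rec["year"].min()), int(rec["year"].max()) + 1))
    ids = rec["individual_id"].unique()
    col = {y: j for j, y in enumerate(years)}
    H = np.zeros((len(ids), len(years)), dtype=int)
    row = {i: k for k, i in enumerate(ids)}
    for r in rec.itertuples(index=False):
        H[row[r.individual_id], col[int(r.year)]] = 1
    sex = rec.groupby("individual_id")["sex"].first().reindex(ids).to_numpy()
    return H, sex, years


def build_marray(histories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Releases R_i and the m-array m[i, j] of first recaptures at j > i."""
    H = np.asarray(histories)
    n, K = H.shape
    R = np.zeros(K, dtype=int)
    m = np.zeros((K, K), dtype=int)
    for h in H:
        occ = np.flatnonzero(h)
        for a, b in zip(occ[:-1], occ[1:]):
            R[a] += 1
            m[a, b] += 1
        if occ.size and occ[-1] < K - 1:
            R[occ[-1]] += 1  # released after final detection, never seen again
    return R, m


def cjs_loglik(phi: np.ndarray, p: np.ndarray, R: np.ndarray, m: np.ndarray) -> float:
    """CJS multinomial log-likelihood from the m-array.

    ``phi`` has K-1 entries (survival occasion i -> i+1), ``p`` has K-1
    entries (detection at occasions 2..K).
    """
    K = len(R)
    ll = 0.0
    for i in range(K - 1):
        if R[i] == 0:
            continue
        probs = np.zeros(K)
        surv = 1.0
        for j in range(i + 1, K):
            surv *= phi[j - 1]
            probs[j] = surv * p[j - 1]
            surv *= 1.0 - p[j - 1]
        chi = max(1.0 - probs[i + 1:].sum(), 0.0)
        never = R[i] - m[i, i + 1:].sum()
        ll += float(xlogy(m[i, i + 1:], probs[i + 1:]).sum() + xlogy(never, chi))
    return ll


# --------------------------------------------------------------------------
# maximum-likelihood fit
# --------------------------------------------------------------------------

_STRUCTURES = ("constant", "time", "sex")


def _param_map(structure: str, K: int, groups: list) -> list:
    if structure == "constant":
        return ["const"]
    if structure == "time":
        return [f"t{i}" for i in range(1, K)]
    return [f"sex_{g}" for g in groups]


def _expand(structure: str, values: np.ndarray, K: int, groups: list) -> dict:
    """Per-group per-occasion probability vectors from the raw parameters."""
    out = {}
    for gi, g in enumerate(groups):
        if structure == "constant":
            out[g] = np.full(K - 1, values[0])
        elif structure == "time":
            out[g] = values.copy()
        else:
            out[g] = np.full(K - 1, values[gi])
    return out


def fit_cjs(
    histories: np.ndarray,
    sexes: np.ndarray | None = None,
    phi_structure: str = "constant",
    p_structure: str = "constant",
    n_restarts: int = 5,
    seed: int = 0,
) -> CJSFit:
    """Fit a CJS model by maximum likelihood on the logit scale.

    ``sexes`` is required for the 'sex' structures.  With both phi and p
    fully time dependent the terminal phi_{K-1} and p_K are confounded; the
    fit then reports their product and flags the confounding.
    """
    H = np.asarray(histories)
    n, K = H.shape
    if K < 2:
        raise ValueError("need >= 2 occasions")
    if phi_structure not in _STRUCTURES or p_structure not in _STRUCTURES:
        raise ValueError("unknown model structure")
    needs_sex = "sex" in (phi_structure, p_structure)
    if needs_sex and sexes is None:
        raise ValueError("sex-structured model requires per-individual sexes")
    groups = sorted(set(sexes)) if needs_sex else ["all"]
    marrays = {}
    for g in groups:
        sub = H if g == "all" else H[np.asarray(sexes) == g]
        marrays[g] = build_marray(sub)

    phi_lab = _param_map(phi_structure, K, groups)
    p_lab = _param_map(p_structure, K, groups)
    k_phi, k_p = len(phi_lab), len(p_lab)

    def negll(theta: np.ndarray) -> float:
        phi_v = expit(theta[:k_phi])
        p_v = expit(theta[k_phi:])
        phis = _expand(phi_structure, phi_v, K, groups)
        ps = _expand(p_structure, p_v, K, groups)
        ll = 0.0
        for g in groups:
            R, m = marrays[g]
            ll += cjs_loglik(phis[g], ps[g], R, m)
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    bounds = [(-15.0, 15.0)] * (k_phi + k_p)
    for r in range(max(1, n_restarts)):
        x0 = rng.normal(0.0, 1.0, size=k_phi + k_p) if r else np.zeros(k_phi + k_p)
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("CJS optimization failed to produce a finite likelihood")

    theta = best.x
    phi_hat = expit(theta[:k_phi])
    p_hat = expit(theta[k_phi:])
    se = _delta_se(negll, theta)
    phi_se = se[:k_phi] * phi_hat * (1 - phi_hat)
    p_se = se[k_phi:] * p_hat * (1 - p_hat)

    flags: list[str] = []
    if K == 2:
        flags.append("two occasions: only the product phi*p is identifiable")
    confounded = phi_structure == "time" and p_structure == "time"
    if confounded:
        flags.append("terminal phi and p confounded; reporting their product")
    if np.any(phi_hat > 1 - 1e-4) or np.any(p_hat > 1 - 1e-4) \
            or np.any(phi_hat < 1e-4) or np.any(p_hat < 1e-4):
        flags.append("boundary estimate")

    n_params = k_phi + k_p - (1 if confounded else 0)
    ess = int(sum(marrays[g][0].sum() for g in groups))
    ll = -float(best.fun)
    denom = ess - n_params - 1
    aicc = -2 * ll + 2 * n_params + (
        (2 * n_params * (n_params + 1)) / denom if denom > 0 else np.inf
    )
    return CJSFit(
        phi_structure, p_structure,
        dict(zip(phi_lab, phi_hat.tolist())), dict(zip(phi_lab, phi_se.tolist())),
        dict(zip(p_lab, p_hat.tolist())), dict(zip(p_lab, p_se.tolist())),
        ll, n_params, ess, float(aicc), bool(best.success), flags,
        float(phi_hat[-1] * p_hat[-1]) if confounded else None,
    )


def _delta_se(negll, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """SEs on the logit scale from a finite-difference Hessian (0 if singular)."""
    k = len(theta)
    Hm = np.zeros((k, k))
    f0 = negll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            Hm[i, j] = Hm[j, i] = (
                negll(theta + ei + ej) - negll(theta + ei)
                - negll(theta + ej) + f0
            ) / eps**2
    try:
        cov = np.linalg.inv(Hm)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, 0.0))
    except np.linalg.LinAlgError:
        return np.zeros(k)


# --------------------------------------------------------------------------
# static life table and Euler-Lotka
# --------------------------------------------------------------------------

def build_life_table(
    phi_by_age, fecundity_by_age, first_year_survival: float = 1.0
) -> LifeTable:
    """Static life table over breeding ages 1..A.

    ``phi_by_age`` holds adult survival from age x to x+1 (length A-1);
    ``fecundity_by_age`` holds m_x for ages 1..A.  Survivorship is
    l_x = s0 * prod_{i<x} phi_i.  The growth rate solves Euler-Lotka;
    an all-zero fecundity schedule is flagged degenerate (growth_rate 0).
    """
    m = np.asarray(fecundity_by_age, dtype=float)
    if m.size == 0:
        raise ValueError("empty fecundity schedule")
    if (m < 0).any():
        raise ValueError("fecundity must be nonnegative")
    phi = np.asarray(phi_by_age, dtype=float)
    if phi.size != m.size - 1:
        raise ValueError("phi_by_age must have one entry fewer than fecundity_by_age")
    s0 = float(first_year_survival)
    lx = s0 * np.concatenate([[1.0], np.cumprod(phi)])
    ages = np.arange(1, m.size + 1)
    if not (lx * m).sum() > 0:
        return LifeTable(ages, lx, m, s0, 0.0, degenerate=True)

    def euler_lotka(lam: float) -> float:
        return float((lam ** (-ages.astype(float)) * lx * m).sum() - 1.0)

    lo, hi = 1e-6, 2.0
    while euler_lotka(hi) > 0:
        hi *= 2.0
    lam = float(optimize.brentq(euler_lotka, lo, hi, xtol=1e-12))
    return LifeTable(ages, lx, m, s0, lam)


def solve_first_year_survival(phi_by_age, fecundity_by_age) -> float:
    """First-year survival making the population stationary (r = 0).

    s0 = 1 / sum_x (prod_{i<x} phi_i) m_x; values above 1 are reported
    clipped to 1 with a warning (the schedule cannot sustain itself).
    """
    m = np.asarray(fecundity_by_age, dtype=float)
    phi = np.asarray(phi_by_age, dtype=float)
    surv = np.concatenate([[1.0], np.cumprod(phi)])
    denom = float((surv * m).sum())
    if not denom > 0:
        raise ValueError("reproductive value is zero; no finite s0 exists")
    s0 = 1.0 / denom
    if s0 > 1.0:
        import warnings

        warnings.warn(
            f"required first-year survival {s0:.3f} exceeds 1; reporting 1.0",
            stacklevel=2,
        )
        return 1.0
    return s0


def recovery_ratio(recaptured: int, marked: int, s0: float) -> float:
    """Recaptured fledglings relative to the expected number of survivors."""
    if marked <= 0:
        raise ValueError("marked must be > 0")
    if not 0 < s0 <= 1:
        raise ValueError("s0 must be in (0, 1]")
    return recaptured / (marked * s0)
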