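"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards,
maximally selected cutpoints and ROC/AUC.

The Cox partial likelihood is maximised by Newton-Raphson with the Efron
tie correction by default (Breslow available); convergence requires the
maximum absolute score component to fall below 1e-8. The univariate screen
z-scores each feature first so hazard ratios are per standard deviation and
comparable across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import TMEScoreError, warn

__all__ = [
    "SurvivalData",
    "CoxFit",
    "CutpointResult",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "optimal_cutpoint",
    "roc_auc",
]

_Z975 = stats.norm.ppf(0.975)
_BETA_CAP = 15.0


@dataclass
class SurvivalData:
    times: np.ndarray
    events: np.ndarray
    sample_ids: pd.Index | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.events = np.asarray(self.events)
        if self.times.shape != self.events.shape:
            raise TMEScoreError("times and events must align")
        if self.times.size == 0:
            raise TMEScoreError("empty survival data")
        if (self.times <= 0).any():
            raise TMEScoreError("survival times must be positive")
        if not set(np.unique(self.events)).issubset({0, 1}):
            raise TMEScoreError("events must be 0/1")
        self.events = self.events.astype(int)

    @classmethod
    def from_clinical(cls, clinical) -> "SurvivalData":
        return cls(clinical.os_time, clinical.os_event, clinical.sample_ids)

    def __len__(self) -> int:
        return self.times.size


def _as_surv(surv, events=None) -> SurvivalData:
    if isinstance(surv, SurvivalData):
        return surv
    if events is not None:
        return SurvivalData(surv, events)
    return SurvivalData.from_clinical(surv)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(surv, events=None) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with one row per distinct event time: ``time``,
    ``survival`` (S(t) just after the step), ``at_risk`` and ``events``.
    Censorings reduce the risk set without a step.
    """
    sd = _as_surv(surv, events)
    order = np.argsort(sd.times, kind="mergesort")
    t, e = sd.times[order], sd.events[order]
    n = len(t)
    rows = []
    s = 1.0
    event_times = np.unique(t[e == 1])
    for v in event_times:
        at_risk = int(np.sum(t >= v))
        d = int(np.sum((t == v) & (e == 1)))
        s *= 1.0 - d / at_risk
        rows.append((v, s, at_risk, d))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def _logrank_two_group(times, events, member) -> tuple[float, float]:
    """(chi2, p) for a two-group log-rank split given a boolean membership."""
    event_times = np.unique(times[events == 1])
    O = E = V = 0.0
    for v in event_times:
        at = times >= v
        n = at.sum()
        if n < 2:
            continue
        n1 = (at & member).sum()
        dmask = (times == v) & (events == 1)
        d = dmask.sum()
        d1 = (dmask & member).sum()
        O += d1
        E += d * n1 / n
        V += d * (n - d) / (n - 1) * n1 * (n - n1) / n**2
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def logrank_test(surv, groups, events=None):
    """Multi-group log-rank test; returns (chi2, df, p)."""
    if events is not None:
        sd = SurvivalData(surv, events)
    else:
        sd = _as_surv(surv)
    g = pd.Series(np.asarray(groups))
    levels = g.unique().tolist()
    if len(levels) < 2:
        raise TMEScoreError("log-rank test needs >=2 groups")
    if len(g) != len(sd):
        raise TMEScoreError("groups must align with survival data")
    masks = [np.asarray(g == lev) for lev in levels]
    k = len(levels)
    t, e = sd.times, sd.events
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for v in np.unique(t[e == 1]):
        at = t >= v
        n = at.sum()
        dmask = (t == v) & (e == 1)
        d = dmask.sum()
        ni = np.array([(at & m).sum() for m in masks], float)
        di = np.array([(dmask & m).sum() for m in masks], float)
        O += di
        E += d * ni / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            V += factor * (np.diag(ni / n) - np.outer(ni, ni) / n**2)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: beta, se, hr, z, p, ci_low, ci_high
    loglik: float
    n: int
    n_events: int
    ties: str
    score_chi2: float
    score_p: float
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)


def _cox_quantities(t, e, X, beta, ties):
    """(loglik, score, information) at beta. Rows must be sorted by time."""
    n, p = X.shape
    theta = np.exp(np.clip(X @ beta, -500, 500))
    thx = theta[:, None] * X
    thxx = thx[:, :, None] * X[:, None, :]
    # suffix sums: risk set at time t[i] is {j : t[j] >= t[i]}
    S0 = np.cumsum(theta[::-1])[::-1]
    S1 = np.cumsum(thx[::-1], axis=0)[::-1]
    S2 = np.cumsum(thxx[::-1], axis=0)[::-1]

    loglik = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dmask = e[i:j] == 1
        d = int(dmask.sum())
        if d > 0:
            Didx = np.arange(i, j)[dmask]
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            s0d = theta[Didx].sum()
            s1d = thx[Didx].sum(axis=0)
            s2d = thxx[Didx].sum(axis=0)
            loglik += float((X[Didx] @ beta).sum())
            U += X[Didx].sum(axis=0)
            fracs = np.arange(d) / d if ties == "efron" else np.zeros(d)
            for frac in fracs:
                phi = s0r - frac * s0d
                u1 = s1r - frac * s1d
                u2 = s2r - frac * s2d
                loglik -= np.log(phi)
                U -= u1 / phi
                I += u2 / phi - np.outer(u1, u1) / phi**2
        i = j
    return loglik, U, I


def cox_fit(
    surv,
    covariates,
    ties: str = "efron",
    events=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``covariates`` is an array/DataFrame of shape (n_samples, n_covariates).
    A monotone partial likelihood (perfect separation) is reported with a
    warning and the offending coefficient capped.
    """
    sd = _as_surv(surv, events)
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != len(sd):
        raise TMEScoreError("covariates must align with survival data")
    if ties not in ("efron", "breslow"):
        raise TMEScoreError(f"unknown ties method {ties!r}")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise TMEScoreError(f"constant covariates: {bad}")
    n_events = int(sd.events.sum())
    if n_events < X.shape[1] + 1:
        raise TMEScoreError(f"{n_events} events for {X.shape[1]} covariates: underdetermined")

    order = np.argsort(sd.times, kind="mergesort")
    t, e, Xs = sd.times[order], sd.events[order], X[order]
    p = Xs.shape[1]
    beta = np.zeros(p)
    warns: list[str] = []

    loglik, U, I = _cox_quantities(t, e, Xs, beta, ties)
    score_chi2 = float(U @ np.linalg.solve(I, U))
    score_p = float(stats.chi2.sf(score_chi2, p))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(U)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            warns.append("singular information matrix; using pseudo-inverse")
            step = np.linalg.pinv(I) @ U
        new_beta = beta + step
        new_ll, new_U, new_I = _cox_quantities(t, e, Xs, new_beta, ties)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_U, new_I = _cox_quantities(t, e, Xs, new_beta, ties)
            halvings += 1
        beta, loglik, U, I = new_beta, new_ll, new_U, new_I
        if np.max(np.abs(beta)) > _BETA_CAP:
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            loglik, U, I = _cox_quantities(t, e, Xs, beta, ties)
            warns.append("monotone partial likelihood (perfect separation); coefficient capped")
            break
    else:
        if np.max(np.abs(U)) < tol:
            converged = True
    if np.max(np.abs(U)) < tol:
        converged = True
    if warns:
        for msg in warns:
            warn(msg)

    cov = np.linalg.inv(I)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "z": z,
            "p": pvals,
            "ci_low": np.exp(beta - _Z975 * se),
            "ci_high": np.exp(beta + _Z975 * se),
        },
        index=names,
    )
    return CoxFit(
        summary=summary,
        loglik=float(loglik),
        n=len(sd),
        n_events=n_events,
        ties=ties,
        score_chi2=score_chi2,
        score_p=score_p,
        converged=converged,
        n_iter=it,
        warnings=warns,
    )


def univariate_screen(
    features,
    surv,
    events=None,
    threshold: float = 0.05,
    ties: str = "efron",
) -> pd.DataFrame:
    """One z-scored single-covariate Cox fit per feature row.

    ``features`` is a DataFrame (features x samples). Returns a frame with
    beta, se, hr, z, p, representative (p < threshold) and skipped
    (zero-variance) flags; hazard ratios are per SD of the feature.
    """
    sd = _as_surv(surv, events)
    F = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    rows = []
    for name, row in F.iterrows():
        x = row.to_numpy(float)
        s = x.std()
        if s == 0:
            rows.append({"feature": name, "beta": np.nan, "se": np.nan, "hr": np.nan,
                         "z": np.nan, "p": np.nan, "representative": False, "skipped": True})
            continue
        z = (x - x.mean()) / s
        fit = cox_fit(sd, z[:, None], ties=ties)
        rec = fit.summary.iloc[0]
        rows.append({
            "feature": name, "beta": rec["beta"], "se": rec["se"], "hr": rec["hr"],
            "z": rec["z"], "p": rec["p"], "representative": bool(rec["p"] < threshold),
            "skipped": False,
        })
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Maximally selected cutpoint and AUC
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    cutoff: float
    chi2: float
    p: float  # naive (uncorrected for the maximisation)
    p_permutation: float | None = None


def optimal_cutpoint(
    score,
    surv,
    events=None,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank split of a continuous score.

    Every split leaving at least ``minprop`` of the samples on each side is
    evaluated; the returned cutoff is the midpoint of the best split. The
    naive p ignores the maximisation multiplicity (warned); with
    ``n_permutations > 0`` a permutation-adjusted p (score permuted against
    survival) is also reported.
    """
    sd = _as_surv(surv, events)
    s = np.asarray(score, float)
    if s.std() == 0:
        raise TMEScoreError("score is constant; no cutpoint exists")
    if not 0 < minprop < 0.5:
        raise TMEScoreError("minprop must be in (0, 0.5)")
    n = len(s)
    t, e = sd.times, sd.events

    def scan(values):
        uniq = np.unique(values)
        best = (-1.0, None)
        for i in range(len(uniq) - 1):
            member = values > uniq[i]
            n_hi = member.sum()
            if min(n_hi, n - n_hi) < minprop * n:
                continue
            chi2, _ = _logrank_two_group(t, e, member)
            if chi2 > best[0]:
                best = (chi2, 0.5 * (uniq[i] + uniq[i + 1]))
        return best

    chi2, cutoff = scan(s)
    if cutoff is None:
        raise TMEScoreError("no admissible split satisfies the minprop constraint")
    p_naive = float(stats.chi2.sf(chi2, 1))
    warn("optimal_cutpoint: naive p ignores the cutpoint-selection multiplicity")

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            null[b] = scan(rng.permutation(s))[0]
        p_perm = float(np.mean(null >= chi2))
    return CutpointResult(cutoff=float(cutoff), chi2=float(chi2), p=p_naive, p_permutation=p_perm)


def roc_auc(score, label) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    y = np.asarray(label)
    if len(np.unique(y)) != 2:
        raise TMEScoreError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(score, float)))
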