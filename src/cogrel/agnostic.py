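"""Model-free behavioural measures and their trial-level GLMM counterparts.

Bandit: the probability of repeating the previous choice (staying) after
each outcome class of the previous trial — win-only (reward 1, punishment
0), loss-only (0, -1), and neither (0, 0). Trials whose previous outcome
delivered both a win and a loss are excluded from these three classes
(the model-based likelihood still uses them).

Gamble: the proportion of gamble choices on mixed and on gain-only trials
of the calibrated phase.

Both measures also exist in trial-level form: a mixed-effects logistic
regression with subject and subject-within-session random intercepts,
fit to both sessions jointly, whose variance components give a one-way
random-effects absolute-agreement single-measure ICC,

    ICC(1) = var_subject / (var_subject + var_subject_within_session).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "p_stay",
    "p_gamble",
    "stay_table",
    "gamble_rate_table",
    "stay_trials",
    "glmm_icc",
    "glmm_subject_effects",
]


def _classify_prev(reward, punishment):
    """Outcome class of a trial: win / loss / neither / both."""
    if reward == 1 and punishment == 0:
        return "win"
    if reward == 0 and punishment == -1:
        return "loss"
    if reward == 0 and punishment == 0:
        return "neither"
    return "both"


def stay_trials(choice, reward, punishment) -> pd.DataFrame:
    """Trial-level stay data: one row per trial t >= 2.

    Columns: prev_outcome (win/loss/neither/both), stay (0/1).
    """
    choice = np.asarray(choice)
    reward = np.asarray(reward)
    punishment = np.asarray(punishment)
    if len(choice) < 2:
        raise ValueError("need at least 2 trials")
    rows = []
    for t in range(1, len(choice)):
        rows.append({
            "prev_outcome": _classify_prev(reward[t - 1], punishment[t - 1]),
            "stay": int(choice[t] == choice[t - 1]),
        })
    return pd.DataFrame(rows)


def p_stay(choice, reward, punishment) -> dict:
    """Stay probabilities after win-only, loss-only and neither outcomes.

    Returns proportions plus denominators; a class that never occurred
    yields NaN (missing), not zero.
    """
    st = stay_trials(choice, reward, punishment)
    out = {}
    for cls in ("win", "loss", "neither"):
        sub = st[st.prev_outcome == cls]
        out[f"p_stay_{cls}"] = sub.stay.mean() if len(sub) else np.nan
        out[f"n_{cls}"] = len(sub)
    return out


def p_gamble(trial_type, gambled) -> dict:
    """Gamble rates on mixed and gain-only trials."""
    trial_type = np.asarray(trial_type, dtype=object)
    gambled = np.asarray(gambled, dtype=float)
    out = {}
    for cls, key in (("mixed", "p_gamble_mixed"), ("gain", "p_gamble_gain")):
        m = trial_type == cls
        out[key] = gambled[m].mean() if m.any() else np.nan
        out[f"n_{cls}"] = int(m.sum())
    return out


def stay_table(bandit_df: pd.DataFrame) -> pd.DataFrame:
    """Per subject-session stay probabilities for a tidy bandit table."""
    rows = []
    for (subj, sess), g in bandit_df.groupby(["subject", "session"], sort=True):
        g = g.sort_values("trial")
        row = {"subject": subj, "session": sess}
        row.update(p_stay(g["choice"], g["reward"], g["punishment"]))
        rows.append(row)
    return pd.DataFrame(rows)


def gamble_rate_table(gamble_df: pd.DataFrame, phase="calibrated") -> pd.DataFrame:
    """Per subject-session gamble rates for the calibrated phase."""
    if "phase" in gamble_df.columns:
        gamble_df = gamble_df[gamble_df["phase"] == phase]
    rows = []
    for (subj, sess), g in gamble_df.groupby(["subject", "session"], sort=True):
        row = {"subject": subj, "session": sess}
        row.update(p_gamble(g["trial_type"], g["gambled"]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trial-level mixed-effects logistic regression
# ---------------------------------------------------------------------------


@dataclass
class GlmmIccResult:
    icc1: float
    var_subject: float
    var_subject_session: float
    converged: bool
    detail: object = None


def _glmm_frame(data: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Binary trial-level response with fixed-effect predictors per measure."""
    if measure == "stay":
        frames = []
        for (subj, sess), g in data.groupby(["subject", "session"], sort=True):
            st = stay_trials(g.sort_values("trial")["choice"].to_numpy(),
                             g.sort_values("trial")["reward"].to_numpy(),
                             g.sort_values("trial")["punishment"].to_numpy())
            st = st[st.prev_outcome != "both"]
            st["subject"] = subj
            st["session"] = sess
            frames.append(st.rename(columns={"stay": "y", "prev_outcome": "cond"}))
        return pd.concat(frames, ignore_index=True)
    if measure == "gamble":
        df = data[data["phase"] == "calibrated"] if "phase" in data.columns else data
        return pd.DataFrame({"y": df["gambled"].astype(int).to_numpy(),
                             "cond": df["trial_type"].to_numpy(),
                             "subject": df["subject"].to_numpy(),
                             "session": df["session"].to_numpy()})
    raise ValueError("measure must be 'stay' or 'gamble'")


def _agq_marginal_nll(beta, var_a, var_b, cells, n_nodes=12):
    """Negative marginal log-likelihood of the nested logistic model.

    Subject i's session intercept pair (u_i1, u_i2) is bivariate normal
    with covariance [[A+B, A], [A, A+B]] (A between-subject, B
    subject-within-session). The two-dimensional integral per subject is
    evaluated by adaptive Gauss-Hermite quadrature: nodes are centred and
    scaled at each subject's conditional mode and curvature.

    ``cells`` maps subject -> two per-session tuples (cond_idx, n, succ)
    of aggregated Bernoulli counts.
    """
    from scipy.special import logsumexp as lse

    sigma = np.array([[var_a + var_b, var_a], [var_a, var_a + var_b]])
    try:
        sig_inv = np.linalg.inv(sigma)
        _, logdet = np.linalg.slogdet(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    zz1, zz2 = np.meshgrid(z, z, indexing="ij")
    logw = np.add.outer(np.log(w), np.log(w)).ravel() + (zz1**2 + zz2**2).ravel()
    zgrid = np.column_stack([zz1.ravel(), zz2.ravel()])

    def data_ll(u, per_sess):
        # u: (..., 2); returns summed Bernoulli log-lik over both sessions
        tot = 0.0
        for s in (0, 1):
            cond_idx, n, succ = per_sess[s]
            eta = beta[cond_idx] + u[..., s:s + 1]
            tot = tot + (succ * eta - n * np.logaddexp(0.0, eta)).sum(axis=-1)
        return tot

    def grad_hess(u, per_sess):
        g = -sig_inv @ u
        h = -sig_inv.copy()
        for s in (0, 1):
            cond_idx, n, succ = per_sess[s]
            p = expit(beta[cond_idx] + u[s])
            g[s] += succ.sum() - (n * p).sum()
            h[s, s] -= (n * p * (1 - p)).sum()
        return g, h

    total = 0.0
    for per_sess in cells.values():
        u = np.zeros(2)
        for _ in range(50):  # Newton to the conditional mode
            g, h = grad_hess(u, per_sess)
            step = np.linalg.solve(h, g)
            u = u - step
            if np.abs(step).max() < 1e-9:
                break
        _, h = grad_hess(u, per_sess)
        L = np.linalg.cholesky(np.linalg.inv(-h))
        pts = u + np.sqrt(2.0) * zgrid @ L.T             # (K^2, 2)
        prior = -0.5 * (np.einsum("ki,ij,kj->k", pts, sig_inv, pts)
                        + logdet) - np.log(2 * np.pi)
        f = prior + data_ll(pts, per_sess)
        total += lse(logw + f) + np.log(2.0) + np.log(np.diag(L)).sum()
    return -total


def _glmm_cells(df):
    """Aggregate trials into (cond_idx, n, succ) per subject-session."""
    conds = sorted(df["cond"].unique())
    cmap = {c: i for i, c in enumerate(conds)}
    cells = {}
    for (subj, sess), g in df.groupby(["subject", "session"], sort=True):
        agg = g.groupby("cond")["y"].agg(["count", "sum"])
        tup = (np.array([cmap[c] for c in agg.index]),
               agg["count"].to_numpy(float), agg["sum"].to_numpy(float))
        cells.setdefault(subj, [None, None])[int(sess) - 1] = tup
    cells = {k: v for k, v in cells.items() if v[0] is not None and v[1] is not None}
    return cells, conds


def glmm_icc(data: pd.DataFrame, measure: str, condition=None,
             method="ml", n_nodes=12) -> GlmmIccResult:
    """ICC(1) from the variance components of a joint two-session GLMM.

    Fits a logistic regression of the binary response on the trial
    condition (outcome class or trial type) with random intercepts for
    subject and for subject-within-session, both sessions jointly. The
    default ``method='ml'`` maximises the exact marginal likelihood with
    adaptive Gauss-Hermite quadrature (deterministic). ``'map'`` and
    ``'vb'`` delegate to statsmodels' Laplace and variational
    approximations instead; both are kept for comparison only, since the
    mean-field VB factorisation cannot represent the negative coupling
    between nested intercepts (it collapses the subject component) and
    MAP estimates the variances at the joint mode, which is erratic.
    ``condition`` restricts the data to one condition level (e.g. a
    single outcome class) so the ICC refers to that measure alone.
    """
    df = _glmm_frame(data, measure)
    if condition is not None:
        df = df[df["cond"] == condition].copy()
    if method == "ml":
        return _glmm_icc_ml(df, n_nodes)
    return _glmm_icc_statsmodels(df, condition, method)


def _glmm_icc_ml(df, n_nodes):
    from scipy.optimize import minimize
    from scipy.special import logit

    cells, conds = _glmm_cells(df)
    if len(cells) < 3:
        return GlmmIccResult(np.nan, np.nan, np.nan, False, "need >= 3 subjects")
    C = len(conds)
    # start from empirical logits and moderate variance components
    p0 = np.clip(df.groupby("cond")["y"].mean().reindex(conds).to_numpy(), 0.05, 0.95)
    x0 = np.concatenate([logit(p0), [np.log(0.5), np.log(0.5)]])

    def nll(x):
        return _agq_marginal_nll(x[:C], float(np.exp(2 * x[C])),
                                 float(np.exp(2 * x[C + 1])), cells, n_nodes)

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 4000})
    v_s = float(np.exp(2 * res.x[C]))
    v_ss = float(np.exp(2 * res.x[C + 1]))
    return GlmmIccResult(icc1=v_s / (v_s + v_ss), var_subject=v_s,
                         var_subject_session=v_ss, converged=bool(res.success),
                         detail=res)


def _glmm_icc_statsmodels(df, condition, method):
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df = df.copy()
    df["subj_sess"] = df["subject"].astype(str) + "_" + df["session"].astype(str)
    fixed = "y ~ 1" if condition is not None or df["cond"].nunique() < 2 else "y ~ C(cond)"
    vc = {"subject": "0 + C(subject)", "subj_sess": "0 + C(subj_sess)"}
    try:
        model = BinomialBayesMixedGLM.from_formula(fixed, vc, df)
        fit = model.fit_map() if method == "map" else model.fit_vb()
        var = dict(zip(model.vcp_names, np.exp(fit.vcp_mean) ** 2))
        v_s = float(var["subject"])
        v_ss = float(var["subj_sess"])
        return GlmmIccResult(icc1=v_s / (v_s + v_ss), var_subject=v_s,
                             var_subject_session=v_ss, converged=True, detail=fit)
    except Exception as err:  # non-convergence: flagged, not raised
        return GlmmIccResult(icc1=np.nan, var_subject=np.nan,
                             var_subject_session=np.nan, converged=False,
                             detail=str(err))


def glmm_subject_effects(data: pd.DataFrame, measure: str, session: int,
                         condition=None) -> pd.Series:
    """Per-session GLMM mode: subject random-intercept estimates.

    Fits one session's trial-level logistic regression with a subject
    random intercept and returns the posterior-mean subject effects, which
    can feed the standard paired ICC estimators.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df = _glmm_frame(data[data["session"] == session], measure)
    if condition is not None:
        df = df[df["cond"] == condition].copy()
    fixed = "y ~ 1" if condition is not None or df["cond"].nunique() < 2 else "y ~ C(cond)"
    model = BinomialBayesMixedGLM.from_formula(fixed, {"subject": "0 + C(subject)"}, df)
    fit = model.fit_map()
    subj_ids = [lbl.split("[", 1)[1].rstrip("]") for lbl in model.vc_names]
    return pd.Series(fit.vc_mean, index=subj_ids, name=f"{measure}_s{session}")
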