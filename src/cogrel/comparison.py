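"""Model comparison by PSIS-LOO (leave-one-trial-out by default).

Candidates are scored by the leave-one-out information criterion,
LOOIC = -2 * elpd_loo, where elpd_loo is estimated from pointwise
log-likelihood draws with Pareto-smoothed importance sampling. Lower is
better; the ranked table reports each candidate's LOOIC, its standard
error, the difference to the winner, and the fraction of observations
with Pareto k above 0.7 (unreliable importance ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["PointwiseLogLik", "pointwise_loglik", "looic", "looic_compare"]


@dataclass
class PointwiseLogLik:
    """Draws x observations matrix of log-likelihood values."""

    values: np.ndarray        # (n_draws_total, n_obs)
    name: str = ""
    obs_index: pd.MultiIndex | None = None  # (subject, session, trial)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("pointwise log-lik must be 2-D (draws, observations)")
        if not np.isfinite(self.values).all():
            raise ValueError("pointwise log-lik contains non-finite entries")

    @property
    def n_obs(self):
        return self.values.shape[1]


def pointwise_loglik(posterior, data, max_draws=400, name=None) -> PointwiseLogLik:
    """Per-draw, per-trial log-likelihoods under a fitted posterior.

    Entry (d, t) is log p(choice_t | subject parameters at draw d), with
    the subject's trials scored under that subject's own draw. Draws are
    thinned to at most ``max_draws`` per chain.
    """
    from ._kernels import bandit_trial_logp
    from .fitting import _bandit_arrays, _gamble_arrays
    from .tasks import _pt_trial_logp

    model = posterior.model
    x = posterior.subject_native_draws(max_draws=max_draws)  # (C, D, N, K)
    C, D, N, K = x.shape
    if model.task == "bandit":
        units, ch, rw, pn = _bandit_arrays(data, posterior.session)
    else:
        units, su, ga, lo, gm = _gamble_arrays(data, posterior.session)
    if units != posterior.units:
        raise ValueError("data units do not match the posterior's units")
    T = ch.shape[1] if model.task == "bandit" else su.shape[1]
    out = np.empty((C * D, N * T))
    flat = x.reshape(C * D, N, K)
    for d in range(C * D):
        canon = model.expand(flat[d])
        if model.task == "bandit":
            for i in range(N):
                out[d, i * T:(i + 1) * T] = bandit_trial_logp(
                    ch[i], rw[i], pn[i], canon[i])
        else:
            out[d] = _pt_trial_logp(canon, su, ga, lo, gm).reshape(-1)
    idx = pd.MultiIndex.from_tuples(
        [(s, sess, t + 1) for (s, sess) in units for t in range(T)],
        names=["subject", "session", "trial"])
    return PointwiseLogLik(out, name=name or model.label, obs_index=idx)


def looic(pw: PointwiseLogLik):
    """PSIS-LOO for one candidate: (looic, se, elpd_i, pareto_k).

    Observations whose log-likelihood is constant across draws have
    constant importance ratios, for which leave-one-out is exact and
    equals the pointwise value; Pareto smoothing is applied elsewhere.
    """
    import arviz as az

    ll = pw.values
    S, n = ll.shape
    elpd_i = np.empty(n)
    k_hat = np.zeros(n)
    spread = ll.max(axis=0) - ll.min(axis=0)
    const = spread < 1e-12
    elpd_i[const] = ll[0, const]
    var_cols = np.where(~const)[0]
    if var_cols.size:
        # psislw smooths along the last axis: pass (n_obs, n_draws)
        lw, k = az.psislw(-ll[:, var_cols].T, reff=1.0)
        elpd_i[var_cols] = logsumexp(lw + ll[:, var_cols].T, axis=1)
        k_hat[var_cols] = k
    loo = -2.0 * elpd_i.sum()
    se = 2.0 * np.sqrt(n * np.var(elpd_i))
    return loo, se, elpd_i, k_hat


def looic_compare(candidates, names=None) -> pd.DataFrame:
    """Rank candidates by LOOIC (ascending; rank 1 wins).

    All candidates must score the same observations.
    """
    candidates = list(candidates)
    n_obs = {c.n_obs for c in candidates}
    if len(n_obs) != 1:
        raise ValueError("candidates must be computed on identical data")
    rows = []
    for i, c in enumerate(candidates):
        loo, se, elpd_i, k = looic(c)
        rows.append({
            "model": (names[i] if names else None) or c.name or f"model_{i}",
            "looic": loo, "se": se,
            "pareto_k_frac": float(np.mean(k > 0.7)),
            "_elpd_i": elpd_i,
        })
    df = pd.DataFrame(rows).sort_values("looic", ignore_index=True)
    df["delta_looic"] = df["looic"] - df["looic"].iloc[0]
    # SE of each delta vs the winner, from the paired pointwise differences
    best = df["_elpd_i"].iloc[0]
    df["delta_se"] = [2.0 * np.sqrt(len(e) * np.var(e - best)) for e in df["_elpd_i"]]
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_elpd_i")
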