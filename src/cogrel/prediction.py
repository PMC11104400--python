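"""Posterior-predictive forecasting of session-2 choices.

How well do parameters estimated in session 1 predict the same person's
choices two weeks later? For each subject the predictive accuracy is the
mean probability the generative model assigns to the choices the subject
actually made in session 2 (for the bandit, Q-values evolve along the
observed session-2 choices and outcomes). Three predictors are compared:

* own      — the subject's own session-1 posterior-mean parameters;
* other    — every other subject's session-1 parameters, with the
             per-trial probabilities averaged across donors first;
* prior    — the session-1 group-level mean parameters.

Chance is 0.25 for the four-armed bandit and 0.50 for the gamble task.
Paired t-tests compare own vs chance, own vs other and own vs prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import bandit_trial_logp
from .fitting import _bandit_arrays, _gamble_arrays
from .tasks import _pt_trial_logp

__all__ = ["PredictionReport", "predictive_probability", "prediction_battery",
           "CHANCE"]

CHANCE = {"bandit": 0.25, "gamble": 0.5}


def _trial_probs(model, params, data_arrays, i):
    """Per-trial probabilities of subject i's observed choices under params."""
    canon = model.expand(np.atleast_2d(params))
    if model.task == "bandit":
        _, ch, rw, pn = data_arrays
        return np.exp(bandit_trial_logp(ch[i], rw[i], pn[i], canon[0]))
    _, su, ga, lo, gm = data_arrays
    return np.exp(_pt_trial_logp(canon, su[i:i + 1], ga[i:i + 1],
                                 lo[i:i + 1], gm[i:i + 1])[0])


def predictive_probability(model, params, trials_df, subject=None, session=2):
    """Mean per-trial probability of one subject's observed choices.

    ``params`` is a native-scale vector in the model's free-parameter
    order. ``trials_df`` is a tidy table; ``subject`` selects the subject
    when the table holds several.
    """
    df = trials_df if subject is None else trials_df[trials_df.subject == subject]
    arrays = (_bandit_arrays(df, session) if model.task == "bandit"
              else _gamble_arrays(df, session))
    if len(arrays[0]) != 1:
        raise ValueError("trials must come from exactly one subject-session")
    return float(_trial_probs(model, params, arrays, 0).mean())


@dataclass
class PredictionReport:
    """Per-subject predictive accuracies plus paired comparisons."""

    table: pd.DataFrame            # subject, accuracy_own/other/prior
    chance: float
    tests: dict = field(default_factory=dict)

    def summary(self):
        m = self.table[["accuracy_own", "accuracy_other", "accuracy_prior"]].mean()
        out = dict(m)
        out["chance"] = self.chance
        return out


def prediction_battery(posterior_s1, data_s2, session=2) -> PredictionReport:
    """Score own / other / prior predictors on session-2 data.

    ``posterior_s1`` is a session-1 GroupPosterior; its subject roster
    must match the subjects present in ``data_s2`` for the target session.
    """
    model = posterior_s1.model
    est = posterior_s1.subject_means.droplevel("session")
    arrays = (_bandit_arrays(data_s2, session) if model.task == "bandit"
              else _gamble_arrays(data_s2, session))
    units = arrays[0]
    subjects = [u[0] for u in units]
    if sorted(subjects) != sorted(est.index):
        raise ValueError("subject rosters differ between posterior and data")
    prior_params = posterior_s1.group_mean_native.to_numpy()

    # per-trial probabilities of subject i's choices under subject j's params
    n = len(subjects)
    rows = []
    all_probs = np.empty((n, n), dtype=object)
    for i in range(n):  # data of subject i
        for j in range(n):  # parameters of subject j
            all_probs[i, j] = _trial_probs(model, est.loc[subjects[j]].to_numpy(),
                                           arrays, i)
    for i, subj in enumerate(subjects):
        own = all_probs[i, i].mean()
        donors = [all_probs[i, j] for j in range(n) if j != i]
        # average probabilities per trial across donors, then across trials
        other = np.mean(np.stack(donors), axis=0).mean()
        prior = _trial_probs(model, prior_params, arrays, i).mean()
        rows.append({"subject": subj, "accuracy_own": own,
                     "accuracy_other": other, "accuracy_prior": prior})
    table = pd.DataFrame(rows)
    chance = CHANCE[model.task]
    tests = {
        "own_vs_chance": _paired_t(table.accuracy_own, chance),
        "own_vs_other": _paired_t(table.accuracy_own, table.accuracy_other),
        "own_vs_prior": _paired_t(table.accuracy_own, table.accuracy_prior),
    }
    return PredictionReport(table=table, chance=chance, tests=tests)


def _paired_t(a, b):
    a = np.asarray(a, dtype=float)
    if np.isscalar(b) or np.ndim(b) == 0:
        t, p = stats.ttest_1samp(a, float(b))
    else:
        t, p = stats.ttest_rel(a, np.asarray(b, dtype=float))
    return {"t": float(t), "p": float(p), "df": len(a) - 1}
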