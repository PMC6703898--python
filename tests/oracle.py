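"""Straight-line brute-force oracles, intentionally independent of the
package's likelihood implementations.

``oracle_loglik`` recomputes the learner's beliefs from scratch for every
trial (replaying the whole history each time) using plain dicts and floats,
and evaluates the softmax directly. ``pure_mf_loglik`` / ``pure_mb_loglik``
are separate single-strategy learners used to check the omega = 0 / 1
reductions.
"""

import math


def _fresh_beliefs(mid):
    q1 = {(s, a): mid for s in (0, 1) for a in (0, 1)}
    q2 = {0: mid, 1: mid}
    T = {(s, a, p): 0.5 for s in (0, 1) for a in (0, 1) for p in (0, 1)}
    return q1, q2, T


def _replay_history(dataset, params, upto, mid):
    """Beliefs and stickiness memory after trials 0 .. upto-1."""
    q1, q2, T = _fresh_beliefs(mid)
    prev_action = None
    prev_key = None
    for obs in dataset.observations[:upto]:
        if obs.action1 is None:
            continue
        s = obs.trial.start_state
        a = obs.action1 - 2 * s
        p = obs.planet
        if obs.trial.block_condition == "stable":
            eta = 1.0
            eta_cf = 1.0
        else:
            eta = params.eta
            eta_cf = params.eta if params.eta_cf is None else params.eta_cf
        # factual then counterfactual transition update
        T[(s, a, p)] = T[(s, a, p)] + eta * (1.0 - T[(s, a, p)])
        T[(s, a, 1 - p)] = T[(s, a, 1 - p)] * (1.0 - eta)
        T[(s, 1 - a, 1 - p)] = T[(s, 1 - a, 1 - p)] + eta_cf * (
            1.0 - T[(s, 1 - a, 1 - p)]
        )
        T[(s, 1 - a, p)] = T[(s, 1 - a, p)] * (1.0 - eta_cf)
        if obs.reward is not None:
            d1 = q2[p] - q1[(s, a)]
            d2 = obs.reward - q2[p]
            q1[(s, a)] = q1[(s, a)] + params.alpha * d1 + params.alpha * params.lam * d2
            q2[p] = q2[p] + params.alpha * d2
        prev_action = obs.action1
        prev_key = obs.trial.key_of(obs.action1)
    return q1, q2, T, prev_action, prev_key


def oracle_loglik(dataset, params):
    lo, hi = dataset.sequence.config.reward_bounds
    mid = (lo + hi) / 2.0
    total = 0.0
    for t, obs in enumerate(dataset.observations):
        if obs.action1 is None:
            continue
        q1, q2, T, prev_action, prev_key = _replay_history(
            dataset, params, t, mid
        )
        tr = obs.trial
        s = tr.start_state
        omega = params.omega[(tr.stakes, tr.block_condition)]
        logits = []
        for a in (0, 1):
            q_mb = T[(s, a, 0)] * q2[0] + T[(s, a, 1)] * q2[1]
            q_net = (1.0 - omega) * q1[(s, a)] + omega * q_mb
            z = params.beta * q_net
            if prev_action is not None and prev_action == 2 * s + a:
                z += params.pi
            if prev_key is not None and prev_key == tr.key_of(2 * s + a):
                z += params.rho
            logits.append(z)
        chosen = obs.action1 - 2 * s
        denom = math.exp(logits[0]) + math.exp(logits[1])
        total += math.log(math.exp(logits[chosen]) / denom)
    return total


def pure_mf_loglik(dataset, params):
    """Model-free-only learner: choice values are the cached first-stage
    expectations; the transition model is never consulted."""
    lo, hi = dataset.sequence.config.reward_bounds
    mid = (lo + hi) / 2.0
    q1 = {(s, a): mid for s in (0, 1) for a in (0, 1)}
    q2 = {0: mid, 1: mid}
    prev_action = None
    prev_key = None
    total = 0.0
    for obs in dataset.observations:
        if obs.action1 is None:
            continue
        tr = obs.trial
        s = tr.start_state
        logits = []
        for a in (0, 1):
            z = params.beta * q1[(s, a)]
            if prev_action == 2 * s + a:
                z += params.pi
            if prev_key is not None and prev_key == tr.key_of(2 * s + a):
                z += params.rho
            logits.append(z)
        chosen = obs.action1 - 2 * s
        total += logits[chosen] - math.log(
            math.exp(logits[0]) + math.exp(logits[1])
        )
        if obs.reward is not None:
            a, p = chosen, obs.planet
            d1 = q2[p] - q1[(s, a)]
            d2 = obs.reward - q2[p]
            q1[(s, a)] += params.alpha * (d1 + params.lam * d2)
            q2[p] += params.alpha * d2
        prev_action = obs.action1
        prev_key = tr.key_of(obs.action1)
    return total


def pure_mb_loglik(dataset, params):
    """Model-based-only learner: choice values are transition-weighted
    planet expectations; cached first-stage values are never consulted
    (planet values still learn from rewards)."""
    lo, hi = dataset.sequence.config.reward_bounds
    mid = (lo + hi) / 2.0
    q2 = {0: mid, 1: mid}
    T = {(s, a, p): 0.5 for s in (0, 1) for a in (0, 1) for p in (0, 1)}
    prev_action = None
    prev_key = None
    total = 0.0
    for obs in dataset.observations:
        if obs.action1 is None:
            continue
        tr = obs.trial
        s = tr.start_state
        logits = []
        for a in (0, 1):
            z = params.beta * (T[(s, a, 0)] * q2[0] + T[(s, a, 1)] * q2[1])
            if prev_action == 2 * s + a:
                z += params.pi
            if prev_key is not None and prev_key == tr.key_of(2 * s + a):
                z += params.rho
            logits.append(z)
        chosen = obs.action1 - 2 * s
        total += logits[chosen] - math.log(
            math.exp(logits[0]) + math.exp(logits[1])
        )
        a, p = chosen, obs.planet
        if tr.block_condition == "stable":
            eta = eta_cf = 1.0
        else:
            eta = params.eta
            eta_cf = params.eta if params.eta_cf is None else params.eta_cf
        T[(s, a, p)] += eta * (1.0 - T[(s, a, p)])
        T[(s, a, 1 - p)] *= 1.0 - eta
        T[(s, 1 - a, 1 - p)] += eta_cf * (1.0 - T[(s, 1 - a, 1 - p)])
        T[(s, 1 - a, p)] *= 1.0 - eta_cf
        if obs.reward is not None:
            q2[p] += params.alpha * (obs.reward - q2[p])
        prev_action = obs.action1
        prev_key = tr.key_of(obs.action1)
    return total
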