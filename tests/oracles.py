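"""Independent oracles used to cross-check the inference engine.

These deliberately avoid the package's filtering code path: the posterior
is obtained by enumerating every joint hidden-state trajectory and summing
unnormalized trajectory probabilities, and expected free energy is
re-derived by direct summation of its defining formula.
"""

import itertools

import numpy as np


def enumerate_posterior(prior, b_by_action, a_wealth, a_approval,
                        actions, observations):
    """Exact filtering posterior over the final state by brute-force
    enumeration of all state trajectories ``s_0 .. s_T``.

    ``actions`` and ``observations`` are aligned: action t moves
    ``s_t -> s_{t+1}`` and the observation pair t is emitted by
    ``s_{t+1}``.  The prefix ``s_0 .. s_{T-1}`` is enumerated explicitly;
    only the terminal state is handled as a vector.
    """
    n = prior.size
    T = len(actions)
    assert len(observations) == T and T >= 1
    posterior = np.zeros(n)
    last_action = actions[-1]
    o_w_last, o_a_last = observations[-1]
    terminal_obs = a_wealth[o_w_last] * a_approval[o_a_last]
    for prefix in itertools.product(range(n), repeat=T):
        p = prior[prefix[0]]
        if p == 0.0:
            continue
        for t in range(T - 1):
            o_w, o_a = observations[t]
            p *= (b_by_action[actions[t]][prefix[t + 1], prefix[t]]
                  * a_wealth[o_w, prefix[t + 1]]
                  * a_approval[o_a, prefix[t + 1]])
            if p == 0.0:
                break
        if p == 0.0:
            continue
        posterior += p * b_by_action[last_action][:, prefix[-1]] * terminal_obs
    total = posterior.sum()
    assert total > 0, "observation sequence impossible under the prior"
    return posterior / total


def direct_efe(belief, actions, b_by_action, a_mats, c_vecs):
    """Expected free energy of an action sequence by direct summation:
    per step, KL(predicted outcomes || softmax preferences) plus the
    belief-weighted likelihood column entropy, summed over modalities."""
    q = belief.copy()
    total = 0.0
    for action in actions:
        q = b_by_action[action] @ q
        for a, c in zip(a_mats, c_vecs):
            pref = np.exp(c - c.max())
            pref = pref / pref.sum()
            predicted = a @ q
            for o in range(a.shape[0]):
                if predicted[o] > 0:
                    total += predicted[o] * (np.log(predicted[o])
                                             - np.log(pref[o]))
            for s in range(a.shape[1]):
                h = 0.0
                for o in range(a.shape[0]):
                    if a[o, s] > 0:
                        h -= a[o, s] * np.log(a[o, s])
                total += q[s] * h
    return total
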