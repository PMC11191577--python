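"""Independent brute-force oracles for the HMM and BN models.

Everything here works on sets of involved levels and pure-Python products,
enumerating state trajectories and observation patterns explicitly, so it
shares no code path with the package's vectorized matrix implementation.
"""

from __future__ import annotations

from itertools import product as iproduct
from math import comb


def powerset(levels):
    out = []
    for bits in iproduct((0, 1), repeat=len(levels)):
        out.append(frozenset(v for v, b in zip(levels, bits) if b))
    return out


def step_probability(x, y, levels, parents, b, t):
    """One-step transition probability between involvement sets.

    Healthy levels become involved independently with the noisy-OR rate
    whose parent set is read from the destination (within-step cascade in
    topological order); involved levels persist.
    """
    if not x <= y:
        return 0.0
    p = 1.0
    for v in levels:
        if v in x:
            continue
        stay = 1.0 - b[v]
        for r in parents.get(v, ()):
            if r in y:
                stay *= 1.0 - t[(r, v)]
        pv = 1.0 - stay
        p *= pv if v in y else 1.0 - pv
    return p


def binom_weights(t_max, p):
    w = [comb(t_max, k) * p**k * (1 - p) ** (t_max - k) for k in range(t_max + 1)]
    s = sum(w)
    return [x / s for x in w]


def final_state_distribution(levels, parents, b, t, weights):
    """P(final involvement set) marginalized over the time prior, by
    explicit enumeration of every monotone state trajectory."""
    states = powerset(levels)
    t_max = len(weights) - 1
    dist = {s: 0.0 for s in states}

    def recurse(x, prob, steps_left, weight):
        if steps_left == 0:
            dist[x] += weight * prob
            return
        for y in states:
            sp = step_probability(x, y, levels, parents, b, t)
            if sp > 0.0:
                recurse(y, prob * sp, steps_left - 1, weight)

    for T in range(t_max + 1):
        recurse(frozenset(), 1.0, T, weights[T])
    return dist


def observation_probability(state, diagnosis, levels, sens, spec):
    """P(diagnosis | state) by explicit enumeration over full observation
    patterns compatible with the (possibly partially unknown) diagnosis."""
    known = [(v, s) for v, s in zip(levels, diagnosis) if s is not None]
    unknown = [v for v, s in zip(levels, diagnosis) if s is None]
    total = 0.0
    for fill in iproduct((0, 1), repeat=len(unknown)):
        full = dict(known)
        full.update(dict(zip(unknown, fill)))
        p = 1.0
        for v in levels:
            if v in state:
                p *= sens if full[v] == 1 else 1.0 - sens
            else:
                p *= 1.0 - spec if full[v] == 1 else spec
        total += p
    return total


def patient_likelihood_oracle(levels, parents, b, t, weights, diagnosis, sens, spec):
    dist = final_state_distribution(levels, parents, b, t, weights)
    return sum(
        pr * observation_probability(s, diagnosis, levels, sens, spec)
        for s, pr in dist.items()
    )


def state_posterior_oracle(levels, parents, b, t, weights, diagnosis, sens, spec):
    dist = final_state_distribution(levels, parents, b, t, weights)
    joint = {
        s: pr * observation_probability(s, diagnosis, levels, sens, spec)
        for s, pr in dist.items()
    }
    norm = sum(joint.values())
    return {s: v / norm for s, v in joint.items()}


def risk_oracle(levels, parents, b, t, weights, diagnosis, sens, spec, targets):
    post = state_posterior_oracle(levels, parents, b, t, weights, diagnosis, sens, spec)
    targets = set(targets)
    return sum(pr for s, pr in post.items() if targets <= s)


def bn_prior_oracle(levels_topological, parents, b, t):
    """BN joint over involvement sets by the topological closed form."""
    out = {}
    for s in powerset(levels_topological):
        p = 1.0
        for v in levels_topological:
            stay = 1.0 - b[v]
            for r in parents.get(v, ()):
                if r in s:
                    stay *= 1.0 - t[(r, v)]
            pv = 1.0 - stay
            p *= pv if v in s else 1.0 - pv
        out[s] = p
    return out


def bn_risk_oracle(levels_topological, parents, b, t, diagnosis, sens, spec, targets):
    prior = bn_prior_oracle(levels_topological, parents, b, t)
    joint = {
        s: pr * observation_probability(s, diagnosis, levels_topological, sens, spec)
        for s, pr in prior.items()
    }
    norm = sum(joint.values())
    targets = set(targets)
    return sum(v for s, v in joint.items() if targets <= s) / norm
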