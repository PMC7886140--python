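"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the posterior oracle
enumerates the full 2-state joint table over all feature assignments, and
the AUROC oracle loops over every case-control pair.
"""

import itertools


def posterior_bruteforce(present, p_case, p_control, prior):
    """P(case | evidence) by enumerating the joint distribution.

    ``present`` is a set of feature indices instantiated "present"; every
    other feature is unobserved and marginalised over both of its states.
    """
    n = len(p_case)
    joint = {True: 0.0, False: 0.0}
    for assignment in itertools.product([0, 1], repeat=n):
        if any(assignment[i] == 0 for i in present):
            continue  # inconsistent with the instantiated evidence
        for is_case, class_prior, p in (
            (True, prior, p_case),
            (False, 1.0 - prior, p_control),
        ):
            prob = class_prior
            for i in range(n):
                prob *= p[i] if assignment[i] else (1.0 - p[i])
            joint[is_case] += prob
    return joint[True] / (joint[True] + joint[False])


def auroc_allpairs(labels, scores):
    """P(case score > control score) + 0.5 P(tie), by exhaustive pairing."""
    cases = [s for y, s in zip(labels, scores) if y in (1, True, "case")]
    controls = [s for y, s in zip(labels, scores) if y not in (1, True, "case")]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))
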