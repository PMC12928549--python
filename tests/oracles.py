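"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's engine code paths: the cohort oracle
enumerates every state path explicitly (writing the transition probabilities
out by hand), and the dominance oracle uses exhaustive pairwise checks plus
a convex-combination test for extended dominance.
"""

from __future__ import annotations

import itertools

# state indices, mirroring the documented ordering
NP_NO_IUD, NP_IUD, P_NO_IUD, P_IUD = 0, 1, 2, 3


def hand_transition_matrix(
    p_preg_no_iud: float,
    p_preg_iud: float,
    p_loss: float,
    p_provision: float,
    retain_iud_after_loss: bool = False,
) -> list[list[float]]:
    """Transition probabilities written out literally from the model's flow rules."""
    row0 = [
        (1 - p_provision) * (1 - p_preg_no_iud),
        p_provision,
        (1 - p_provision) * p_preg_no_iud,
        0.0,
    ]
    row1 = [0.0, 1 - p_preg_iud, 0.0, p_preg_iud]
    row2 = [p_loss, 0.0, 1 - p_loss, 0.0]
    if retain_iud_after_loss:
        row3 = [0.0, p_loss, 0.0, 1 - p_loss]
    else:
        row3 = [p_loss, 0.0, 0.0, 1 - p_loss]
    return [row0, row1, row2, row3]


def path_enumeration_cohort(
    p_provision: float,
    cohort_size: int,
    n_professionals: int,
    p_preg_no_iud: float,
    p_preg_iud: float,
    p_loss: float,
    retain_iud_after_loss: bool,
    utilities: tuple[float, float, float, float],
    c_training: float,
    c_insertion: float,
    c_consultation: float,
    c_pregnancy: float,
    n_cycles: int,
    cycle_length: float,
    discount_rate: float = 0.0,
) -> tuple[float, float, float, float]:
    """(cost_pp, qaly_pp, cost_total, qaly_total) by exhaustive path enumeration.

    Every state path of length n_cycles starting in NP_NO_IUD is weighted by
    its probability; utilities and the consultation cost accrue on the state
    at the start of each cycle, insertion and pregnancy costs on the
    transition taken during the cycle.
    """
    m = hand_transition_matrix(
        p_preg_no_iud, p_preg_iud, p_loss, p_provision, retain_iud_after_loss
    )
    cost_pp = 0.0
    qaly_pp = 0.0
    for path in itertools.product(range(4), repeat=n_cycles):
        prob = 1.0
        cost = 0.0
        qaly = 0.0
        prev = NP_NO_IUD
        for t, state in enumerate(path, start=1):
            prob *= m[prev][state]
            if prob == 0.0:
                break
            disc = (1.0 + discount_rate) ** (-(t - 1) * cycle_length)
            qaly += disc * utilities[prev] * cycle_length
            if prev == NP_NO_IUD:
                cost += disc * c_consultation
                if state == NP_IUD:
                    cost += disc * c_insertion
                if state == P_NO_IUD:
                    cost += disc * c_pregnancy
            if prev == NP_IUD and state == P_IUD:
                cost += disc * c_pregnancy
            prev = state
        if prob == 0.0:
            continue
        cost_pp += prob * cost
        qaly_pp += prob * qaly
    cost_total = cohort_size * cost_pp + n_professionals * c_training
    return cost_pp, qaly_pp, cost_total, cohort_size * qaly_pp


def brute_force_dominance(strategies) -> dict[str, str]:
    """Exhaustive dominance labels: pairwise strong dominance, then a
    convex-combination test for extended dominance among the survivors."""
    labels = {}
    survivors = []
    for s in strategies:
        strong = any(
            t.cost <= s.cost
            and t.effectiveness >= s.effectiveness
            and (t.cost < s.cost or t.effectiveness > s.effectiveness)
            for t in strategies
            if t is not s
        )
        if strong:
            labels[s.name] = "DOMINATED"
        else:
            survivors.append(s)

    for s in survivors:
        extended = False
        for a, b in itertools.permutations(survivors, 2):
            if not (a.effectiveness < s.effectiveness < b.effectiveness):
                continue
            lam = (s.effectiveness - b.effectiveness) / (
                a.effectiveness - b.effectiveness
            )
            mix_cost = lam * a.cost + (1 - lam) * b.cost
            if mix_cost < s.cost:
                extended = True
                break
        labels[s.name] = "EXTENDEDLY_DOMINATED" if extended else "NOT_DOMINATED"
    return labels
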