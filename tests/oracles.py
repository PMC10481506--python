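"""Independent literal transcriptions of the penalty formulas and tiny
brute-force searches, used as test oracles.

Everything here is written directly from the printed definitions, on purpose
without reusing any archlabel internals beyond the public column order of the
assignment matrix (11..18, 21..28, 31..38, 41..48).
"""

import itertools
import math

import numpy as np

UPPER_CODES = list(range(11, 19)) + list(range(21, 29))
LOWER_CODES = list(range(31, 39)) + list(range(41, 49))
ALL_CODES = (
    list(range(11, 19)) + list(range(21, 29))
    + list(range(31, 39)) + list(range(41, 49))
)
COL = {c: i for i, c in enumerate(ALL_CODES)}

# geometric order along each arch, one end to the other
UPPER_ARCH = list(range(18, 10, -1)) + list(range(21, 29))
LOWER_ARCH = list(range(48, 40, -1)) + list(range(31, 39))
ARCH_POS = {c: i for arch in (UPPER_ARCH, LOWER_ARCH) for i, c in enumerate(arch)}


def f11(E):
    return sum(max(sum(E[n, c] for n in range(len(E))) - 1, 0) for c in range(32))


def f12(E, coms, watershed_z):
    total = 0
    for n in range(len(E)):
        for c in UPPER_CODES:
            total += E[n, COL[c]] * (coms[n][2] < watershed_z)
        for c in LOWER_CODES:
            total += E[n, COL[c]] * (watershed_z < coms[n][2])
    return total


def f13(E):
    return sum(max(1 - sum(E[n, c] for c in range(32)), 0) for n in range(len(E)))


def f1(E, coms, watershed_z, lambda12=0.1, lambda13=0.01):
    return f11(E) + lambda12 * f12(E, coms, watershed_z) + lambda13 * f13(E)


def f2(E, coms):
    total = 0
    for jaw in (UPPER_CODES, LOWER_CODES):
        for n1 in range(len(E)):
            for c1 in jaw:
                if not E[n1, COL[c1]]:
                    continue
                for n2 in range(len(E)):
                    for c2 in jaw:
                        if not E[n2, COL[c2]]:
                            continue
                        inverted = (coms[n1][0] > coms[n2][0]) != (
                            ARCH_POS[c1] > ARCH_POS[c2]
                        )
                        total += int(inverted)
    return total


def f3(E, coms, D):
    """D is the 32x32 prior in ALL_CODES order; squared discrepancy."""
    total = 0.0
    for jaw in (UPPER_CODES, LOWER_CODES):
        for n1 in range(len(E)):
            for c1 in jaw:
                if not E[n1, COL[c1]]:
                    continue
                for n2 in range(len(E)):
                    if n1 == n2:
                        continue
                    for c2 in jaw:
                        if not E[n2, COL[c2]]:
                            continue
                        dist = math.dist(coms[n1], coms[n2])
                        total += (dist - D[COL[c1], COL[c2]]) ** 2
    return total


def min_f2_over_permutations(E, coms):
    """Minimum inversion count over per-jaw permutations of the used codes."""
    total = 0
    for jaw in (UPPER_CODES, LOWER_CODES):
        rows, codes = [], []
        for n in range(len(E)):
            for c in jaw:
                if E[n, COL[c]]:
                    rows.append(n)
                    codes.append(c)
        if len(rows) < 2:
            continue
        best = None
        for perm in itertools.permutations(codes):
            inv = 0
            for (na, ca), (nb, cb) in itertools.permutations(
                list(zip(rows, perm)), 2
            ):
                inv += (coms[na][0] > coms[nb][0]) != (ARCH_POS[ca] > ARCH_POS[cb])
            best = inv if best is None else min(best, inv)
        total += best
    return total


def min_f3_over_placements(coms_in_x_order, arch_codes, D):
    """Exhaustive order-preserving placement of one jaw's detections.

    ``coms_in_x_order``: COMs of the jaw's detections sorted by x;
    ``arch_codes``: the jaw's 16 codes in arch order.  Returns the minimal
    ordered-pair squared discrepancy over all C(16, k) placements.
    """
    k = len(coms_in_x_order)
    best = None
    for slots in itertools.combinations(range(16), k):
        cost = 0.0
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                dist = math.dist(coms_in_x_order[i], coms_in_x_order[j])
                prior = D[COL[arch_codes[slots[i]]], COL[arch_codes[slots[j]]]]
                cost += (dist - prior) ** 2
        if best is None or cost < best:
            best = cost
    return 0.0 if best is None else best


def confusion_counts(pred_mask, gt_mask):
    """Brute-force 2x2 contingency counting, tooth = positive."""
    tp = tn = fp = fn = 0
    for p, g in zip(pred_mask, gt_mask):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn
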