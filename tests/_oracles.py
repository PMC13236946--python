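"""Independent brute-force oracles used by the tests.

Deliberately shares no code with the package: the weight table, the
sextant map and the ANOVA sums are written out from scratch so that
agreement with the package is a genuine dual-route check.
"""

# Presence weight of every scorable tooth, written out longhand.
ORACLE_PRESENCE = {
    11: 6, 12: 6, 13: 8, 14: 4, 15: 4, 16: 4, 17: 4,
    21: 6, 22: 6, 23: 8, 24: 4, 25: 4, 26: 4, 27: 4,
    31: 6, 32: 6, 33: 8, 34: 4, 35: 4, 36: 4, 37: 4,
    41: 6, 42: 6, 43: 8, 44: 4, 45: 4, 46: 4, 47: 4,
}

# Sextant of every scorable tooth, written out longhand.
ORACLE_SEXTANT = {
    17: 1, 16: 1, 15: 1, 14: 1,
    13: 2, 12: 2, 11: 2, 21: 2, 22: 2, 23: 2,
    24: 3, 25: 3, 26: 3, 27: 3,
    34: 4, 35: 4, 36: 4, 37: 4,
    33: 5, 32: 5, 31: 5, 41: 5, 42: 5, 43: 5,
    44: 6, 45: 6, 46: 6, 47: 6,
}


def brute_force_score(a):
    """Enumerate every item of an assessment and sum default weights.

    Returns (base_total, adjustment, final_total, per_sextant) computed
    with the published defaults: +5 once if any sextant strictly exceeds
    10 points; condyle/ramus points attributed to no sextant.
    """
    per_sextant = {1: 0, 2: 0, 3: 0, 4: 0, 5: 0, 6: 0}
    base = 0
    for t in a.teeth:
        if t.exclusion_note:
            continue
        if t.status == "missing":
            pts = ORACLE_PRESENCE[t.tooth]
        else:
            pts = 0
            for flag in (
                t.crown_abnormal,
                t.root_abnormal,
                t.crown_root_ratio_abnormal,
                t.eruption_not_age_appropriate,
            ):
                if flag:
                    pts += 1
        base += pts
        per_sextant[ORACLE_SEXTANT[t.tooth]] += pts
    for s in a.sextants:
        pts = (1 if s.alveolar_reduced else 0) + (1 if s.tooth_wear else 0)
        base += pts
        per_sextant[s.sextant] += pts
    for flag in (a.bony.condyle_left_abnormal, a.bony.condyle_right_abnormal):
        if flag:
            base += 3
    for flag in (a.bony.ramus_left_abnormal, a.bony.ramus_right_abnormal):
        if flag:
            base += 1
    adjustment = 5 if any(v > 10 for v in per_sextant.values()) else 0
    return base, adjustment, base + adjustment, per_sextant


def icc21_oracle(matrix):
    """ICC(2,1) from first principles: plain-Python two-way ANOVA sums."""
    rows = [list(map(float, r)) for r in matrix]
    n = len(rows)
    k = len(rows[0])
    grand = sum(sum(r) for r in rows) / (n * k)
    row_means = [sum(r) / k for r in rows]
    col_means = [sum(rows[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((rows[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def confusion_recount(scores, threshold):
    """Naive per-subject recount of the 2x2 table at one threshold."""
    tp = fp = fn = tn = 0
    for total, label in scores:
        if total >= threshold:
            if label:
                tp += 1
            else:
                fp += 1
        else:
            if label:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
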