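"""Independent brute-force reference implementations.

Pure-Python (math/statistics only, no numpy/pandas) re-derivations of the
four stability statistics, used to cross-check the package's vectorized
implementations on small complete panels. Data are plain dicts mapping
gene id -> list of Ct values (one per sample, no missing values).
"""

import math
import statistics


def _sd(xs):
    return statistics.stdev(xs)  # n-1 denominator


def log_quantities(ct, efficiency=2.0):
    scale = math.log2(efficiency)
    out = {}
    for g, vals in ct.items():
        cal = max(vals)  # calibrate to the least-expressed sample
        out[g] = [(cal - v) * scale for v in vals]
    return out


def oracle_delta_ct(ct):
    """Mean pairwise SD of per-sample Ct differences, per gene."""
    genes = list(ct)
    S = {}
    for gi in genes:
        sds = []
        for gk in genes:
            if gk == gi:
                continue
            diffs = [a - b for a, b in zip(ct[gi], ct[gk])]
            sds.append(_sd(diffs))
        S[gi] = sum(sds) / len(sds)
    return S


def _m_values(a, genes):
    M = {}
    for gi in genes:
        vs = []
        for gk in genes:
            if gk == gi:
                continue
            vs.append(_sd([x - y for x, y in zip(a[gi], a[gk])]))
        M[gi] = sum(vs) / len(vs)
    return M


def oracle_genorm(ct, efficiency=2.0):
    """Full stepwise elimination: M traces, removal order, final pair, V series.

    Tie-break on equal worst M: remove the lexicographically last gene.
    """
    a = log_quantities(ct, efficiency)
    remaining = list(ct)
    steps = []
    removal_order = []
    while len(remaining) > 2:
        M = _m_values(a, remaining)
        worst_val = max(M.values())
        worst = max(g for g in remaining if M[g] == worst_val)
        steps.append({"m_values": dict(M), "removed": worst})
        remaining.remove(worst)
        removal_order.append(worst)
    steps.append({"m_values": _m_values(a, remaining), "removed": None})
    final_pair = list(remaining)

    ranking = final_pair + removal_order[::-1]
    n_samples = len(next(iter(ct.values())))
    nf = {}
    for n in range(2, len(ct) + 1):
        top = ranking[:n]
        nf[n] = [
            2 ** (sum(a[g][s] for g in top) / n) for s in range(n_samples)
        ]
    v_series = {}
    for n in range(2, len(ct)):
        ratios = [math.log2(nf[n][s] / nf[n + 1][s]) for s in range(n_samples)]
        v_series[f"V{n}/{n + 1}"] = _sd(ratios)
    return {
        "steps": steps,
        "final_pair": final_pair,
        "v_series": v_series,
        "ranking": ranking,
    }


def oracle_normfinder(ct, groups, efficiency=2.0):
    """Stability value: shrunken intergroup bias + intragroup error, per gene.

    ``groups`` is a list of group labels, one per sample.
    """
    a = log_quantities(ct, efficiency)
    genes = list(ct)
    n_samples = len(groups)
    # center each sample across genes
    x = {g: list(vals) for g, vals in a.items()}
    for s in range(n_samples):
        mu = sum(a[g][s] for g in genes) / len(genes)
        for g in genes:
            x[g][s] = a[g][s] - mu

    labels = []
    for lab in groups:
        if lab not in labels:
            labels.append(lab)
    rho = {}
    for g in genes:
        by_group = {lab: [x[g][s] for s in range(n_samples) if groups[s] == lab]
                    for lab in labels}
        m = {lab: sum(v) / len(v) for lab, v in by_group.items()}
        v = {lab: statistics.variance(by_group[lab]) for lab in labels}
        overall = sum(len(by_group[lab]) * m[lab] for lab in labels) / n_samples
        total = 0.0
        for lab in labels:
            n_g = len(by_group[lab])
            d = m[lab] - overall
            d2 = max(d * d - v[lab] / n_g, 0.0)
            total += (n_g / n_samples) * (math.sqrt(d2) + math.sqrt(v[lab] / n_g))
        rho[g] = total
    return rho


def _pearson(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def oracle_bestkeeper(ct):
    """Descriptors on raw Ct: arithmetic/geometric mean, MAD, CV%, r vs index."""
    genes = list(ct)
    n_samples = len(next(iter(ct.values())))
    table = {}
    for g in genes:
        vals = ct[g]
        am = sum(vals) / len(vals)
        mad = sum(abs(v - am) for v in vals) / len(vals)
        gm = math.exp(sum(math.log(v) for v in vals) / len(vals))
        table[g] = {
            "arith_mean": am,
            "geo_mean": gm,
            "sd": mad,
            "cv_pct": 100.0 * mad / am,
            "min": min(vals),
            "max": max(vals),
        }
    bki = [
        math.exp(sum(math.log(ct[g][s]) for g in genes) / len(genes))
        for s in range(n_samples)
    ]
    for g in genes:
        table[g]["r"] = _pearson(ct[g], bki)
    return {"table": table, "index": bki}
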