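"""Independent brute-force oracles used by the test suite.

Each function re-derives a pipeline quantity from its definition with plain
loops and small-scale arithmetic, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def bh_oracle(p):
    """BH step-up by literal definition: sort, scale, running min, restore."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        q[i] = val
        prev = val
    return q


def simes_oracle(p):
    p = sorted(x for x in p if not math.isnan(x))
    m = len(p)
    return min(1.0, min(m * pk / (k + 1) for k, pk in enumerate(p)))


def hypergeom_tail_oracle(n_universe, n_a, n_b, k):
    """P(overlap >= k) by exact combinatorial enumeration."""
    total = math.comb(n_universe, n_b)
    acc = 0
    for j in range(k, min(n_a, n_b) + 1):
        acc += math.comb(n_a, j) * math.comb(n_universe - n_a, n_b - j)
    return acc / total


def psi_oracle(tpm_by_isoform):
    """Per-sample isoform proportions; None where the gene total is zero."""
    n = len(next(iter(tpm_by_isoform.values())))
    out = {iso: [] for iso in tpm_by_isoform}
    for s in range(n):
        tot = sum(vals[s] for vals in tpm_by_isoform.values())
        for iso, vals in tpm_by_isoform.items():
            out[iso].append(vals[s] / tot if tot > 0 else None)
    return out


def delta_psi_oracle(psi_trt, psi_ctl, min_valid):
    """Masked group-mean difference; None when either support < min_valid."""
    t = [x for x in psi_trt if x is not None]
    c = [x for x in psi_ctl if x is not None]
    if len(t) < min_valid or len(c) < min_valid:
        return None
    return sum(t) / len(t) - sum(c) / len(c)


def combination_oracle(sets):
    """Exclusive subset counts via per-element membership signatures."""
    names = list(sets)
    clean = {n: set(v) for n, v in sets.items()}
    union = set().union(*clean.values())
    out = {}
    for el in union:
        sig = tuple(n for n in names if el in clean[n])
        out[sig] = out.get(sig, 0) + 1
    return out


def tmm_oracle(counts, lib_sizes, ref_index):
    """Literal transcription of the TMM rules for one sample vs the reference.

    Returns the unrescaled per-sample factors (2**weighted trimmed mean M).
    """
    n_feat, n_samp = counts.shape
    factors = []
    for j in range(n_samp):
        ms, aas, ws = [], [], []
        for i in range(n_feat):
            o, r = counts[i, j], counts[i, ref_index]
            if o > 0 and r > 0:
                po, pr = o / lib_sizes[j], r / lib_sizes[ref_index]
                ms.append(math.log2(po / pr))
                aas.append(0.5 * math.log2(po * pr))
                ws.append(
                    (lib_sizes[j] - o) / (lib_sizes[j] * o)
                    + (lib_sizes[ref_index] - r) / (lib_sizes[ref_index] * r)
                )
        if all(abs(m) < 1e-6 for m in ms):
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m, hi_m = math.floor(n * 0.30) + 1, n - math.floor(n * 0.30)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rank_m = _rank(ms)
        rank_a = _rank(aas)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
        factors.append(2.0 ** (num / den))
    log_mean = sum(math.log(f) for f in factors) / len(factors)
    return [f / math.exp(log_mean) for f in factors]


def _rank(values):
    """Average ranks (1-based) with ties, as R's rank()."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wls_t_oracle(y, w, x, c):
    """Ordinary WLS t for one feature via the sqrt-weight transform and lstsq."""
    sw = np.sqrt(w)
    xt = x * sw[:, None]
    yt = y * sw
    beta, _, rank, _ = np.linalg.lstsq(xt, yt, rcond=None)
    resid = yt - xt @ beta
    df = len(y) - x.shape[1]
    s2 = float(resid @ resid) / df
    cov_unscaled = np.linalg.inv(xt.T @ xt)
    est = float(c @ beta)
    se = math.sqrt(float(c @ cov_unscaled @ c) * s2)
    return est, est / se, s2, df


def length_scaled_oracle(tpm, efflen, numreads_totals):
    """Spreadsheet-style evaluation: TPM x mean efflen, column-sum matched."""
    n_tx, n_samp = len(tpm), len(tpm[0])
    mean_len = [sum(efflen[i][s] for s in range(n_samp)) / n_samp for i in range(n_tx)]
    raw = [[tpm[i][s] * mean_len[i] for s in range(n_samp)] for i in range(n_tx)]
    out = [[0.0] * n_samp for _ in range(n_tx)]
    for s in range(n_samp):
        colsum = sum(raw[i][s] for i in range(n_tx))
        for i in range(n_tx):
            out[i][s] = raw[i][s] * numreads_totals[s] / colsum
    return out
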