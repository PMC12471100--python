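"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, separate from
the package implementation, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Codon change counting: exhaustive pathway enumeration
# ---------------------------------------------------------------------------

def codon_counts_oracle(a: str, b: str) -> tuple[float, float]:
    """(syn, nonsyn) averaged over minimal non-stop pathways a -> b."""
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    blocked_paths = []
    for order in itertools.permutations(pos):
        steps = []
        cur = a
        hits_stop = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            steps.append((cur, nxt))
            if nxt in STOPS:
                hits_stop = True
            cur = nxt
        record = tuple(steps)
        blocked_paths.append(record)
        if not hits_stop:
            paths.append(record)
    use = paths if paths else blocked_paths
    syn = nonsyn = 0.0
    for path in use:
        for cur, nxt in path:
            if aa(cur) == aa(nxt):
                syn += 1
            else:
                nonsyn += 1
    return syn / len(use), nonsyn / len(use)


def pair_counts_oracle(row_a: str, row_b: str) -> tuple[float, float, int]:
    """(sd, nd, codons_compared) over a codon row pair, excluding codons
    with gaps/N/stops in either row."""
    assert len(row_a) == len(row_b) and len(row_a) % 3 == 0
    sd = nd = 0.0
    used = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i:i + 3], row_b[i:i + 3]
        if set(ca) - set("ACGT") or set(cb) - set("ACGT"):
            continue
        if ca in STOPS or cb in STOPS:
            continue
        s, n = codon_counts_oracle(ca, cb)
        sd += s
        nd += n
        used += 1
    return sd, nd, used


# ---------------------------------------------------------------------------
# Neutrality statistics: direct formula transcriptions
# ---------------------------------------------------------------------------

def _an(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _bn(n: int) -> float:
    return sum(1.0 / (i * i) for i in range(1, n))


def tajima_oracle(matrix: list[str]) -> float | None:
    """Tajima's D from a list of equal-length sequences (complete deletion)."""
    n = len(matrix)
    L = len(matrix[0])
    cols = ["".join(row[j] for row in matrix) for j in range(L)
            if set(row[j] for row in matrix) <= set("ACGT")]
    S = sum(1 for col in cols if len(set(col)) > 1)
    if S == 0:
        return None
    pi = 0.0
    npairs = n * (n - 1) / 2
    for col in cols:
        for x, y in itertools.combinations(col, 2):
            if x != y:
                pi += 1.0 / npairs
    a1, a2 = _an(n), _bn(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_star_oracle(matrix: list[str]) -> tuple[float, float] | None:
    """(D*, F*) without outgroup, transcribed independently."""
    n = len(matrix)
    L = len(matrix[0])
    cols = ["".join(row[j] for row in matrix) for j in range(L)
            if set(row[j] for row in matrix) <= set("ACGT")]
    eta = 0
    eta_s = 0
    pi = 0.0
    npairs = n * (n - 1) / 2
    for col in cols:
        alleles = {}
        for ch in col:
            alleles[ch] = alleles.get(ch, 0) + 1
        if len(alleles) < 2:
            continue
        eta += len(alleles) - 1
        if len(alleles) == 2:
            eta_s += 1 if min(alleles.values()) == 1 else 0
        else:
            eta_s += sum(1 for v in alleles.values() if v == 1)
        for x, y in itertools.combinations(col, 2):
            if x != y:
                pi += 1.0 / npairs
    if eta == 0:
        return None
    an, bn = _an(n), _bn(n)
    an1 = an + 1.0 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    vds = ((n / (n - 1)) ** 2 * bn + an ** 2 * dn
           - 2 * n * an * (an + 1) / (n - 1) ** 2) / (an ** 2 + bn)
    uds = n / (n - 1) * (an - n / (n - 1)) - vds
    dstar = (n / (n - 1) * eta - an * eta_s) / math.sqrt(
        uds * eta + vds * eta ** 2)
    vfs = (dn + 2 * (n * n + n + 3) / (9 * n * (n - 1))
           - 2 / (n - 1) * (4 * bn - 6 + 8.0 / n)) / (an ** 2 + bn)
    ufs = (n / (n - 1) + (n + 1) / (3 * (n - 1)) - 4 / (n * (n - 1))
           + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))) / an - vfs
    fstar = (pi - (n - 1) / n * eta_s) / math.sqrt(ufs * eta + vfs * eta ** 2)
    return dstar, fstar


# ---------------------------------------------------------------------------
# F84 numerical maximum-likelihood oracle
# ---------------------------------------------------------------------------

def f84_ml_oracle(P: float, Q: float, freqs) -> float:
    """MLE of the F84 distance by 2-D numerical optimization over (t, kappa)
    of the multinomial likelihood of (match, transition, transversion)."""
    from scipy.linalg import expm
    from scipy.optimize import minimize

    freqs = np.asarray(freqs, dtype=float)
    pr, py = freqs[0] + freqs[2], freqs[1] + freqs[3]
    ts_pairs = {(0, 2), (2, 0), (1, 3), (3, 1)}

    def pq(t: float, kappa: float) -> tuple[float, float]:
        Qm = np.zeros((4, 4))
        cls = {0: pr, 2: pr, 1: py, 3: py}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = freqs[j]
                if (i, j) in ts_pairs:
                    rate = freqs[j] * (1 + kappa / cls[j])
                Qm[i, j] = rate
            Qm[i, i] = -Qm[i].sum()
        mu = -sum(freqs[i] * Qm[i, i] for i in range(4))
        Pm = expm(Qm * t / mu)
        pts = sum(freqs[i] * Pm[i, j] for i, j in ts_pairs)
        ptv = sum(freqs[i] * Pm[i, j] for i in range(4) for j in range(4)
                  if i != j and (i, j) not in ts_pairs)
        return pts, ptv

    def nll(x) -> float:
        t, kappa = x
        if t <= 0 or kappa < 0:
            return 1e9
        pts, ptv = pq(t, kappa)
        pm = 1 - pts - ptv
        if min(pts, ptv, pm) <= 0:
            return 1e9
        return -(P * math.log(pts) + Q * math.log(ptv)
                 + (1 - P - Q) * math.log(pm))

    best = None
    for x0 in ([0.1, 1.0], [0.3, 2.0], [0.05, 0.5], [0.6, 4.0]):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15,
                                "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0])


# ---------------------------------------------------------------------------
# Mann-Whitney exact enumeration oracle
# ---------------------------------------------------------------------------

def mwu_oracle(a: list[float], b: list[float]) -> tuple[float, float]:
    """(U of sample a, exact two-sided p) by full label enumeration."""
    n1, n2 = len(a), len(b)
    combined = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(combined)}  # tie-free only

    def u_of(sample: list[float]) -> float:
        r = sum(ranks[v] for v in sample)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(a)
    us = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        sample = [combined[i] for i in idx]
        us.append(u_of(sample))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)
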