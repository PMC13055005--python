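"""Independent brute-force oracles used by the test suite.

These re-derive the reference quantities from first principles with
implementations that share no code (and as little structure as possible)
with the package: translation goes through Bio.Seq, pathway enumeration is
recursive, and the Weir & Cockerham components are literal scalar
transcriptions of the 1984 equations.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# NG86 oracle
# ---------------------------------------------------------------------------

def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """(N, S) sites of one codon; mutations to stop codons excluded."""
    n_sites = s_sites = 0.0
    for pos in range(3):
        muts = [codon[:pos] + b + codon[pos + 1:] for b in BASES if b != codon[pos]]
        muts = [m for m in muts if _aa(m) != "*"]
        if not muts:
            n_sites += 1.0
            continue
        syn_frac = sum(1 for m in muts if _aa(m) == _aa(codon)) / len(muts)
        s_sites += syn_frac
        n_sites += 1.0 - syn_frac
    return n_sites, s_sites


def _paths(ca: str, cb: str):
    """Recursively enumerate all substitution orderings ca -> cb.

    Yields (steps, passed_stop) where steps is the list of (before, after)
    codons along the path.
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        yield [], False
        return
    for pos in diff:
        nxt = ca[:pos] + cb[pos] + ca[pos + 1:]
        stop_here = _aa(nxt) == "*"
        for rest, stop_later in _paths(nxt, cb):
            yield [(ca, nxt)] + rest, stop_here or stop_later


def ng86_pair_oracle(ca: str, cb: str) -> tuple[float, float]:
    """(Nd, Sd) of one codon pair averaged over allowed pathways."""
    clean = [steps for steps, stop in _paths(ca, cb) if not stop]
    paths = clean or [steps for steps, _ in _paths(ca, cb)]
    nds, sds = [], []
    for steps in paths:
        nd = sum(1 for c1, c2 in steps
                 if _aa(c1) == "*" or _aa(c2) == "*" or _aa(c1) != _aa(c2))
        nds.append(nd)
        sds.append(len(steps) - nd)
    return sum(nds) / len(nds), sum(sds) / len(sds)


def ng86_oracle(codon_pairs: list[tuple[str, str]]) -> dict:
    """Full NG86 on a gap-free codon alignment, via the oracles above."""
    N = S = Nd = Sd = 0.0
    for ca, cb in codon_pairs:
        na, sa = ng86_sites_oracle(ca)
        nb, sb = ng86_sites_oracle(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = ng86_pair_oracle(ca, cb)
        Nd += nd
        Sd += sd
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"N": N, "S": S, "Nd": Nd, "Sd": Sd, "pN": pN, "pS": pS,
            "Ka": jc(pN), "Ks": jc(pS)}


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) oracle, two populations, one site at a time
# ---------------------------------------------------------------------------

def wc_site_oracle(dos1: list[int], dos2: list[int], missing: int = -1):
    """Literal transcription of W&C 1984 equations (2)-(4) for r = 2.

    dos1/dos2 are per-individual alt dosages of one site; ``missing``
    entries are dropped. Returns (a, b, c) or None when a population has no
    called individual or n_bar <= 1.
    """
    r = 2
    pops = []
    for dos in (dos1, dos2):
        called = [d for d in dos if d != missing]
        n_i = len(called)
        if n_i < 1:
            return None
        p_i = sum(called) / (2 * n_i)
        h_i = sum(1 for d in called if d == 1) / n_i
        pops.append((n_i, p_i, h_i))
    nbar = sum(n for n, _, _ in pops) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# Exhaustive chaining oracle
# ---------------------------------------------------------------------------

def best_chain_size_oracle(ranks: list[tuple[int, int]], orientation: str,
                           max_gap: int) -> int:
    """Size of the largest valid collinear chain, by exhaustive enumeration.

    A chain is valid when, ordered by rank_a, both rank sequences are
    strictly monotone (rank_b increasing for "same", decreasing for
    "inverted") with consecutive gaps of at most ``max_gap`` on both sides.
    """
    sgn = 1 if orientation == "same" else -1
    n = len(ranks)
    best = 0
    for mask in range(1, 1 << n):
        subset = sorted((ranks[i] for i in range(n) if mask >> i & 1),
                        key=lambda t: (t[0], sgn * t[1]))
        ok = True
        for (a1, b1), (a2, b2) in zip(subset, subset[1:]):
            da, db = a2 - a1, sgn * (b2 - b1)
            if not (0 < da <= max_gap and 0 < db <= max_gap):
                ok = False
                break
        if ok:
            best = max(best, len(subset))
    return best
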