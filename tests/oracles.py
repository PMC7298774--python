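"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's precomputed codon tables: translation
goes through Biopython's Seq.translate and every enumeration is done from
scratch, so agreement with the library is a genuine dual-route check.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from Bio.Seq import Seq


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_count_sites(cds: str) -> tuple[float, float]:
    """NG86 fractional site counts by explicit enumeration of all 9 changes per codon."""
    s = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        for pos in range(3):
            syn = 0
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                    syn += 1
            s += syn / 3.0
    return s, len(cds) - s


def oracle_count_differences(cds_a: str, cds_b: str) -> tuple[float, float]:
    """NG86 pathway-averaged difference counts by explicit pathway enumeration."""
    sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        pos = [j for j in range(3) if ca[j] != cb[j]]
        if not pos:
            continue
        open_paths, blocked_paths = [], []
        for order in permutations(pos):
            cur, syn, nonsyn, blocked = ca, 0, 0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if _aa(nxt) == "*":
                    blocked = True
                if _aa(nxt) == _aa(cur):
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            (blocked_paths if blocked else open_paths).append((syn, nonsyn))
        paths = open_paths or blocked_paths
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    return sd, nd


def oracle_mann_whitney(a, b) -> tuple[float, float]:
    """U statistic and exact two-sided p by full enumeration of group labelings."""
    a, b = list(map(float, a)), list(map(float, b))
    pooled = a + b
    n1, n = len(a), len(a) + len(b)
    mu = len(a) * len(b) / 2.0

    def u_of(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_of(a, b)
    extreme = total = 0
    for comb in combinations(range(n), n1):
        in_a = set(comb)
        u = u_of([pooled[i] for i in comb], [pooled[i] for i in range(n) if i not in in_a])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, min(1.0, extreme / total)


def random_sense_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS built with rejection sampling against translation."""
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if _aa(codon) != "*":
            out.append(codon)
    return "".join(out)


def random_codon_pair(
    n_codons: int, rng: np.random.Generator, mutate_p: float = 0.4
) -> tuple[str, str]:
    """Two stop-free CDS of equal length with multi-position codon differences."""
    a = random_sense_cds(n_codons, rng)
    b_codons = []
    for i in range(0, len(a), 3):
        if rng.random() < mutate_p:
            codon = "".join(rng.choice(list("ACGT"), size=3))
            while _aa(codon) == "*":
                codon = "".join(rng.choice(list("ACGT"), size=3))
            b_codons.append(codon)
        else:
            b_codons.append(a[i : i + 3])
    return a, "".join(b_codons)
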