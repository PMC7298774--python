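"""Nei–Gojobori (1986) Ka/Ks estimation for codon-aligned paralog pairs.

The method counts, per codon, the fractional number of synonymous (S) and
nonsynonymous (N) *sites* — each codon position contributes the fraction of
its three possible single-nucleotide changes that are synonymous (changes to
stop codons count as nonsynonymous) — and, per differing codon, the
pathway-averaged synonymous (Sd) and nonsynonymous (Nd) *differences*:
codons differing at k positions are connected by k! single-step substitution
orders; pathways passing through a stop codon are excluded unless every
pathway is blocked, in which case all are kept. Proportions Sd/S and Nd/N
are corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4) ln(1 - (4/3) p), giving Ks and Ka. Ka/Ks > 1 is read as positive
selection, < 1 as purifying (negative) selection and == 1 (within 1e-9) as
neutral; when Ks is zero or saturated the ratio and the selection class are
undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import ParalogPair, ValidationError

__all__ = [
    "SaturationError",
    "DivergenceEstimate",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "compute_ka_ks",
    "CODON_AA",
    "SENSE_CODONS",
    "STOP_CODONS",
    "SYN_SITES",
    "CHANGE_CLASS",
]

_NTS = "ACGT"
_TABLE = unambiguous_dna_by_id[1]

#: codon -> amino acid, with '*' for the three stop codons (standard code)
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c in CODON_AA if CODON_AA[c] != "*"))


def _syn_sites_of(codon: str) -> float:
    """Fractional synonymous sites of one sense codon (NG86 site counting)."""
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            # stop-codon targets are nonsynonymous by convention
            if CODON_AA[alt] == aa and alt not in STOP_CODONS:
                s += 1.0 / 3.0
    return s


#: sense codon -> fractional synonymous site count (sums with N to 3)
SYN_SITES: dict[str, float] = {c: _syn_sites_of(c) for c in SENSE_CODONS}

#: (codon, position, new nt) -> "syn" | "nonsyn" | "stop"
CHANGE_CLASS: dict[tuple[str, int, str], str] = {}
for _c in SENSE_CODONS:
    for _pos in range(3):
        for _nt in _NTS:
            if _nt == _c[_pos]:
                continue
            _alt = _c[:_pos] + _nt + _c[_pos + 1 :]
            if _alt in STOP_CODONS:
                cls = "stop"
            elif CODON_AA[_alt] == CODON_AA[_c]:
                cls = "syn"
            else:
                cls = "nonsyn"
            CHANGE_CLASS[(_c, _pos, _nt)] = cls


class SaturationError(ValueError):
    """Observed proportion of differences is beyond the Jukes–Cantor domain."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """NG86 divergence summary for one paralog pair.

    ``ks``/``ka`` are None when the corresponding site count is zero or the
    proportion is saturated (p >= 3/4); ``ka_ks`` is None whenever Ks is zero
    or undefined, and ``selection`` is then "undefined".
    """

    pair_id: str
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    ks: Optional[float]
    ka: Optional[float]
    ka_ks: Optional[float]
    selection: str


def _codons(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def count_sites(cds: str) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts (S, N); S + N = len(cds)."""
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not a multiple of 3")
    s = 0.0
    for i, codon in enumerate(_codons(cds)):
        if codon in STOP_CODONS:
            raise ValidationError(f"stop codon {codon} at codon {i + 1}")
        try:
            s += SYN_SITES[codon]
        except KeyError:
            raise ValidationError(f"invalid codon {codon!r} at codon {i + 1}") from None
    return s, len(cds) - s


def _codon_pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts between two sense codons."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    if k == 1:
        pos = diff_pos[0]
        cls = CHANGE_CLASS[(ca, pos, cb[pos])]
        # both endpoints are sense codons, so the single step cannot hit a stop
        return (1.0, 0.0) if cls == "syn" else (0.0, 1.0)

    open_paths: list[tuple[int, int]] = []
    blocked_paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = ca
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != cb:
                blocked = True
            # classify with '*' treated as an amino acid so blocked pathways
            # can still be tallied when every pathway is blocked
            if CODON_AA[nxt] == CODON_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked_paths if blocked else open_paths).append((syn, nonsyn))
    paths = open_paths if open_paths else blocked_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def count_differences(cds_a: str, cds_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous and nonsynonymous differences (Sd, Nd)."""
    if len(cds_a) != len(cds_b):
        raise ValidationError(f"unequal CDS lengths ({len(cds_a)} vs {len(cds_b)})")
    sd = nd = 0.0
    for ca, cb in zip(_codons(cds_a), _codons(cds_b)):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValidationError(f"stop codon in aligned codons {ca}/{cb}")
        dsd, dnd = _codon_pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Raises :class:`SaturationError` for p >= 0.75 where the distance diverges.
    """
    if p < 0:
        raise ValueError(f"proportion {p} negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: distance undefined (saturation)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _corrected(diffs: float, sites: float) -> Optional[float]:
    if sites <= 0:
        return None
    try:
        return jukes_cantor(diffs / sites)
    except SaturationError:
        return None


def compute_ka_ks(pair: ParalogPair) -> DivergenceEstimate:
    """Full NG86 estimate for one pair: sites, differences, Ka, Ks, Ka/Ks, selection class."""
    s_a, _ = count_sites(pair.cds_a)
    s_b, _ = count_sites(pair.cds_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = len(pair.cds_a) - s_sites
    s_diffs, n_diffs = count_differences(pair.cds_a, pair.cds_b)

    ks = _corrected(s_diffs, s_sites)
    ka = _corrected(n_diffs, n_sites)

    if ks is None or ka is None or ks == 0.0:
        ka_ks = None
        selection = "undefined"
    else:
        ka_ks = ka / ks
        if abs(ka_ks - 1.0) <= 1e-9:
            selection = "neutral"
        elif ka_ks > 1.0:
            selection = "positive"
        else:
            selection = "negative"

    return DivergenceEstimate(
        pair_id=pair.pair_id,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        ks=ks,
        ka=ka,
        ka_ks=ka_ks,
        selection=selection,
    )
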