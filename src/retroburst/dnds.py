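"""Uncorrected counting dN/dS on codon alignments.

Synonymous and nonsynonymous codon changes are counted directly: single
differences are classified by the standard code; multi-hit codons average
the (syn, nonsyn) step composition over all minimal mutational pathways that
avoid stop codons, each pathway weighted equally. Counts are not corrected
for multiple substitutions and are not normalized by site opportunities —
the reported ratio is nd/sd of raw change counts. Codon positions holding a
gap, an ambiguous base, or a stop codon in either row of a pair are removed
as missing data for that pair only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .seqio import Alignment
from .simulate import STOP_CODONS, translate_codon

logger = logging.getLogger("retroburst")

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_ID = {c: i for i, c in enumerate(ALL_CODONS)}
MISSING = -1


# ---------------------------------------------------------------------------
# Codon-pair change counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_change_counts(codon_a: str, codon_b: str,
                        skip_multihit: bool = False) -> tuple[float, float]:
    """(synonymous, nonsynonymous) change counts between two sense codons.

    Multi-hit pairs average over all minimal pathways avoiding stop-codon
    intermediates (all pathways if none avoids a stop); with
    ``skip_multihit`` such pairs contribute (0, 0) instead.
    """
    for c in (codon_a, codon_b):
        if len(c) != 3 or set(c) - set(BASES):
            raise ValueError(f"not an unambiguous codon: {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} must be excluded upstream")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    if len(diff_pos) == 1:
        syn = translate_codon(codon_a) == translate_codon(codon_b)
        return (1.0, 0.0) if syn else (0.0, 1.0)
    if skip_multihit:
        return (0.0, 0.0)

    results = []
    fallback = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        fallback.append((sd, nd))
        if not blocked:
            results.append((sd, nd))
    use = results if results else fallback
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return (sd, nd)


def _build_tables(skip_multihit: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(SD, ND, valid) lookup tables over 64x64 codon-id pairs."""
    SD = np.zeros((64, 64))
    ND = np.zeros((64, 64))
    valid = np.zeros((64, 64), dtype=bool)
    for a in ALL_CODONS:
        for b in ALL_CODONS:
            if a in STOP_CODONS or b in STOP_CODONS:
                continue
            sd, nd = codon_change_counts(a, b, skip_multihit)
            ia, ib = CODON_ID[a], CODON_ID[b]
            SD[ia, ib] = sd
            ND[ia, ib] = nd
            valid[ia, ib] = True
    return SD, ND, valid


_TABLES: dict[bool, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _tables(skip_multihit: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if skip_multihit not in _TABLES:
        _TABLES[skip_multihit] = _build_tables(skip_multihit)
    return _TABLES[skip_multihit]


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon-partitioned alignment; codons with gaps/N are missing units."""

    alignment: Alignment
    frame_anchor: int = 0

    def __post_init__(self) -> None:
        usable = self.alignment.length - self.frame_anchor
        if usable % 3 != 0:
            raise ValueError(
                f"length {usable} after frame anchor is not divisible by 3")

    @property
    def n_codons(self) -> int:
        return (self.alignment.length - self.frame_anchor) // 3

    @property
    def ids(self) -> list[str]:
        return self.alignment.ids

    @property
    def groups(self) -> dict[str, str]:
        return self.alignment.groups

    def encoded(self) -> np.ndarray:
        """(n, n_codons) codon-id matrix; gap/N codons = MISSING."""
        out = np.full((self.alignment.n, self.n_codons), MISSING, dtype=np.int16)
        for i, rec in enumerate(self.alignment.records):
            s = rec.seq[self.frame_anchor:]
            for j in range(self.n_codons):
                codon = s[3 * j:3 * j + 3]
                if set(codon) <= set(BASES):
                    out[i, j] = CODON_ID[codon]
        return out


def encode_codon_row(seq: str) -> np.ndarray:
    if len(seq) % 3:
        raise ValueError("row length not divisible by 3")
    out = np.full(len(seq) // 3, MISSING, dtype=np.int16)
    for j in range(len(out)):
        codon = seq[3 * j:3 * j + 3]
        if set(codon) <= set(BASES):
            out[j] = CODON_ID[codon]
    return out


# ---------------------------------------------------------------------------
# Pairwise counting
# ---------------------------------------------------------------------------

@dataclass
class PairDnds:
    id_a: str
    id_b: str
    nd: float
    sd: float
    codons_compared: int
    excluded_codons: int
    empty: bool = False

    @property
    def ratio(self) -> float | None:
        """nd/sd, or None when sd == 0 (undefined)."""
        if self.sd == 0:
            return None
        return self.nd / self.sd


_STOP_IDS = np.array([CODON_ID[c] for c in sorted(STOP_CODONS)])


def pair_dnds(row_a: str | np.ndarray, row_b: str | np.ndarray,
              id_a: str = "a", id_b: str = "b",
              skip_multihit: bool = False) -> PairDnds:
    """Counting dN/dS for one row pair of a codon alignment.

    Codon positions where either row has a gap, N, or a stop codon are
    excluded for this pair; the remainder is summed via the pathway-averaged
    per-codon change counts.
    """
    ea = encode_codon_row(row_a) if isinstance(row_a, str) else row_a
    eb = encode_codon_row(row_b) if isinstance(row_b, str) else row_b
    if len(ea) != len(eb):
        raise ValueError("rows differ in codon length")
    SD, ND, valid_tab = _tables(skip_multihit)
    present = (ea != MISSING) & (eb != MISSING)
    stops = np.isin(ea, _STOP_IDS) | np.isin(eb, _STOP_IDS)
    usable = present & ~stops
    excluded = int(len(ea) - usable.sum())
    if not usable.any():
        return PairDnds(id_a, id_b, 0.0, 0.0, 0, excluded, empty=True)
    a, b = ea[usable], eb[usable]
    sd = float(SD[a, b].sum())
    nd = float(ND[a, b].sum())
    return PairDnds(id_a, id_b, nd, sd, int(usable.sum()), excluded)


# ---------------------------------------------------------------------------
# Per-family distributions and group comparisons
# ---------------------------------------------------------------------------

@dataclass
class FamilyDnds:
    group: str
    n_pairs: int
    n_defined: int
    n_undefined: int
    median: float | None
    q1: float | None
    q3: float | None
    ratios: list[float] = field(default_factory=list)
    flagged: bool = False


def family_dnds(codon_alignment: CodonAlignment,
                skip_multihit: bool = False) -> list[FamilyDnds]:
    """Pooled intra-group pairwise nd/sd distributions with median and IQR.

    Pairs with sd == 0 are excluded from the distribution but counted;
    groups where every ratio is undefined are flagged.
    """
    enc = codon_alignment.encoded()
    idx_of = {rid: i for i, rid in enumerate(codon_alignment.ids)}
    members: dict[str, list[str]] = {}
    for rid in codon_alignment.ids:
        members.setdefault(codon_alignment.groups[rid], []).append(rid)
    out: list[FamilyDnds] = []
    for group in sorted(members):
        mem = members[group]
        if len(mem) < 2:
            continue
        ratios: list[float] = []
        undefined = 0
        n_pairs = 0
        for a, b in itertools.combinations(mem, 2):
            pr = pair_dnds(enc[idx_of[a]], enc[idx_of[b]], a, b, skip_multihit)
            n_pairs += 1
            r = pr.ratio
            if r is None:
                undefined += 1
            else:
                ratios.append(r)
        if ratios:
            med = float(np.median(ratios))
            q1, q3 = (float(q) for q in np.percentile(ratios, [25, 75]))
            out.append(FamilyDnds(group, n_pairs, len(ratios), undefined,
                                  med, q1, q3, ratios))
        else:
            logger.info("group %s: all dN/dS ratios undefined", group)
            out.append(FamilyDnds(group, n_pairs, 0, undefined, None, None,
                                  None, [], flagged=True))
    return out


@dataclass
class MwuResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")
        if not 0 < self.p <= 1:
            raise ValueError("p outside (0, 1]")

    @property
    def significance_tier(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def mann_whitney(ratios_a: list[float], ratios_b: list[float]) -> MwuResult:
    """Two-sided Mann-Whitney U; exact for small tie-free samples, normal
    approximation with tie correction otherwise."""
    if not ratios_a or not ratios_b:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(ratios_a), len(ratios_b)
    has_ties = len(set(ratios_a) | set(ratios_b)) < n1 + n2
    if n1 <= 10 and n2 <= 10 and not has_ties:
        method = "exact"
    else:
        method = "normal-with-ties"
    res = sps.mannwhitneyu(ratios_a, ratios_b, alternative="two-sided",
                           method="exact" if method == "exact" else "asymptotic")
    p = float(min(res.pvalue, 1.0))
    if math.isnan(p):  # zero-variance tie degeneracy
        p = 1.0
    return MwuResult(u=float(res.statistic), p=p, n1=n1, n2=n2, method=method)


def group_tests(distributions: list[FamilyDnds]) -> list[dict]:
    """All pairwise group Mann-Whitney comparisons with significance tiers."""
    rows = []
    usable = [d for d in distributions if d.ratios]
    for a, b in itertools.combinations(usable, 2):
        res = mann_whitney(a.ratios, b.ratios)
        rows.append({
            "group_a": a.group, "group_b": b.group, "U": res.u,
            "p_value": res.p, "n_a": res.n1, "n_b": res.n2,
            "method": res.method, "significance": res.significance_tier,
        })
    return rows
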