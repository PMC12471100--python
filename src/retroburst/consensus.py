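"""Consensus building, ORF prediction, family clustering and PBS matching."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import global_identity
from .seqio import Alignment, SequenceRecord, revcomp
from .simulate import STOP_CODONS, translate_codon

logger = logging.getLogger("retroburst")


@dataclass
class PbsMatch:
    trna_id: str
    offset: int          # bases between the 5'-LTR end and the PBS start
    length: int
    mismatches: int


@dataclass
class ConsensusElement:
    family_id: str
    consensus_seq: str
    orf_interval: tuple[int, int] | None
    orf_protein: str | None
    pbs_match: PbsMatch | None = None

    def __post_init__(self) -> None:
        if self.orf_interval is not None:
            s, e = self.orf_interval
            if (e - s) % 3 != 0:
                raise ValueError("ORF interval length must be divisible by 3")
        if self.orf_protein and "*" in self.orf_protein:
            raise ValueError("ORF protein must have no internal stop")
        if self.pbs_match is not None and self.pbs_match.offset < 0:
            raise ValueError("PBS offset must be >= 0")


@dataclass
class FamilyAssignment:
    assignment: dict[str, str]
    linkage: pd.DataFrame  # pairwise identity matrix used for clustering

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, fam in self.assignment.items():
            out.setdefault(fam, []).append(cid)
        return out


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGT"


def build_consensus(alignment: Alignment, plurality: float = 0.5) -> str:
    """Column-plurality consensus.

    Per column the most frequent non-N symbol wins (ties broken A<C<G<T);
    columns where the gap is the most frequent symbol with fraction >=
    ``plurality`` are dropped. All-N columns emit N.
    """
    rows = [r.seq for r in alignment.records]
    n = len(rows)
    out: list[str] = []
    for j in range(alignment.length):
        counts: dict[str, int] = {}
        for row in rows:
            counts[row[j]] = counts.get(row[j], 0) + 1
        gap = counts.get("-", 0)
        base_counts = [(counts.get(b, 0), b) for b in _BASE_ORDER]
        best_count = max(c for c, _ in base_counts)
        # deterministic tie-break: first of A<C<G<T among maxima
        best_base = next(b for c, b in base_counts if c == best_count)
        if gap > best_count and gap / n >= plurality:
            continue
        if best_count == 0:
            if counts.get("N", 0) > 0 and gap == 0:
                out.append("N")
            elif gap > 0 and gap / n >= plurality:
                continue
            else:
                out.append("N")
        else:
            out.append(best_base)
    return "".join(out)


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def find_orf(consensus_seq: str, min_len: int = 300,
             require_atg: bool = True) -> tuple[tuple[int, int], str] | None:
    """Longest start-codon-initiated ORF on the three sense-strand frames.

    The interval includes the stop codon; the returned translation does not.
    Returns None (logged) when no ORF of at least ``min_len`` nt exists.
    """
    if len(consensus_seq) < min_len:
        raise ValueError("consensus shorter than min_len")
    best: tuple[int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(consensus_seq) - 2, 3):
            codon = consensus_seq[i:i + 3]
            if start is None:
                if codon == "ATG" or (not require_atg
                                      and codon not in STOP_CODONS
                                      and set(codon) <= set("ACGT")):
                    start = i
            elif codon in STOP_CODONS:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    if best is None or best[1] - best[0] < min_len:
        logger.info("no ORF of >= %d nt found", min_len)
        return None
    s, e = best
    protein = "".join(translate_codon(consensus_seq[i:i + 3])
                      for i in range(s, e - 3, 3))
    return (s, e), protein


# ---------------------------------------------------------------------------
# Family clustering at the identity threshold
# ---------------------------------------------------------------------------

def cluster_families(copies: Sequence[SequenceRecord],
                     threshold: float = 0.70) -> FamilyAssignment:
    """Single-linkage clustering on pairwise global identity.

    Two copies land in one family iff they are connected by a chain of pairs
    with identity >= threshold. Family labels are the smallest member id.
    """
    if not copies:
        raise ValueError("need at least one copy")
    ids = [c.id for c in copies]
    n = len(ids)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = global_identity(copies[i].seq,
                                                        copies[j].seq)
    # union-find single linkage
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    assignment: dict[str, str] = {}
    for members in clusters.values():
        label = min(ids[m] for m in members)
        for m in members:
            assignment[ids[m]] = label
    linkage = pd.DataFrame(ident, index=ids, columns=ids)
    return FamilyAssignment(assignment=assignment, linkage=linkage)


# ---------------------------------------------------------------------------
# Primer binding site
# ---------------------------------------------------------------------------

def locate_pbs(consensus_seq: str, ltr5_end: int,
               trna_lib: Sequence[SequenceRecord], search_span: int = 30,
               min_match: int = 8, max_mismatch: int = 1,
               max_len: int = 18) -> PbsMatch | None:
    """Best reverse-complement match of a tRNA 3' end just inside the 5'-LTR.

    Scans ``search_span`` bases 3' of the LTR for matches to each tRNA's
    3'-terminal ``max_len`` nt; ties resolve to fewest mismatches, then tRNA
    file order, then smallest offset. Returns None below ``min_match``.
    """
    if not trna_lib:
        raise ValueError("tRNA library is empty")
    best: tuple[tuple, PbsMatch] | None = None
    for order, trna in enumerate(trna_lib):
        target = revcomp(trna.seq[-max_len:])
        for off in range(search_span + 1):
            pos = ltr5_end + off
            for k in range(min(max_len, len(trna.seq), len(consensus_seq) - pos),
                           min_match - 1, -1):
                seg = consensus_seq[pos:pos + k]
                if len(seg) < k:
                    continue
                mm = sum(x != y or x == "N" for x, y in zip(seg, target[:k]))
                if mm <= max_mismatch:
                    key = (-k, mm, order, off)
                    cand = PbsMatch(trna_id=trna.id, offset=off, length=k,
                                    mismatches=mm)
                    if best is None or key < best[0]:
                        best = (key, cand)
                    break  # longer k failed or succeeded; shorter k not better
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Convenience: per-family consensus elements
# ---------------------------------------------------------------------------

def consensus_elements(alignment: Alignment, trna_lib: Sequence[SequenceRecord]
                       | None = None, ltr5_end_hint: int | None = None,
                       orf_min_len: int = 300) -> list[ConsensusElement]:
    """Build one ConsensusElement per group label of the alignment."""
    out: list[ConsensusElement] = []
    for fam, members in sorted(alignment.group_members().items()):
        if len(members) < 2:
            logger.info("family %s has a single member; consensus equals it", fam)
            rec = next(r for r in alignment.records if r.id == members[0])
            cons = rec.seq.replace("-", "")
        else:
            cons = build_consensus(alignment.subset(members))
        orf = find_orf(cons, min_len=orf_min_len) if len(cons) >= orf_min_len else None
        interval, protein = orf if orf else (None, None)
        pbs = None
        if trna_lib and ltr5_end_hint is not None:
            pbs = locate_pbs(cons, ltr5_end_hint, trna_lib)
        out.append(ConsensusElement(family_id=fam, consensus_seq=cons,
                                    orf_interval=interval, orf_protein=protein,
                                    pbs_match=pbs))
    return out
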