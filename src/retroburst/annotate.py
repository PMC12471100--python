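"""Delimit full-unit LTR retrotransposons around seed loci.

Elements are found as long direct repeats (the LTR pair) inside a window
around each seed hit, snapped to canonical TGT...ACA repeat termini, and
confirmed by identical 4-bp target site duplications in the immediate
flanks. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .seqio import PipelineConfig, SequenceRecord

logger = logging.getLogger("retroburst")


# ---------------------------------------------------------------------------
# Pairwise global identity (shared scorer; also used for family clustering)
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in one optimal global alignment.

    Scoring: match 1, mismatch 0, gap open 10, gap extend 0.5. Gap columns
    count as non-matches; N never matches.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _ALIGNER.align(a.replace("N", "n"), b.replace("N", "m"))[0]
    counts = aln.counts()
    return counts.identities / aln.length


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LtrCandidate:
    """A direct-repeat pair inside a window (window-relative coordinates)."""

    left: tuple[int, int]
    right: tuple[int, int]
    identity: float
    termini_ok: bool
    termini_mismatches: int = 0
    tsd_match: bool = False

    def __post_init__(self) -> None:
        if self.left[0] >= self.right[0]:
            raise ValueError("left repeat must start before the right repeat")
        if self.left[1] > self.right[0]:
            raise ValueError("repeats must not overlap")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return (self.left[0], self.right[1])


@dataclass
class LtrElement:
    """A delimited full-unit element on a contig."""

    contig_id: str
    interval: tuple[int, int]
    strand: str
    ltr5_interval: tuple[int, int]
    ltr3_interval: tuple[int, int]
    internal_interval: tuple[int, int]
    tsd_left: str
    tsd_right: str
    tsd_confirmed: bool
    ltr_identity: float
    termini_ok: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        s, e = self.interval
        if self.ltr5_interval[0] != s or self.ltr3_interval[1] != e:
            raise ValueError("LTRs must lie at the element boundaries")
        if self.internal_interval != (self.ltr5_interval[1], self.ltr3_interval[0]):
            raise ValueError("internal region must be the interval minus the LTRs")
        if self.tsd_confirmed and self.tsd_left != self.tsd_right:
            raise ValueError("confirmed TSDs must be identical")
        if not 0.0 <= self.ltr_identity <= 1.0:
            raise ValueError("ltr_identity outside [0, 1]")


@dataclass
class AnnotationResult:
    elements: list[LtrElement]
    unresolved: list[tuple[str, int, int]]
    n_skipped_contigs: int = 0
    n_deduplicated: int = 0


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_window(contig: SequenceRecord, anchor: tuple[int, int],
                   total_span: int = 15000) -> tuple[str, int]:
    """Window of ~total_span centered on the anchor, clipped at contig ends.

    Returns (window sequence, offset) with window[i] == contig.seq[offset+i].
    """
    s, e = anchor
    if not (0 <= s < e <= len(contig.seq)):
        raise ValueError(
            f"anchor {anchor} outside contig {contig.id!r} (len {len(contig.seq)})")
    center = (s + e) // 2
    start = max(0, center - total_span // 2)
    end = min(len(contig.seq), start + total_span)
    start = max(0, end - total_span)
    return contig.seq[start:end], start


# ---------------------------------------------------------------------------
# Direct-repeat (LTR pair) detection
# ---------------------------------------------------------------------------

def _kmer_seed_diagonals(window: str, k: int, min_sep: int) -> dict[int, list[int]]:
    """Positions of exact k-mer self-matches, keyed by diagonal (separation)."""
    index: dict[str, list[int]] = {}
    for i in range(len(window) - k + 1):
        index.setdefault(window[i:i + k], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d >= min_sep:
                    diagonals.setdefault(d, []).append(positions[ai])
    return diagonals


def _cluster_diagonals(diagonals: dict[int, list[int]], band: int) -> list[int]:
    """Group nearby diagonals; return the dominant diagonal of each group."""
    reps: list[int] = []
    for d in sorted(diagonals):
        placed = False
        for gi, rep in enumerate(reps):
            if abs(d - rep) <= band:
                if len(diagonals[d]) > len(diagonals[rep]):
                    reps[gi] = d
                placed = True
                break
        if not placed:
            reps.append(d)
    return reps


def _chain_runs(positions: list[int], k: int, chain_gap: int) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    positions = sorted(positions)
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev <= chain_gap:
            prev = p
        else:
            runs.append((start, prev + k))
            start = prev = p
    runs.append((start, prev + k))
    return runs


def _extend_run(window: str, a: int, b: int, d: int, max_len: int,
                mismatch_stop: int = 6, roll: int = 16,
                roll_min: int = 9) -> tuple[int, int]:
    """Greedy outward extension of a co-diagonal run.

    Stops on a burst of consecutive mismatches or when rolling identity over
    the last ``roll`` comparisons drops below ``roll_min`` matches — the
    latter bounds overshoot into unrelated flanking sequence, where chance
    matches would otherwise let the extension drift far past the repeat."""
    W = len(window)
    from collections import deque

    def walk(start: int, direction: int, limit: int) -> int:
        pos = start
        bad = 0
        recent: deque[bool] = deque(maxlen=roll)
        steps = 0
        while steps < limit:
            x = pos - 1 if direction < 0 else pos
            if x < 0 or x + d >= W:
                break
            hit = window[x] == window[x + d]
            recent.append(hit)
            if hit:
                bad = 0
            else:
                bad += 1
                if bad > mismatch_stop:
                    break
            if len(recent) == roll and sum(recent) < roll_min:
                break
            pos += direction
            steps += 1
        # trim the trailing mismatch overhang
        return pos + bad if direction < 0 else pos - bad

    a = walk(a, -1, max_len + 2 * mismatch_stop)
    b = walk(b, +1, max_len + 2 * mismatch_stop)
    return a, b


def _terminus_options(window: str, d: int, lo: int, hi: int, motif: str,
                      anchor_offset: int, max_mm: int) -> list[tuple[int, int]]:
    """Positions in [lo, hi] where both repeats carry ``motif``.

    ``anchor_offset`` is the offset of the motif start relative to the
    returned boundary position. Returns (boundary, mismatches) options.
    """
    W = len(window)
    out: list[tuple[int, int]] = []
    for pos in range(lo, hi + 1):
        m0 = pos + anchor_offset
        m1 = m0 + d
        if m0 < 0 or m1 + 3 > W:
            continue
        mm = sum(window[m0 + i] != motif[i] for i in range(3))
        mm += sum(window[m1 + i] != motif[i] for i in range(3))
        if mm <= max_mm:
            out.append((pos, mm))
    return out


def _repeat_continues(window: str, pos: int, d: int, direction: int,
                      probe: int = 20, thresh: float = 0.7) -> bool:
    """True when the direct repeat clearly extends past ``pos`` (going
    ``direction`` = +1 right / -1 left), i.e. the boundary would truncate."""
    W = len(window)
    matches = total = 0
    for step in range(probe):
        x = pos + direction * step if direction > 0 else pos - 1 - step
        if x < 0 or x + d >= W:
            break
        total += 1
        if window[x] == window[x + d]:
            matches += 1
    if total < 8:
        return False
    return matches / total >= thresh


def find_ltr_pairs(window: str, ltr_min_len: int = 100, ltr_max_len: int = 1000,
                   min_identity: float = 0.8, require_termini: bool = True,
                   termini_mismatch: int = 0, k: int = 12, band: int = 50,
                   chain_gap: int = 200, terminus_slack: int = 90,
                   tsd_len: int = 4) -> list[LtrCandidate]:
    """Find direct-repeat (LTR) pairs in a window by exact k-mer seeding.

    Co-diagonal seeds are chained and extended to maximal similar repeats,
    then boundaries are snapped so both repeats start with TGT and end with
    ACA. With ``require_termini`` a candidate is kept only if the snapped
    termini have at most ``termini_mismatch`` mismatching bases (out of 12);
    boundary choice prefers TSD-consistent, low-mismatch, nearby positions.
    Candidates are sorted by identity descending (ties: longer, leftmost).
    """
    W = len(window)
    if W < 2 * ltr_min_len:
        return []
    diagonals = _kmer_seed_diagonals(window, k, min_sep=ltr_min_len)
    if not diagonals:
        return []
    candidates: list[LtrCandidate] = []
    for d in _cluster_diagonals(diagonals, band):
        for a0, b0 in _chain_runs(diagonals[d], k, chain_gap):
            if b0 - a0 > ltr_max_len + 200:
                continue
            a, b = _extend_run(window, a0, b0, d, max_len=ltr_max_len)
            max_mm = termini_mismatch if require_termini else 6
            # raw extension overshoots into chance flank matches, never far
            # inward, so the snap range is asymmetric around the raw ends
            starts = _terminus_options(window, d, a - 8, a + terminus_slack,
                                       "TGT", 0, max_mm)
            ends = _terminus_options(window, d, b - terminus_slack, b + 8,
                                     "ACA", -3, max_mm)
            if require_termini and (not starts or not ends):
                continue
            if not starts:
                starts = [(a, 6)]
            if not ends:
                ends = [(b, 6)]
            # boundaries that truncate an ongoing repeat are artifacts of
            # chance TGT/ACA occurrences inside the repeat — drop them
            starts = [(s, mm) for s, mm in starts
                      if not _repeat_continues(window, s, d, -1)]
            ends = [(e, mm) for e, mm in ends
                    if not _repeat_continues(window, e, d, +1)]
            best = None
            for s, mm_s in starts:
                for e, mm_e in ends:
                    if not ltr_min_len <= e - s <= ltr_max_len:
                        continue
                    if e > s + d:  # repeats would overlap
                        continue
                    mm = mm_s + mm_e
                    if require_termini and mm > termini_mismatch:
                        continue
                    tsd_ok = (s - tsd_len >= 0 and e + d + tsd_len <= W
                              and "N" not in window[s - tsd_len:s]
                              and window[s - tsd_len:s]
                              == window[e + d:e + d + tsd_len])
                    key = (0 if tsd_ok else 1, mm, abs(s - a) + abs(e - b))
                    if best is None or key < best[0]:
                        best = (key, s, e, mm, tsd_ok)
            if best is None:
                continue
            _, s, e, mm, tsd_ok = best
            matches = sum(window[s + i] == window[s + d + i]
                          and window[s + i] != "N"
                          for i in range(e - s))
            identity = matches / (e - s)
            if identity < min_identity:
                continue
            candidates.append(LtrCandidate(
                left=(s, e), right=(s + d, e + d), identity=identity,
                termini_ok=(mm == 0), termini_mismatches=mm,
                tsd_match=tsd_ok))
    # dedupe near-identical candidates (same span +- a few bp)
    deduped: list[LtrCandidate] = []
    for c in sorted(candidates,
                    key=lambda c: (-c.identity, -(c.left[1] - c.left[0]),
                                   c.left[0])):
        if any(abs(c.left[0] - o.left[0]) < 10 and abs(c.right[1] - o.right[1]) < 10
               for o in deduped):
            continue
        deduped.append(c)
    return deduped


# ---------------------------------------------------------------------------
# Element confirmation
# ---------------------------------------------------------------------------

def confirm_element(window: str, candidate: LtrCandidate, tsd_len: int = 4,
                    offset: int = 0, contig_id: str = "",
                    strand: str = "+") -> LtrElement:
    """Attach TSD evidence to a candidate (``if possible`` semantics).

    Reads ``tsd_len`` bases immediately upstream of the 5'-LTR and downstream
    of the 3'-LTR; the element is returned regardless of whether the TSDs
    match, with ``tsd_confirmed`` set accordingly.
    """
    (ls, le), (rs, re) = candidate.left, candidate.right
    left_flank = window[max(0, ls - tsd_len):ls]
    right_flank = window[re:re + tsd_len]
    notes = ""
    if len(left_flank) < tsd_len or len(right_flank) < tsd_len:
        confirmed = False
        notes = "element at window edge; flank shorter than tsd_len"
        logger.info("TSD unconfirmed for candidate at %d-%d: %s",
                    ls + offset, re + offset, notes)
    else:
        confirmed = (left_flank == right_flank and "N" not in left_flank)
    return LtrElement(
        contig_id=contig_id,
        interval=(ls + offset, re + offset),
        strand=strand,
        ltr5_interval=(ls + offset, le + offset),
        ltr3_interval=(rs + offset, re + offset),
        internal_interval=(le + offset, rs + offset),
        tsd_left=left_flank,
        tsd_right=right_flank,
        tsd_confirmed=confirmed,
        ltr_identity=candidate.identity,
        termini_ok=candidate.termini_ok,
        notes=notes,
    )


def ltr_pair_identity(element: LtrElement, contig: SequenceRecord) -> float:
    """Global-alignment identity of the element's two LTRs on the contig."""
    l5 = contig.seq[element.ltr5_interval[0]:element.ltr5_interval[1]]
    l3 = contig.seq[element.ltr3_interval[0]:element.ltr3_interval[1]]
    return global_identity(l5, l3)


# ---------------------------------------------------------------------------
# Whole-genome annotation
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def annotate_genome(contigs: Sequence[SequenceRecord],
                    seed_hits: Iterable[tuple[str, int, int]],
                    config: PipelineConfig | None = None) -> AnnotationResult:
    """Run extract_window -> find_ltr_pairs -> confirm_element per seed.

    Contigs shorter than ``config.min_contig_len`` are skipped (counted);
    elements sharing >50% reciprocal overlap are deduplicated, keeping the
    higher LTR identity. Seeds with no qualifying candidate are reported
    as unresolved.
    """
    config = config or PipelineConfig()
    by_id = {c.id: c for c in contigs}
    elements: list[LtrElement] = []
    unresolved: list[tuple[str, int, int]] = []
    skipped: set[str] = set()

    for contig_id, s, e in seed_hits:
        contig = by_id.get(contig_id)
        if contig is None:
            raise KeyError(f"seed contig {contig_id!r} not in genome")
        if len(contig.seq) < config.min_contig_len:
            skipped.add(contig_id)
            continue
        window, offset = extract_window(contig, (s, e), config.window_span)
        cands = find_ltr_pairs(
            window, ltr_min_len=config.ltr_min_len,
            ltr_max_len=config.ltr_max_len,
            min_identity=config.ltr_min_identity, require_termini=True,
            termini_mismatch=config.termini_mismatch,
            tsd_len=config.tsd_len)
        anchor_mid = (s + e) // 2 - offset
        containing = [c for c in cands
                      if c.left[0] <= anchor_mid < c.right[1]]
        if not containing:
            unresolved.append((contig_id, s, e))
            continue
        best = containing[0]  # already identity-desc, longest, leftmost
        elem = confirm_element(window, best, tsd_len=config.tsd_len,
                               offset=offset, contig_id=contig_id)
        elements.append(elem)

    if skipped:
        logger.info("skipped %d contigs shorter than %d bp",
                    len(skipped), config.min_contig_len)

    # dedup elements with >50% reciprocal overlap on the same contig
    kept: list[LtrElement] = []
    n_dropped = 0
    for elem in sorted(elements, key=lambda e: (-e.ltr_identity,
                                                e.interval[1] - e.interval[0])):
        dup = any(e.contig_id == elem.contig_id
                  and _reciprocal_overlap(e.interval, elem.interval) > 0.5
                  for e in kept)
        if dup:
            n_dropped += 1
        else:
            kept.append(elem)
    kept.sort(key=lambda e: (e.contig_id, e.interval))
    return AnnotationResult(elements=kept, unresolved=unresolved,
                            n_skipped_contigs=len(skipped),
                            n_deduplicated=n_dropped)
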