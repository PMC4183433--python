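"""Locate the templated source of a junction insertion within references.

Insertions are searched by exhaustive local alignment (Smith-Waterman
with affine gaps) against every reference, on both strands when
configured.  A gap of length n costs ``gap_open + n * gap_extend``; all
scores are integer-valued, so traceback comparisons are exact.  Hits are
ranked by score; uniqueness requires the best score to exceed the best
hit at a non-overlapping locus by at least the configured margin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError
from .sequences import Reference, revcomp, validate_dna

try:  # the DP kernel is hot; JIT it when numba is available
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not args else args[0]


@dataclass(frozen=True)
class OriginConfig:
    min_templated_len: int = 10
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_identity: float = 0.8
    uniqueness_margin: int = 2
    search_both_strands: bool = True
    max_report_distance: int = 5000
    max_hits: int = 5

    def __post_init__(self) -> None:
        if self.min_templated_len < 4:
            raise InvalidArgumentError("min_templated_len must be >= 4")
        if not 0 < self.min_identity <= 1:
            raise InvalidArgumentError("min_identity must be in (0, 1]")
        if self.match_score <= 0 or self.mismatch_score >= 0:
            raise InvalidArgumentError("match_score must be positive, mismatch_score negative")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise InvalidArgumentError("gap penalties must be non-positive/negative")


@dataclass(frozen=True)
class OriginHit:
    ref_id: str
    start: int  # 1-based inclusive, sense coordinates
    end: int
    strand: str  # "+" | "-"
    score: int
    identity: float
    gap_count: int
    query_start: int  # 1-based within the insertion
    query_end: int
    unique: bool = False
    distance_to_breakpoint: int | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@_njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), -1e18, dtype=np.float64)
    F = np.full((m + 1, n + 1), -1e18, dtype=np.float64)
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            e = H[i, j - 1] + gap_open + gap_ext
            if E[i, j - 1] + gap_ext > e:
                e = E[i, j - 1] + gap_ext
            f = H[i - 1, j] + gap_open + gap_ext
            if F[i - 1, j] + gap_ext > f:
                f = F[i - 1, j] + gap_ext
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int8)


def _traceback(H, E, F, q, r, i, j, cfg: OriginConfig):
    """Walk back from cell (i, j); returns (q_start, r_start, n_match,
    n_cols, n_gapcols) with 1-based starts."""
    n_match = n_cols = n_gap = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0.0:
                break
            s = cfg.match_score if q[i - 1] == r[j - 1] else cfg.mismatch_score
            if H[i, j] == H[i - 1, j - 1] + s:
                n_cols += 1
                if q[i - 1] == r[j - 1]:
                    n_match += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consumes reference base
            n_cols += 1
            n_gap += 1
            opened = H[i, j - 1] + cfg.gap_open + cfg.gap_extend
            if E[i, j] == opened:
                state = "H"
            j -= 1
        else:  # "F": gap in reference, consumes query base
            n_cols += 1
            n_gap += 1
            opened = H[i - 1, j] + cfg.gap_open + cfg.gap_extend
            if F[i, j] == opened:
                state = "H"
            i -= 1
    return i + 1, j + 1, n_match, n_cols, n_gap


def _hits_for_orientation(
    query: str, ref: Reference, strand: str, cfg: OriginConfig
) -> list[OriginHit]:
    ref_seq = ref.sequence if strand == "+" else revcomp(ref.sequence)
    q = _encode(query)
    r = _encode(ref_seq)
    H, E, F = _sw_fill(
        q, r,
        float(cfg.match_score), float(cfg.mismatch_score),
        float(cfg.gap_open), float(cfg.gap_extend),
    )
    n = len(ref_seq)
    hits: list[OriginHit] = []
    masked = np.zeros(n + 1, dtype=bool)
    work = H.copy()
    for _ in range(cfg.max_hits):
        flat = int(np.argmax(work))
        i, j = divmod(flat, n + 1)
        score = work[i, j]
        if score <= 0:
            break
        q_start, r_start, n_match, n_cols, n_gap = _traceback(H, E, F, q, r, i, j, cfg)
        r_lo, r_hi = r_start, j  # 1-based inclusive on this orientation
        if strand == "+":
            start, end = r_lo, r_hi
        else:
            start, end = n - r_hi + 1, n - r_lo + 1
        hits.append(
            OriginHit(
                ref_id=ref.id,
                start=start,
                end=end,
                strand=strand,
                score=int(round(score)),
                identity=n_match / n_cols if n_cols else 0.0,
                gap_count=n_gap,
                query_start=q_start,
                query_end=i,
            )
        )
        masked[r_lo : r_hi + 1] = True
        work[:, masked] = -1.0
    return hits


def find_origin(
    insertion_seq: str, refs: list[Reference], cfg: OriginConfig | None = None
) -> list[OriginHit]:
    """Rank candidate origins of ``insertion_seq`` across ``refs``.

    Hits below ``min_identity`` or aligning fewer than
    ``min(|insertion|, min_templated_len)`` insertion bases are discarded.
    The top hit's ``unique`` flag is set when its score exceeds the best
    hit at any non-overlapping locus by at least ``uniqueness_margin``.
    Deletions relative to the origin are representable as gaps.
    """
    cfg = cfg or OriginConfig()
    if not insertion_seq:
        raise InvalidArgumentError("insertion_seq must be nonempty")
    if not refs:
        raise InvalidArgumentError("reference set must be nonempty")
    query = validate_dna(insertion_seq, what="insertion")

    raw: list[OriginHit] = []
    for ref in refs:
        raw.extend(_hits_for_orientation(query, ref, "+", cfg))
        if cfg.search_both_strands:
            raw.extend(_hits_for_orientation(query, ref, "-", cfg))

    min_aligned = min(len(query), cfg.min_templated_len)
    kept = [
        h for h in raw
        if h.identity >= cfg.min_identity and (h.query_end - h.query_start + 1) >= min_aligned
    ]
    # rank by score; sense preferred on ties (all printed annotations are
    # sense-coordinate), then leftmost
    kept.sort(key=lambda h: (-h.score, h.strand != "+", h.ref_id, h.start))
    if not kept:
        return []

    best = kept[0]
    runner_up = 0
    for h in kept[1:]:
        overlaps = (
            h.ref_id == best.ref_id
            and h.strand == best.strand
            and not (h.end < best.start or h.start > best.end)
        )
        if not overlaps:
            runner_up = h.score
            break
    kept[0] = replace(best, unique=(best.score - runner_up) >= cfg.uniqueness_margin)
    return kept


def classify_templated(
    hits: list[OriginHit], insertion_seq: str, cfg: OriginConfig | None = None
) -> str:
    """Classify an insertion as ``templated`` / ``ambiguous`` /
    ``untemplated``; insertions shorter than ``min_templated_len`` are
    reported as ``below_threshold`` (too short to call either way)."""
    cfg = cfg or OriginConfig()
    if len(insertion_seq) < cfg.min_templated_len:
        return "below_threshold"
    if not hits:
        return "untemplated"
    best = hits[0]
    covered = best.query_end - best.query_start + 1
    if best.identity >= cfg.min_identity and covered >= cfg.min_templated_len:
        return "templated" if best.unique else "ambiguous"
    return "untemplated"


def origin_distance(hit: OriginHit, breakpoints: dict[str, int]) -> int:
    """Minimum absolute distance (bp) between the hit interval and the
    junction breakpoint on the hit's reference.

    ``breakpoints`` maps reference id -> 1-based breakpoint position (the
    donor break and/or the acceptor break, whichever references apply).
    """
    if hit.ref_id not in breakpoints:
        raise InvalidArgumentError(f"no breakpoint recorded on reference {hit.ref_id!r}")
    b = breakpoints[hit.ref_id]
    if hit.start <= b <= hit.end:
        return 0
    return min(abs(b - hit.start), abs(b - hit.end))


def decompose_insertion(
    insertion_seq: str, refs: list[Reference], cfg: OriginConfig | None = None
) -> list[OriginHit]:
    """Greedy longest-first decomposition of a composite insertion into
    templated blocks of at least ``min_templated_len`` aligned bases.

    The best hit is taken, its query span masked, and the flanking query
    segments searched recursively."""
    cfg = cfg or OriginConfig()
    out: list[OriginHit] = []

    def recurse(seg: str, offset: int) -> None:
        if len(seg) < cfg.min_templated_len:
            return
        hits = find_origin(seg, refs, cfg)
        hits = [h for h in hits if (h.query_end - h.query_start + 1) >= cfg.min_templated_len]
        if not hits:
            return
        best = hits[0]
        out.append(
            replace(best, query_start=best.query_start + offset, query_end=best.query_end + offset)
        )
        recurse(seg[: best.query_start - 1], offset)
        recurse(seg[best.query_end :], offset + best.query_end)

    recurse(validate_dna(insertion_seq, what="insertion"), 0)
    out.sort(key=lambda h: h.query_start)
    return out
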