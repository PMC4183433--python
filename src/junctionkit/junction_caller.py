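"""Map junction reads onto donor/acceptor references and classify joins.

A read is assumed oriented donor->acceptor (the amplicon design
guarantees this; reverse-complement first otherwise).  The donor
alignment is a maximal extension of a read *prefix*, the acceptor
alignment of a read *suffix*; extension is substitution-only along a
fixed diagonal and stops when too many mismatches cluster in a sliding
window.  The junction class then follows from the gap or overlap between
the two read intervals:

* acceptor starts immediately after donor ends   -> blunt
* intervals overlap by k bases                   -> microhomology (k bp)
* a gap of bases covered by neither alignment    -> insertion

Microhomology placement is intrinsically ambiguous; the ambiguity
interval is reported and the canonical row assigns the shared bases to
the donor side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .errors import InvalidArgumentError, NoAnchorError
from .sequences import Reference, validate_dna


@dataclass(frozen=True)
class CallerConfig:
    flank_width: int = 30
    seed_len: int = 12
    mismatch_stop_window: int = 10
    mismatch_stop_count: int = 3
    insertion_report_min: int = 2  # ">1 nt" reporting threshold

    def __post_init__(self) -> None:
        for name in ("flank_width", "seed_len", "mismatch_stop_window", "mismatch_stop_count"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.insertion_report_min < 1:
            raise InvalidArgumentError("insertion_report_min must be >= 1")


@dataclass(frozen=True)
class EndAlignment:
    ref_id: str
    ref_start: int  # 1-based inclusive
    ref_end: int
    read_start: int  # 1-based inclusive
    read_end: int
    mismatch_read_offsets: tuple[int, ...]  # 0-based offsets into the read
    anchored_end: str  # "5prime" (donor) | "3prime" (acceptor)

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start != self.read_end - self.read_start:
            raise InvalidArgumentError("reference and read interval lengths differ")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start + 1


@dataclass(frozen=True)
class FlankMutation:
    side: str  # "donor" | "acceptor"
    ref_pos: int  # 1-based position on that reference
    ref_base: str
    read_base: str


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    donor_aln: EndAlignment
    acceptor_aln: EndAlignment
    junction_class: str  # "blunt" | "microhomology" | "insertion"
    mh_len: int
    mh_seq: str
    mh_ambiguity_read_interval: tuple[int, int] | None  # read coords, [a, d]
    insertion_seq: str
    flank_mutations: tuple[FlankMutation, ...]
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.junction_class == "insertion" and (self.mh_len != 0 or not self.insertion_seq):
            raise InvalidArgumentError("insertion calls require mh_len == 0 and a nonempty insertion")
        if self.junction_class == "microhomology" and (self.mh_len < 1 or self.insertion_seq):
            raise InvalidArgumentError("microhomology calls require mh_len >= 1 and no insertion")
        if self.junction_class == "blunt" and (self.mh_len != 0 or self.insertion_seq):
            raise InvalidArgumentError("blunt calls carry no microhomology or insertion")


# trailing-trim scoring: the extension tail is cut back to the
# maximal-scoring prefix so that a junction boundary is not overrun by a
# lucky isolated match beyond a cluster of mismatches
_TRIM_MATCH = 1
_TRIM_MISMATCH = 3


def _extend_on_diagonal(
    read: str, ref: str, read_from: int, ref_from: int, direction: int, cfg: CallerConfig
) -> tuple[int, list[int]]:
    """Extend base-by-base from (read_from, ref_from) (0-based) in
    ``direction`` (+1 donor / -1 acceptor).  Stops before the mismatch
    that would place ``mismatch_stop_count`` mismatches inside any
    ``mismatch_stop_window``-wide window, then trims the tail back to the
    prefix maximising ``matches - 3*mismatches`` (ending on a match).
    Returns (extent, mismatch read offsets): extent counts bases from the
    anchor up to and including the last base kept.
    """
    w, cmax = cfg.mismatch_stop_window, cfg.mismatch_stop_count
    mism: list[int] = []  # step indices (0-based from the anchor) of mismatches
    steps = 0
    i, j = read_from, ref_from
    score = 0
    best_score = 0
    best_step = -1  # last step of the maximal-scoring prefix (a match)
    while 0 <= i < len(read) and 0 <= j < len(ref):
        is_mismatch = read[i] != ref[j] or read[i] == "N" or ref[j] == "N"
        if is_mismatch:
            recent = [s for s in mism if s > steps - w]
            if len(recent) + 1 >= cmax:
                break
            mism.append(steps)
            score -= _TRIM_MISMATCH
        else:
            score += _TRIM_MATCH
            if score > best_score:
                best_score = score
                best_step = steps
        steps += 1
        i += direction
        j += direction
    extent = best_step + 1
    offsets = [read_from + direction * s for s in mism if s < extent]
    return extent, sorted(offsets), best_score


@lru_cache(maxsize=16)
def _kmer_index(refseq: str, k: int) -> dict[str, tuple[int, ...]]:
    index: dict[str, list[int]] = {}
    for j in range(len(refseq) - k + 1):
        index.setdefault(refseq[j : j + k], []).append(j)
    return {kmer: tuple(pos) for kmer, pos in index.items()}


def align_end(read: str, ref: Reference, cfg: CallerConfig | None = None) -> EndAlignment:
    """Highest-scoring anchored placement of a read end on a reference.

    Donor references anchor the read 5' end (a read prefix), acceptor
    references the 3' end (a read suffix).  Candidate diagonals are those
    sharing an exact ``seed_len``-mer with the reference; the
    highest-scoring extension wins (score = matches - 3*mismatches), ties
    broken toward longer extension, then fewer mismatches, then toward
    the 5'-most reference position (donor) / 3'-most (acceptor, the
    mirror rule, keeping calls reverse-complement symmetric).
    """
    cfg = cfg or CallerConfig()
    read = validate_dna(read, allow_n=True, what="read")
    if len(read) < cfg.seed_len:
        raise InvalidArgumentError(f"read shorter than seed_len={cfg.seed_len}")
    k = cfg.seed_len
    refseq = ref.sequence
    kmer_index = _kmer_index(refseq, k)

    diagonals: set[int] = set()  # ref_pos - read_pos (0-based)
    for i in range(len(read) - k + 1):
        for j in kmer_index.get(read[i : i + k], ()):
            diagonals.add(j - i)
    if not diagonals:
        raise NoAnchorError(
            f"no exact {k}-mer anchors read to reference {ref.id!r}"
        )

    best: tuple | None = None
    for diag in diagonals:
        if ref.role == "donor":
            # read prefix: read[0] maps to ref[diag]
            if diag < 0:
                continue
            extent, offsets, score = _extend_on_diagonal(read, refseq, 0, diag, +1, cfg)
            if extent <= 0:
                continue
            key = (-score, -extent, len(offsets), diag)
            aln = EndAlignment(
                ref_id=ref.id,
                ref_start=diag + 1,
                ref_end=diag + extent,
                read_start=1,
                read_end=extent,
                mismatch_read_offsets=tuple(offsets),
                anchored_end="5prime",
            )
        else:
            # read suffix: read[-1] maps to ref[diag + len(read) - 1]
            ref_last = diag + len(read) - 1
            if ref_last >= len(refseq):
                continue
            extent, offsets, score = _extend_on_diagonal(read, refseq, len(read) - 1, ref_last, -1, cfg)
            if extent <= 0:
                continue
            key = (-score, -extent, len(offsets), -ref_last)  # 3'-most on ties
            aln = EndAlignment(
                ref_id=ref.id,
                ref_start=ref_last - extent + 2,
                ref_end=ref_last + 1,
                read_start=len(read) - extent + 1,
                read_end=len(read),
                mismatch_read_offsets=tuple(offsets),
                anchored_end="3prime",
            )
        if best is None or key < best[0]:
            best = (key, aln)
    if best is None:
        raise NoAnchorError(f"no anchored placement of read on reference {ref.id!r}")
    return best[1]


def annotate_flank_mutations(
    donor_aln: EndAlignment,
    acceptor_aln: EndAlignment,
    donor: Reference,
    acceptor: Reference,
    read: str,
    cfg: CallerConfig | None = None,
) -> tuple[FlankMutation, ...]:
    """Report every aligned mismatch within ``flank_width`` nt of the
    breakpoint on either side as (side, reference position, ref base,
    read base).  Bases beyond the aligned intervals are never reported."""
    cfg = cfg or CallerConfig()
    read = read.upper()
    out: list[FlankMutation] = []
    d_lo = max(donor_aln.read_start - 1, donor_aln.read_end - cfg.flank_width)  # 0-based
    for off in donor_aln.mismatch_read_offsets:
        if off >= d_lo:
            ref_pos = donor_aln.ref_start + (off - (donor_aln.read_start - 1))
            out.append(FlankMutation("donor", ref_pos, donor.sequence[ref_pos - 1], read[off]))
    a_hi = min(acceptor_aln.read_end, acceptor_aln.read_start - 1 + cfg.flank_width)  # 0-based bound
    for off in acceptor_aln.mismatch_read_offsets:
        if off < a_hi:
            ref_pos = acceptor_aln.ref_start + (off - (acceptor_aln.read_start - 1))
            out.append(FlankMutation("acceptor", ref_pos, acceptor.sequence[ref_pos - 1], read[off]))
    return tuple(out)


def call_junction(
    read: str,
    donor: Reference,
    acceptor: Reference,
    cfg: CallerConfig | None = None,
    read_id: str = "read",
) -> JunctionCall:
    """Classify the junction in ``read`` against donor and acceptor.

    Let the donor read interval end at d and the acceptor interval start
    at a: a == d+1 is blunt; a <= d is a microhomology of d-a+1 bp (the
    shared bases are assigned donor-side for the canonical row, with the
    ambiguity interval [a, d] reported); a > d+1 is an insertion of
    read[d+1 .. a-1].  Calls whose alignments jointly cover less than half
    the read are flagged low-confidence but still emitted.
    """
    cfg = cfg or CallerConfig()
    read = validate_dna(read, allow_n=True, what="read")
    donor_aln = align_end(read, donor, cfg)
    acceptor_aln = align_end(read, acceptor, cfg)
    d = donor_aln.read_end
    a = acceptor_aln.read_start

    mh_len = 0
    mh_seq = ""
    insertion_seq = ""
    ambiguity: tuple[int, int] | None = None
    if a == d + 1:
        junction_class = "blunt"
    elif a <= d:
        junction_class = "microhomology"
        mh_len = d - a + 1
        mh_seq = read[a - 1 : d]
        ambiguity = (a, d)
        # canonical placement: shared bases belong to the donor; trim the
        # acceptor alignment so its read interval starts at d+1
        shift = d + 1 - a
        offsets = tuple(o for o in acceptor_aln.mismatch_read_offsets if o >= d)
        acceptor_aln = EndAlignment(
            ref_id=acceptor_aln.ref_id,
            ref_start=acceptor_aln.ref_start + shift,
            ref_end=acceptor_aln.ref_end,
            read_start=d + 1,
            read_end=acceptor_aln.read_end,
            mismatch_read_offsets=offsets,
            anchored_end="3prime",
        )
    else:
        junction_class = "insertion"
        insertion_seq = read[d : a - 1]

    coverage = donor_aln.length + acceptor_aln.length
    low_confidence = coverage < 0.5 * len(read)
    mutations = annotate_flank_mutations(donor_aln, acceptor_aln, donor, acceptor, read, cfg)
    return JunctionCall(
        read_id=read_id,
        donor_aln=donor_aln,
        acceptor_aln=acceptor_aln,
        junction_class=junction_class,
        mh_len=mh_len,
        mh_seq=mh_seq,
        mh_ambiguity_read_interval=ambiguity,
        insertion_seq=insertion_seq,
        flank_mutations=mutations,
        low_confidence=low_confidence,
    )


@dataclass(frozen=True)
class TableRow:
    """A junction record in the printed-table dialect: 30-nt flanks with
    mutations lower-cased, intervals as ``start:end`` spanning 30 nt."""

    donor_interval: str
    donor_flank: str
    insertion: str
    acceptor_flank: str
    acceptor_interval: str
    homology: str = ""
    mh_markup: str = ""  # donor flank with microhomology bases bracketed

    def formatted(self) -> str:
        return " | ".join(
            [self.donor_interval, self.donor_flank, self.insertion,
             self.acceptor_flank, self.acceptor_interval]
        )


def to_table_row(
    call: JunctionCall,
    donor: Reference,
    acceptor: Reference,
    read: str,
    cfg: CallerConfig | None = None,
    homology: str = "",
) -> TableRow:
    """Render a call as a table-dialect row.

    The donor interval covers the last ``flank_width`` aligned donor
    bases (likewise the first for the acceptor); mutated bases are
    lower-cased in the flanks; microhomology bases are bracketed in the
    markup column (a stand-in for underlining)."""
    cfg = cfg or CallerConfig()
    read = read.upper()
    w = cfg.flank_width

    d_len = min(w, call.donor_aln.length)
    d_end = call.donor_aln.ref_end
    d_start = d_end - d_len + 1
    donor_flank = list(read[call.donor_aln.read_end - d_len : call.donor_aln.read_end])
    a_len = min(w, call.acceptor_aln.length)
    a_start = call.acceptor_aln.ref_start
    a_end = a_start + a_len - 1
    acceptor_flank = list(read[call.acceptor_aln.read_start - 1 : call.acceptor_aln.read_start - 1 + a_len])

    for mut in call.flank_mutations:
        if mut.side == "donor" and d_start <= mut.ref_pos <= d_end:
            donor_flank[mut.ref_pos - d_start] = mut.read_base.lower()
        elif mut.side == "acceptor" and a_start <= mut.ref_pos <= a_end:
            acceptor_flank[mut.ref_pos - a_start] = mut.read_base.lower()

    markup = ""
    if call.mh_len and call.mh_len <= d_len:
        flank = "".join(donor_flank)
        markup = flank[: d_len - call.mh_len] + "[" + flank[d_len - call.mh_len :] + "]"

    return TableRow(
        donor_interval=f"{d_start}:{d_end}",
        donor_flank="".join(donor_flank),
        insertion=call.insertion_seq,
        acceptor_flank="".join(acceptor_flank),
        acceptor_interval=f"{a_start}:{a_end}",
        homology=homology,
        mh_markup=markup,
    )
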