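"""Seeded generators for switch-region-like references and junction reads.

Reads are simulated under three joining mechanisms:

* ``CNHEJ`` — minimal processing: small trims, at most a 1-nt insertion.
* ``MMEJ``  — ends annealed at a pre-existing 2-5 bp microhomology that
  occurs in both 3' overhangs; the joined read carries a single copy of
  the shared bases and a net deletion.
* ``SDEJ``  — synthesis-dependent joining: the insertion is built from
  one or more templated blocks copied from reference positions near the
  breaks, each block initiated by minimal terminal pairing, with
  slippage/repriming possibly appending further blocks.

Every read carries full ground truth.  Because breakpoint placement at a
junction is intrinsically ambiguous whenever boundary bases happen to
match a flank, truth is *canonicalised* after assembly: boundary bases
that extend a flank match are assigned to the flanks (microhomologies
maximal, shared bases donor-side), exactly the convention the caller
reports.  Reads whose canonical annotation differs from the drawn
mechanism parameters are flagged ``ambiguous``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError, SimulationInfeasibleError
from .sequences import Reference, validate_dna, write_fasta

MECHANISMS = ("CNHEJ", "MMEJ", "SDEJ")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SwitchRegion:
    id: str
    sequence: str
    repeat_units: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, what=f"region {self.id}"))
        if len(self.sequence) < 200:
            raise InvalidArgumentError("switch region length must be >= 200")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def as_reference(self, role: str) -> Reference:
        return Reference(id=self.id, sequence=self.sequence, role=role)


@dataclass(frozen=True)
class JoinConfig:
    mechanism: str = "SDEJ"
    overhang_len: int = 45
    terminal_complement_len: int = 4
    mh_len_range: tuple[int, int] = (2, 5)
    insertion_len_range: tuple[int, int] = (2, 35)
    min_pair: int = 1
    slippage_prob: float = 0.3
    max_template_distance: int = 5000
    flank_mutation_rate: float = 0.02
    seed: int = 0
    # artifact plumbing, not drawn from any reported geometry:
    read_flank: int = 60          # reference bases kept on each side of the junction
    cnhej_max_trim: int = 3
    cnhej_insertion_prob: float = 0.5
    block_len_range: tuple[int, int] = (4, 15)
    antisense_templates: bool = False

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise InvalidArgumentError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        for name in ("mh_len_range", "insertion_len_range", "block_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise InvalidArgumentError(f"{name} must be a non-empty positive range")
        if self.min_pair < 1:
            raise InvalidArgumentError("min_pair must be >= 1")
        for name in ("slippage_prob", "flank_mutation_rate", "cnhej_insertion_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        if self.overhang_len < 1 or self.terminal_complement_len < 0:
            raise InvalidArgumentError("overhang geometry must be positive")
        if self.max_template_distance < 1:
            raise InvalidArgumentError("max_template_distance must be >= 1")


@dataclass(frozen=True)
class OriginSegment:
    ref_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FlankMutationTruth:
    side: str  # "donor" | "acceptor"
    ref_pos: int
    ref_base: str
    read_base: str


@dataclass(frozen=True)
class JunctionTruth:
    mechanism: str
    donor_start: int       # first donor base present in the read
    donor_break: int       # last donor base present in the read
    acceptor_break: int    # first acceptor base present in the read
    acceptor_end: int      # last acceptor base present in the read
    donor_deletion: int
    acceptor_deletion: int
    mh_seq: str
    insertion_seq: str
    origin_segments: tuple[OriginSegment, ...]
    mutations: tuple[FlankMutationTruth, ...]
    intended_class: str
    ambiguous: bool

    @property
    def junction_class(self) -> str:
        if self.mh_seq:
            return "microhomology"
        if self.insertion_seq:
            return "insertion"
        return "blunt"


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    truth: JunctionTruth


def generate_switch_region(
    length: int,
    repeat_units: tuple[str, ...] = ("GAGCT", "GGGGT"),
    seed: int = 0,
    noise: float = 0.02,
    region_id: str = "region",
) -> SwitchRegion:
    """Seeded tandem concatenation of short motifs with per-base
    substitution noise, mimicking switch-region repetitiveness so that
    short microhomologies recur."""
    if length < 200:
        raise InvalidArgumentError("length must be >= 200")
    if not repeat_units:
        raise InvalidArgumentError("repeat_units must be nonempty")
    units = tuple(validate_dna(u, what="repeat unit") for u in repeat_units)
    for u in units:
        if not 3 <= len(u) <= 10:
            # single-base units are allowed for degenerate test cases
            if len(u) != 1:
                raise InvalidArgumentError("repeat units must be 3-10 nt (or 1 nt)")
    if not 0 <= noise <= 1:
        raise InvalidArgumentError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    total = 0
    while total < length:
        u = units[int(rng.integers(len(units)))]
        parts.append(u)
        total += len(u)
    seq = np.array(list("".join(parts)[:length]))
    if noise > 0:
        hit = rng.random(length) < noise
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(3))]
    return SwitchRegion(id=region_id, sequence="".join(seq), repeat_units=units)


def _draw_break(rng: np.random.Generator, region_len: int, cfg: JoinConfig) -> int:
    margin = cfg.overhang_len + cfg.read_flank + 5
    lo, hi = margin, region_len - margin
    if lo > hi:
        raise InvalidArgumentError(
            f"region of length {region_len} too short for overhang {cfg.overhang_len} "
            f"and read flank {cfg.read_flank}"
        )
    return int(rng.integers(lo, hi + 1))


def _random_base(rng: np.random.Generator) -> str:
    return "ACGT"[int(rng.integers(4))]


def _find_shared_kmers(donor_tail: str, acceptor_tail: str, m: int) -> list[str]:
    donor_kmers = {donor_tail[i : i + m] for i in range(len(donor_tail) - m + 1)}
    acceptor_kmers = {acceptor_tail[i : i + m] for i in range(len(acceptor_tail) - m + 1)}
    return sorted(donor_kmers & acceptor_kmers)


def _template_candidates(
    tail_kmer: str,
    refs: list[tuple[Reference, int]],  # (reference, breakpoint on it)
    cfg: JoinConfig,
) -> list[tuple[Reference, int]]:
    """Reference positions where a templated block may start: the k bases
    immediately 5' of the start equal ``tail_kmer`` (minimal terminal
    pairing) and the locus lies within max_template_distance of the
    break on that reference."""
    k = len(tail_kmer)
    out: list[tuple[Reference, int]] = []
    for ref, brk in refs:
        lo = max(1, brk - cfg.max_template_distance)
        hi = min(len(ref), brk + cfg.max_template_distance)
        seq = ref.sequence
        pos = seq.find(tail_kmer, lo - 1, hi)
        while pos != -1:
            start = pos + k + 1  # 1-based position after the paired kmer
            if start <= hi:
                out.append((ref, start))
            pos = seq.find(tail_kmer, pos + 1, hi)
    return out


def _canonicalise(
    read0: str,
    donor: Reference,
    acceptor: Reference,
    donor_start: int,
    donor_break: int,
    acceptor_break: int,
    acceptor_end: int,
    insertion_len: int,
) -> tuple[int, int, str, str, int, int, int, int]:
    """Maximal flank extension on the true diagonals; returns
    (d, a, mh_seq, insertion_seq, donor_break', acceptor_break',
    front_absorbed, back_absorbed) with d/a in 1-based read coordinates.
    """
    seg_d_len = donor_break - donor_start + 1
    orig_a = seg_d_len + insertion_len + 1  # read pos of first acceptor base
    n = len(read0)
    # extend donor prefix rightwards
    d = seg_d_len
    while d < n:
        ref_pos = donor_break + (d + 1 - seg_d_len)
        if ref_pos > len(donor) or read0[d] != donor.sequence[ref_pos - 1]:
            break
        d += 1
    # extend acceptor suffix leftwards
    a = orig_a
    while a > 1:
        ref_pos = acceptor_break + (a - 1 - orig_a)
        if ref_pos < 1 or read0[a - 2] != acceptor.sequence[ref_pos - 1]:
            break
        a -= 1
    if a <= d:
        mh_seq = read0[a - 1 : d]
        ins_seq = ""
    else:
        mh_seq = ""
        ins_seq = read0[d : a - 1]
    donor_break_c = donor_break + (d - seg_d_len)
    # donor-side placement: the acceptor retains bases from read pos d+1 on
    acceptor_break_c = acceptor_break + (d + 1 - orig_a) if a <= d else acceptor_break + (a - orig_a)
    front = d - seg_d_len
    back = orig_a - a
    return d, a, mh_seq, ins_seq, donor_break_c, acceptor_break_c, front, back


def _trim_segments(
    segments: list[OriginSegment], front: int, back: int
) -> tuple[OriginSegment, ...]:
    """Drop ``front`` bases from the head and ``back`` from the tail of a
    block list (bases absorbed into flanks during canonicalisation)."""
    out: list[OriginSegment] = []
    for seg in segments:
        length = seg.length
        cut_front = min(front, length)
        front -= cut_front
        if cut_front == length:
            continue
        out.append(OriginSegment(seg.ref_id, seg.start + cut_front, seg.end, seg.strand))
    while back > 0 and out:
        seg = out[-1]
        if seg.length <= back:
            back -= seg.length
            out.pop()
        else:
            out[-1] = OriginSegment(seg.ref_id, seg.start, seg.end - back, seg.strand)
            back = 0
    return tuple(out)


def simulate_junction(
    donor: SwitchRegion | Reference,
    acceptor: SwitchRegion | Reference,
    cfg: JoinConfig,
    rng: np.random.Generator | None = None,
    read_id: str = "sim",
) -> SimulatedRead:
    """Simulate one junction read with full, canonicalised ground truth.

    Deterministic for a fixed ``cfg.seed`` (when ``rng`` is not given).
    MMEJ mode raises :class:`SimulationInfeasibleError` when no
    microhomology of the drawn length exists in both overhangs.
    """
    donor_ref = donor.as_reference("donor") if isinstance(donor, SwitchRegion) else donor
    acceptor_ref = acceptor.as_reference("acceptor") if isinstance(acceptor, SwitchRegion) else acceptor
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    donor_break0 = _draw_break(rng, len(donor_ref), cfg)
    acceptor_break0 = _draw_break(rng, len(acceptor_ref), cfg)

    insertion = ""
    segments: list[OriginSegment] = []
    mh_intended = ""

    if cfg.mechanism == "CNHEJ":
        trim_d = int(rng.integers(0, cfg.cnhej_max_trim + 1))
        trim_a = int(rng.integers(0, cfg.cnhej_max_trim + 1))
        donor_break = donor_break0 - trim_d
        acceptor_break = acceptor_break0 + trim_a
        if rng.random() < cfg.cnhej_insertion_prob:
            insertion = _random_base(rng)
        intended_class = "insertion" if insertion else "blunt"
    elif cfg.mechanism == "MMEJ":
        m = int(rng.integers(cfg.mh_len_range[0], cfg.mh_len_range[1] + 1))
        donor_tail = donor_ref.slice(donor_break0 - cfg.overhang_len + 1, donor_break0)
        acceptor_tail = acceptor_ref.slice(acceptor_break0, acceptor_break0 + cfg.overhang_len - 1)
        shared = _find_shared_kmers(donor_tail, acceptor_tail, m)
        if not shared:
            raise SimulationInfeasibleError(
                f"no shared {m}-mer between the {cfg.overhang_len}-nt overhangs at "
                f"{donor_ref.id}:{donor_break0} / {acceptor_ref.id}:{acceptor_break0}"
            )
        mh_intended = shared[int(rng.integers(len(shared)))]
        d_offsets = [i for i in range(len(donor_tail) - m + 1) if donor_tail[i : i + m] == mh_intended]
        a_offsets = [i for i in range(len(acceptor_tail) - m + 1) if acceptor_tail[i : i + m] == mh_intended]
        d_off = d_offsets[int(rng.integers(len(d_offsets)))]
        a_off = a_offsets[int(rng.integers(len(a_offsets)))]
        donor_break = (donor_break0 - cfg.overhang_len + 1) + d_off + m - 1
        acceptor_break = acceptor_break0 + a_off + m  # first retained base, mh donor-side
        intended_class = "microhomology"
    else:  # SDEJ
        donor_break = donor_break0 - int(rng.integers(0, 3))
        acceptor_break = acceptor_break0 + int(rng.integers(0, 3))
        target = int(rng.integers(cfg.insertion_len_range[0], cfg.insertion_len_range[1] + 1))
        refs_with_breaks = [(donor_ref, donor_break), (acceptor_ref, acceptor_break)]
        for attempt in range(30):
            insertion = ""
            segments = []
            while len(insertion) < target:
                tail_src = insertion if insertion else donor_ref.slice(
                    max(1, donor_break - 19), donor_break
                )
                k = min(cfg.min_pair, len(tail_src))
                candidates = _template_candidates(tail_src[-k:], refs_with_breaks, cfg)
                if not candidates:
                    break
                ref, start = candidates[int(rng.integers(len(candidates)))]
                remaining = target - len(insertion)
                blen = int(rng.integers(cfg.block_len_range[0], cfg.block_len_range[1] + 1))
                blen = min(blen, remaining, len(ref) - start + 1)
                if blen < 1:
                    break
                segments.append(OriginSegment(ref.id, start, start + blen - 1, "+"))
                insertion += ref.slice(start, start + blen - 1)
                if len(insertion) >= target or rng.random() >= cfg.slippage_prob:
                    break
            if len(insertion) >= cfg.insertion_len_range[0]:
                break
        else:  # pragma: no cover - essentially unreachable on repeat-rich refs
            raise SimulationInfeasibleError("could not assemble a templated insertion")
        if len(insertion) < cfg.insertion_len_range[0]:
            raise SimulationInfeasibleError("could not assemble a templated insertion")
        intended_class = "insertion"

    donor_start = donor_break - cfg.read_flank + 1
    acceptor_end = acceptor_break + cfg.read_flank - 1
    seg_d = donor_ref.slice(donor_start, donor_break)
    seg_a = acceptor_ref.slice(acceptor_break, acceptor_end)
    read0 = seg_d + insertion + seg_a

    d, a, mh_seq, ins_seq, donor_break_c, acceptor_break_c, front, back = _canonicalise(
        read0, donor_ref, acceptor_ref, donor_start, donor_break,
        acceptor_break, acceptor_end, len(insertion),
    )
    if mh_seq:
        canon_class = "microhomology"
    elif ins_seq:
        canon_class = "insertion"
    else:
        canon_class = "blunt"

    # a junction is also intrinsically ambiguous when the caller's
    # mismatch-tolerant extension rule would place a boundary elsewhere
    # than exact matching does (lucky matches just beyond the junction)
    from .junction_caller import CallerConfig, _extend_on_diagonal

    _ccfg = CallerConfig()
    d_tol, _, _ = _extend_on_diagonal(read0, donor_ref.sequence, 0, donor_start - 1, +1, _ccfg)
    ext_a, _, _ = _extend_on_diagonal(
        read0, acceptor_ref.sequence, len(read0) - 1, acceptor_end - 1, -1, _ccfg
    )
    a_tol = len(read0) - ext_a + 1
    boundary_ambiguous = (d_tol != d) or (a_tol != a)

    if canon_class == "insertion" and cfg.mechanism == "SDEJ":
        segments_c = _trim_segments(segments, front, back)
    elif canon_class == "insertion" and insertion and cfg.mechanism == "CNHEJ":
        segments_c = ()
    else:
        segments_c = ()
    ambiguous = (
        boundary_ambiguous
        or canon_class != intended_class
        or (intended_class == "microhomology" and mh_seq != mh_intended)
        or (intended_class == "insertion" and ins_seq != insertion)
    )

    # apply flank point mutations to the assembled read
    read_chars = list(read0)
    mutations: list[FlankMutationTruth] = []
    if cfg.flank_mutation_rate > 0:
        junction_right = d + len(ins_seq)  # last read pos before acceptor bases
        donor_positions = range(max(1, d - 29), d + 1)
        acceptor_positions = range(junction_right + 1, min(len(read0), junction_right + 30) + 1)
        for p in donor_positions:
            if rng.random() < cfg.flank_mutation_rate:
                old = read_chars[p - 1]
                new = "ACGT".replace(old, "")[int(rng.integers(3))]
                read_chars[p - 1] = new
                mutations.append(
                    FlankMutationTruth("donor", donor_break_c - (d - p), old, new)
                )
        for p in acceptor_positions:
            if rng.random() < cfg.flank_mutation_rate:
                old = read_chars[p - 1]
                new = "ACGT".replace(old, "")[int(rng.integers(3))]
                read_chars[p - 1] = new
                mutations.append(
                    FlankMutationTruth("acceptor", acceptor_break_c + (p - junction_right - 1), old, new)
                )

    truth = JunctionTruth(
        mechanism=cfg.mechanism,
        donor_start=donor_start,
        donor_break=donor_break_c,
        acceptor_break=acceptor_break_c,
        acceptor_end=acceptor_end,
        donor_deletion=donor_break0 - donor_break_c if donor_break0 >= donor_break_c else 0,
        acceptor_deletion=acceptor_break_c - acceptor_break0 if acceptor_break_c >= acceptor_break0 else 0,
        mh_seq=mh_seq,
        insertion_seq=ins_seq,
        origin_segments=segments_c,
        mutations=tuple(mutations),
        intended_class=intended_class,
        ambiguous=ambiguous,
    )
    return SimulatedRead(read_id=read_id, sequence="".join(read_chars), truth=truth)


def reconstruct_read(
    truth: JunctionTruth, donor: SwitchRegion | Reference, acceptor: SwitchRegion | Reference
) -> str:
    """Rebuild the emitted read from the truth record alone (exactness is
    the reconstruction invariant)."""
    donor_seq = donor.sequence
    acceptor_seq = acceptor.sequence
    seg_d = list(donor_seq[truth.donor_start - 1 : truth.donor_break])
    seg_a = list(acceptor_seq[truth.acceptor_break - 1 : truth.acceptor_end])
    for mut in truth.mutations:
        if mut.side == "donor":
            idx = mut.ref_pos - truth.donor_start
            seg_d[idx] = mut.read_base
        else:
            idx = mut.ref_pos - truth.acceptor_break
            seg_a[idx] = mut.read_base
    return "".join(seg_d) + truth.insertion_seq + "".join(seg_a)


def origin_block(segment: OriginSegment, refs_by_id: dict[str, Reference | SwitchRegion]) -> str:
    """The sense-strand block a templated segment contributes: a
    reverse-complement walk along the antisense template, which for a
    sense segment is the segment itself."""
    seq = refs_by_id[segment.ref_id].sequence[segment.start - 1 : segment.end]
    if segment.strand == "-":
        from .sequences import revcomp

        return revcomp(seq)
    return seq


def simulate_dataset(
    n_per_group: int,
    mixture: dict[str, float],
    donor: SwitchRegion | Reference,
    acceptor: SwitchRegion | Reference,
    cfg: JoinConfig,
) -> tuple[list[SimulatedRead], dict[str, int]]:
    """Draw ``n_per_group`` reads with mechanisms sampled from ``mixture``
    (weights normalised); returns the reads and the exact seeded
    mechanism composition."""
    if n_per_group < 1:
        raise InvalidArgumentError("n_per_group must be >= 1")
    if not mixture:
        raise InvalidArgumentError("mixture must be nonempty")
    for mech, w in mixture.items():
        if mech not in MECHANISMS:
            raise InvalidArgumentError(f"unknown mechanism {mech!r}")
        if w < 0:
            raise InvalidArgumentError("mixture weights must be >= 0")
    total = sum(mixture.values())
    if total <= 0:
        raise InvalidArgumentError("mixture weights must sum to > 0")

    rng = np.random.default_rng(cfg.seed)
    mechs = sorted(mixture)
    probs = np.array([mixture[m] for m in mechs]) / total
    draws = rng.choice(len(mechs), size=n_per_group, p=probs)
    counts = {m: 0 for m in mechs}
    reads: list[SimulatedRead] = []
    for i, mi in enumerate(draws):
        mech = mechs[int(mi)]
        counts[mech] += 1
        sub_cfg = replace(cfg, mechanism=mech)
        # an individual breakpoint draw may be infeasible (e.g. no shared
        # microhomology of the drawn length); redraw positions a bounded
        # number of times rather than aborting the whole dataset
        for attempt in range(30):
            try:
                reads.append(
                    simulate_junction(donor, acceptor, sub_cfg, rng=rng, read_id=f"read{i:05d}")
                )
                break
            except SimulationInfeasibleError:
                if attempt == 29:
                    raise
    return reads, counts


def simulate_translocation_counts(
    freq_per_genome: dict[str, float], n_genomes: int, seed: int = 0
) -> dict[str, int]:
    """Binomial draw of translocation counts per genotype over
    ``n_genomes`` surveyed genomes."""
    if n_genomes < 1:
        raise InvalidArgumentError("n_genomes must be >= 1")
    for g, f in freq_per_genome.items():
        if not 0 <= f <= 1:
            raise InvalidArgumentError(f"frequency for {g!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return {g: int(rng.binomial(n_genomes, freq_per_genome[g])) for g in sorted(freq_per_genome)}


TRUTH_COLUMNS = [
    "read_id", "mechanism", "junction_class", "donor_start", "donor_break",
    "acceptor_break", "acceptor_end", "donor_deletion", "acceptor_deletion",
    "mh_seq", "insertion_seq", "origins", "mutations", "ambiguous",
]


def truth_row(read: SimulatedRead) -> list[str]:
    t = read.truth
    origins = ";".join(f"{s.ref_id}:{s.start}-{s.end}:{s.strand}" for s in t.origin_segments)
    muts = ";".join(f"{m.side}:{m.ref_pos}:{m.ref_base}>{m.read_base}" for m in t.mutations)
    return [
        read.read_id, t.mechanism, t.junction_class, str(t.donor_start),
        str(t.donor_break), str(t.acceptor_break), str(t.acceptor_end),
        str(t.donor_deletion), str(t.acceptor_deletion), t.mh_seq,
        t.insertion_seq, origins, muts, str(int(t.ambiguous)),
    ]


def write_truth_tsv(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for read in reads:
            fh.write("\t".join(truth_row(read)) + "\n")


def write_reads_fasta(reads: list[SimulatedRead], path: str | Path) -> None:
    write_fasta(((r.read_id, r.sequence) for r in reads), path)
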