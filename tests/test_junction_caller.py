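"""Junction caller tests.

The extension stop rule has an independent oracle: enumerate every
prefix length satisfying the sliding-window mismatch constraint and pick
the one maximising the trim score, rather than extending greedily.
"""

from __future__ import annotations

import numpy as np
import pytest

from junctionkit.errors import InvalidArgumentError, NoAnchorError
from junctionkit.junction_caller import (
    CallerConfig,
    align_end,
    annotate_flank_mutations,
    call_junction,
    to_table_row,
)
from junctionkit.sequences import Reference, revcomp

WT_ROW1_DONOR_FLANK = "GGGACCCAGGCTTTGAAGGCAATCCTGGGA"  # printed flank, uppercased
WT_ROW1_INSERTION = "GCACTTC"
WT_ROW1_ACCEPTOR_FLANK = "GTACTTATAGAGGAACAGGGGCAGCGTAGA"


def oracle_prefix_extension(read: str, ref: str, cfg: CallerConfig) -> int:
    """Independent formulation of the donor-side extension: over all
    prefix lengths L whose mismatch pattern never places
    ``mismatch_stop_count`` mismatches inside one window, and whose last
    base matches, return the L maximising matches - 3*mismatches
    (earliest maximum)."""
    best_L, best_score = 0, 0
    n = min(len(read), len(ref))
    mismatches: list[int] = []
    for L in range(1, n + 1):
        if read[L - 1] != ref[L - 1]:
            mismatches.append(L - 1)
        recent = [m for m in mismatches if m > L - 1 - cfg.mismatch_stop_window]
        if len(recent) >= cfg.mismatch_stop_count:
            break
        if read[L - 1] == ref[L - 1]:
            score = (L - len(mismatches)) - 3 * len(mismatches)
            if score > best_score:
                best_score, best_L = score, L
    return best_L


class TestAlignEnd:
    def test_printed_flank_as_reference(self):
        # the 30-nt flank used verbatim as a truncated donor reference
        donor = Reference(id="d", sequence=WT_ROW1_DONOR_FLANK, role="donor")
        read = WT_ROW1_DONOR_FLANK + "GCACTTCAAAA"
        aln = align_end(read, donor)
        assert (aln.ref_start, aln.ref_end) == (1, 30)
        assert (aln.read_start, aln.read_end) == (1, 30)
        assert aln.mismatch_read_offsets == ()

    def test_identity_full_length(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 80))
        ref = Reference(id="d", sequence=seq, role="donor")
        aln = align_end(seq, ref)
        assert aln.length == 80
        assert aln.mismatch_read_offsets == ()

    def test_two_adjacent_substitutions(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 30))
        read = list(seq)
        for off in (13, 14):
            read[off] = "ACGT"[("ACGT".index(read[off]) + 1) % 4]
        read = "".join(read)
        ref = Reference(id="d", sequence=seq, role="donor")
        aln = align_end(read, ref)
        assert aln.length == 30
        assert aln.mismatch_read_offsets == (13, 14)
        assert aln.length == oracle_prefix_extension(read, seq, CallerConfig())

    @pytest.mark.parametrize("case", range(30))
    def test_extension_matches_oracle(self, case):
        # single-diagonal reads with random planted substitutions
        rng = np.random.default_rng(4000 + case)
        seq = "".join(rng.choice(list("ACGT"), 120))
        read = list(seq[:90])
        for _ in range(int(rng.integers(0, 8))):
            off = int(rng.integers(12, 90))  # keep the seed region clean
            read[off] = "ACGT"[int(rng.integers(4))]
        read = "".join(read)
        cfg = CallerConfig()
        aln = align_end(read, Reference(id="d", sequence=seq, role="donor"), cfg)
        oracle = oracle_prefix_extension(read, seq, cfg)
        if aln.ref_start == 1:  # caller picked the planted diagonal
            assert aln.length == oracle

    def test_budget_monotonic_on_fixed_diagonal(self):
        # raising the mismatch budget never shortens the extension
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 100))
        read = list(seq)
        for off in (20, 24, 27, 40, 44, 48):
            read[off] = "ACGT"[("ACGT".index(read[off]) + 1) % 4]
        read = "".join(read)
        ref = Reference(id="d", sequence=seq, role="donor")
        prev = 0
        for budget in (2, 3, 4, 5):
            aln = align_end(read, ref, CallerConfig(mismatch_stop_count=budget))
            assert aln.length >= prev
            prev = aln.length

    def test_no_anchor_raises(self):
        ref = Reference(id="d", sequence="A" * 60, role="donor")
        with pytest.raises(NoAnchorError):
            align_end("C" * 40, ref)

    def test_short_read_rejected(self):
        ref = Reference(id="d", sequence="ACGTACGTACGTACGT", role="donor")
        with pytest.raises(InvalidArgumentError):
            align_end("ACGT", ref)

    def test_coordinate_identity(self):
        donor = Reference(id="d", sequence=WT_ROW1_DONOR_FLANK, role="donor")
        aln = align_end(WT_ROW1_DONOR_FLANK + "TTTTTTTTTTTT", donor)
        assert aln.ref_end - aln.ref_start + 1 == aln.length
        assert aln.read_end - aln.read_start + 1 == aln.length


class TestCallJunction:
    def test_printed_row_insertion(self):
        donor = Reference(id="d", sequence=WT_ROW1_DONOR_FLANK, role="donor")
        acceptor = Reference(id="a", sequence=WT_ROW1_ACCEPTOR_FLANK, role="acceptor")
        read = WT_ROW1_DONOR_FLANK + WT_ROW1_INSERTION + WT_ROW1_ACCEPTOR_FLANK
        call = call_junction(read, donor, acceptor)
        assert call.junction_class == "insertion"
        assert call.insertion_seq == "GCACTTC"
        assert call.mh_len == 0

    def test_blunt_join(self):
        rng = np.random.default_rng(2)
        d_seq = "".join(rng.choice(list("CT"), 40))
        a_seq = "".join(rng.choice(list("AG"), 40))
        donor = Reference(id="d", sequence=d_seq, role="donor")
        acceptor = Reference(id="a", sequence=a_seq, role="acceptor")
        call = call_junction(d_seq + a_seq, donor, acceptor)
        assert call.junction_class == "blunt"
        assert call.mh_len == 0 and call.insertion_seq == ""

    def test_planted_microhomology(self):
        # donor ends ...ACGT, acceptor begins ACGT...; read holds one copy
        donor = Reference(id="d", sequence="C" * 30 + "TTTACGT", role="donor")
        acceptor = Reference(id="a", sequence="ACGTCCC" + "G" * 30, role="acceptor")
        read = "C" * 30 + "TTTACGT" + "CCC" + "G" * 30
        call = call_junction(read, donor, acceptor)
        assert call.junction_class == "microhomology"
        assert call.mh_len == 4
        assert call.mh_seq == "ACGT"
        a, d = call.mh_ambiguity_read_interval
        assert d - a + 1 == 4
        # brute force: no breakpoint assignment admits a longer overlap
        best = 0
        for split in range(1, len(read)):
            left, right = read[:split], read[split:]
            if donor.sequence.endswith(left[-min(len(left), 37):]):
                for k in range(0, min(split, 7) + 1):
                    if (
                        donor.sequence.endswith(read[:split][-k:] if k else "")
                        and acceptor.sequence.startswith(read[split - k : split + 3])
                    ):
                        best = max(best, k)
        assert best == 4

    def test_mh_reported_donor_side(self):
        donor = Reference(id="d", sequence="C" * 30 + "TTTACGT", role="donor")
        acceptor = Reference(id="a", sequence="ACGTCCC" + "G" * 30, role="acceptor")
        read = "C" * 30 + "TTTACGT" + "CCC" + "G" * 30
        call = call_junction(read, donor, acceptor)
        # acceptor alignment trimmed to start after the donor interval
        assert call.acceptor_aln.read_start == call.donor_aln.read_end + 1

    def test_intervals_overlap_at_most_mh_len(self):
        donor = Reference(id="d", sequence="C" * 30 + "TTTACGT", role="donor")
        acceptor = Reference(id="a", sequence="ACGTCCC" + "G" * 30, role="acceptor")
        read = "C" * 30 + "TTTACGT" + "CCC" + "G" * 30
        call = call_junction(read, donor, acceptor)
        overlap = call.donor_aln.read_end - call.acceptor_aln.read_start + 1
        assert overlap <= call.mh_len

    def test_reverse_complement_symmetry(self, repeat_regions, clean_join_cfg):
        from junctionkit.synthetic_data import simulate_dataset

        donor, acceptor = repeat_regions
        refD, refA = donor.as_reference("donor"), acceptor.as_reference("acceptor")
        rcD = Reference(id="d_rc", sequence=revcomp(donor.sequence), role="acceptor")
        rcA = Reference(id="a_rc", sequence=revcomp(acceptor.sequence), role="donor")
        reads, _ = simulate_dataset(
            60, {"CNHEJ": 1, "MMEJ": 1, "SDEJ": 1}, donor, acceptor, clean_join_cfg
        )
        for r in reads:
            c1 = call_junction(r.sequence, refD, refA)
            c2 = call_junction(revcomp(r.sequence), rcA, rcD)
            assert c1.junction_class == c2.junction_class
            assert c1.mh_len == c2.mh_len
            assert len(c1.insertion_seq) == len(c2.insertion_seq)

    def test_low_confidence_flagged(self):
        # alignments cover only the two flanks of a long unmappable middle
        rng = np.random.default_rng(8)
        d_seq = "".join(rng.choice(list("ACGT"), 40))
        a_seq = "".join(rng.choice(list("ACGT"), 40))
        middle = "".join(rng.choice(list("ACGT"), 150))
        donor = Reference(id="d", sequence=d_seq, role="donor")
        acceptor = Reference(id="a", sequence=a_seq, role="acceptor")
        call = call_junction(d_seq + middle + a_seq, donor, acceptor)
        assert call.low_confidence


class TestFlankMutations:
    def _refs_with_mutated_read(self):
        # reference differs from the printed flank at the two lower-case
        # positions: plant different bases there in the reference
        ref_donor = list(WT_ROW1_DONOR_FLANK)
        ref_donor[12] = "C" if ref_donor[12] != "C" else "G"  # printed 't'
        ref_donor[13] = "C" if ref_donor[13] != "C" else "G"  # printed 't'
        donor = Reference(id="d", sequence="".join(ref_donor), role="donor")
        acceptor = Reference(id="a", sequence=WT_ROW1_ACCEPTOR_FLANK, role="acceptor")
        read = WT_ROW1_DONOR_FLANK + WT_ROW1_INSERTION + WT_ROW1_ACCEPTOR_FLANK
        return donor, acceptor, read

    def test_two_donor_mutations(self):
        donor, acceptor, read = self._refs_with_mutated_read()
        call = call_junction(read, donor, acceptor)
        donor_muts = [m for m in call.flank_mutations if m.side == "donor"]
        assert len(donor_muts) == 2
        assert {m.ref_pos for m in donor_muts} == {13, 14}
        assert all(m.read_base == "T" for m in donor_muts)

    def test_zero_mismatch_alignment_empty(self):
        donor = Reference(id="d", sequence=WT_ROW1_DONOR_FLANK, role="donor")
        acceptor = Reference(id="a", sequence=WT_ROW1_ACCEPTOR_FLANK, role="acceptor")
        read = WT_ROW1_DONOR_FLANK + WT_ROW1_INSERTION + WT_ROW1_ACCEPTOR_FLANK
        call = call_junction(read, donor, acceptor)
        assert call.flank_mutations == ()

    def test_planted_single_mismatch(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 60))
        a_seq = "".join(rng.choice(list("ACGT"), 60))
        read = list(seq)
        read[5] = "ACGT"[("ACGT".index(read[5]) + 2) % 4]
        read = "".join(read) + a_seq
        donor = Reference(id="d", sequence=seq, role="donor")
        acceptor = Reference(id="a", sequence=a_seq, role="acceptor")
        call = call_junction(read, donor, acceptor, CallerConfig(flank_width=60))
        donor_muts = [m for m in call.flank_mutations if m.side == "donor"]
        assert len(donor_muts) == 1
        assert donor_muts[0].ref_pos == 6
        assert donor_muts[0].ref_base == seq[5]


class TestTableRow:
    def test_insertion_row_fields(self):
        donor = Reference(id="d", sequence=WT_ROW1_DONOR_FLANK, role="donor")
        acceptor = Reference(id="a", sequence=WT_ROW1_ACCEPTOR_FLANK, role="acceptor")
        read = WT_ROW1_DONOR_FLANK + WT_ROW1_INSERTION + WT_ROW1_ACCEPTOR_FLANK
        call = call_junction(read, donor, acceptor)
        row = to_table_row(call, donor, acceptor, read)
        assert row.donor_interval == "1:30"
        assert row.donor_flank == WT_ROW1_DONOR_FLANK
        assert row.insertion == "GCACTTC"
        assert row.acceptor_flank == WT_ROW1_ACCEPTOR_FLANK
        assert row.acceptor_interval == "1:30"
        assert row.formatted().count("|") == 4

    def test_lowercase_mutations_in_row(self):
        ref_donor = list(WT_ROW1_DONOR_FLANK)
        ref_donor[12], ref_donor[13] = "C", "C"
        donor = Reference(id="d", sequence="".join(ref_donor), role="donor")
        acceptor = Reference(id="a", sequence=WT_ROW1_ACCEPTOR_FLANK, role="acceptor")
        read = WT_ROW1_DONOR_FLANK + WT_ROW1_INSERTION + WT_ROW1_ACCEPTOR_FLANK
        call = call_junction(read, donor, acceptor)
        row = to_table_row(call, donor, acceptor, read)
        assert row.donor_flank[12:14] == "tt"
        assert row.donor_flank.upper() == WT_ROW1_DONOR_FLANK

    def test_blunt_row_empty_insertion(self):
        rng = np.random.default_rng(2)
        d_seq = "".join(rng.choice(list("CT"), 40))
        a_seq = "".join(rng.choice(list("AG"), 40))
        donor = Reference(id="d", sequence=d_seq, role="donor")
        acceptor = Reference(id="a", sequence=a_seq, role="acceptor")
        call = call_junction(d_seq + a_seq, donor, acceptor)
        row = to_table_row(call, donor, acceptor, d_seq + a_seq)
        assert row.insertion == ""

    def test_mh_markup_brackets_shared_bases(self):
        donor = Reference(id="d", sequence="C" * 30 + "TTTACGT", role="donor")
        acceptor = Reference(id="a", sequence="ACGTCCC" + "G" * 30, role="acceptor")
        read = "C" * 30 + "TTTACGT" + "CCC" + "G" * 30
        call = call_junction(read, donor, acceptor)
        row = to_table_row(call, donor, acceptor, read)
        assert row.mh_markup.endswith("[ACGT]")

    def test_round_trip(self):
        donor = Reference(id="d", sequence=WT_ROW1_DONOR_FLANK, role="donor")
        acceptor = Reference(id="a", sequence=WT_ROW1_ACCEPTOR_FLANK, role="acceptor")
        read = WT_ROW1_DONOR_FLANK + WT_ROW1_INSERTION + WT_ROW1_ACCEPTOR_FLANK
        row1 = to_table_row(call_junction(read, donor, acceptor), donor, acceptor, read)
        rebuilt = (row1.donor_flank + row1.insertion.replace("-", "") + row1.acceptor_flank).upper()
        row2 = to_table_row(call_junction(rebuilt, donor, acceptor), donor, acceptor, rebuilt)
        assert row1 == row2
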