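"""Six-frame translation, ORF extraction, variant naming, assembly stats."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from byssomap.transcriptome import (
    FastaParseError,
    ProteinIsoform,
    SignalAnnotation,
    Transcript,
    assembly_stats,
    assign_variant_names,
    complete_signal_from_variants,
    extract_orfs,
    read_transcripts,
    reverse_complement,
    six_frame_translate,
)

# independently typed standard codon table (oracle for translation)
_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _oracle_translate(nt: str) -> str:
    return "".join(
        _CODONS.get(nt[i:i + 3], "X") for i in range(0, len(nt) - len(nt) % 3, 3)
    )


class TestReadTranscripts:
    def test_component_parsed_from_trinity_style_id(self, tmp_path):
        fa = tmp_path / "t.fasta"
        fa.write_text(">comp35860_c0_seq1\nATGGCC\n")
        (t,) = read_transcripts(fa)
        assert t.component_id == "comp35860_c0"
        assert t.length_bp == 6

    def test_case_folding_and_u_mapping(self, tmp_path):
        fa = tmp_path / "t.fasta"
        fa.write_text(">x\naugn\n")
        (t,) = read_transcripts(fa)
        assert t.sequence == "ATGN"

    def test_ids_without_component_prefix_become_singletons(self, tmp_path):
        fa = tmp_path / "t.fasta"
        fa.write_text(">a\nACGT\n>b\nACGT\n>c\nACGT\n")
        ts = read_transcripts(fa)
        assert {t.component_id for t in ts} == {"a", "b", "c"}

    def test_empty_file_is_an_error(self, tmp_path):
        fa = tmp_path / "t.fasta"
        fa.write_text("")
        with pytest.raises(FastaParseError):
            read_transcripts(fa)

    def test_bad_alphabet_is_an_error(self, tmp_path):
        fa = tmp_path / "t.fasta"
        fa.write_text(">x\nAZGT\n")
        with pytest.raises(FastaParseError):
            read_transcripts(fa)


class TestSixFrameTranslate:
    def test_forward_frame(self):
        frames = dict(six_frame_translate("ATGGCC"))
        assert frames["+1"] == "MA"

    def test_reverse_frame_matches_hand_translation(self):
        # revcomp of ATGGCC is GGCCAT -> GGC=G, CAT=H
        frames = dict(six_frame_translate("ATGGCC"))
        assert frames["-1"] == "GH"

    def test_n_codon_yields_x_even_when_wobble_resolvable(self):
        frames = dict(six_frame_translate("ATGNAA"))
        assert frames["+1"] == "MX"
        # GGN resolves to Gly in a permissive translator; the contract
        # here is strict: any N-containing codon is X
        assert dict(six_frame_translate("GGNAAA"))["+1"] == "XK"

    def test_always_six_frames_with_expected_codon_counts(self, rng):
        for _ in range(25):
            n = rng.randint(3, 90)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            frames = six_frame_translate(seq)
            assert len(frames) == 6
            for name, aa in frames:
                offset = int(name[1]) - 1
                assert len(aa) == (n - offset) // 3

    def test_matches_independent_codon_table(self, rng):
        for _ in range(50):
            n = rng.randint(3, 120)
            seq = "".join(rng.choice("ACGTN") for _ in range(n))
            frames = dict(six_frame_translate(seq))
            rc = reverse_complement(seq)
            for off in range(3):
                assert frames[f"+{off + 1}"] == _oracle_translate(seq[off:])
                assert frames[f"-{off + 1}"] == _oracle_translate(rc[off:])

    def test_double_reverse_complement_is_involution(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 60)))
            assert reverse_complement(reverse_complement(seq)) == seq
            assert six_frame_translate(seq) == six_frame_translate(
                reverse_complement(reverse_complement(seq))
            )

    def test_too_short_is_an_error(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")


def _orf_oracle(frame_aa: str, min_aa: int):
    """Brute force: substrings between stops, with flanking info."""
    out = []
    segments = frame_aa.split("*")
    for i, seg in enumerate(segments):
        if len(seg) >= min_aa:
            out.append((seg, seg.startswith("M"), i < len(segments) - 1))
    return out


class TestExtractOrfs:
    def test_length_filter_and_flags(self):
        orfs = extract_orfs([("+1", "MAAAK*GG")], min_aa=3)
        assert len(orfs) == 1
        assert orfs[0].aa_sequence == "MAAAK"
        assert orfs[0].has_start and orfs[0].has_stop

    def test_keep_all_retains_met_less_segments(self):
        (orf,) = extract_orfs([("+1", "AAAA")], min_aa=3, mode="keep_all")
        assert not orf.has_start and not orf.has_stop

    def test_require_start_trims_to_first_met(self):
        (orf,) = extract_orfs([("+1", "AAMKAA")], min_aa=3, mode="require_start")
        assert orf.aa_sequence == "MKAA"

    def test_matches_bruteforce_over_random_transcripts(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(60))
            frames = six_frame_translate(seq)
            got = [(o.aa_sequence, o.has_start, o.has_stop)
                   for o in extract_orfs(frames, min_aa=5)]
            expected = []
            for _, aa in frames:
                expected.extend(_orf_oracle(aa, 5))
            assert got == expected

    def test_invariant_to_stop_padding(self, rng):
        frames = [("+1", "MAAAKAAAG"), ("+2", "KKKKKKK")]
        padded = [(f, "*" + aa + "*") for f, aa in frames]
        a = [(o.aa_sequence) for o in extract_orfs(frames, min_aa=5)]
        b = [(o.aa_sequence) for o in extract_orfs(padded, min_aa=5)]
        assert a == b


class TestVariantNaming:
    def test_greek_letters_by_decreasing_mass(self):
        isos = [ProteinIsoform("t%d" % i, "+1", "AAAA") for i in range(4)]
        masses = [6600.0, 5600.0, 6500.0, 5400.0]
        labelled = assign_variant_names(isos, masses)
        assert [i.variant_label for i in labelled] == ["α", "γ", "β", "δ"]

    def test_single_isoform_is_alpha(self):
        (iso,) = assign_variant_names([ProteinIsoform("t", "+1", "AAA")], [1000.0])
        assert iso.variant_label == "α"

    def test_tie_broken_by_sequence(self):
        isos = [ProteinIsoform("t1", "+1", "AAB"), ProteinIsoform("t2", "+1", "AAA")]
        labelled = assign_variant_names(isos, [1000.0, 1000.0])
        assert labelled[0].variant_label == "β"
        assert labelled[1].variant_label == "α"

    def test_label_order_is_bijective_with_sort_order(self, rng):
        n = 10
        isos = [ProteinIsoform(f"t{i}", "+1",
                               "".join(rng.choice("ACDEFG") for _ in range(8)))
                for i in range(n)]
        masses = [rng.uniform(4000, 22000) for _ in range(n)]
        labelled = assign_variant_names(isos, masses)
        ranked = sorted(
            zip(labelled, masses),
            key=lambda im: (-im[1], im[0].aa_sequence, im[0].transcript_id),
        )
        assert [i.variant_label for i, _ in ranked] == list("αβγδεζηθικ")[:n]

    def test_alphabet_exhaustion_is_an_error(self):
        isos = [ProteinIsoform(f"t{i}", "+1", "AAA") for i in range(25)]
        with pytest.raises(ValueError):
            assign_variant_names(isos, list(range(25, 0, -1)))


class TestSignalCompletion:
    def _donor(self):
        return ProteinIsoform(
            "donor", "+1", "MKLALLAVIAFVAPSCYEATYPVPNQGRCLKDGQYFASGH",
            has_start=True, signal=SignalAnnotation(19, "annotation_file"),
        )

    def test_acceptor_completed_from_donor_prefix(self):
        donor = self._donor()
        acceptor = ProteinIsoform("acc", "+1", donor.aa_sequence[8:])
        completed = complete_signal_from_variants([donor, acceptor])
        acc = next(i for i in completed if i.transcript_id == "acc")
        assert acc.aa_sequence == donor.aa_sequence
        assert acc.signal is not None
        assert acc.signal.source == "variant_completion"

    def test_acceptor_with_divergent_mature_region_still_completed(self):
        donor = self._donor()
        # same partial signal, different mature sequence downstream
        acceptor = ProteinIsoform("acc", "+1", donor.aa_sequence[5:25] + "WWWWWW")
        completed = complete_signal_from_variants([donor, acceptor])
        acc = next(i for i in completed if i.transcript_id == "acc")
        assert acc.aa_sequence == donor.aa_sequence[:5] + acceptor.aa_sequence
        assert acc.signal is not None and acc.signal.cleavage_pos == 19

    def test_zero_overlap_leaves_family_unchanged(self):
        donor = self._donor()
        acceptor = ProteinIsoform("acc", "+1", "WWWWWWWWWWWW")
        completed = complete_signal_from_variants([donor, acceptor])
        acc = next(i for i in completed if i.transcript_id == "acc")
        assert acc.aa_sequence == "WWWWWWWWWWWW" and acc.signal is None

    def test_short_overlap_is_not_completed(self):
        donor = self._donor()
        acceptor = ProteinIsoform("acc", "+1", donor.aa_sequence[15:19] + "WWWWWWWW")
        completed = complete_signal_from_variants([donor, acceptor], min_overlap=10)
        acc = next(i for i in completed if i.transcript_id == "acc")
        assert acc.signal is None


class TestAssemblyStats:
    def _ts(self, lengths):
        return [Transcript(f"t{i}", "A" * n) for i, n in enumerate(lengths)]

    def test_n50_by_cumulative_enumeration(self):
        stats = assembly_stats(self._ts([2, 2, 2, 10]))
        assert stats["N50_bp"] == 10  # 10 >= 8 of 16 bases

    def test_single_transcript(self):
        stats = assembly_stats(self._ts([100]))
        assert stats["N50_bp"] == stats["N30_bp"] == stats["median_bp"] == 100

    def test_median_of_run(self):
        assert assembly_stats(self._ts(range(1, 10)))["median_bp"] == 5

    def test_against_bruteforce_on_random_lengths(self, rng):
        for _ in range(20):
            lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 40))]
            stats = assembly_stats(self._ts(lengths))
            total = sum(lengths)
            for frac, key in ((0.5, "N50_bp"), (0.3, "N30_bp")):
                best = None
                for cand in sorted(set(lengths), reverse=True):
                    if sum(x for x in lengths if x >= cand) >= frac * total:
                        best = cand
                        break
                assert stats[key] == best

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            assembly_stats([])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=120))
def test_six_frame_involution_property(seq):
    assert six_frame_translate(seq) == six_frame_translate(
        reverse_complement(reverse_complement(seq))
    )
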