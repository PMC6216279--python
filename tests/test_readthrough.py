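"""Stop-context analysis, read-through prediction and protein mass."""

import pytest
from hypothesis import given, strategies as st

import mitofidelity as mf
from mitofidelity.readthrough import END_OF_MESSAGE, STOP_AT_TERMINUS, STOP_IN_UTR
from mitofidelity.seqio import COMPLETE_STOP, HUNGRY

WATER = 18.0153


def _cds(body, terminal, utr, code, flag=None):
    if flag is None:
        flag = HUNGRY if code.is_hungry(terminal) else COMPLETE_STOP
    return mf.CodingSequence("t", body, terminal, flag, utr, (0, 0, 1), code)


class TestProteinMW:
    def test_empty_chain_is_one_water(self):
        assert mf.protein_mw("") == pytest.approx(WATER, abs=0.01)

    def test_diglycine(self):
        # 2 x 57.05 residue mass + water
        assert mf.protein_mw("GG") == pytest.approx(132.12, abs=0.01)

    def test_additivity(self):
        p, q = "MKTAYIAK", "WLVPREQC"
        assert mf.protein_mw(p + q) == pytest.approx(
            mf.protein_mw(p) + mf.protein_mw(q) - WATER, abs=1e-6
        )

    def test_monoisotopic_below_average(self):
        assert mf.protein_mw("MKW", "monoisotopic") < mf.protein_mw("MKW", "average")

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="position 2"):
            mf.protein_mw("MKXA")

    def test_determinism(self):
        assert mf.protein_mw("ACDEFGHIKLMNPQRSTVWY") == mf.protein_mw(
            "ACDEFGHIKLMNPQRSTVWY"
        )


class TestStopContext:
    def test_stop_at_utr_start(self, code1):
        cds = _cds("ATGTGT", "TAA", "TAAAAAAAA", code1)
        ctx = mf.stop_context(cds)
        assert ctx.frame_stops[0][0] == 0

    def test_frames_against_sliding_window_oracle(self, code2):
        import numpy as np

        rng = np.random.default_rng(4)
        for _ in range(25):
            utr = "".join(rng.choice(list("ACGT"), size=60))
            cds = _cds("ATGTGTTCT", "AGA", utr, code2)
            ctx = mf.stop_context(cds)
            stops = code2.stop_codons - code2.hungry_codons
            ext = "AGA" + utr
            for frame in (0, -1, 1):
                expected = tuple(
                    i - 3
                    for i in range(3 + frame, len(ext) - 2, 3)
                    if ext[i : i + 3] in stops
                )
                assert ctx.frame_stops[frame] == expected, (frame, utr)

    def test_minus1_shift_detection(self, code2):
        # ...TCT AGA: slipping back one nt exposes T+AG = TAG
        cds = _cds("ATGTCT", "AGA", "A" * 12, code2)
        assert mf.stop_context(cds).minus1_stop_at_terminus
        # ...GCT AGA exposes TAG too; ...TCA AGA exposes AAG, not a stop
        cds = _cds("ATGTCA", "AGA", "A" * 12, code2)
        assert not mf.stop_context(cds).minus1_stop_at_terminus

    def test_empty_utr_with_window(self, code1):
        cds = _cds("ATGTGT", "TAA", "", code1)
        ctx = mf.stop_context(cds, window=30)
        assert ctx.truncated
        assert all(v == () for v in ctx.frame_stops.values())

    def test_hungry_codons_optionally_count_as_stops(self, code2):
        cds = _cds("ATGTGT", "AGA", "AAAAGG" + "A" * 24, code2)
        assert mf.stop_context(cds).frame_stops[0] == ()
        strict = mf.stop_context(cds, treat_hungry_as_stop=True)
        assert strict.frame_stops[0] == (3,)


class TestPredictReadthrough:
    def test_polyA_tract_length(self, code1):
        # UTR without stops, then 51 nt of polyA -> 17 lysines
        cds = _cds("ATGGCC", "TAA", "GGCGGCGGC", code1)
        res = mf.predict_readthrough(
            cds, polyA_len=51, decode_code=code1, terminal_policy="skip"
        )
        assert res.polyK_length == 17
        assert res.termination_reason == END_OF_MESSAGE

    def test_three_more_As_one_more_lysine(self, code1):
        cds = _cds("ATGGCC", "TAA", "GGCGGC", code1)
        k = [
            mf.predict_readthrough(
                cds, polyA_len=n, decode_code=code1, terminal_policy="skip"
            ).polyK_length
            for n in (12, 15, 18)
        ]
        assert k == [4, 5, 6]

    def test_partial_trailing_codon_not_decoded(self, code1):
        cds = _cds("ATGGCC", "TAA", "", code1)
        a = mf.predict_readthrough(cds, 9, code1, terminal_policy="skip")
        b = mf.predict_readthrough(cds, 11, code1, terminal_policy="skip")
        assert a.polyK_length == b.polyK_length == 3

    def test_terminal_stop_blocks_without_suppression(self, code1):
        cds = _cds("ATGGCC", "TGA", "TAAGGG", code1)
        res = mf.predict_readthrough(cds, polyA_len=0, decode_code=code1)
        assert res.extension_peptide == ""
        assert res.termination_reason == STOP_AT_TERMINUS
        assert res.extended_mw == pytest.approx(res.native_mw, abs=1e-9)

    def test_suppression_reads_through_terminal_stop(self, code1):
        cds = _cds("ATGGCC", "TGA", "GGGGCC", code1)
        res = mf.predict_readthrough(
            cds, polyA_len=0, decode_code=code1, suppress_stops=True
        )
        assert res.extension_peptide == "WGA"
        assert res.termination_reason == END_OF_MESSAGE

    def test_stop_in_utr_terminates_extension(self, code1):
        cds = _cds("ATGGCC", "AGA", "GGGTAACCC", code1)
        res = mf.predict_readthrough(cds, polyA_len=30, decode_code=code1)
        assert res.extension_peptide == "RG"  # AGA->Arg then GGG, stop at TAA
        assert res.termination_reason == STOP_IN_UTR

    def test_extension_mass_independent_of_body(self, code1):
        utr = "GGCAGCTTC"
        a = _cds("ATGGCC", "AGA", utr, code1)
        b = _cds("ATGAAAGATCCC", "AGA", utr, code1)
        ra = mf.predict_readthrough(a, 12, code1)
        rb = mf.predict_readthrough(b, 12, code1)
        assert ra.extension_peptide == rb.extension_peptide
        assert ra.extended_mw - ra.native_mw == pytest.approx(
            rb.extended_mw - rb.native_mw, abs=1e-6
        )

    def test_extension_mass_is_residue_sum(self, code1):
        cds = _cds("ATGGCC", "AGA", "GGCAGCTTC", code1)
        res = mf.predict_readthrough(cds, 9, code1)
        assert res.extension_peptide != ""
        assert res.extended_mw > res.native_mw
        assert res.extended_mw - res.native_mw == pytest.approx(
            mf.protein_mw(res.extension_peptide) - WATER, abs=1e-6
        )

    @given(st.integers(0, 40))
    def test_polyk_never_exceeds_message_capacity(self, code1, polya):
        cds = _cds("ATGGCC", "TAA", "GGG", code1)
        res = mf.predict_readthrough(
            cds, polyA_len=polya, decode_code=code1, terminal_policy="skip"
        )
        assert res.polyK_length <= (3 + polya) // 3


def test_insert_codon_models_construct(code2, co1):
    constr = mf.insert_codon(co1, "GCG", index=1)
    assert constr.n_codons == co1.n_codons + 1
    assert mf.translate(constr) == "MA" + mf.translate(co1)[1:]
    with pytest.raises(ValueError, match="triplet"):
        mf.insert_codon(co1, "GC")
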