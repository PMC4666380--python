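"""Amplicon template parsing, IUPAC expansion, pools and FASTQ emission."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcrdistort.templates import (
    BARCODE_LEN,
    READ_LEN,
    build_input_pool,
    default_templates,
    emit_read_pairs,
    expand_iupac_template,
    read_region_sequence,
    reverse_complement,
)


class TestTemplateParsing:
    def test_read_region_is_101nt(self, templates):
        for t in templates.values():
            a, b = t.read_region
            assert b - a == READ_LEN == 101

    def test_anchors_lie_inside_barcode_slots(self, templates):
        for t in templates.values():
            for slot, off, sym in t.anchor_positions:
                assert 0 <= off < BARCODE_LEN
                assert sym in "RYS"

    def test_constant_region_has_no_degeneracy(self, templates):
        for t in templates.values():
            assert set(t.constant_sequence) <= set("ACGT")
            assert len(t.constant_sequence) == 46

    def test_bc1_bc2_differ_exactly_at_anchors(self, templates):
        """BC1 and BC2 share offsets but carry complementary R/Y symbols."""
        t1, t2 = templates["BC1-BC1"], templates["BC2-BC2"]
        for slot in range(2):
            a1 = dict(t1.anchors_in_slot(slot))
            a2 = dict(t2.anchors_in_slot(slot))
            assert sorted(a1) == sorted(a2)
            for off in a1:
                assert {a1[off], a2[off]} == {"R", "Y"}
            # outside anchors both templates are unconstrained N
            b1, b2 = t1.barcode_templates[slot], t2.barcode_templates[slot]
            for off in range(BARCODE_LEN):
                if off not in a1:
                    assert b1[off] == b2[off] == "N"


class TestExpandIupac:
    def test_fixed_bases_verbatim(self, rng):
        assert expand_iupac_template("ACGT", rng) == "ACGT"

    def test_unknown_code_rejected_with_position(self, rng):
        with pytest.raises(ValueError, match="'X' at position 2"):
            expand_iupac_template("ACXGT", rng)

    def test_all_S_barcode_is_pure_gc(self, rng):
        seq = expand_iupac_template("S" * 20, rng)
        assert set(seq) <= set("GC")

    def test_bc3_barcode_gc_content_is_80_percent(self, templates, rng):
        """The GC-rich design: 12 S + 8 N positions give E[GC] = 0.80."""
        bc3 = templates["BC3-BC3"].barcode_templates[0]
        draws = [expand_iupac_template(bc3, rng) for _ in range(2000)]
        gc = np.mean([(s.count("G") + s.count("C")) / 20 for s in draws])
        assert abs(gc - 0.80) < 0.01

    def test_r_code_draws_a_half_the_time(self, rng):
        n = 10_000
        freq = sum(expand_iupac_template("R", rng) == "A" for _ in range(n)) / n
        assert 0.48 <= freq <= 0.52

    @given(st.text(alphabet="ACGTNRYS", min_size=1, max_size=60), st.integers(0, 2**31 - 1))
    def test_expansion_properties(self, template, seed):
        out = expand_iupac_template(template, np.random.default_rng(seed))
        assert len(out) == len(template)
        assert set(out) <= set("ACGT")
        choices = {"N": "ACGT", "R": "AG", "Y": "CT", "S": "GC"}
        for got, code in zip(out, template):
            assert got in choices.get(code, code)


class TestInputPool:
    def test_single_molecule_pool(self, rng):
        pool = build_input_pool(1, {"BC1-BC1": 1.0}, rng)
        assert len(pool) == 1
        assert pool[0].class_pair == ("BC1", "BC1")
        assert pool[0].copy_number_before_pcr == 1
        assert len(pool[0].barcode_pair) == 40 and len(pool[0].tag) == 15

    def test_zero_bc3_when_excluded(self, rng):
        pool = build_input_pool(5000, {"BC1-BC1": 0.5, "BC2-BC2": 0.5, "BC3-BC3": 0.0}, rng)
        assert len(pool) == 5000
        assert not any(m.class_pair[0] == "BC3" for m in pool)

    def test_bc3_spike_in_fraction(self, rng):
        pool = build_input_pool(
            10_000, {"BC1-BC1": 0.45, "BC2-BC2": 0.45, "BC3-BC3": 0.10}, rng
        )
        frac = np.mean([m.class_pair[0] == "BC3" for m in pool])
        assert 0.08 <= frac <= 0.12

    def test_empty_mix_rejected(self, rng):
        with pytest.raises(ValueError):
            build_input_pool(10, {}, rng)

    def test_barcodes_respect_anchor_classes(self, templates, rng):
        pool = build_input_pool(200, {"BC1-BC1": 0.5, "BC2-BC2": 0.5}, rng)
        for m in pool:
            t = templates[f"{m.class_pair[0]}-{m.class_pair[1]}"]
            for slot, off, sym in t.anchor_positions:
                base = m.barcode_pair[slot * BARCODE_LEN + off]
                expected = {"R": "AG", "Y": "CT", "S": "GC"}[sym]
                assert base in expected


class TestEmitReadPairs:
    def _rows(self, rng, n=50, reads=1):
        pool = build_input_pool(n, {"BC1-BC1": 1.0}, rng)
        return pd.DataFrame(
            {
                "sequence": [m.barcode_pair for m in pool],
                "tag": [m.tag for m in pool],
                "read_count": reads,
            }
        )

    def test_zero_error_r2_is_revcomp_of_r1(self, tmp_path, templates, rng):
        rows = self._rows(rng)
        t = templates["BC1-BC1"]
        emit_read_pairs(rows, t, tmp_path / "r1.fq", tmp_path / "r2.fq", rng)
        r1 = (tmp_path / "r1.fq").read_text().splitlines()[1::4]
        r2 = (tmp_path / "r2.fq").read_text().splitlines()[1::4]
        assert len(r1) == len(rows)
        assert all(b == reverse_complement(a) for a, b in zip(r1, r2))

    def test_read_count_conservation(self, tmp_path, templates, rng):
        rows = self._rows(rng, n=10, reads=3)
        t = templates["BC1-BC1"]
        emit_read_pairs(rows, t, tmp_path / "r1.fq", tmp_path / "r2.fq", rng)
        n_reads = len((tmp_path / "r1.fq").read_text().splitlines()) // 4
        assert n_reads == 30

    def test_error_rate_within_poisson_interval(self, tmp_path, templates, rng):
        """~1e6 emitted bases at rate 1e-3: mismatches to truth ~ Poisson(1000)."""
        rows = self._rows(rng, n=4951)  # 2 * 4951 * 101 = 1,000,102 bases
        t = templates["BC1-BC1"]
        emit_read_pairs(
            rows, t, tmp_path / "r1.fq", tmp_path / "r2.fq", rng, seq_error_rate=1e-3
        )
        sources = [
            read_region_sequence(r.sequence, r.tag, t) for r in rows.itertuples()
        ]
        r1 = (tmp_path / "r1.fq").read_text().splitlines()[1::4]
        r2 = (tmp_path / "r2.fq").read_text().splitlines()[1::4]
        mism = sum(
            sum(a != b for a, b in zip(read, src))
            for read, src in zip(r1, sources)
        ) + sum(
            sum(a != b for a, b in zip(read, reverse_complement(src)))
            for read, src in zip(r2, sources)
        )
        assert 860 <= mism <= 1145  # +-4.5 sd around 1000

    def test_wrong_read_length_rejected(self, tmp_path, templates, rng):
        with pytest.raises(ValueError, match="read_length"):
            emit_read_pairs(
                self._rows(rng, n=1),
                templates["BC1-BC1"],
                tmp_path / "a.fq",
                tmp_path / "b.fq",
                rng,
                read_length=100,
            )

    def test_excessive_error_rate_rejected(self, tmp_path, templates, rng):
        with pytest.raises(ValueError, match="seq_error_rate"):
            emit_read_pairs(
                self._rows(rng, n=1),
                templates["BC1-BC1"],
                tmp_path / "a.fq",
                tmp_path / "b.fq",
                rng,
                seq_error_rate=0.5,
            )
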