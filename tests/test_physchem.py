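"""Hydropathy scales, mid-region extraction and hydrophobicity scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrphys import (
    BUILTIN_SCALES,
    KYTE_DOOLITTLE,
    WIMLEY_WHITE_INTERFACE,
    build_clones,
    hydrophobicity,
    length_distribution,
    load_scale_file,
    mid_region,
    score_repertoire,
)
from tcrphys.scales import AMINO_ACIDS, HydropathyScale

from conftest import toy_records

peptides = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30)


class TestScales:
    def test_builtin_scales_cover_all_residues(self):
        for scale in BUILTIN_SCALES.values():
            assert set(scale.values) == set(AMINO_ACIDS)

    def test_kyte_doolittle_reference_values(self):
        assert KYTE_DOOLITTLE.values["I"] == 4.5
        assert KYTE_DOOLITTLE.values["R"] == -4.5

    def test_wimley_white_sign_flipped_at_load(self):
        # published interface ΔG: W = -1.85 (favourable); after the flip
        # tryptophan must score positive (hydrophobic)
        assert WIMLEY_WHITE_INTERFACE.raw_values["W"] == -1.85
        assert WIMLEY_WHITE_INTERFACE.values["W"] == 1.85

    def test_scales_rank_homopolymers_concordantly(self):
        hydrophobic, hydrophilic = ["I", "L", "F"], ["R", "K", "D"]
        for scale in BUILTIN_SCALES.values():
            lo = max(hydrophobicity(aa * 5, scale) for aa in hydrophilic)
            hi = min(hydrophobicity(aa * 5, scale) for aa in hydrophobic)
            assert hi > lo

    def test_incomplete_scale_rejected(self):
        with pytest.raises(ValueError, match="20 standard"):
            HydropathyScale("broken", {"A": 1.0})

    def test_load_scale_file(self, tmp_path):
        f = tmp_path / "scale.txt"
        f.write_text(
            "\n".join(f"{aa} {KYTE_DOOLITTLE.values[aa]}" for aa in AMINO_ACIDS)
        )
        scale = load_scale_file(f, name="kd_copy")
        assert scale.values == KYTE_DOOLITTLE.values


class TestMidRegion:
    @pytest.mark.parametrize(
        "seq,tn,tc,expected",
        [
            ("CASSLGQAYEQYF", 3, 3, "SLGQAYE"),
            ("CASF", 3, 3, ""),
            ("CASSLG", 0, 0, "CASSLG"),
            ("CASSLG", 6, 0, ""),
        ],
    )
    def test_examples(self, seq, tn, tc, expected):
        assert mid_region(seq, tn, tc) == expected

    def test_negative_trim_rejected(self):
        with pytest.raises(ValueError):
            mid_region("CASS", -1, 0)


class TestHydrophobicity:
    @pytest.mark.parametrize(
        "seq,expected",
        [("III", 4.5), ("IR", 0.0), ("CASS", 0.675)],
    )
    def test_kyte_doolittle_values(self, seq, expected):
        assert hydrophobicity(seq, "kyte_doolittle") == pytest.approx(expected)

    def test_empty_sequence_is_missing_not_zero(self):
        assert math.isnan(hydrophobicity("", "kyte_doolittle"))

    def test_unknown_letter_named_with_position(self):
        with pytest.raises(ValueError, match=r"'X' at position 3"):
            hydrophobicity("CAXS", "kyte_doolittle")

    @settings(max_examples=100, deadline=None)
    @given(seq=peptides, seed=st.integers(0, 10**6))
    def test_permutation_invariance(self, seq, seed):
        rng = np.random.default_rng(seed)
        perm = "".join(rng.permutation(list(seq)))
        assert hydrophobicity(seq) == pytest.approx(
            hydrophobicity(perm), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(seq=peptides)
    def test_appending_extreme_residue_is_monotone(self, seq):
        for scale in BUILTIN_SCALES.values():
            base = hydrophobicity(seq, scale)
            top = max(scale.values, key=scale.values.get)
            bottom = min(scale.values, key=scale.values.get)
            assert hydrophobicity(seq + top, scale) >= base - 1e-12
            assert hydrophobicity(seq + bottom, scale) <= base + 1e-12

    def test_mean_bounded_by_scale_range(self):
        for scale in BUILTIN_SCALES.values():
            v = hydrophobicity("CASSLGQAYEQYF", scale)
            assert scale.min <= v <= scale.max


def _toy_rep(aa_counts):
    """Repertoire with the given {cdr3_aa: cell count} on TRB."""
    rows = []
    i = 0
    for aa, (nt, count) in aa_counts.items():
        for _ in range(count):
            rows.append(
                (f"B{i:03d}", "TRB", "TRBV19", "TRBJ2-1", nt, aa, 1,
                 "s1", "case", "CD8 GZMK+")
            )
            i += 1
    meta = pd.DataFrame({"sample_id": ["s1"], "condition": ["case"]})
    return build_clones(toy_records(rows), meta)


class TestScoreRepertoire:
    def test_mid_score_composes_the_two_operations(self):
        rep = _toy_rep({
            "CASSLGQAYEQYF": ("TGTGCCAGCAGTCTGGGACAGGCCTACGAGCAGTACTTT", 1),
        })
        m = score_repertoire(rep, scales=("kyte_doolittle",))
        assert m.loc[0, "mid_sequence"] == "SLGQAYE"
        assert m.loc[0, "hydro_mid"] == pytest.approx(
            hydrophobicity("SLGQAYE", "kyte_doolittle")
        )

    def test_one_row_per_clone_per_scale(self, small_sim):
        rep, _ = small_sim
        m = score_repertoire(
            rep, scales=("kyte_doolittle", "wimley_white_interface")
        )
        assert len(m) == 2 * len(rep.clones)

    def test_vectorized_scoring_matches_per_residue_loop(self, small_sim):
        """Independent brute-force oracle: plain Python sum over residues."""
        rep, _ = small_sim
        m = score_repertoire(rep, scales=("kyte_doolittle",))
        kd = KYTE_DOOLITTLE.values
        for _, row in m.iterrows():
            expected = sum(kd[a] for a in row["cdr3_aa"]) / len(row["cdr3_aa"])
            assert abs(row["hydro_full"] - expected) < 1e-12

    def test_empty_mid_region_is_missing(self):
        rep = _toy_rep({"CASF": ("TGTGCCAGCTTT", 1)})
        m = score_repertoire(rep)
        assert math.isnan(m.loc[0, "hydro_mid"])


class TestLengthDistribution:
    def _rep(self):
        # mid lengths 5, 5, 8 with cell counts 1, 1, 4
        return _toy_rep({
            "CASSLGQAYEF": ("TGTGCCAGCAGTCTGGGACAGGCCTACGAGTTT", 1),
            "CASSPGQAYEF": ("TGTGCCAGCAGTCCGGGACAGGCCTACGAGTTT", 1),
            "CASSLGQAYLMNEF": ("TGTGCCAGCAGTCTGGGACAGGCCTACCTGATGAATGAGTTT", 4),
        })

    def test_clone_weighted(self):
        freqs = length_distribution(self._rep(), by="clone", region="mid")
        got = dict(zip(freqs["length"], freqs["frequency"]))
        assert got == pytest.approx({5: 2 / 3, 8: 1 / 3})

    def test_cell_weighted(self):
        freqs = length_distribution(self._rep(), by="cell", region="mid")
        got = dict(zip(freqs["length"], freqs["frequency"]))
        assert got == pytest.approx({5: 2 / 6, 8: 4 / 6})

    def test_frequencies_sum_to_one_per_condition(self, small_sim):
        rep, _ = small_sim
        freqs = length_distribution(rep, by="cell", region="full")
        sums = freqs.groupby("condition")["frequency"].sum()
        assert np.allclose(sums, 1.0)
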