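"""Translation, CrE classification, V-gene convergence and α–β pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tcrphys import (
    alpha_beta_pairing,
    build_clones,
    classify_convergence,
    convergence_vs_physchem,
    cre_class,
    translate,
    v_gene_convergence,
)
from tcrphys.simulate import AA_TO_CODONS

from conftest import toy_records

# independent oracle: codon table assembled by hand from first principles
# (enumerate all 64 codons through the standard-code wheel)
_BASES = "TCAG"
_AA_WHEEL = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
ORACLE_CODE = {
    a + b + c: _AA_WHEEL[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class TestTranslate:
    @pytest.mark.parametrize("nt,aa", [("TGT", "C"), ("TGC", "C"), ("TGTGCCAGC", "CAS")])
    def test_standard_code(self, nt, aa):
        assert translate(nt) == aa

    @pytest.mark.parametrize(
        "nt,err",
        [("TGAGCC", "stop"), ("TGTG", "divisible"), ("TGN", "non-ACGT")],
    )
    def test_errors(self, nt, err):
        with pytest.raises(ValueError, match=err):
            translate(nt)

    def test_agrees_with_independent_codon_oracle(self):
        """10,000 random in-frame stop-free sequences translate identically
        under a hand-built codon wheel."""
        rng = np.random.default_rng(7)
        sense = sorted(c for c, a in ORACLE_CODE.items() if a != "*")
        for _ in range(10_000):
            codons = [sense[i] for i in rng.integers(0, len(sense), rng.integers(1, 8))]
            nt = "".join(codons)
            assert translate(nt) == "".join(ORACLE_CODE[c] for c in codons)


class TestCreClassification:
    def test_class_is_deterministic_in_variant_count(self):
        assert [cre_class(k) for k in (1, 2, 3, 7)] == [
            "CrE-1", "CrE-2", "CrE-3", "CrE-3",
        ]

    def _rep(self, rows):
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "condition": ["case", "control"]}
        )
        return build_clones(toy_records(rows), meta)

    def test_two_synonymous_variants_are_cre2(self):
        rep = self._rep([
            ("A", "TRB", "TRBV19", "TRBJ2-1", "TGTGCCAGC", "CAS", 1, "s1", "case", ""),
            ("B", "TRB", "TRBV19", "TRBJ2-1", "TGCGCCAGC", "CAS", 1, "s1", "case", ""),
        ])
        records, pct = classify_convergence(rep)
        assert records.loc[0, "cre_class"] == "CrE-2"
        trb = pct[(pct["chain"] == "TRB") & (pct["cre_class"] == "CrE-2")]
        assert trb["pct_clones"].iloc[0] == 100.0

    def test_unique_nt_singletons_are_all_cre1(self):
        rep = self._rep([
            ("A", "TRB", "TRBV19", "TRBJ2-1", "TGTGCCAGC", "CAS", 1, "s1", "case", ""),
            ("B", "TRB", "TRBV30", "TRBJ2-1", "TGTGCCTGG", "CAW", 1, "s1", "case", ""),
        ])
        records, pct = classify_convergence(rep)
        assert (records["cre_class"] == "CrE-1").all()

    def test_row_order_invariance(self, small_sim):
        rep, _ = small_sim
        records, _ = classify_convergence(rep)
        shuffled = rep.records.sample(frac=1, random_state=0)
        rep2 = build_clones(shuffled.reset_index(drop=True), rep.metadata)
        records2, _ = classify_convergence(rep2)
        keys = ["condition", "chain", "cdr3_aa"]
        pd.testing.assert_frame_equal(
            records.sort_values(keys).reset_index(drop=True)[
                keys + ["n_nt_variants", "cre_class"]
            ],
            records2.sort_values(keys).reset_index(drop=True)[
                keys + ["n_nt_variants", "cre_class"]
            ],
        )

    def test_totals_conserved_over_classes(self, small_sim):
        rep, _ = small_sim
        records, _ = classify_convergence(rep, scope="pooled")
        assert records["n_cells"].sum() == len(rep.records)
        assert len(records) == len(rep.clones)

    def test_matches_brute_force_grouping(self, small_sim):
        """Oracle: group raw nucleotide sequences by their translation with
        plain dict bookkeeping and compare every variant count."""
        rep, _ = small_sim
        records, _ = classify_convergence(rep, scope="pooled")
        brute: dict[tuple, set] = {}
        for row in rep.records.itertuples():
            brute.setdefault((row.chain, translate(row.cdr3_nt)), set()).add(
                row.cdr3_nt
            )
        got = {
            (r.chain, r.cdr3_aa): r.n_nt_variants for r in records.itertuples()
        }
        assert got == {k: len(v) for k, v in brute.items()}


class TestConvergenceVsPhyschem:
    def test_single_clone_per_class_means_equal_inputs(self):
        conv = pd.DataFrame(
            {
                "chain": "TRB",
                "cdr3_aa": ["A1", "A2", "A3"],
                "cre_class": ["CrE-1", "CrE-2", "CrE-3"],
            }
        )
        metrics = pd.DataFrame(
            {
                "chain": "TRB",
                "cdr3_aa": ["A1", "A2", "A3"],
                "mid_length": 6,
                "hydro_mid": [0.5, 1.5, 2.5],
            }
        )
        out = convergence_vs_physchem(conv, metrics)
        got = dict(zip(out["cre_class"], out["mean_hydro_mid"]))
        assert got == pytest.approx({"CrE-1": 0.5, "CrE-2": 1.5, "CrE-3": 2.5})

    def test_single_class_stratum_flagged_untested(self):
        conv = pd.DataFrame(
            {"chain": "TRB", "cdr3_aa": ["A1", "A2"], "cre_class": "CrE-1"}
        )
        metrics = pd.DataFrame(
            {
                "chain": "TRB",
                "cdr3_aa": ["A1", "A2"],
                "mid_length": 6,
                "hydro_mid": [0.5, 1.5],
            }
        )
        out = convergence_vs_physchem(conv, metrics)
        assert not out["tested"].any()


class TestVGeneConvergence:
    def test_multi_v_clone_listed_single_v_excluded(self):
        rows = [
            ("A", "TRB", "TRBV19", "TRBJ2-1", "TGTGCCAGC", "CAS", 1, "s1", "case", ""),
            ("B", "TRB", "TRBV6-5", "TRBJ2-1", "TGCGCTTCA", "CAS", 1, "s1", "case", ""),
            ("C", "TRB", "TRBV30", "TRBJ2-1", "TGTGCCTGG", "CAW", 1, "s1", "case", ""),
            ("D", "TRB", "TRBV30", "TRBJ2-1", "TGCGCCTGG", "CAW", 1, "s1", "case", ""),
        ]
        meta = pd.DataFrame({"sample_id": ["s1"], "condition": ["case"]})
        rep = build_clones(toy_records(rows), meta)
        out = v_gene_convergence(rep)
        assert set(out["cdr3_aa"]) == {"CAS"}  # CAW converges within one V
        assert set(out["v_gene"]) == {"TRBV19", "TRBV6-5"}


class TestAlphaBetaPairing:
    def test_partner_multiset_counts_cells(self):
        rows = []
        alphas = ["CAVNYF", "CAVNYF", "CAANYF"]
        for i, a_aa in enumerate(alphas):
            a_nt = "".join(
                AA_TO_CODONS[ch][0] for ch in a_aa
            )
            rows.append((f"X{i}", "TRB", "TRBV19", "TRBJ2-1",
                         "TGTGCCAGCCTGGAGCAGTTC", "CASLEQF", 1, "s1", "case", ""))
            rows.append((f"X{i}", "TRA", "TRAV8-2", "TRAJ33",
                         a_nt, a_aa, 1, "s1", "case", ""))
        # one unpaired β-only cell
        rows.append(("Y0", "TRB", "TRBV19", "TRBJ2-1",
                     "TGTGCCAGCCTGGAGCAGTTC", "CASLEQF", 1, "s1", "case", ""))
        pairs, summary = alpha_beta_pairing(toy_records(rows), expanded_threshold=2)
        got = dict(zip(pairs["alpha_cdr3_aa"], pairs["n_cells"]))
        assert got == {"CAVNYF": 2, "CAANYF": 1}
        assert summary["n_paired_cells"] == 3
        assert summary["n_chain_orphan_cells"] == 1

    def test_planted_length_coupling_recovered(self, small_sim):
        rep, ledger = small_sim
        assert ledger["config"]["pairing_coupling"] > 0
        _, summary = alpha_beta_pairing(rep.records)
        assert summary["length_spearman_rho"] > 0
        assert summary["length_spearman_p"] < 0.05
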