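"""Synthetic single-cell V(D)J repertoire generator.

Emulates, with planted ground truth, the statistical structure every
analysis stage consumes:

* paired CDR3 nucleotide/amino-acid sequences assembled from a germline
  V stub, a random in-frame stop-free junction insert and a J stub, so
  every CDR3 starts with the conserved cysteine and ends with the
  J-encoded phenylalanine;
* power-law clone-size expansion, with the case condition's sizes
  allocated preferentially to hydrophobic mid-regions (the
  hydrophobicity–expansion coupling, ``hydro_coupling_beta``) while the
  marginal clone-size law stays identical across conditions;
* a condition-dependent CDR3 length mixture (``length_modes``), giving
  the case condition its shorter, bimodal length distribution;
* synonymous-nucleotide convergence: expanded clones receive extra
  nucleotide variants that recode codons without changing the protein,
  optionally through an alternative V stub encoding the same prefix;
* per-cell TRA partners with a β–α mid-length coupling, phenotypic
  subset labels, samples, barcodes and UMI counts.

The generator returns both the repertoire and a ground-truth ledger
(every planted clone with its size, variants and V genes) so downstream
modules can be tested against known answers.  The germline stubs are
short invented sequences, not database downloads; they exist to make
generated CDR3s look canonical, not to model real gene segments.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import io as rio
from .convergence import translate
from .physchem import hydrophobicity, mid_region

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# amino acid → sorted list of its codons (stops excluded)
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    AA_TO_CODONS.setdefault(aa, []).append(codon)
for _codons in AA_TO_CODONS.values():
    _codons.sort()

# Invented germline stubs.  V stubs encode the conserved "C..." start,
# J stubs end on phenylalanine.  Each stub spans exactly 3 aa so that
# the default mid-region trims (3, 3) strip precisely the stub-encoded
# residues and the mid region is purely junctional.  TRBV19 and TRBV6-5
# are a synonymous pair (both encode CAS through different codons) so
# that convergent clones can arise through distinct V segments.
DEFAULT_V_POOL = {
    "TRB": [
        ("TRBV19", "TGTGCCAGC"),     # CAS
        ("TRBV6-5", "TGCGCTTCA"),    # CAS (synonymous with TRBV19)
        ("TRBV20-1", "TGCAGTGCC"),   # CSA
        ("TRBV30", "TGTGCCTGG"),     # CAW
    ],
    "TRA": [
        ("TRAV12-1", "TGTGTGGTG"),   # CVV
        ("TRAV8-2", "TGTGCCGTG"),    # CAV
        ("TRAV29", "TGTGCAGCA"),     # CAA
    ],
}
DEFAULT_J_POOL = {
    "TRB": [
        ("TRBJ2-1", "GAGCAGTTC"),    # EQF
        ("TRBJ2-7", "CAGTACTTT"),    # QYF
        ("TRBJ1-2", "TACACCTTC"),    # YTF
    ],
    "TRA": [
        ("TRAJ33", "AACTATTTC"),     # NYF
        ("TRAJ49", "ACCGGCTTC"),     # TGF
    ],
}

DEFAULT_SUBSETS = {
    "CD8 GZMK+": 0.25,
    "CD8 PRF1+": 0.20,
    "CD8 TCF7+": 0.15,
    "CD4 Treg": 0.20,
    "CD4 TCM": 0.20,
}


@dataclass
class SimulationConfig:
    """All generator parameters.

    ``hydro_coupling_beta``, ``convergence_rate``, ``length_modes`` and
    ``n_cells`` may be a single value applied to every condition or a
    per-condition mapping.  Defaults encode the study conditions the
    analyses probe: 2,000 cells per condition, a power-law clone-size
    tail, hydrophobicity-coupled expansion and extra synonymous
    convergence in the case condition, and a shorter bimodal case length
    mixture.
    """

    seed: int = 0
    conditions: tuple[str, ...] = ("case", "control")
    n_cells: int | dict = 2000
    n_samples_per_condition: int = 3
    clone_size_exponent: float = 2.5
    max_clone_frac: float = 0.1
    hydro_coupling_beta: float | dict = field(
        default_factory=lambda: {"case": 0.5, "control": 0.0}
    )
    length_modes: dict = field(
        default_factory=lambda: {
            "case": [(12, 0.5), (15, 0.5)],
            "control": [(15, 1.0)],
        }
    )
    length_jitter: float = 0.1  # P(±1 aa), each direction
    convergence_rate: float | dict = field(
        default_factory=lambda: {"case": 0.35, "control": 0.15}
    )
    n_extra_variant_choices: tuple[int, ...] = (1, 2)
    multi_v_prob: float = 0.25
    shared_clone_rate: float = 0.05
    subset_labels: dict = field(default_factory=lambda: dict(DEFAULT_SUBSETS))
    pairing_coupling: float = 0.6
    alpha_length_sd: float = 1.0
    alpha_secondary_prob: float = 0.15
    alpha_secondary_cell_frac: float = 0.3
    umi_geom_p: float = 0.4
    trim_n: int = 3
    trim_c: int = 3
    scale: str = "kyte_doolittle"
    v_pool: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_V_POOL))
    j_pool: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_J_POOL))

    def per_condition(self, value, condition):
        return value[condition] if isinstance(value, dict) else value

    def validate(self) -> None:
        for cond in self.conditions:
            modes = self.per_condition(self.length_modes, cond)
            w = sum(wt for _, wt in modes)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(
                    f"length_modes weights for {cond!r} sum to {w}, not 1"
                )
            rate = self.per_condition(self.convergence_rate, cond)
            if not 0.0 <= rate <= 1.0:
                raise ValueError("convergence_rate must lie in [0, 1]")
            min_mode = min(L for L, _ in modes) - 1  # jitter can shorten by 1
            feasible = min(
                len(v_nt) // 3 + len(j_nt) // 3
                for _, v_nt in self.v_pool["TRB"]
                for _, j_nt in self.j_pool["TRB"]
            )
            if min_mode < feasible:
                raise ValueError(
                    f"length_modes for {cond!r} reach {min_mode} aa but the "
                    f"shortest V+J stub combination already spans {feasible} aa"
                )
        s = sum(self.subset_labels.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"subset proportions sum to {s}, not 1")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["conditions"] = list(d["conditions"])
        d["n_extra_variant_choices"] = list(d["n_extra_variant_choices"])
        return d


def _synonym_groups(pool):
    """Map each V gene to the others in its pool encoding the same aa stub."""
    by_aa: dict[str, list[tuple[str, str]]] = {}
    for name, nt in pool:
        by_aa.setdefault(translate(nt), []).append((name, nt))
    partners = {}
    for group in by_aa.values():
        for name, _ in group:
            partners[name] = [(n, s) for n, s in group if n != name]
    return partners


def _draw_clone_sizes(rng, n_cells, exponent, max_clone_frac):
    """Power-law sizes trimmed to sum exactly to ``n_cells``."""
    cap = max(2, int(n_cells * max_clone_frac))
    sizes = []
    total = 0
    while total < n_cells:
        batch = rng.zipf(exponent, size=256)
        for s in batch:
            s = int(min(s, cap))
            if total + s >= n_cells:
                sizes.append(n_cells - total)
                total = n_cells
                break
            sizes.append(s)
            total += s
    return np.array(sizes, dtype=int)


def _sample_length(rng, modes, jitter):
    lengths = np.array([L for L, _ in modes])
    weights = np.array([w for _, w in modes])
    L = int(rng.choice(lengths, p=weights))
    u = rng.random()
    if u < jitter:
        L -= 1
    elif u < 2 * jitter:
        L += 1
    return L


def _random_insert(rng, n_aa):
    aas = [AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), n_aa)]
    nt = "".join(
        AA_TO_CODONS[a][rng.integers(0, len(AA_TO_CODONS[a]))] for a in aas
    )
    return nt, "".join(aas)


def _make_skeleton(rng, chain, L, v_pool, j_pool, used_aa, max_tries=200):
    """One clone skeleton: (cdr3_nt, cdr3_aa, v_gene, j_gene)."""
    for _ in range(max_tries):
        vi = rng.integers(0, len(v_pool))
        ji = rng.integers(0, len(j_pool))
        v_name, v_nt = v_pool[vi]
        j_name, j_nt = j_pool[ji]
        n_ins = L - len(v_nt) // 3 - len(j_nt) // 3
        if n_ins < 0:
            continue
        ins_nt, _ = _random_insert(rng, n_ins)
        nt = v_nt + ins_nt + j_nt
        aa = translate(nt)
        if aa in used_aa:
            continue
        used_aa.add(aa)
        return nt, aa, v_name, j_name
    raise ValueError(
        f"could not build a fresh length-{L} {chain} skeleton "
        f"(stub lengths incompatible or amino-acid space exhausted)"
    )


def _recode_synonymous(rng, nt, existing, max_tries=100):
    """A synonymous recoding of ``nt`` distinct from every ``existing``."""
    codons = [nt[i: i + 3] for i in range(0, len(nt), 3)]
    aas = [standard_dna_table.forward_table[c] for c in codons]
    for _ in range(max_tries):
        new = "".join(
            AA_TO_CODONS[a][rng.integers(0, len(AA_TO_CODONS[a]))] for a in aas
        )
        if new not in existing:
            return new
    return None


def generate_repertoire(config: SimulationConfig):
    """Draw one synthetic repertoire.

    Returns ``(rep, ledger)`` where ``rep`` is a
    :class:`~tcrphys.io.RepertoireTable` built from the emitted per-cell
    records and ``ledger`` is the planted ground truth: for every
    condition, the list of β clones with size, nucleotide variants,
    V genes and mid-region hydrophobicity, plus the full configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    partners_b = _synonym_groups(config.v_pool["TRB"])
    subsets = sorted(config.subset_labels)
    subset_p = np.array([config.subset_labels[s] for s in subsets])
    scale = config.scale

    used_beta_aa: set[str] = set()
    used_alpha_aa: set[str] = set()
    mean_beta_L = {
        c: sum(L * w for L, w in config.per_condition(config.length_modes, c))
        for c in config.conditions
    }
    grand_mean_beta = float(np.mean(list(mean_beta_L.values())))
    alpha_feasible_min = min(
        len(v) // 3 + len(j) // 3
        for _, v in config.v_pool["TRA"]
        for _, j in config.j_pool["TRA"]
    )

    rows: dict[str, list] = {c: [] for c in rio.RECORD_COLUMNS}
    ledger: dict = {"config": config.to_dict(), "conditions": {}}
    barcode_counter = 0
    prev_skeletons: list[tuple[str, str, str, str]] = []  # for shared clones

    for cond in config.conditions:
        n_cells = int(config.per_condition(config.n_cells, cond))
        beta = float(config.per_condition(config.hydro_coupling_beta, cond))
        conv_rate = float(config.per_condition(config.convergence_rate, cond))
        modes = config.per_condition(config.length_modes, cond)
        samples = [
            f"{cond}_{i + 1}" for i in range(config.n_samples_per_condition)
        ]

        sizes = _draw_clone_sizes(
            rng, n_cells, config.clone_size_exponent, config.max_clone_frac
        )
        K = len(sizes)

        skeletons = []
        for _ in range(K):
            if prev_skeletons and rng.random() < config.shared_clone_rate:
                skeletons.append(
                    prev_skeletons[rng.integers(0, len(prev_skeletons))]
                )
                continue
            L = _sample_length(rng, modes, config.length_jitter)
            skeletons.append(
                _make_skeleton(
                    rng, "TRB", L, config.v_pool["TRB"],
                    config.j_pool["TRB"], used_beta_aa,
                )
            )
        hydro = np.array(
            [
                hydrophobicity(
                    mid_region(aa, config.trim_n, config.trim_c), scale
                )
                for _, aa, _, _ in skeletons
            ]
        )
        hydro_f = np.nan_to_num(hydro, nan=0.0)

        # Hydrophobicity-coupled size allocation (Gumbel top-k trick):
        # sorting by beta*h + Gumbel noise is weighted sampling without
        # replacement with weights exp(beta*h), so larger sizes land on
        # more hydrophobic clones while the marginal size law is untouched.
        priority = beta * hydro_f + rng.gumbel(size=K)
        order = np.argsort(-priority, kind="stable")
        sizes_desc = np.sort(sizes)[::-1]
        clone_size = np.empty(K, dtype=int)
        clone_size[order] = sizes_desc

        cond_clones = []
        for idx in range(K):
            nt, aa, v_name, j_name = skeletons[idx]
            size = int(clone_size[idx])
            variants = [(nt, v_name)]
            if size >= 2 and rng.random() < conv_rate:
                n_extra = int(
                    config.n_extra_variant_choices[
                        rng.integers(0, len(config.n_extra_variant_choices))
                    ]
                )
                for k in range(n_extra):
                    alt = partners_b.get(v_name, [])
                    if k == 0 and alt and rng.random() < config.multi_v_prob:
                        alt_name, alt_nt = alt[rng.integers(0, len(alt))]
                        new_nt = alt_nt + nt[len(alt_nt):]
                        if new_nt not in {v for v, _ in variants}:
                            variants.append((new_nt, alt_name))
                            continue
                    new_nt = _recode_synonymous(
                        rng, nt, {v for v, _ in variants}
                    )
                    if new_nt is not None:
                        variants.append((new_nt, v_name))

            # α partners: primary (and maybe secondary) chain, with the
            # α mid length coupled to the β length.
            L_beta = len(aa)
            alpha_chains = []
            for _ in range(
                2 if rng.random() < config.alpha_secondary_prob else 1
            ):
                L_alpha = int(
                    round(
                        14
                        + config.pairing_coupling * (L_beta - grand_mean_beta)
                        + rng.normal(0, config.alpha_length_sd)
                    )
                )
                L_alpha = max(alpha_feasible_min, min(22, L_alpha))
                alpha_chains.append(
                    _make_skeleton(
                        rng, "TRA", L_alpha, config.v_pool["TRA"],
                        config.j_pool["TRA"], used_alpha_aa,
                    )
                )

            variant_p = np.array([2.0] + [1.0] * (len(variants) - 1))
            variant_p /= variant_p.sum()
            cell_samples = []
            for _ in range(size):
                barcode = f"BC{barcode_counter:07d}-1"
                barcode_counter += 1
                sample = samples[rng.integers(0, len(samples))]
                subset = subsets[
                    rng.choice(len(subsets), p=subset_p)
                ] if len(subsets) else ""
                var_nt, var_v = variants[
                    rng.choice(len(variants), p=variant_p)
                ]
                a_idx = (
                    1
                    if len(alpha_chains) > 1
                    and rng.random() < config.alpha_secondary_cell_frac
                    else 0
                )
                a_nt, a_aa, a_v, a_j = alpha_chains[a_idx]
                for chain, c_nt, c_aa, c_v, c_j in (
                    ("TRB", var_nt, aa, var_v, j_name),
                    ("TRA", a_nt, a_aa, a_v, a_j),
                ):
                    rows["barcode"].append(barcode)
                    rows["chain"].append(chain)
                    rows["v_gene"].append(c_v)
                    rows["j_gene"].append(c_j)
                    rows["cdr3_nt"].append(c_nt)
                    rows["cdr3_aa"].append(c_aa)
                    rows["productive"].append(True)
                    rows["umis"].append(int(rng.geometric(config.umi_geom_p)))
                    rows["sample_id"].append(sample)
                    rows["condition"].append(cond)
                    rows["subset"].append(subset)
                cell_samples.append(sample)

            cond_clones.append(
                {
                    "chain": "TRB",
                    "cdr3_aa": aa,
                    "length_aa": len(aa),
                    "size": size,
                    "nt_variants": sorted({v for v, _ in variants}),
                    "v_genes": sorted({g for _, g in variants}),
                    "j_gene": j_name,
                    "hydro_mid": float(hydro[idx]) if hydro[idx] == hydro[idx] else None,
                    "alpha_partners": sorted(a[1] for a in alpha_chains),
                }
            )
        prev_skeletons = prev_skeletons + [
            s for s in skeletons if s not in prev_skeletons
        ]
        ledger["conditions"][cond] = {
            "n_cells": n_cells,
            "n_clones": K,
            "clone_sizes": [int(s) for s in sorted(sizes, reverse=True)],
            "clones": cond_clones,
        }

    records = pd.DataFrame(rows)
    metadata = pd.DataFrame(
        [
            {"sample_id": f"{cond}_{i + 1}", "condition": cond}
            for cond in config.conditions
            for i in range(config.n_samples_per_condition)
        ]
    )
    rep = rio.build_clones(records, metadata)
    rep.params = {"simulation": config.to_dict()}
    return rep, ledger


def _plant_cre3_multi_v(records: pd.DataFrame, ledger: dict, seed: int):
    """Force exactly one case β clone to carry three nucleotide variants,
    one of them through an alternative V stub (the planted CrE-3 and
    multi-V convergent clone of the unit-test fixtures)."""
    rng = np.random.default_rng(seed + 1)
    partners = _synonym_groups(
        [(name, nt) for name, nt in DEFAULT_V_POOL["TRB"]]
    )
    case_clones = ledger["conditions"]["case"]["clones"]
    candidates = sorted(
        (c for c in case_clones if c["size"] >= 3 and partners.get(c["v_genes"][0])),
        key=lambda c: (-c["size"], c["cdr3_aa"]),
    )
    if not candidates:
        raise RuntimeError("fixture repertoire has no plantable CrE-3 clone")
    clone = candidates[0]
    aa = clone["cdr3_aa"]
    mask = (records["chain"] == "TRB") & (records["cdr3_aa"] == aa) & (
        records["condition"] == "case"
    )
    idx = records.index[mask]
    base_v = clone["v_genes"][0]
    base_nt = [
        v for v in clone["nt_variants"]
        if translate(v) == aa
    ][0]
    alt_name, alt_nt = partners[base_v][0]
    variant2 = alt_nt + base_nt[len(alt_nt):]
    variant3 = _recode_synonymous(rng, base_nt, {base_nt, variant2})
    variants = [(base_nt, base_v), (variant2, alt_name), (variant3, base_v)]
    for i, row in enumerate(idx):
        nt, v = variants[i % 3]
        records.loc[row, "cdr3_nt"] = nt
        records.loc[row, "v_gene"] = v
    clone["nt_variants"] = sorted(v for v, _ in variants)
    clone["v_genes"] = sorted({g for _, g in variants})
    ledger["planted_cre3"] = {
        "cdr3_aa": aa,
        "condition": "case",
        "nt_variants": clone["nt_variants"],
        "v_genes": clone["v_genes"],
    }


def make_fixtures(out_dir, seed: int = 1234):
    """Write small plain-text test fixtures (≤200 cells per condition).

    Emits a 10x-dialect contig CSV, the same records as an AIRR TSV, a
    per-barcode metadata CSV and a ground-truth JSON ledger, including a
    single planted CrE-3 clone whose variants span two V genes.  The
    files are deterministic for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(
        seed=seed,
        n_cells=100,
        n_samples_per_condition=2,
        n_extra_variant_choices=(1,),  # all generated convergence is CrE-2
        convergence_rate={"case": 0.3, "control": 0.1},
        multi_v_prob=0.0,
    )
    rep, ledger = generate_repertoire(config)
    records = rep.records.copy()
    _plant_cre3_multi_v(records, ledger, seed)
    rep = rio.build_clones(records, rep.metadata)

    rio.write_contigs(records, out / "contigs_tenx.csv", "tenx_csv")
    rio.write_contigs(records, out / "contigs_airr.tsv", "airr_tsv")
    records[["barcode", "sample_id", "condition", "subset"]].drop_duplicates(
        "barcode"
    ).to_csv(out / "barcode_metadata.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    return rep, ledger
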