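"""Reading, filtering and clone construction for single-cell V(D)J data.

Two on-disk dialects are supported: the 10x Genomics per-contig
annotation CSV (``filtered_contig_annotations.csv``-style header) and the
AIRR Rearrangement TSV (v1.4 column names).  Records are held as a
pandas DataFrame with one row per retained contig; a clone is the set of
cells sharing one CDR3 amino-acid sequence on one chain.

Retention rules: productive contigs only, TRA/TRB loci only, non-empty
nucleotide and amino-acid CDR3, nucleotide length exactly three times the
amino-acid length, and the nucleotide sequence must translate to the
annotated amino-acid sequence.  Every dropped row is counted by reason
and the counts logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .convergence import translate

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "barcode", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
    "productive", "umis", "sample_id", "condition", "subset",
]

_TENX_REQUIRED = [
    "barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
    "productive", "umis",
]
_AIRR_REQUIRED = [
    "cell_id", "locus", "v_call", "j_call", "junction", "junction_aa",
    "productive", "duplicate_count",
]
_AIRR_TO_RECORD = {
    "cell_id": "barcode", "locus": "chain", "v_call": "v_gene",
    "j_call": "j_gene", "junction": "cdr3_nt", "junction_aa": "cdr3_aa",
    "productive": "productive", "duplicate_count": "umis",
}

_TRUE_TOKENS = {"true", "t", "yes", "1"}
_FALSE_TOKENS = {"false", "f", "no", "0", "none", "not productive"}


class FormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


def _parse_productive(value) -> bool | None:
    """True/False, or None when the token is unrecognisable."""
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    return None


def read_contigs(path, dialect: str) -> pd.DataFrame:
    """Read and filter a per-contig table.

    Returns a DataFrame with columns barcode, chain, v_gene, j_gene,
    cdr3_nt, cdr3_aa, productive (all True), umis.  Sample metadata
    columns are attached separately (:func:`attach_metadata`).  Drop
    counts per reason are logged and stored in ``df.attrs['drop_counts']``.
    """
    if dialect == "tenx_csv":
        raw = pd.read_csv(path, dtype=str)
        required = _TENX_REQUIRED
    elif dialect == "airr_tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        required = _AIRR_REQUIRED
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{dialect} file {path} is missing required column(s): "
            + ", ".join(missing)
        )

    if dialect == "airr_tsv":
        df = raw[list(_AIRR_TO_RECORD)].rename(columns=_AIRR_TO_RECORD)
    else:
        df = raw[_TENX_REQUIRED].rename(columns={"cdr3": "cdr3_aa"})

    drops: dict[str, int] = {}

    prod = df["productive"].map(_parse_productive)
    n_unparseable = int(prod.isna().sum())
    if n_unparseable:
        logger.warning(
            "%d rows with unparseable productivity value dropped", n_unparseable
        )
        drops["unparseable_productive"] = n_unparseable
    keep = prod.map(lambda v: bool(v) if v is not None else False)
    drops["non_productive"] = int((~keep & prod.notna()).sum())
    df = df[keep.to_numpy()].copy()
    df["productive"] = True

    mask = df["chain"].isin(["TRA", "TRB"])
    drops["non_tr_chain"] = int((~mask).sum())
    df = df[mask]

    for col in ("cdr3_nt", "cdr3_aa"):
        present = df[col].notna() & (df[col].str.len() > 0)
        drops[f"empty_{col}"] = int((~present).sum())
        df = df[present]

    valid_nt = df["cdr3_nt"].map(lambda s: set(s) <= set("ACGT"))
    drops["non_acgt"] = int((~valid_nt).sum())
    if drops["non_acgt"]:
        logger.warning("%d rows with non-ACGT CDR3 dropped", drops["non_acgt"])
    df = df[valid_nt]

    in_frame = df["cdr3_nt"].str.len() == 3 * df["cdr3_aa"].str.len()
    drops["length_mismatch"] = int((~in_frame).sum())
    df = df[in_frame]

    def _translates(row) -> bool:
        try:
            return translate(row.cdr3_nt) == row.cdr3_aa
        except ValueError:
            return False

    ok = df.apply(_translates, axis=1) if len(df) else pd.Series(dtype=bool)
    drops["translation_mismatch"] = int((~ok).sum()) if len(df) else 0
    df = df[ok] if len(df) else df

    df = df.copy()
    df["umis"] = pd.to_numeric(df["umis"]).astype(int)
    df["v_gene"] = df["v_gene"].fillna("")
    df["j_gene"] = df["j_gene"].fillna("")
    df = df.reset_index(drop=True)
    df.attrs["drop_counts"] = drops
    logger.info("read %d records from %s (drops: %s)", len(df), path, drops)
    return df


def write_contigs(records: pd.DataFrame, path, dialect: str) -> None:
    """Write records in one of the supported dialects (round-trips)."""
    if dialect == "tenx_csv":
        out = pd.DataFrame(
            {
                "barcode": records["barcode"],
                "is_cell": "True",
                "contig_id": [
                    f"{b}_contig_{i}" for i, b in enumerate(records["barcode"], 1)
                ],
                "high_confidence": "True",
                "length": records["cdr3_nt"].str.len() + 300,
                "chain": records["chain"],
                "v_gene": records["v_gene"],
                "d_gene": "None",
                "j_gene": records["j_gene"],
                "c_gene": "None",
                "full_length": "True",
                "productive": records["productive"].map(
                    {True: "True", False: "False"}
                ),
                "cdr3": records["cdr3_aa"],
                "cdr3_nt": records["cdr3_nt"],
                "reads": records["umis"] * 50,
                "umis": records["umis"],
            }
        )
        out.to_csv(path, index=False)
    elif dialect == "airr_tsv":
        out = pd.DataFrame(
            {
                "cell_id": records["barcode"],
                "locus": records["chain"],
                "v_call": records["v_gene"],
                "j_call": records["j_gene"],
                "junction": records["cdr3_nt"],
                "junction_aa": records["cdr3_aa"],
                "productive": records["productive"].map({True: "T", False: "F"}),
                "duplicate_count": records["umis"],
            }
        )
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def dedupe_per_barcode(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one contig per (barcode, chain): highest UMI count, ties
    broken by lexicographically smallest cdr3_nt.  Deterministic."""
    ordered = records.sort_values(
        ["barcode", "chain", "umis", "cdr3_nt"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = ordered.drop_duplicates(["barcode", "chain"], keep="first")
    return out.sort_values(["barcode", "chain"], kind="mergesort").reset_index(
        drop=True
    )


def load_barcode_metadata(path) -> pd.DataFrame:
    """Per-barcode metadata CSV: barcode, sample_id, condition, subset."""
    meta = pd.read_csv(path, dtype=str)
    required = ["barcode", "sample_id", "condition"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise FormatError(
            "barcode metadata is missing required column(s): " + ", ".join(missing)
        )
    if "subset" not in meta.columns:
        meta["subset"] = ""
    return meta


def attach_metadata(records: pd.DataFrame, barcode_meta: pd.DataFrame) -> pd.DataFrame:
    """Join sample_id / condition / subset onto records by barcode."""
    merged = records.merge(
        barcode_meta[["barcode", "sample_id", "condition", "subset"]],
        on="barcode",
        how="left",
    )
    orphans = merged.loc[merged["sample_id"].isna(), "barcode"].unique()
    if len(orphans):
        raise ValueError(
            f"{len(orphans)} barcodes absent from metadata "
            f"(first few: {list(orphans[:5])})"
        )
    return merged


@dataclass
class RepertoireTable:
    """Filtered records, the clone table derived from them, and metadata."""

    records: pd.DataFrame
    clones: pd.DataFrame
    metadata: pd.DataFrame  # sample_id → condition (+ covariates)
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        per_chain_records = self.records.groupby("chain").size()
        per_chain_clones = self.clones.groupby("chain")["n_cells"].sum()
        for chain, n in per_chain_records.items():
            if per_chain_clones.get(chain, 0) != n:
                raise AssertionError(
                    f"cell conservation violated for {chain}: "
                    f"{per_chain_clones.get(chain, 0)} clone cells vs {n} records"
                )

    def clone_condition_counts(self) -> pd.DataFrame:
        """Long table: chain, cdr3_aa, condition, n_cells."""
        return (
            self.records.groupby(["chain", "cdr3_aa", "condition"])
            .size()
            .rename("n_cells")
            .reset_index()
            .sort_values(["chain", "cdr3_aa", "condition"])
            .reset_index(drop=True)
        )

    def clone_subset_counts(self) -> pd.DataFrame:
        """Long table: chain, cdr3_aa, subset, n_cells."""
        return (
            self.records.groupby(["chain", "cdr3_aa", "subset"])
            .size()
            .rename("n_cells")
            .reset_index()
            .sort_values(["chain", "cdr3_aa", "subset"])
            .reset_index(drop=True)
        )

    def condition_totals(self, chain: str | None = None) -> pd.Series:
        recs = self.records
        if chain is not None:
            recs = recs[recs["chain"] == chain]
        return recs.groupby("condition").size()

    def save(self, out_dir) -> None:
        """Serialise to a directory of TSVs (records + metadata; the clone
        table is re-derived on load, so a round-trip is exact)."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, in_dir) -> "RepertoireTable":
        from pathlib import Path

        p = Path(in_dir)
        records = pd.read_csv(
            p / "records.tsv", sep="\t",
            dtype={"barcode": str, "cdr3_nt": str, "cdr3_aa": str},
            keep_default_na=False, na_values=[],
        )
        records["productive"] = records["productive"].astype(bool)
        records["umis"] = records["umis"].astype(int)
        metadata = pd.read_csv(
            p / "metadata.tsv", sep="\t", dtype=str,
            keep_default_na=False, na_values=[],
        )
        return build_clones(records, metadata)


def build_clones(records: pd.DataFrame, metadata: pd.DataFrame) -> RepertoireTable:
    """Aggregate deduplicated records into amino-acid-defined clones.

    The clone key is (chain, cdr3_aa); V/J genes and nucleotide variants
    are recorded per clone but do not split it.  ``metadata`` maps
    sample_id → condition; records referencing samples absent from the
    metadata raise, naming the orphans.
    """
    known = set(metadata["sample_id"])
    orphan = sorted(set(records["sample_id"]) - known)
    if orphan:
        raise ValueError(
            "records reference sample_id(s) absent from metadata: "
            + ", ".join(orphan)
        )
    clones = (
        records.groupby(["chain", "cdr3_aa"])
        .agg(
            n_cells=("barcode", "size"),
            n_nt_variants=("cdr3_nt", "nunique"),
            nt_variants=("cdr3_nt", lambda s: tuple(sorted(set(s)))),
            v_genes=("v_gene", lambda s: tuple(sorted(set(s)))),
        )
        .reset_index()
        .sort_values(["chain", "cdr3_aa"])
        .reset_index(drop=True)
    )
    rep = RepertoireTable(
        records=records.reset_index(drop=True),
        clones=clones,
        metadata=metadata.reset_index(drop=True),
    )
    rep.validate()
    return rep
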