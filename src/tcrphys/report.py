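"""Report assembly: run every analysis stage and bundle the outputs.

The bundle is a directory of TSV tables plus a ``summary.json`` that
echoes the full parameter set (scales, trims, pseudocounts, bins, seed)
and the headline statistics.  Output is deterministic for a given
repertoire and configuration: tables are sorted, floats formatted to a
fixed precision, and the JSON serialised with sorted keys, so two runs
from one seed/config are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import clonality, convergence as conv, physchem, stats as tstats

DEFAULT_REPORT_CONFIG = {
    "case_label": "case",
    "control_label": "control",
    "chain": "TRB",
    "scales": ["kyte_doolittle", "wimley_white_interface"],
    "primary_scale": "kyte_doolittle",
    "trim_n": 3,
    "trim_c": 3,
    "pseudo": 1.0,
    "copy_number_bin_edges": list(clonality.DEFAULT_BIN_EDGES),
    "expanded_threshold": clonality.DEFAULT_EXPANDED_THRESHOLD,
    "convergence_scope": "condition",
}

_FLOAT_FMT = "%.10g"


def _write(df, path):
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if v != v else float(f"{v:.12g}")
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if hasattr(obj, "to_dict") and not isinstance(obj, (str, bytes)):
        try:
            return _jsonable(obj.to_dict(orient="records"))
        except TypeError:
            return _jsonable(obj.to_dict())
    return obj


def hydro_report(rep, config: dict | None = None, out_dir=None):
    """Run the full analysis over a repertoire and assemble the bundle.

    Returns ``(tables, summary)``; when ``out_dir`` is given the tables
    are written as TSVs and the summary as ``summary.json``.  Raises if
    an upstream stage cannot run, naming the stage.
    """
    cfg = dict(DEFAULT_REPORT_CONFIG)
    if config:
        cfg.update(config)
    case, control = cfg["case_label"], cfg["control_label"]
    chain = cfg["chain"]

    tables: dict = {}

    metrics = physchem.score_repertoire(
        rep, scales=cfg["scales"], trim_n=cfg["trim_n"], trim_c=cfg["trim_c"]
    )
    tables["metrics"] = metrics.sort_values(
        ["scale", "chain", "cdr3_aa"]
    ).reset_index(drop=True)
    primary = metrics[metrics["scale"] == cfg["primary_scale"]]

    for region in ("full", "mid"):
        tables[f"length_distribution_{region}"] = physchem.length_distribution(
            rep, by="cell", region=region,
            trim_n=cfg["trim_n"], trim_c=cfg["trim_c"], chain=chain,
        )

    try:
        expansion = clonality.expansion_table(
            rep, case, control, chain=chain, pseudo=cfg["pseudo"],
            bin_edges=tuple(cfg["copy_number_bin_edges"]),
        )
    except ValueError as exc:
        raise RuntimeError(f"clonality stage failed: {exc}") from exc
    tables["expansion"] = expansion
    tables["berger_parker"] = clonality.berger_parker_by_sample(rep, chain)

    per_bin, spearman = clonality.hydro_vs_expansion(
        primary, expansion, bin_edges=tuple(cfg["copy_number_bin_edges"])
    )
    tables["hydro_by_copy_number"] = per_bin

    sharing, sharing_summary = clonality.sharing_matrix(
        rep, group_by="subset", chain=chain
    )
    tables["sharing"] = sharing.reset_index()

    conv_records, conv_pct = conv.classify_convergence(
        rep, scope=cfg["convergence_scope"]
    )
    tables["convergence"] = conv_records.drop(columns=["v_genes"]).assign(
        v_genes=conv_records["v_genes"].map(",".join)
    )
    tables["convergence_pct"] = conv_pct
    tables["convergence_hydro"] = conv.convergence_vs_physchem(
        conv_records[conv_records["chain"] == chain], primary
    )
    tables["v_gene_convergence"] = conv.v_gene_convergence(rep)

    pairs, pairing_summary = conv.alpha_beta_pairing(
        rep.records, expanded_threshold=cfg["expanded_threshold"],
        trim_n=cfg["trim_n"], trim_c=cfg["trim_c"],
        scale=cfg["primary_scale"],
    )
    tables["pairing"] = pairs
    hydro_mult = pairing_summary.pop("beta_hydro_by_alpha_multiplicity")
    tables["pairing_hydro_by_multiplicity"] = hydro_mult

    shift, case_vals, control_vals = tstats.expanded_hydro_shift(
        primary, rep, case, control, chain=chain,
        expanded_threshold=cfg["expanded_threshold"],
    )
    mw = tstats.compare_groups(case_vals, control_vals, test="mann_whitney")
    roc = tstats.roc_from_scores(
        np.concatenate([np.ones(len(case_vals)), np.zeros(len(control_vals))]),
        np.concatenate([case_vals, control_vals]),
    )

    bp = tables["berger_parker"]
    summary = {
        "config": _jsonable(cfg),
        "repertoire": {
            "n_records": int(len(rep.records)),
            "n_clones": int(len(rep.clones)),
            "n_cells_by_condition": _jsonable(
                rep.condition_totals(chain).to_dict()
            ),
            "simulation_params": _jsonable(rep.params),
        },
        "expanded_hydro_shift": {
            "ks_d": shift.value,
            "ks_p": shift.p_two_tailed,
            "mann_whitney_u": mw.value,
            "mann_whitney_p": mw.p_two_tailed,
            "n_case_clones": shift.n_a,
            "n_control_clones": shift.n_b,
            "mean_case": float(np.mean(case_vals)) if len(case_vals) else None,
            "mean_control": float(np.mean(control_vals))
            if len(control_vals)
            else None,
        },
        "hydro_vs_expansion_spearman": _jsonable(spearman),
        "roc_expanded_case_vs_control": {
            "auroc": roc.auroc, "p_value": roc.p_value,
            "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        },
        "berger_parker_by_condition": _jsonable(
            bp.groupby("condition")["berger_parker"].mean().to_dict()
        ),
        "sharing": _jsonable(sharing_summary),
        "pairing": _jsonable(pairing_summary),
        "convergence_pct": _jsonable(
            conv_pct.to_dict(orient="records")
        ),
    }
    summary = _jsonable(summary)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            _write(df, out / f"{name}.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return tables, summary
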