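"""Proteome-transcriptome concordance and qRT-PCR cross-checks.

DEPs are matched to DEGs through an explicit accession -> gene mapping
table (no sequence search is attempted); a matched pair is concordant
when the protein's direction of change agrees in sign with at least one
matched gene, where presence-only-in-infected counts as up and
presence-only-in-control as down.

qRT-PCR relative expression uses the 2^-ddCT model: for each gene,
dCT = CT_target - CT_reference within a condition, ddCT is the
infected-minus-control difference of dCTs, and the fold change is
2^-ddCT. Folds inside the configurable "unchanged" band (default
[0.67, 1.5]) are treated as no change.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = ["ddct_fold", "match_dep_deg", "trend_compare"]

logger = logging.getLogger("twolib")

DEFAULT_UNCHANGED_BAND = (0.67, 1.5)

_PROTEIN_SIGN = {"up": 1, "infected_only": 1, "down": -1, "control_only": -1}


def ddct_fold(
    ct_target_infected: float,
    ct_target_control: float,
    ct_ref_infected: float,
    ct_ref_control: float,
) -> tuple[float, float]:
    """Relative quantification: returns (ddCT, 2^-ddCT)."""
    cts = (ct_target_infected, ct_target_control, ct_ref_infected, ct_ref_control)
    if any(c is None or not math.isfinite(c) for c in cts):
        raise ValueError("all four CT values must be finite")
    dct_infected = ct_target_infected - ct_ref_infected
    dct_control = ct_target_control - ct_ref_control
    ddct = dct_infected - dct_control
    return ddct, 2.0 ** (-ddct)


def match_dep_deg(
    deps: pd.DataFrame,
    degs: pd.DataFrame,
    mapping: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Match called DEPs to called DEGs and flag direction concordance.

    ``deps`` is the output of ``proteomics.call_deps`` (rows with
    dep_call == "none" are ignored); ``degs`` the annotated expression
    table (only deg_call in {up, down} rows participate); ``mapping``
    has columns accession, gene_id. Returns the concordance table (one
    row per DEP accession with at least one mapped DEG) and the list of
    DEP accessions with no mapped DEG.
    """
    for col in ("accession", "gene_id"):
        if col not in mapping.columns:
            raise ValueError("mapping table must have columns accession, gene_id")
    empty = pd.DataFrame(columns=["accession", "spot_id", "protein_direction",
                                  "matched_gene_ids", "gene_directions",
                                  "gene_log2_ratios", "concordant"])
    if deps.empty or "dep_call" not in deps.columns:
        return empty, []
    n0 = len(mapping)
    mapping = mapping.drop_duplicates(subset=["accession", "gene_id"])
    if len(mapping) < n0:
        logger.warning("match_dep_deg: %d duplicate mapping rows dropped", n0 - len(mapping))
    gene_dir = (
        degs.loc[degs["deg_call"].isin(["up", "down"])]
        .set_index("gene_id")[["deg_call", "log2_ratio"]]
    )
    by_acc = mapping.groupby("accession")["gene_id"].apply(list)

    rows, unmatched = [], []
    called = deps.loc[deps["dep_call"].isin(_PROTEIN_SIGN)]
    for _, dep in called.iterrows():
        acc = dep["accession"]
        candidates = by_acc.get(acc, [])
        matched = [g for g in candidates if g in gene_dir.index]
        if not matched:
            unmatched.append(acc)
            continue
        matched = sorted(matched)
        p_sign = _PROTEIN_SIGN[dep["dep_call"]]
        gene_calls = [gene_dir.loc[g, "deg_call"] for g in matched]
        g_signs = [1 if c == "up" else -1 for c in gene_calls]
        rows.append(
            {
                "accession": acc,
                "spot_id": dep.get("spot_id", ""),
                "protein_direction": dep["dep_call"],
                "matched_gene_ids": ",".join(matched),
                "gene_directions": ",".join(gene_calls),
                "gene_log2_ratios": ",".join(
                    f"{gene_dir.loc[g, 'log2_ratio']:.6g}" for g in matched),
                "concordant": any(s == p_sign for s in g_signs),
            }
        )
    return (pd.DataFrame(rows) if rows else empty), unmatched


def trend_compare(
    qpcr: pd.DataFrame,
    degs: pd.DataFrame,
    unchanged_band: tuple[float, float] = DEFAULT_UNCHANGED_BAND,
    min_abs_log2: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Compare qRT-PCR folds with RNA-seq log2 ratios gene by gene.

    ``qpcr`` columns: gene_id, ct_target_infected, ct_target_control,
    ct_ref_infected, ct_ref_control. Each gene's fold is classified
    against ``unchanged_band``; the RNA-seq direction is up/down when
    |log2 ratio| >= min_abs_log2, else unchanged. trend_match is the
    shared direction when the two platforms agree and "discordant"
    otherwise. The summary tallies the qPCR classifications.
    """
    lo, hi = unchanged_band
    if not 0 < lo < 1 < hi:
        raise ValueError("unchanged_band must straddle 1")
    rnaseq = degs.set_index("gene_id")["log2_ratio"]
    rows = []
    for _, rec in qpcr.iterrows():
        ddct, fold = ddct_fold(
            rec["ct_target_infected"], rec["ct_target_control"],
            rec["ct_ref_infected"], rec["ct_ref_control"],
        )
        gene = rec["gene_id"]
        if gene not in rnaseq.index:
            logger.warning("trend_compare: gene %s absent from RNA-seq table", gene)
            continue
        log2_rna = float(rnaseq.loc[gene])
        qdir = "up" if fold > hi else ("down" if fold < lo else "unchanged")
        rdir = ("up" if log2_rna >= min_abs_log2
                else "down" if log2_rna <= -min_abs_log2 else "unchanged")
        trend = qdir if qdir == rdir else "discordant"
        rows.append(
            {
                "gene_id": gene,
                "ddct": ddct,
                "fold": fold,
                "qpcr_direction": qdir,
                "rnaseq_log2": log2_rna,
                "rnaseq_direction": rdir,
                "trend_match": trend,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        summary = {"n_up": 0, "n_down": 0, "n_unchanged": 0, "n_concordant": 0}
    else:
        summary = {
            "n_up": int((df["qpcr_direction"] == "up").sum()),
            "n_down": int((df["qpcr_direction"] == "down").sum()),
            "n_unchanged": int((df["qpcr_direction"] == "unchanged").sum()),
            "n_concordant": int((df["trend_match"] != "discordant").sum()),
        }
    return df, summary
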