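"""Cross-platform concordance of per-gene trends.

Effect sizes from the count model (log2 fold change per year) and the
protein mixed model (rank-normal slope) live in incomparable units, so each
gene's trend is summarized as a z-score (estimate / standard error) per
platform.  Genes significant on both platforms (BH q below a threshold,
default 0.1) are classified by the signs of their two z-scores:

====== ======== ===========
group  z_mrna   z_protein
====== ======== ===========
A      > 0      > 0   (concordant increasing)
B      < 0      > 0   (discordant)
C      > 0      < 0   (discordant)
D      < 0      < 0   (concordant decreasing)
====== ======== ===========

Genes not significant on both platforms are labelled NS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["collapse_proteins", "classify_groups", "group_fractions", "z_correlation"]


def collapse_proteins(protein_table: pd.DataFrame, gene_map: pd.Series) -> pd.DataFrame:
    """Collapse multiple protein isoforms per gene to one row per gene.

    ``gene_map`` maps protein feature_id -> gene_id.  When several proteins
    map to one gene the one with the smallest raw p is kept (ties broken by
    feature_id for reproducibility).
    """
    t = protein_table.copy()
    t["gene_id"] = t["feature_id"].map(gene_map)
    t = t.dropna(subset=["gene_id"])
    t = t.sort_values(["gene_id", "p", "feature_id"], kind="mergesort")
    collapsed = t.groupby("gene_id", sort=True).head(1).copy()
    collapsed["feature_id"] = collapsed["gene_id"]
    return collapsed.drop(columns="gene_id").reset_index(drop=True)


def _classify_one(z_m: float, z_p: float, sig_both: bool) -> str:
    if not sig_both:
        return "NS"
    if z_m == 0 or z_p == 0:
        raise ValueError("z-score of exactly 0 on a doubly-significant gene")
    if z_m > 0:
        return "A" if z_p > 0 else "C"
    return "B" if z_p > 0 else "D"


def classify_groups(
    mrna_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Join mRNA and protein trend tables on feature_id and assign A/B/C/D/NS.

    Both inputs are trend-result tables with feature_id, z and q_bh columns;
    protein isoforms must be collapsed to genes beforehand
    (:func:`collapse_proteins`).  Returns one record per shared gene with
    columns gene_id, z_mrna, z_protein, sig_mrna, sig_protein, group.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must lie in (0, 1)")
    m = mrna_table.set_index("feature_id")
    p = protein_table.set_index("feature_id")
    shared = m.index.intersection(p.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the mRNA and protein tables")
    records = []
    for g in shared:
        z_m, q_m = m.at[g, "z"], m.at[g, "q_bh"]
        z_p, q_p = p.at[g, "z"], p.at[g, "q_bh"]
        sig_m = bool(np.isfinite(q_m) and q_m < q_threshold)
        sig_p = bool(np.isfinite(q_p) and q_p < q_threshold)
        records.append({
            "gene_id": g, "z_mrna": z_m, "z_protein": z_p,
            "sig_mrna": sig_m, "sig_protein": sig_p,
            "group": _classify_one(z_m, z_p, sig_m and sig_p),
        })
    return pd.DataFrame(records)


def group_fractions(records: pd.DataFrame) -> dict:
    """Counts per group plus concordant/discordant percentages of all shared genes.

    %concordant = (nA + nD) / N * 100 and %discordant = (nB + nC) / N * 100,
    where N counts every shared gene (NS included).
    """
    if len(records) == 0:
        raise ValueError("no concordance records")
    counts = records["group"].value_counts()
    n = {g: int(counts.get(g, 0)) for g in ["A", "B", "C", "D", "NS"]}
    total = len(records)
    return {
        **{f"n_{g}": n[g] for g in ["A", "B", "C", "D", "NS"]},
        "n_total": total,
        "n_doubly_significant": n["A"] + n["B"] + n["C"] + n["D"],
        "pct_concordant": (n["A"] + n["D"]) / total * 100.0,
        "pct_discordant": (n["B"] + n["C"]) / total * 100.0,
    }


def z_correlation(records: pd.DataFrame, subset: str = "all") -> tuple[float, float]:
    """Pearson correlation of mRNA vs protein z-scores with its p-value.

    subset="all" uses every shared gene; "doubly_significant" restricts to
    genes significant on both platforms.
    """
    if subset == "all":
        sub = records
    elif subset == "doubly_significant":
        sub = records[records["group"] != "NS"]
    else:
        raise ValueError("subset must be 'all' or 'doubly_significant'")
    sub = sub.dropna(subset=["z_mrna", "z_protein"])
    if len(sub) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    x = sub["z_mrna"].to_numpy(dtype=float)
    y = sub["z_protein"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant z vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
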