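"""Replication-transcription relationships for labeled tracks.

For each track the mean RPKM of overlapping expressed genes (RPKM > 0)
measures local transcription, and the fork-movement direction against the
strand of those genes classifies the encounter geometry: a rightward fork
over a minus-strand gene (or a leftward fork over a plus-strand gene) is
head-on; the inverse is co-directional; both strands overlapped is mixed;
no expressed gene overlapped is none.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

__all__ = [
    "assign_expression",
    "classify_orientation",
    "expression_correlations",
    "expression_by_quintile",
]

ORIENTATIONS = ("head_on", "co_directional", "mixed", "none")


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        tree = IntervalTree()
        for _, g in sub.iterrows():
            tree.addi(int(g["start"]), int(g["end"]), (g["strand"], float(g["rpkm"])))
        trees[chrom] = tree
    return trees


def classify_orientation(direction: str, gene_strands) -> str:
    """Encounter geometry of one fork against the strands of overlapped genes."""
    strands = set(gene_strands)
    if not strands:
        return "none"
    if strands == {"+", "-"}:
        return "mixed"
    strand = strands.pop()
    head_on = (direction == "R" and strand == "-") or (direction == "L" and strand == "+")
    return "head_on" if head_on else "co_directional"


def assign_expression(tracks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-track mean RPKM over overlapping expressed genes, plus orientation.

    ``tracks`` needs ``chrom``, ``start``, ``end`` and ``direction``; genes
    with RPKM 0 are excluded before any overlap is considered (>= 1 bp
    overlap qualifies).  Tracks without a qualifying gene get NaN mean RPKM
    and orientation ``none``; they are excluded from expression analyses.
    """
    expressed = genes[genes["rpkm"] > 0]
    trees = _gene_trees(expressed)
    mean_rpkm = np.full(len(tracks), np.nan)
    n_genes = np.zeros(len(tracks), dtype=int)
    orientation = []
    for i, (_, t) in enumerate(tracks.iterrows()):
        tree = trees.get(t["chrom"])
        hits = sorted(tree.overlap(int(t["start"]), int(t["end"]))) if tree else []
        if hits:
            rpkms = [h.data[1] for h in hits]
            mean_rpkm[i] = float(np.mean(rpkms))
            n_genes[i] = len(hits)
        orientation.append(classify_orientation(t["direction"], [h.data[0] for h in hits]))
    out = tracks.copy().reset_index(drop=True)
    out["mean_rpkm"] = mean_rpkm
    out["n_genes"] = n_genes
    out["orientation"] = orientation
    return out


def _pearson(x, y):
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def expression_correlations(expr: pd.DataFrame, min_n: int = 3,
                            log_transform: bool = False) -> pd.DataFrame:
    """Pearson r between track length and mean RPKM per stratum.

    Strata: all expression-qualifying tracks, chromatin categories (when a
    ``category`` column is present) and orientation classes head_on /
    co_directional (mixed tracks enter only the all-tracks stratum).
    Undersized strata are reported with NaN statistics and a note.
    """
    df = expr.dropna(subset=["mean_rpkm"])
    if "length" not in df:
        df = df.assign(length=df["end"] - df["start"])
    strata = {"all": df}
    if "category" in df:
        for cat in ("euchromatin", "heterochromatin"):
            strata[cat] = df[df["category"] == cat]
    for ori in ("head_on", "co_directional"):
        strata[ori] = df[df["orientation"] == ori]
    rows = []
    for name, sub in strata.items():
        x, y = sub["mean_rpkm"].to_numpy(float), sub["length"].to_numpy(float)
        if log_transform:
            ok = (x > 0) & (y > 0)
            x, y = np.log10(x[ok]), np.log10(y[ok])
        if len(x) < min_n or np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan, len(x), "skipped: undersized or degenerate"))
            continue
        r, p = _pearson(x, y)
        rows.append((name, r, p, len(x), ""))
    return pd.DataFrame(rows, columns=["stratum", "r", "p_value", "n", "note"])


def expression_by_quintile(expr: pd.DataFrame) -> pd.DataFrame:
    """Rank expression-qualifying tracks into length quintiles; pairwise rank-sum tests.

    Quintiles are computed on the expression-qualifying set (tracks with a
    defined mean RPKM), Q1 shortest to Q5 longest.
    """
    df = expr.dropna(subset=["mean_rpkm"]).copy()
    if "length" not in df:
        df["length"] = df["end"] - df["start"]
    if len(df) < 5:
        raise ValueError("need at least five expression-qualifying tracks")
    df = df.sort_values(["length", "chrom", "start"], kind="stable").reset_index(drop=True)
    df["quintile"] = pd.cut(np.arange(len(df)), bins=5,
                            labels=["Q1", "Q2", "Q3", "Q4", "Q5"])
    labels = ["Q1", "Q2", "Q3", "Q4", "Q5"]
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va = df.loc[df["quintile"] == a, "mean_rpkm"]
            vb = df.loc[df["quintile"] == b, "mean_rpkm"]
            _u, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append((a, b, float(va.median()), float(vb.median()), float(p)))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "median_a", "median_b",
                                        "p_value"])
    tests.attrs["assignments"] = df
    return tests
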