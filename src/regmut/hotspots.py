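"""Windows whose observed mutations exceed epigenome-informed expectations.

The residual of the burden regression — observed minus (out-of-bag)
predicted SNV count — measures mutation load the chromatin-accessibility
and replication-timing profiles cannot explain. Residuals are
Z-transformed per cohort, converted to one-tailed upper normal
P-values, and Benjamini-Hochberg adjusted across all retained windows
of the cohort. Significant windows are annotated with overlapping genes
(each gene inherits its best window P-value, the input to downstream
pathway tools), and enrichment of labelled genes (e.g. known cancer
genes) among hits is tested with a one-sided Fisher / hypergeometric
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .burden import BurdenVector
from .grid import WindowGrid


def score_residuals(
    observed: BurdenVector | np.ndarray,
    expected: np.ndarray,
    grid: WindowGrid | None = None,
    cohort: str = "",
) -> pd.DataFrame:
    """Z-scores, one-tailed P and BH FDR for observed-minus-expected burden.

    The Z-transform uses the cohort's own residual mean and sample
    (n-1) standard deviation; ``p = P(Z >= z)`` under the standard
    normal; q is BH step-up over all windows. Rows are sorted by q then
    residual descending, with the original window index in ``window``.
    """
    if isinstance(observed, BurdenVector):
        cohort = cohort or observed.cohort
        obs = observed.counts
    else:
        obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if len(obs) != len(exp):
        raise ValueError("observed and expected must align")
    if len(obs) < 10:
        raise ValueError("need at least 10 windows")
    resid = obs - exp
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("zero residual variance")
    z = (resid - resid.mean()) / sd
    p = stats.norm.sf(z)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "window": np.arange(len(obs)),
            "observed": obs,
            "expected": exp,
            "residual": resid,
            "z": z,
            "p": p,
            "q": q,
        }
    )
    if grid is not None:
        df.insert(1, "chrom", grid.chroms)
        df.insert(2, "start", grid.starts)
        df.insert(3, "end", grid.ends)
    df["cohort"] = cohort
    return df.sort_values(["q", "residual"], ascending=[True, False]).reset_index(
        drop=True
    )


def annotate_genes(
    hits: pd.DataFrame, genes: pd.DataFrame, grid: WindowGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach overlapping genes to each window; derive the per-gene table.

    A gene overlaps a window when their half-open intervals intersect.
    The gene-level table assigns each gene the minimum P (and its q)
    over the windows it touches — the format consumed by pathway
    enrichment tools.
    """
    table = hits.copy()
    gene_lists: list[str] = [""] * len(table)
    best: dict[str, dict] = {}
    win_of_row = table["window"].to_numpy()
    for _, g in genes.iterrows():
        cidx = np.flatnonzero(grid.chroms == g["chrom"])
        if len(cidx) == 0:
            continue
        ov = cidx[
            (grid.starts[cidx] < g["end"]) & (grid.ends[cidx] > g["start"])
        ]
        if len(ov) == 0:
            continue
        rows = np.flatnonzero(np.isin(win_of_row, ov))
        for r in rows:
            gene_lists[r] = (
                f"{gene_lists[r]},{g['gene_id']}" if gene_lists[r] else str(g["gene_id"])
            )
        sub = table.iloc[rows]
        if len(sub):
            i = sub["p"].idxmin()
            rec = {"gene_id": g["gene_id"], "p": table.loc[i, "p"], "q": table.loc[i, "q"]}
            best[g["gene_id"]] = rec
    table["genes"] = gene_lists
    gene_table = pd.DataFrame(
        best.values(), columns=["gene_id", "p", "q"]
    ).sort_values("p").reset_index(drop=True)
    return table, gene_table


def fisher_enrichment(
    k_hits_labelled: int,
    n_hits: int,
    K_labelled_total: int,
    N_total: int,
    alternative: str = "greater",
) -> tuple[float, float, float]:
    """Over-representation of labelled items among hits.

    Drawing ``n_hits`` items from ``N_total`` of which ``K_labelled_total``
    are labelled, returns (expected labelled hits, odds ratio, P) with
    ``P = P(X >= k)`` under Hypergeom(N, K, n) for the default one-sided
    test ("greater"); ``alternative="two-sided"`` uses Fisher's exact.
    """
    k, n, K, N = k_hits_labelled, n_hits, K_labelled_total, N_total
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError("inconsistent counts")
    expected = n * K / N
    table = np.array([[k, n - k], [K - k, N - K - (n - k)]])
    if np.any(table < 0):
        raise ValueError("inconsistent counts")
    odds, p_two = stats.fisher_exact(table, alternative="two-sided")
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif alternative == "two-sided":
        p = float(p_two)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return float(expected), float(odds), p


def cancer_gene_enrichment(
    gene_table: pd.DataFrame,
    genes: pd.DataFrame,
    cancer_genes: set[str],
    q_threshold: float = 0.05,
) -> dict:
    """One-sided enrichment of flagged cancer genes among genes in
    significant windows (q below threshold)."""
    hit_genes = set(gene_table.loc[gene_table["q"] < q_threshold, "gene_id"])
    all_genes = set(genes["gene_id"])
    k = len(hit_genes & cancer_genes)
    expected, odds, p = fisher_enrichment(
        k, len(hit_genes), len(all_genes & cancer_genes), len(all_genes)
    )
    return {
        "n_hit_genes": len(hit_genes),
        "n_cancer_gene_hits": k,
        "expected": expected,
        "odds_ratio": odds,
        "p": p,
    }
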