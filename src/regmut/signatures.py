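"""Per-window mutational-signature burden from per-SNV probabilities.

Each SNV carries a probability vector over single-base-substitution
(SBS) signatures — its multinomial attribution to mutational processes.
The expected signature-specific burden of a window is the sum of those
probabilities over the SNVs it contains, so signature burdens conserve
the total SNV count exactly. An alternative hard assignment gives each
SNV wholly to its top-ranking signature; the two agree closely when
attributions are confident, and their per-window rank correlation is a
useful diagnostic.

Signatures supported by fewer than 20,000 (expected) SNVs genome-wide in
a cohort are too sparse for stable regional modelling and are filtered.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .burden import BurdenVector, PAN_CANCER
from .grid import WindowGrid

logger = logging.getLogger(__name__)

#: Minimum genome-wide (expected) SNV support for a signature in a cohort.
MIN_SIGNATURE_SNVS = 20_000

#: Aetiology classes used to group SBS signatures.
SIGNATURE_CLASSES = (
    "AID/APOBEC",
    "DNA-repair",
    "carcinogen",
    "unknown/other",
    "SBS5/40",
    "SBS1",
)

_KEY = ["chrom", "pos", "sample_id"]


def _signature_columns(probs: pd.DataFrame) -> list[str]:
    return [c for c in probs.columns if c not in _KEY]


def _merged_probs(
    snvs: pd.DataFrame, probs: pd.DataFrame, cohort: str
) -> tuple[pd.DataFrame, list[str]]:
    sub = snvs if cohort == PAN_CANCER else snvs[snvs["cohort"] == cohort]
    sig_cols = _signature_columns(probs)
    merged = sub.merge(probs, on=_KEY, how="left", validate="many_to_one")
    missing = merged[sig_cols[0]].isna()
    if missing.any():
        keys = (
            merged.loc[missing, _KEY].astype(str).agg(":".join, axis=1).head(10).tolist()
        )
        raise ValueError(
            f"{int(missing.sum())} SNVs lack signature probabilities, e.g. {keys}"
        )
    return merged, sig_cols


def signature_burden(
    snvs: pd.DataFrame, probs: pd.DataFrame, grid: WindowGrid, cohort: str
) -> dict[str, BurdenVector]:
    """Expected per-window burden per signature (probabilistic binning).

    ``counts_s[w] = sum over SNVs in w of P(signature = s | SNV)``; the
    burdens of all signatures sum to the window's total SNV count.
    """
    merged, sig_cols = _merged_probs(snvs, probs, cohort)
    idx = grid.window_index(
        merged["chrom"].to_numpy(dtype=object), merged["pos"].to_numpy() - 1
    )
    keep = idx >= 0
    out = {}
    for s in sig_cols:
        counts = np.zeros(len(grid))
        np.add.at(counts, idx[keep], merged.loc[keep, s].to_numpy())
        out[s] = BurdenVector(cohort=cohort, mutation_class=s, counts=counts)
    return out


def top_signature_burden(
    snvs: pd.DataFrame, probs: pd.DataFrame, grid: WindowGrid, cohort: str
) -> dict[str, BurdenVector]:
    """Hard-assignment alternative: each SNV contributes 1 to its
    argmax-probability signature, ties broken by lexicographic id."""
    merged, sig_cols = _merged_probs(snvs, probs, cohort)
    sig_sorted = sorted(sig_cols)
    P = merged[sig_sorted].to_numpy()
    top = np.argmax(P, axis=1)  # first (lexicographically smallest) argmax wins
    idx = grid.window_index(
        merged["chrom"].to_numpy(dtype=object), merged["pos"].to_numpy() - 1
    )
    keep = idx >= 0
    out = {}
    for j, s in enumerate(sig_sorted):
        counts = np.zeros(len(grid))
        sel = keep & (top == j)
        np.add.at(counts, idx[sel], 1.0)
        out[s] = BurdenVector(cohort=cohort, mutation_class=s, counts=counts)
    return out


def filter_signatures(
    burdens: dict[str, BurdenVector], min_total_snvs: float = MIN_SIGNATURE_SNVS
) -> list[str]:
    """Signatures whose genome-wide summed burden reaches
    ``min_total_snvs`` (inclusive at the boundary)."""
    kept = sorted(s for s, b in burdens.items() if b.total >= min_total_snvs)
    if not kept:
        logger.warning("no signature passes the %g-SNV filter", min_total_snvs)
    return kept


def class_accuracy_test(
    accuracy: pd.DataFrame,
    class_map: dict[str, str],
    covariate: pd.DataFrame | None = None,
) -> dict:
    """ANOVA of model accuracy across signature aetiology classes.

    Fits ``adj_r2 ~ signature class + mean regional burden`` by OLS over
    (cohort, signature) observations and reports the F-test for the
    class term plus pairwise class contrasts. The burden covariate
    absorbs the advantage that high-burden cohorts have in any
    regression of regional counts.

    Parameters
    ----------
    accuracy
        Columns (cohort, signature, adj_r2).
    class_map
        signature id -> aetiology class.
    covariate
        Optional columns (cohort, signature, mean_burden); merged on the
        first two. Omitted => plain one-way ANOVA.
    """
    df = accuracy[["cohort", "signature", "adj_r2"]].copy()
    df["sig_class"] = df["signature"].map(class_map)
    if df["sig_class"].isna().any():
        missing = sorted(df.loc[df["sig_class"].isna(), "signature"].unique())
        raise ValueError(f"signatures without a class: {missing}")
    if covariate is not None:
        df = df.merge(covariate, on=["cohort", "signature"], validate="one_to_one")
    counts = df["sig_class"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("insufficient replication: need >=2 classes with >=2 obs")
    formula = "adj_r2 ~ C(sig_class)"
    if covariate is not None:
        formula += " + mean_burden"
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    class_row = anova.loc["C(sig_class)"]
    classes = sorted(df["sig_class"].unique())
    contrasts = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            L = np.zeros(len(fit.params))
            names = list(fit.params.index)
            for j, name in enumerate(names):
                if name == f"C(sig_class)[T.{a}]":
                    L[j] += 1
                if name == f"C(sig_class)[T.{b}]":
                    L[j] -= 1
            tt = fit.t_test(L)
            contrasts[(a, b)] = {
                "estimate": float(np.atleast_1d(tt.effect)[0]),
                "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
            }
    return {
        "f_stat": float(class_row["F"]),
        "p_class": float(class_row["PR(>F)"]),
        "anova": anova,
        "contrasts": contrasts,
        "fit": fit,
    }


def conservation_check(
    burdens: dict[str, BurdenVector], all_counts: np.ndarray, tol: float = 1e-6
) -> bool:
    """Do per-window signature burdens sum to the all-SNV counts?"""
    total = np.sum([b.counts for b in burdens.values()], axis=0)
    return bool(np.all(np.abs(total - all_counts) <= tol * np.maximum(all_counts, 1)))
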