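"""Pulldown-enrichment statistics: fold change, t test, FDR, volcano classes.

Downstream analysis of a TMT pulldown comparing proteins bound to the
trapped precursor (+MTX) against the imported control (−MTX): per-protein
log2 fold change, classical unpaired two-tailed t test on log2
intensities, Benjamini–Hochberg adjustment across proteins, volcano
classification at a ≥2-fold cutoff, and the fraction of hits carried by
a reference annotation set (e.g. the MitoCoP compendium of mitochondrial
proteins).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_columns",
    "test_enrichment",
    "classify_volcano",
    "annotation_fraction",
]

CLASSES = ("enhanced_trap", "enhanced_imported", "NS")


def normalize_columns(intensity_table: pd.DataFrame) -> pd.DataFrame:
    """Median-centre each intensity column on the log2 scale.

    Adjusts channels to parity (equal medians) while preserving the
    table's overall scale: column medians are aligned to the *median* of
    the column medians. The robust target makes the operation exact under
    single-channel loading artefacts — rescaling a minority of columns is
    centred back precisely, and an already-centred table passes through
    unchanged. Input and output are linear-scale intensities.
    """
    if (intensity_table <= 0).to_numpy().any():
        raise ValueError("intensities must be positive for log2 centring")
    logged = np.log2(intensity_table)
    medians = logged.median(axis=0)
    centred = logged - medians + medians.median()
    return np.exp2(centred)


def _split_groups(columns, group_labels) -> tuple[list, list]:
    labels = list(group_labels)
    if len(labels) != len(columns):
        raise ValueError("group_labels must match the table's columns")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    # convention: '+MTX'-like group is the one whose label sorts last
    # unless labels are exactly plus/minus tags
    plus = [c for c, l in zip(columns, labels) if "plus" in str(l).lower()
            or str(l) == uniq[1]]
    minus = [c for c in columns if c not in plus]
    return plus, minus


def test_enrichment(table: pd.DataFrame, group_labels,
                    fc_threshold: float = 2.0, alpha: float = 0.05,
                    use_q: bool = True) -> pd.DataFrame:
    """Per-protein enrichment statistics for a two-group pulldown table.

    Parameters
    ----------
    table : linear-scale intensities, rows = proteins, columns = channels.
    group_labels : one label per column; exactly two distinct labels, the
        "+MTX"/trap group being the one containing ``plus`` (else the
        lexicographically larger label).
    use_q : classify on BH-adjusted q values (default) or on raw p.

    Returns
    -------
    DataFrame indexed like ``table`` with columns mean_log2_plusMTX,
    mean_log2_minusMTX, log2fc, t_stat, p, q, volcano_class.

    Notes
    -----
    The test is the classical (pooled-variance) unpaired two-tailed t on
    log2 intensities.  Proteins with zero variance in both groups get the
    documented fallback: p = 1 when the group means tie, else the
    smallest positive float (an exact difference with no scatter).
    """
    plus_cols, minus_cols = _split_groups(table.columns, group_labels)
    lp = np.log2(table[plus_cols].to_numpy(dtype=float))
    lm = np.log2(table[minus_cols].to_numpy(dtype=float))

    mean_p, mean_m = lp.mean(axis=1), lm.mean(axis=1)
    log2fc = mean_p - mean_m
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(lp, lm, axis=1, equal_var=True)

    pooled = lp.var(axis=1, ddof=1) + lm.var(axis=1, ddof=1)
    degenerate = pooled == 0
    if degenerate.any():
        tie = degenerate & np.isclose(log2fc, 0.0)
        shift = degenerate & ~tie
        p = np.asarray(p, dtype=float)
        t_stat = np.asarray(t_stat, dtype=float)
        p[tie], t_stat[tie] = 1.0, 0.0
        p[shift] = np.nextafter(0, 1)
        t_stat[shift] = np.sign(log2fc[shift]) * np.inf

    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "mean_log2_plusMTX": mean_p,
        "mean_log2_minusMTX": mean_m,
        "log2fc": log2fc,
        "t_stat": t_stat,
        "p": p,
        "q": q,
    }, index=table.index)
    out["volcano_class"] = classify_volcano(out, fc_threshold, alpha, use_q)
    return out


def classify_volcano(stats_table: pd.DataFrame, fc_threshold: float = 2.0,
                     alpha: float = 0.05, use_q: bool = True) -> pd.Series:
    """Volcano classification of per-protein statistics.

    ``enhanced_trap``: log2fc ≥ log2(fc_threshold) and significant;
    ``enhanced_imported``: log2fc ≤ −log2(fc_threshold) and significant;
    otherwise ``NS``.  The fold-change cutoff is inclusive (≥2-fold) and
    significance uses the BH-adjusted q (``use_q=False`` switches to raw
    p, since the source protocol is ambiguous).
    """
    lfc_cut = np.log2(fc_threshold)
    sig = stats_table["q" if use_q else "p"] < alpha
    cls = pd.Series("NS", index=stats_table.index, name="volcano_class")
    cls[sig & (stats_table["log2fc"] >= lfc_cut)] = "enhanced_trap"
    cls[sig & (stats_table["log2fc"] <= -lfc_cut)] = "enhanced_imported"
    return cls


def annotation_fraction(protein_ids, annotation_set) -> tuple[int, int, float]:
    """(k, n, k/n): how many of ``protein_ids`` carry the annotation.

    Reports exact arithmetic — e.g. 55 mitochondrial proteins among 238
    hits gives 55/238 = 0.2311...
    """
    ids = list(protein_ids)
    k = len(set(ids) & set(annotation_set))
    n = len(ids)
    return k, n, (k / n if n else float("nan"))
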