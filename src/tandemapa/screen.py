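"""Pooled shRNA proliferation-screen statistics.

Counts-per-million normalization, per-hairpin/per-gene enrichment scores
(mean normalized log2 day-d / day-0 ratios), gene-level depletion tests
against the non-targeting controls, replicate rank-correlation QC and a
diversity-shift test between timepoints.  All statistics are rank-based or
closed-form: no randomness enters after the count table.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffapa import bh_adjust

CONTROL_GENE = "CONTROL"
_COL_RE = re.compile(r"^d(\d+)_r(\d+)$")

META_COLS = ["hairpin_id", "gene", "is_control"]


def count_columns(table: pd.DataFrame) -> list[tuple[int, int, str]]:
    """(day, replicate, column) triples parsed from ``d<day>_r<rep>`` columns."""
    out = []
    for col in table.columns:
        m = _COL_RE.match(str(col))
        if m:
            out.append((int(m.group(1)), int(m.group(2)), col))
    return sorted(out)


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per (day, replicate) column.

    ``cpm = 1e6 * count / column_total``; metadata columns pass through.
    """
    cols = [c for _, _, c in count_columns(table)]
    if not cols:
        raise ValueError("no d<day>_r<rep> count columns found")
    out = table.copy()
    for c in cols:
        total = float(table[c].sum())
        if total <= 0:
            raise ValueError(f"column {c} has zero total count")
        out[c] = 1e6 * table[c].astype(float) / total
    return out


def enrichment_scores(
    cpm: pd.DataFrame, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-hairpin and per-gene log2 day-ratio enrichment scores.

    Per hairpin, replicate and day ``d > 0``:
    ``e = log2((cpm_d + pc) / (cpm_0 + pc))``.  The per-gene score for a day
    is the mean over the gene's hairpins and replicates.  Returns
    (hairpin table with ``score_d<d>_r<r>`` columns, gene x day table).
    """
    cols = count_columns(cpm)
    days = sorted({d for d, _, _ in cols})
    if 0 not in days:
        raise ValueError("day 0 column required")
    reps_by_day = {d: [(r, c) for dd, r, c in cols if dd == d] for d in days}
    hp = cpm[META_COLS].copy()
    for d in days:
        if d == 0:
            continue
        for r, c in reps_by_day[d]:
            c0 = dict((rr, cc) for rr, cc in reps_by_day[0])[r]
            hp[f"score_d{d}_r{r}"] = np.log2(
                (cpm[c].to_numpy(dtype=float) + pseudocount)
                / (cpm[c0].to_numpy(dtype=float) + pseudocount)
            )
    gene_rows = {}
    score_cols = [c for c in hp.columns if c.startswith("score_")]
    for gene, grp in hp.groupby("gene"):
        gene_rows[gene] = {
            f"score_d{d}": grp[[c for c in score_cols if c.startswith(f"score_d{d}_")]]
            .to_numpy()
            .mean()
            for d in days
            if d != 0
        }
    gene_scores = pd.DataFrame(gene_rows).T.sort_index()
    gene_scores.index.name = "gene"
    return hp, gene_scores


def depletion_test(
    hairpin_scores: pd.DataFrame, day: int = 21
) -> pd.DataFrame:
    """One-sided Mann-Whitney depletion test of each gene vs controls.

    Pools each gene's hairpin x replicate log2 ratios at ``day`` and tests
    whether they are stochastically smaller than the control hairpins'
    ratios (exact tail when both groups have <= 10 values and no ties).
    BH adjustment across genes.
    """
    cols = [c for c in hairpin_scores.columns if c.startswith(f"score_d{day}_")]
    if not cols:
        raise ValueError(f"no scores for day {day}")
    ctrl = hairpin_scores.loc[
        hairpin_scores["is_control"].astype(bool), cols
    ].to_numpy().ravel()
    if ctrl.size == 0:
        raise ValueError("no control hairpins")
    rows = []
    for gene, grp in hairpin_scores.groupby("gene"):
        if bool(grp["is_control"].astype(bool).all()):
            continue
        vals = grp[cols].to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"gene {gene}: all scores missing; skipped")
            continue
        if len(set(grp["hairpin_id"])) < 2:
            warnings.warn(f"gene {gene}: fewer than 2 hairpins")
        exact = (
            len(vals) <= 10
            and len(ctrl) <= 10
            and len(np.unique(np.concatenate([vals, ctrl])))
            == len(vals) + len(ctrl)
        )
        res = stats.mannwhitneyu(
            vals, ctrl, alternative="less",
            method="exact" if exact else "asymptotic",
        )
        rows.append({"gene": gene, "U": float(res.statistic), "p": float(res.pvalue),
                     "n_scores": int(len(vals))})
    out = pd.DataFrame(rows).set_index("gene").sort_index()
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def diversity_shift(
    cpm_a: np.ndarray | pd.Series,
    cpm_b: np.ndarray | pd.Series,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test for a shift in the hairpin-abundance curve.

    Compares the log10 cpm distributions of two timepoint columns; a
    depleted subset of hairpins shifts the cumulative curve and raises D.
    Returns (D, p).
    """
    a = np.log10(np.asarray(cpm_a, dtype=float) + pseudocount)
    b = np.log10(np.asarray(cpm_b, dtype=float) + pseudocount)
    if len(a) != len(b):
        raise ValueError("both columns must cover the same hairpin set")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def replicate_concordance(cpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of all count columns (mid-rank ties)."""
    cols = [c for _, _, c in count_columns(cpm)]
    if len(cols) < 2:
        raise ValueError("need >= 2 count columns")
    return cpm[cols].corr(method="spearman")
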