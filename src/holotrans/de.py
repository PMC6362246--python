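"""TPM computation, expression pre-filters and fixed-dispersion DE calls.

The study design has four unreplicated stage libraries (blastula, gastrula,
auricularia, pentactula) with blastula as reference.  With no replicates a
dispersion cannot be estimated, so differential expression is assessed with
a negative-binomial exact test at a fixed dispersion (phi = 0.1; variance =
mu + phi * mu^2).  Genes enter the analysis only if they carry more than 20
mapped read pairs in total and enough mapped bases for 10-fold coverage of
the sequence; a zero count at any single stage never disqualifies a gene by
itself.  A gene is called differentially expressed at a stage when its
library-normalized fold change versus the reference is at least 2 in either
direction and the Benjamini-Hochberg adjusted p-value is below 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

# relative tolerance for the "probability <= observed" tie rule of the
# two-sided exact test; guards float noise on exactly-tied splits
_TIE_RTOL = 1e-12


@dataclass
class CountMatrix:
    """Gene x stage read-pair counts with per-gene effective lengths.

    The first stage column is the reference.  ``read_pair_span`` is the
    number of nucleotides one mapped pair contributes to coverage (200 for
    2 x 100 nt paired-end reads).
    """

    counts: pd.DataFrame  # genes x stages, non-negative integers
    lengths: pd.Series  # per gene, nucleotides
    read_pair_span: int = 200

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths <= 0).any():
            raise ValueError("effective lengths must be positive")
        if self.counts.columns.duplicated().any():
            raise ValueError("stage names must be unique")

    @property
    def stages(self) -> list:
        return list(self.counts.columns)

    @property
    def reference_stage(self) -> str:
        return self.counts.columns[0]


@dataclass(frozen=True)
class DeParams:
    dispersion: float = 0.1
    fold_threshold: float = 2.0
    alpha: float = 0.05
    min_pairs: int = 20
    coverage_multiple: float = 10.0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def compute_tpm(
    counts: pd.DataFrame, lengths: pd.Series
) -> pd.DataFrame:
    """Transcripts-per-million: rate = count/length, scaled to 1e6 per stage.

    An all-zero stage column yields zeros, not NaN.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = lengths.reindex(counts.index)
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    tpm = rate.div(denom.replace(0, np.nan), axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expressed(cm: CountMatrix, p: DeParams = DeParams()) -> pd.Series:
    """Boolean mask: total pairs > min_pairs and total bases >= 10x length.

    Both rules use totals summed across stages, so a zero at any one stage
    never excludes a gene on its own.
    """
    total = cm.counts.sum(axis=1)
    enough_pairs = total > p.min_pairs
    enough_cov = total * cm.read_pair_span >= p.coverage_multiple * cm.lengths
    return enough_pairs & enough_cov


def _equalize(y_ref: int, y_alt: int, lib_ref: float, lib_alt: float):
    """Rescale both counts to the geometric-mean library size, rounding to int."""
    if lib_ref <= 0 or lib_alt <= 0:
        raise ValueError("library sizes must be positive")
    gm = math.sqrt(lib_ref * lib_alt)
    return int(round(y_ref * gm / lib_ref)), int(round(y_alt * gm / lib_alt))


def nb_exact_test(
    y_ref: int,
    y_alt: int,
    lib_ref: float = 1.0,
    lib_alt: float = 1.0,
    dispersion: float = 0.1,
) -> float:
    """Two-sided NB exact test of equal means at fixed dispersion.

    Counts are first rescaled to a common (geometric-mean) library size.
    Conditional on the rescaled total s, each split (k, s-k) has probability
    proportional to f(k; mu, phi) * f(s-k; mu, phi) with null mean
    mu = s/2; the p-value is the normalized mass of all splits no more
    probable than the observed one.  s = 0 returns 1 (no information).
    """
    if y_ref < 0 or y_alt < 0:
        raise ValueError("counts must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    yr, ya = _equalize(y_ref, y_alt, lib_ref, lib_alt)
    s = yr + ya
    if s == 0:
        return 1.0
    mu = s / 2.0
    r = 1.0 / dispersion
    prob = r / (r + mu)
    k = np.arange(s + 1)
    lp = nbinom.logpmf(k, r, prob) + nbinom.logpmf(s - k, r, prob)
    obs = lp[yr]
    tail = lp[lp <= obs + _TIE_RTOL]
    return float(min(1.0, math.exp(logsumexp(tail) - logsumexp(lp))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(cm: CountMatrix, p: DeParams = DeParams()) -> pd.DataFrame:
    """Per-stage DE calls versus the reference stage.

    Returns a table with one row per (filter-passing gene, non-reference
    stage): log2 fold change (library-normalized; a 0.5 pseudo-count is
    applied only when either raw count is zero), raw and BH-adjusted
    p-values (adjusted within each stage), and the DEG flag
    (|logFC| >= log2(fold_threshold) and padj < alpha).
    """
    if len(cm.stages) < 2:
        raise ValueError("need a reference stage and at least one other stage")
    mask = filter_expressed(cm, p)
    genes = cm.counts.index[mask]
    ref = cm.reference_stage
    libs = cm.counts.sum(axis=0).astype(float)
    rows = []
    lfc_cut = math.log2(p.fold_threshold)
    for stage in cm.stages[1:]:
        pvals = []
        lfcs = []
        for g in genes:
            yr = int(cm.counts.at[g, ref])
            ya = int(cm.counts.at[g, stage])
            pv = nb_exact_test(yr, ya, libs[ref], libs[stage], p.dispersion)
            pc = 0.5 if (yr == 0 or ya == 0) else 0.0
            lfc = math.log2(((ya + pc) / libs[stage]) / ((yr + pc) / libs[ref]))
            pvals.append(pv)
            lfcs.append(lfc)
        padj = bh_adjust(pvals)
        for g, lfc, pv, pa in zip(genes, lfcs, pvals, padj):
            rows.append(
                {
                    "gene": g,
                    "stage": stage,
                    "log2_fold_change": lfc,
                    "p_value": pv,
                    "p_adjusted": pa,
                    "is_deg": abs(lfc) >= lfc_cut and pa < p.alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "stage",
            "log2_fold_change",
            "p_value",
            "p_adjusted",
            "is_deg",
        ],
    )
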