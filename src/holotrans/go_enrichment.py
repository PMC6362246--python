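"""Hypergeometric GO-term enrichment without ancestor propagation.

Counts use direct annotations only (the behaviour of running an
enrichment tool with count propagation disabled); the ontology is needed
solely for term names and namespaces.  The enrichment p-value for a term
with k_test annotated genes in a test set of n_test, against k_ref of
n_ref in the reference, is the hypergeometric upper tail P[X >= k_test].
Output rows are post-filtered by annotated-gene count (rows with fewer
than 5 removed) and enrichment ratio (rows below 1.5 removed); stage test
sets and TPM-weighted top-K ranking reproduce the per-stage predominant
term views.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Set, Tuple

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust

#: gene -> set of term ids
AnnotationMap = Mapping[str, Set[str]]
#: term -> (name, namespace)
TermMap = Mapping[str, Tuple[str, str]]

ENRICHMENT_COLUMNS = [
    "term",
    "name",
    "k_test",
    "n_test",
    "k_ref",
    "n_ref",
    "ratio",
    "p_value",
    "p_adjusted",
]


def enrich(
    test: Set[str],
    reference: Set[str],
    annotation: AnnotationMap,
    terms: TermMap | None = None,
) -> pd.DataFrame:
    """One row per term directly annotated in the test set.

    ratio = (k_test/n_test) / (k_ref/n_ref); p = hypergeometric
    P[X >= k_test] for a population of n_ref with k_ref successes and
    n_test draws.  A BH-adjusted column is reported for reference but is
    not used by the downstream filters.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    if not test <= reference:
        raise ValueError("test set must be a subset of the reference set")
    n_test, n_ref = len(test), len(reference)
    term_test: Dict[str, int] = {}
    term_ref: Dict[str, int] = {}
    for g in reference:
        for t in annotation.get(g, ()):
            term_ref[t] = term_ref.get(t, 0) + 1
            if g in test:
                term_test[t] = term_test.get(t, 0) + 1
    rows = []
    for t in sorted(term_test):
        k_test, k_ref = term_test[t], term_ref[t]
        ratio = (k_test / n_test) / (k_ref / n_ref)
        p = float(hypergeom.sf(k_test - 1, n_ref, k_ref, n_test))
        name = terms[t][0] if terms and t in terms else ""
        rows.append(
            {
                "term": t,
                "name": name,
                "k_test": k_test,
                "n_test": n_test,
                "k_ref": k_ref,
                "n_ref": n_ref,
                "ratio": ratio,
                "p_value": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df["p_adjusted"] = bh_adjust(df["p_value"]) if len(df) else []
    return df


def filter_terms(
    rows: pd.DataFrame, min_count: int = 5, min_ratio: float = 1.5
) -> pd.DataFrame:
    """Keep rows with k_test >= min_count and ratio >= min_ratio."""
    if rows.empty:
        return rows
    keep = (rows["k_test"] >= min_count) & (rows["ratio"] >= min_ratio)
    return rows[keep].reset_index(drop=True)


def stage_test_set(
    tpm: pd.DataFrame, degs: Set[str], stage: str
) -> Set[str]:
    """DEGs whose TPM at the stage exceeds both their cross-stage mean and 1."""
    if stage not in tpm.columns:
        raise KeyError(f"unknown stage {stage!r}")
    sub = tpm.loc[[g for g in tpm.index if g in degs]]
    mean = sub.mean(axis=1)
    mask = (sub[stage] > mean) & (sub[stage] > 1.0)
    return set(sub.index[mask])


def rank_predominant_terms(
    rows: pd.DataFrame,
    tpm: pd.DataFrame,
    annotation: AnnotationMap,
    test_set: Set[str],
    stage: str,
    top_k: int = 10,
) -> list:
    """Terms ordered by summed stage TPM over directly annotated test genes.

    Returns at most top_k term ids, descending by summed TPM, ties by term
    id.
    """
    scores = {}
    for t in rows["term"]:
        total = 0.0
        for g in test_set:
            if t in annotation.get(g, ()) and g in tpm.index:
                total += float(tpm.at[g, stage])
        scores[t] = total
    ranked = sorted(scores, key=lambda t: (-scores[t], t))
    return ranked[:top_k]
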