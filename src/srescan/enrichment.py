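"""GO Biological Process enrichment of SRE/NF-Y-positive promoters.

For each BP term the universe of annotated, scanned genes is split into the
term's genes and everyone else, and the enrichment of positive promoter
calls in the term is expressed as an odds ratio.

The headline statistic here is the cross-product ratio of the table

    [[positives_in_group, positives_out_group],
     [total_in_group,     total_out_group    ]]

i.e. numerically the ratio of positive-gene *proportions*
``(pos_in/n_in) / (pos_out/n_out)`` — not the textbook case/control odds
ratio.  That is the reporting convention this package reproduces; the
conventional odds ratio on ``[[pos_in, neg_in], [pos_out, neg_out]]`` is
also computed and reported in its own clearly labeled column.  The exact
Fisher p-value and the exact-conditional 95% CI are computed on the same
proportions table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    pos_in: int
    n_in: int
    pos_out: int
    n_out: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    conventional_or: float
    zero_cell_corrected: bool = False


def read_annotations(path, names_path=None) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read gene->GO TSV (gene_id, go_id[, aspect]) and optional term names.

    When an aspect column is present only Biological Process rows
    ('P' / 'biological_process') are kept; without one, the file is assumed
    to be BP-only (as a QuickGO BP export is).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] >= 3:
        aspect = df[2].str.lower()
        df = df[aspect.isin(["p", "bp", "biological_process"])]
    annotations: dict[str, set[str]] = {}
    for gene, term in zip(df[0], df[1]):
        annotations.setdefault(gene, set()).add(term)
    names: dict[str, str] = {}
    if names_path is not None:
        ndf = pd.read_csv(names_path, sep="\t", header=None, comment="#", dtype=str)
        names = dict(zip(ndf[0], ndf[1]))
    return annotations, names


def build_universe(
    gene_calls: dict[str, bool], annotations: dict[str, set[str]]
) -> dict[str, bool]:
    """Genes with >=1 BP annotation AND a scanned promoter, flagged positive."""
    universe = {g: bool(call) for g, call in gene_calls.items() if annotations.get(g)}
    if not universe:
        raise ValueError("no overlap between scanned genes and GO-annotated genes")
    return universe


def contingency(
    term_genes: set[str], universe: dict[str, bool]
) -> tuple[int, int, int, int]:
    """(pos_in, n_in, pos_out, n_out) counts partitioning the universe."""
    in_group = [g for g in universe if g in term_genes]
    n_in = len(in_group)
    pos_in = sum(universe[g] for g in in_group)
    n_out = len(universe) - n_in
    pos_out = sum(universe.values()) - pos_in
    return pos_in, n_in, pos_out, n_out


def enrichment_statistic(
    pos_in: int, n_in: int, pos_out: int, n_out: int
) -> tuple[float, tuple[float, float], float, bool]:
    """Proportions-table odds ratio, exact 95% CI and two-sided exact p.

    Point estimate = (pos_in * n_out) / (pos_out * n_in) on the table
    [[pos_in, pos_out], [n_in, n_out]].  A zero cell triggers the Haldane
    0.5 continuity correction for the point estimate and flags the row.
    Returns (odds_ratio, (ci_low, ci_high), p, corrected).
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("group totals must be positive")
    if min(pos_in, n_in, pos_out, n_out) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[pos_in, pos_out], [n_in, n_out]], dtype=np.int64)
    corrected = (table == 0).any()
    if corrected:
        t = table + 0.5
        point = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    else:
        point = (pos_in * n_out) / (pos_out * n_in)
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(point), (float(ci.low), float(ci.high)), float(p), bool(corrected)


def conventional_odds_ratio(pos_in: int, n_in: int, pos_out: int, n_out: int) -> float:
    """Textbook OR on [[pos_in, neg_in], [pos_out, neg_out]] (0.5-corrected on zeros)."""
    a, b = pos_in, n_in - pos_in
    c, d = pos_out, n_out - pos_out
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich_all(
    universe: dict[str, bool],
    annotations: dict[str, set[str]],
    term_names: dict[str, str] | None = None,
    min_term_size: int = 10,
    fdr: bool = False,
) -> list[EnrichmentRow]:
    """One EnrichmentRow per BP term with >= min_term_size universe genes.

    Sorted by descending odds ratio, ties by smaller p then term id.  With
    ``fdr=True`` a Benjamini-Hochberg adjusted p replaces the raw p.
    """
    term_names = term_names or {}
    term_to_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_to_genes.setdefault(term, set()).add(gene)
    rows: list[EnrichmentRow] = []
    for term, genes in term_to_genes.items():
        pos_in, n_in, pos_out, n_out = contingency(genes, universe)
        if n_in < min_term_size or n_out == 0:
            continue
        oratio, (lo, hi), p, corrected = enrichment_statistic(pos_in, n_in, pos_out, n_out)
        rows.append(
            EnrichmentRow(
                term_id=term,
                term_name=term_names.get(term, ""),
                pos_in=pos_in,
                n_in=n_in,
                pos_out=pos_out,
                n_out=n_out,
                odds_ratio=oratio,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                conventional_or=conventional_odds_ratio(pos_in, n_in, pos_out, n_out),
                zero_cell_corrected=corrected,
            )
        )
    if fdr and rows:
        ps = np.array([r.p_value for r in rows])
        adj = _benjamini_hochberg(ps)
        rows = [
            EnrichmentRow(**{**r.__dict__, "p_value": float(q)}) for r, q in zip(rows, adj)
        ]
    rows.sort(key=lambda r: (-r.odds_ratio, r.p_value, r.term_id))
    return rows


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df["in_group_ratio"] = df.pos_in / df.n_in
        df["out_group_ratio"] = df.pos_out / df.n_out
    return df


def write_enrichment_tsv(rows: list[EnrichmentRow], path) -> None:
    rows_to_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
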