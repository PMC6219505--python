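"""Preranked gene-set enrichment over prognostic transcript scores.

The transcriptional risk model assigns every transcript a prognostic
score (positive = poor prognosis, negative = protective).  Preranked
GSEA asks whether a curated pathway's members concentrate at either
extreme of that ranking: genes are sorted by score, a running sum gains
|score|^q at each member ("hit") and loses a uniform decrement at each
non-member, and the enrichment score ES is the running sum's maximal
deviation from zero.  Significance comes from a gene-label permutation
null: random member sets of the same size drawn from the ranked genes.
NES normalises ES by the mean |null ES| of matching sign, and the
nominal p-value is the one-sided tail frequency within the
matching-sign null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "preranked_gsea",
    "two_direction_report",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols are uppercased for matching."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            seen: list[str] = []
            for g in members:
                gu = str(g).upper()
                if gu not in seen:
                    seen.append(gu)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = seen
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated
    name / description / member symbols."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected "
                                 "name, description and at least one gene")
            name, _desc, *genes = parts
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"malformed GMT line {lineno}: no genes")
            sets[name] = genes
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [f"{name}\t{collection.provenance or 'na'}\t" + "\t".join(members)
             for name, members in collection.sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _running_sum_es(hit_pos: np.ndarray, weights: np.ndarray,
                    n_genes: int) -> float:
    """ES from sorted 0-based hit positions in a ranking of n_genes.

    The running sum's extrema occur at hit positions (upward steps) and
    immediately before them (after a run of misses), so only those
    candidates are evaluated.
    """
    m = len(hit_pos)
    w = weights[hit_pos]
    tot = w.sum()
    if tot <= 0:
        # degenerate all-zero weights: uniform hit increments
        w = np.ones(m)
        tot = float(m)
    miss_dec = 1.0 / (n_genes - m)
    cum_w = np.cumsum(w) / tot
    ranks = hit_pos + 1  # 1-based
    at_hit = cum_w - (ranks - np.arange(1, m + 1)) * miss_dec
    before_hit = np.concatenate([[0.0], cum_w[:-1]]) - (ranks - 1 - np.arange(m)) * miss_dec
    cand = np.concatenate([at_hit, before_hit, [0.0]])
    return float(cand[np.argmax(np.abs(cand))])


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus run metadata."""

    table: pd.DataFrame  # columns: set, size, es, nes, p_nominal, leading_edge
    n_perm: int
    weight_exponent: float
    seed: int

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["leading_edge"] = out["leading_edge"].map(",".join)
        out.to_csv(path, sep="\t", index=False)


def preranked_gsea(scores: pd.Series | dict, sets: GeneSetCollection,
                   n_perm: int = 1000, weight_exponent: float = 1.0,
                   min_size: int = 10, seed: int = 0,
                   bh_correction: bool = False) -> EnrichmentResult:
    """Weighted preranked GSEA with a gene-label permutation null.

    ``scores`` maps gene symbol to a real prognostic score.  Genes are
    ranked by descending score (ties broken by symbol for determinism).
    Set members absent from the ranking are dropped (logged); sets with
    fewer than ``min_size`` matched genes are skipped.  The nominal p
    is the one-sided frequency of same-sign null ES at least as extreme
    as the observed ES, with a +1 continuity guard so p is in (0, 1].
    """
    if isinstance(scores, dict):
        scores = pd.Series(scores)
    scores = scores.copy()
    scores.index = scores.index.str.upper()
    if scores.index.has_duplicates:
        raise ValueError("duplicate gene symbols in the score ranking")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    ranked = scores.loc[order]
    gene_pos = {g: i for i, g in enumerate(order)}
    n_genes = len(order)
    weights = np.abs(ranked.to_numpy(float)) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.sets.items():
        matched = [g for g in members if g in gene_pos]
        dropped = len(members) - len(matched)
        if dropped:
            logger.info("set %s: %d member(s) absent from ranking, dropped",
                        name, dropped)
        m = len(matched)
        if m < min_size or m >= n_genes:
            logger.info("set %s skipped: %d matched genes (min_size=%d)",
                        name, m, min_size)
            continue
        hit_pos = np.sort(np.array([gene_pos[g] for g in matched]))
        es = _running_sum_es(hit_pos, weights, n_genes)
        null = np.array([
            _running_sum_es(np.sort(rng.choice(n_genes, size=m, replace=False)),
                            weights, n_genes)
            for _ in range(n_perm)
        ])
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign):
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
            nes = es / np.mean(np.abs(same_sign))
        else:
            p, nes = 1.0, 0.0
        # leading edge: members at or beyond the running-sum extremum
        at_hit_vals = _at_hit_values(hit_pos, weights, n_genes)
        if es >= 0:
            peak = int(np.argmax(at_hit_vals))
            leading = [order[p_] for p_ in hit_pos[: peak + 1]]
        else:
            before_vals = _before_hit_values(hit_pos, weights, n_genes)
            trough = int(np.argmin(before_vals))
            leading = [order[p_] for p_ in hit_pos[trough:]]
        rows.append({"set": name, "size": m, "es": es, "nes": float(nes),
                     "p_nominal": float(p), "leading_edge": leading})
    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes",
                                        "p_nominal", "leading_edge"])
    if bh_correction and len(table):
        from scipy.stats import false_discovery_control
        table["p_bh"] = false_discovery_control(table["p_nominal"], method="bh")
    return EnrichmentResult(table, n_perm, weight_exponent, seed)


def _at_hit_values(hit_pos, weights, n_genes):
    m = len(hit_pos)
    w = weights[hit_pos]
    tot = w.sum()
    if tot <= 0:
        w, tot = np.ones(m), float(m)
    cum_w = np.cumsum(w) / tot
    ranks = hit_pos + 1
    return cum_w - (ranks - np.arange(1, m + 1)) / (n_genes - m)


def _before_hit_values(hit_pos, weights, n_genes):
    m = len(hit_pos)
    w = weights[hit_pos]
    tot = w.sum()
    if tot <= 0:
        w, tot = np.ones(m), float(m)
    cum_w = np.concatenate([[0.0], np.cumsum(w)[:-1] / tot])
    ranks = hit_pos + 1
    return cum_w - (ranks - 1 - np.arange(m)) / (n_genes - m)


def two_direction_report(result: EnrichmentResult) -> dict[str, pd.DataFrame]:
    """Split the enrichment table by sign of ES.

    Positive-ES sets are enriched in poor-prognosis (positively scored)
    transcripts; negative-ES sets in good-prognosis transcripts.  Each
    table is ordered by nominal p, then |NES| descending, then name.
    """
    t = result.table
    out = {}
    for key, mask in (("poor_prognosis", t["es"] > 0),
                      ("good_prognosis", t["es"] < 0)):
        sub = t[mask].copy()
        sub["abs_nes"] = sub["nes"].abs()
        sub = sub.sort_values(["p_nominal", "abs_nes", "set"],
                              ascending=[True, False, True], kind="stable")
        out[key] = sub.drop(columns="abs_nes").reset_index(drop=True)
    return out
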