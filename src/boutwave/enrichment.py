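"""Cross-species expression enrichment over a fold-enrichment cutoff grid.

A worm glial gene set (e.g. the CEPsh-glia-enriched list) is compared
against mouse brain cell-type-enriched gene sets through an ortholog map.
For each pair of log2 fold-enrichment cutoffs, the enrichment score is the
frequency of worm-set genes having an ortholog on the mouse list divided by
the same frequency over the whole worm gene universe; genes without any
mouse ortholog are excluded from both proportions.  A chi-square-style
observed/expected construction over the (cell type x cutoff) grid then
normalizes away bias that ortholog mapping alone could introduce, yielding
an association score per cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WORM_CUTOFFS",
    "MOUSE_CUTOFFS",
    "EnrichmentCell",
    "EnrichmentResult",
    "rank_transform",
    "unique_enriched_sets",
    "enrichment_score",
    "enrichment_grid",
    "association_score",
]

WORM_CUTOFFS = (1.0, 1.5, 2.0, 2.5)
MOUSE_CUTOFFS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


def rank_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type gene ranks, highest fold-enrichment = rank 1.

    Ties share their average rank.  Any strictly monotone transform of the
    FE values leaves the ranks unchanged.
    """
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("fold-enrichment values must be finite")
    return table.rank(ascending=False, method="average")


def unique_enriched_sets(table: pd.DataFrame, cutoff: float) -> dict:
    """Genes enriched in exactly one cell type at the given log2 FE cutoff.

    A gene above the cutoff in two or more cell types is dropped from all of
    them, enforcing cell-type specificity of the resulting sets.
    """
    above = table >= cutoff
    n_types = above.sum(axis=1)
    unique = above[n_types == 1]
    return {ct: set(unique.index[unique[ct]]) for ct in table.columns}


@dataclass
class EnrichmentCell:
    """Enrichment score and the counts behind it for one cutoff pair."""

    score: float | None          # None when undefined (no mapped genes)
    n_set_mapped: int            # worm-set genes with >= 1 mouse ortholog
    n_set_hit: int               # ... of which an ortholog is on the mouse list
    n_universe_mapped: int       # worm universe genes with >= 1 mouse ortholog
    n_universe_hit: int


def enrichment_score(worm_set, mouse_set, ortholog_map: pd.DataFrame,
                     worm_universe) -> EnrichmentCell:
    """Ortholog-overlap enrichment of a worm gene set in a mouse gene set.

    A worm gene counts as hitting the mouse set if *any* of its orthologs is
    on the list.  Both proportions condition on having at least one mouse
    ortholog at all, so unmapped genes drop out of numerator and denominator
    alike.
    """
    worm_set = set(worm_set)
    mouse_set = set(mouse_set)
    universe = set(worm_universe)
    if not worm_set <= universe:
        raise ValueError("worm_set must be drawn from the worm gene universe")
    orth = ortholog_map.groupby("worm_gene_id")["mouse_gene_id"].agg(set)
    mapped = set(orth.index) & universe
    hits = {wg for wg in mapped if orth[wg] & mouse_set}
    set_mapped = worm_set & mapped
    set_hits = worm_set & hits
    cell = EnrichmentCell(
        score=None,
        n_set_mapped=len(set_mapped), n_set_hit=len(set_hits),
        n_universe_mapped=len(mapped), n_universe_hit=len(hits),
    )
    if cell.n_set_mapped == 0 or cell.n_universe_hit == 0:
        return cell  # undefined, flagged by score=None
    prop_set = cell.n_set_hit / cell.n_set_mapped
    prop_universe = cell.n_universe_hit / cell.n_universe_mapped
    cell.score = prop_set / prop_universe
    return cell


@dataclass
class EnrichmentResult:
    """Score grid over (worm cutoff, mouse cutoff, cell type)."""

    cells: dict                  # (w_cut, m_cut, cell_type) -> EnrichmentCell
    worm_cutoffs: tuple
    mouse_cutoffs: tuple
    cell_types: tuple

    def score_frame(self) -> pd.DataFrame:
        rows = [
            {"worm_cutoff": w, "mouse_cutoff": m, "cell_type": ct,
             "score": cell.score,
             "n_set_mapped": cell.n_set_mapped, "n_set_hit": cell.n_set_hit,
             "n_universe_mapped": cell.n_universe_mapped,
             "n_universe_hit": cell.n_universe_hit}
            for (w, m, ct), cell in self.cells.items()
        ]
        return pd.DataFrame(rows)


def enrichment_grid(worm_table: pd.DataFrame, mouse_table: pd.DataFrame,
                    ortholog_map: pd.DataFrame,
                    worm_cutoffs=WORM_CUTOFFS,
                    mouse_cutoffs=MOUSE_CUTOFFS,
                    worm_cell_type: str | None = None) -> EnrichmentResult:
    """Enrichment scores over the full cutoff grid.

    The worm set at cutoff w is every gene with log2 FE >= w in
    ``worm_cell_type`` (default: the table's only column); mouse sets use
    the uniqueness rule at each mouse cutoff.
    """
    if worm_cell_type is None:
        if worm_table.shape[1] != 1:
            raise ValueError("worm_cell_type required for multi-column tables")
        worm_cell_type = worm_table.columns[0]
    universe = worm_table.index
    cells = {}
    for m_cut in mouse_cutoffs:
        sets = unique_enriched_sets(mouse_table, m_cut)
        for w_cut in worm_cutoffs:
            worm_set = set(universe[worm_table[worm_cell_type] >= w_cut])
            for ct, mouse_set in sets.items():
                cells[(w_cut, m_cut, ct)] = enrichment_score(
                    worm_set, mouse_set, ortholog_map, universe)
    return EnrichmentResult(cells=cells, worm_cutoffs=tuple(worm_cutoffs),
                            mouse_cutoffs=tuple(mouse_cutoffs),
                            cell_types=tuple(mouse_table.columns))


def association_score(result: EnrichmentResult,
                      reciprocal: bool = False) -> pd.Series:
    """Observed/expected association per cell type, averaged over the grid.

    For each cutoff pair, the expected enrichment score under no cell-type
    specificity is the mean score across cell types at that pair; the
    per-cell association there is observed/expected.  A cell type's overall
    association is the mean over all cutoff pairs where it is defined.
    ``reciprocal=True`` reports expected/observed instead.
    """
    if len(result.cell_types) < 2:
        raise ValueError("association requires at least 2 cell types")
    per_type: dict = {ct: [] for ct in result.cell_types}
    for w in result.worm_cutoffs:
        for m in result.mouse_cutoffs:
            scores = {ct: result.cells[(w, m, ct)].score
                      for ct in result.cell_types}
            defined = {ct: s for ct, s in scores.items() if s is not None}
            if len(defined) < 2:
                continue
            expected = float(np.mean(list(defined.values())))
            if expected <= 0:
                continue
            for ct, s in defined.items():
                ratio = s / expected
                if reciprocal:
                    if ratio > 0:
                        per_type[ct].append(1.0 / ratio)
                else:
                    per_type[ct].append(ratio)
    out = pd.Series({ct: (float(np.mean(v)) if v else np.nan)
                     for ct, v in per_type.items()})
    out.name = "association_score"
    return out
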