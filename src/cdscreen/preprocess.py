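"""Probe-to-gene collapsing, ortholog mapping, and DEG-set merging.

Microarray matrices carry multiple probes per gene and probes with no
gene annotation.  Gene filtering keeps, for each gene symbol, the probe
with the largest interquartile range across all samples (the most
informative measurement), and discards unannotated probes.  Mouse-study
gene symbols are converted to their human orthologs before signatures
from different species are compared, and per-study signed DEG sets are
merged by union, with cross-study sign conflicts kept but marked
ambiguous.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cdscreen.dge import AMBIGUOUS, DOWN, UP
from cdscreen.io_formats import ExpressionStudy, OrthologMap, ProbeAnnotation

logger = logging.getLogger(__name__)


def iqr(values: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    q1, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.75])
    return float(q3 - q1)


def collapse_probes(
    study: ExpressionStudy, ann: ProbeAnnotation
) -> tuple[ExpressionStudy, dict[str, str]]:
    """Collapse a probe-level study to gene level by highest-IQR probe.

    Probes with no gene symbol are discarded.  For each symbol measured by
    several probes, the probe with the largest IQR across all samples is
    kept; IQR ties break by ascending probe id.  Returns the gene-level
    study plus a provenance map gene_symbol -> chosen probe id.
    """
    values = study.values
    by_gene: dict[str, list[str]] = {}
    n_unmapped = 0
    for probe in values.index:
        sym = ann.symbol(str(probe))
        if sym is None:
            n_unmapped += 1
            continue
        by_gene.setdefault(sym, []).append(str(probe))
    if not by_gene:
        raise ValueError("no probe mapped to a gene symbol")
    if n_unmapped:
        logger.info("collapse_probes: discarded %d unannotated probes", n_unmapped)

    arr = values.to_numpy(dtype=float)
    row_pos = {str(p): i for i, p in enumerate(values.index)}
    provenance: dict[str, str] = {}
    for sym in sorted(by_gene):
        probes = by_gene[sym]
        if len(probes) == 1:
            provenance[sym] = probes[0]
        else:
            best = max(
                sorted(probes),
                key=lambda p: (iqr(arr[row_pos[p]]), ),
            )
            # max() keeps the first maximal element of the sorted list,
            # i.e. the lexicographically smallest probe on an exact tie
            provenance[sym] = best
    genes = sorted(provenance)
    rows = [row_pos[provenance[g]] for g in genes]
    collapsed = pd.DataFrame(arr[rows], index=genes, columns=values.columns)
    assert not collapsed.index.has_duplicates
    return ExpressionStudy(values=collapsed, groups=study.groups), provenance


def map_orthologs(genes, omap: OrthologMap):
    """Convert a gene-symbol set (plain or signed) to target-species symbols.

    Accepts a plain set/iterable of symbols (returns a set) or a signed
    dict {symbol: sign} (returns a dict).  Symbols absent from the map are
    dropped (logged); outputs are deduplicated.  When several source
    symbols map to one target in the signed form, agreeing signs pass
    through and conflicts become ambiguous.
    """
    if not isinstance(genes, dict):
        plain = set(genes)
        mapped = {omap.mapping[g] for g in plain if g in omap.mapping}
        dropped = sum(1 for g in plain if g not in omap.mapping)
        if dropped:
            logger.info("map_orthologs: dropped %d symbols with no ortholog",
                        dropped)
        return mapped
    out: dict[str, str] = {}
    dropped = 0
    for src in sorted(genes):
        tgt = omap.mapping.get(src)
        if tgt is None:
            dropped += 1
            continue
        sign = genes[src]
        if tgt in out and out[tgt] != sign:
            out[tgt] = AMBIGUOUS
        else:
            out.setdefault(tgt, sign)
    if dropped:
        logger.info("map_orthologs: dropped %d symbols with no ortholog", dropped)
    return out


def merge_deg_sets(deg_sets: list[dict[str, str]]) -> dict[str, str]:
    """Union signed DEG sets; cross-study sign conflicts become ambiguous.

    Order-invariant and idempotent.  Ambiguous genes stay in the union (a
    gene can still seed network analysis) but are excluded from
    direction-dependent uses by their sign.
    """
    merged: dict[str, str] = {}
    for degs in deg_sets:
        for gene, sign in degs.items():
            if gene not in merged:
                merged[gene] = sign
            elif merged[gene] != sign:
                merged[gene] = AMBIGUOUS
    n_amb = sum(1 for s in merged.values() if s == AMBIGUOUS)
    if n_amb:
        logger.info("merge_deg_sets: %d symbols with conflicting signs", n_amb)
    return dict(sorted(merged.items()))


def directional(degs: dict[str, str]) -> dict[str, str]:
    """Restrict a signed gene set to unambiguous up/down members."""
    return {g: s for g, s in degs.items() if s in (UP, DOWN)}
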