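"""Connectivity scoring and rank aggregation.

A disease signature is compared to every drug signature in a library by
cosine distance d = 1 - cos(u, v) in [0, 2], computed on the genes the
two signatures share.  The distance is mapped to a match score in [0, 1]:

* reverse mode: score = d / 2 (1 = perfect reverser, drug anti-parallel
  to the disease direction — the therapeutic-candidate orientation);
* mimic mode: score = (2 - d) / 2 (1 = perfect mimic).

The two scores sum to 1 for every drug, so either orientation yields the
same downstream machinery with "higher = better".

Ranked lists from several studies are merged by a truncated Borda count:
with base score B, the drug at rank r in a list earns max(0, B - r + 1)
points, so only the top B entries of each list contribute and a drug that
appears consistently near the top across lists accumulates the most
points.  Ties in the consensus break by number of contributing lists,
then by drug id.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cdscreen.io_formats import SignatureLibrary
from cdscreen.signature import SignatureVector, top_genes

logger = logging.getLogger(__name__)

DEFAULT_BASE_SCORE = 50
DEFAULT_TOP_N = 500
DEFAULT_MIN_OVERLAP = 5


def cosine_distance(u: pd.Series, v: pd.Series) -> float:
    """Cosine distance 1 - cos(u, v) on the intersection of defined entries.

    Both inputs are gene-indexed; NaN entries are treated as undefined.
    Raises if the shared index is empty or either vector is zero on it.
    """
    shared = u.index.intersection(v.index)
    if len(shared):
        uu = u.loc[shared].to_numpy(dtype=float)
        vv = v.loc[shared].to_numpy(dtype=float)
        defined = ~(np.isnan(uu) | np.isnan(vv))
        uu, vv = uu[defined], vv[defined]
    else:
        uu = vv = np.empty(0)
    if uu.size == 0:
        raise ValueError("no shared genes between the two vectors")
    nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero vector on the shared gene set")
    return float(1.0 - (uu @ vv) / (nu * nv))


def score_library(
    disease: SignatureVector,
    lib: SignatureLibrary,
    mode: str = "reverse",
    top_n: int = DEFAULT_TOP_N,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Score every library drug against the disease signature.

    The disease signature is first restricted to its ``top_n`` genes by
    absolute coefficient; each drug is scored by cosine distance on the
    overlap of those genes with the drug's defined genes.  Drugs with
    fewer than ``min_overlap`` shared genes are skipped (logged).

    Returns a ranked DataFrame with columns rank, drug_id, score,
    overlap_size, sorted by score descending then drug_id ascending.
    """
    if mode not in ("reverse", "mimic"):
        raise ValueError(f"mode must be 'reverse' or 'mimic', got {mode!r}")
    n = min(top_n, len(disease))
    query_genes = top_genes(disease, n, "both")
    query = disease.coefficients.loc[query_genes]

    lib_genes = lib.values.columns
    shared_order = [g for g in query_genes if g in set(lib_genes)]
    if not shared_order:
        raise ValueError("library genes do not overlap the disease signature")
    q = query.loc[shared_order].to_numpy(dtype=float)
    m = lib.values[shared_order].to_numpy(dtype=float)  # drugs x shared

    records = []
    skipped = 0
    for i, drug in enumerate(lib.values.index):
        row = m[i]
        defined = ~np.isnan(row)
        overlap = int(defined.sum())
        if overlap < min_overlap:
            skipped += 1
            continue
        uu, vv = q[defined], row[defined]
        nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
        if nu == 0.0 or nv == 0.0:
            skipped += 1
            continue
        d = 1.0 - float(uu @ vv) / (nu * nv)
        score = d / 2.0 if mode == "reverse" else (2.0 - d) / 2.0
        records.append((drug, score, overlap))
    if skipped:
        logger.info("score_library: skipped %d drugs below min_overlap=%d",
                    skipped, min_overlap)
    if not records:
        raise ValueError(
            f"no drug passed min_overlap = {min_overlap}; library unusable"
        )
    df = pd.DataFrame(records, columns=["drug_id", "score", "overlap_size"])
    df = df.sort_values(
        ["score", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.attrs["skipped"] = skipped
    df.attrs["mode"] = mode
    return df


def _validate_ranked(df: pd.DataFrame) -> None:
    if "drug_id" not in df.columns or "rank" not in df.columns:
        raise ValueError("ranked list needs 'rank' and 'drug_id' columns")
    if df["drug_id"].duplicated().any():
        dup = df["drug_id"][df["drug_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate drug {dup!r} within a single ranked list")


def borda_merge(
    lists: list[pd.DataFrame], base_score: int = DEFAULT_BASE_SCORE
) -> pd.DataFrame:
    """Merge ranked lists into a consensus by truncated Borda counting.

    Each list awards the drug at rank r max(0, base_score - r + 1) points;
    totals are summed across lists.  Returns a DataFrame with columns
    rank, drug_id, points, n_lists, sorted by points descending, then
    n_lists descending, then drug_id ascending.
    """
    if base_score < 1:
        raise ValueError(f"base_score must be >= 1, got {base_score}")
    if not lists:
        raise ValueError("borda_merge requires at least one ranked list")
    points: dict[str, float] = {}
    appearances: dict[str, int] = {}
    for df in lists:
        _validate_ranked(df)
        for rank, drug in zip(df["rank"], df["drug_id"]):
            pts = max(0, base_score - int(rank) + 1)
            points[drug] = points.get(drug, 0) + pts
            appearances[drug] = appearances.get(drug, 0) + 1
    out = pd.DataFrame(
        {
            "drug_id": list(points),
            "points": [points[d] for d in points],
            "n_lists": [appearances[d] for d in points],
        }
    )
    out = out.sort_values(
        ["points", "n_lists", "drug_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
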