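"""Characteristic Direction disease signatures.

The Characteristic Direction treats differential expression as a
multivariate problem: instead of one statistic per gene, it reports the
unit normal of the linear-discriminant hyperplane separating case from
control samples.  With class-mean difference delta = mu_case - mu_ctrl and
pooled within-group covariance Sigma, the direction solves

    R b = delta,        R = gamma * Sigma + (1 - gamma) * nu * I,

where nu = trace(Sigma) / p keeps the identity shrinkage target on the
same scale as Sigma, and b is normalized to unit Euclidean length.  At
gamma = 0 the direction reduces to delta / ||delta|| (genes ranked purely
by mean shift); larger gamma lets the covariance reweight correlated
genes.  The orientation is fixed so that b' delta > 0, making a positive
coefficient mean "higher in case" in aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from cdscreen.io_formats import CASE, CONTROL, ExpressionStudy

DEFAULT_GAMMA = 0.5
DEFAULT_GENE_CAP = 2000


@dataclass
class SignatureVector:
    """Unit-norm gene-indexed direction; positive coefficient = up in case."""

    coefficients: pd.Series  # index = gene ids
    gamma: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.coefficients.to_numpy(dtype=float)
        norm = float(np.linalg.norm(arr))
        if norm == 0.0:
            raise ValueError("signature vector has no nonzero coefficient")
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"signature vector not unit norm (|b| = {norm})")
        if self.coefficients.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coefficients.index)

    def __len__(self) -> int:
        return len(self.coefficients)


def characteristic_direction(
    study: ExpressionStudy,
    gamma: float = DEFAULT_GAMMA,
    gene_cap: int | None = DEFAULT_GENE_CAP,
    _orient: bool = True,
) -> SignatureVector:
    """Compute the Characteristic Direction signature of a two-group study.

    Parameters
    ----------
    study:
        Gene-level study with ``control``/``case`` labels, >= 2 samples per
        group.
    gamma:
        Covariance shrinkage weight in [0, 1).  0 ignores the covariance
        entirely; values near 1 trust the (rank-deficient when p > n)
        sample covariance.
    gene_cap:
        If the study has more genes than this, the direction is computed on
        the ``gene_cap`` most variable genes (the rest get coefficient 0);
        keeps the p x p solve tractable.  ``None`` disables the cap.
    _orient:
        Internal switch: when False the sign convention b' delta > 0 is not
        enforced (used to verify the label-swap antisymmetry property).
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    study.require_two_groups()
    ctrl = study.values[study.samples_in_group(CONTROL)].to_numpy(dtype=float)
    case = study.values[study.samples_in_group(CASE)].to_numpy(dtype=float)
    genes = study.values.index

    capped = False
    if gene_cap is not None and len(genes) > gene_cap:
        pooled_var = np.concatenate([ctrl, case], axis=1).var(axis=1, ddof=1)
        order = np.argsort(-pooled_var, kind="mergesort")
        keep = np.sort(order[:gene_cap])
        full_genes = genes
        genes = genes[keep]
        ctrl, case = ctrl[keep], case[keep]
        capped = True

    p = len(genes)
    n_c, n_t = ctrl.shape[1], case.shape[1]
    delta = case.mean(axis=1) - ctrl.mean(axis=1)
    if np.all(delta == 0.0):
        raise ValueError("no separation: case and control means are identical")

    if gamma == 0.0:
        b = delta / np.linalg.norm(delta)
    else:
        xc = ctrl - ctrl.mean(axis=1, keepdims=True)
        xt = case - case.mean(axis=1, keepdims=True)
        sigma = (xc @ xc.T + xt @ xt.T) / (n_c + n_t - 2)
        nu = np.trace(sigma) / p
        r = gamma * sigma + (1.0 - gamma) * nu * np.eye(p)
        try:
            b = scipy.linalg.solve(r, delta, assume_a="pos")
        except np.linalg.LinAlgError:
            raise ValueError(
                "regularized covariance is singular; use a smaller gamma"
            ) from None
        b = b / np.linalg.norm(b)

    if _orient and float(b @ delta) < 0:
        b = -b

    coeff = pd.Series(b, index=genes, name="coefficient")
    if capped:
        coeff = coeff.reindex(full_genes, fill_value=0.0)
    return SignatureVector(
        coefficients=coeff,
        gamma=gamma,
        provenance={
            "n_control": n_c,
            "n_case": n_t,
            "n_genes": len(coeff),
            "gene_cap_applied": capped,
        },
    )


def top_genes(
    sig: SignatureVector, n: int, direction: str = "both"
) -> list[str]:
    """Return the n genes most extreme in the requested direction.

    ``up`` sorts by coefficient descending, ``down`` ascending, ``both`` by
    absolute coefficient descending.  Ties break by ascending gene id.
    """
    if n > len(sig):
        raise ValueError(f"n = {n} exceeds signature length {len(sig)}")
    coeff = sig.coefficients
    if direction == "up":
        key = -coeff.to_numpy()
    elif direction == "down":
        key = coeff.to_numpy()
    elif direction == "both":
        key = -np.abs(coeff.to_numpy())
    else:
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    order = np.lexsort((np.asarray(coeff.index, dtype=object), key))
    return [coeff.index[i] for i in order[:n]]


def restrict(sig: SignatureVector, genes: list[str]) -> pd.Series:
    """Coefficients of ``sig`` on a gene subset (order preserved)."""
    return sig.coefficients.loc[genes]


def write_signature(sig: SignatureVector, path) -> None:
    """Signature TSV (gene, coefficient), sorted by |coefficient| desc."""
    order = top_genes(sig, len(sig), "both")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tcoefficient\n")
        for g in order:
            fh.write(f"{g}\t{float(sig.coefficients[g])!r}\n")


def read_signature(path) -> SignatureVector:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureVector(
        coefficients=df["coefficient"].astype(float), gamma=float("nan")
    )
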