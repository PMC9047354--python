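"""Per-bull fertility phenotype from binary AI outcomes.

The corrected non-return rate at 56 days (corrected NRR 56) is the BLUP of
the bull random effect from a linear model on the 0/1 insemination score:

    y = X b + Z u + e,   u ~ N(0, r_b * sigma_p^2 I)

solved through the mixed-model equations with ridge term
lambda_b = (1 - r_b) / r_b on the bull block (other random terms folded into
the residual when disabled). The model is linear — not logistic — on the 0/1
score, matching how national sire-fertility evaluations score non-return.
Fixed effects are one-hot encoded with the first level as reference and an
intercept is always included.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = ["MixedModelSpec", "estimate_bull_effects", "classify_fertility",
           "DEFAULT_FIXED_EFFECT_COLUMNS"]

DEFAULT_FIXED_EFFECT_COLUMNS = (
    "herd_year", "month_year", "parity", "interval_class",
    "weekday", "technician", "semen_category",
)


@dataclass
class MixedModelSpec:
    """Variance configuration of the bull mixed model.

    ``bull_variance_ratio`` is sigma^2_bull / sigma^2_phenotypic (default
    0.01, the ratio used for non-return evaluation); the cow random effect is
    optional and off by default.
    """

    bull_variance_ratio: float = 0.01
    include_cow: bool = False
    cow_variance_ratio: float = 0.01

    def __post_init__(self) -> None:
        for name in ("bull_variance_ratio", "cow_variance_ratio"):
            r = getattr(self, name)
            if not 0.0 < r < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {r}")

    @property
    def lambda_bull(self) -> float:
        r = self.bull_variance_ratio
        return (1.0 - r) / r

    @property
    def lambda_cow(self) -> float:
        r = self.cow_variance_ratio
        return (1.0 - r) / r


def _one_hot(levels: pd.Series, drop_first: bool):
    """Sparse one-hot indicator matrix and its column labels."""
    cats = pd.unique(levels)
    codes = pd.Categorical(levels, categories=cats).codes.astype(int)
    start = 1 if drop_first else 0
    rows = np.flatnonzero(codes >= start)
    col_idx = codes[rows] - start
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, col_idx)),
        shape=(len(levels), len(cats) - start),
    )
    return mat, [cats[k] for k in range(start, len(cats))]


def estimate_bull_effects(records: pd.DataFrame,
                          spec: MixedModelSpec | None = None,
                          fixed_effects=None,
                          bulls=None) -> pd.DataFrame:
    """Solve the mixed-model equations for the per-bull effect (corrected NRR 56).

    Parameters
    ----------
    records
        One row per AI with columns ``bull_id``, ``score`` (0/1), optionally
        ``cow_id`` and the fixed-effect columns.
    fixed_effects
        Column names to include as fixed effects. ``None`` uses every default
        fixed-effect column present in ``records``; pass ``[]`` to disable
        them all explicitly.
    bulls
        Bull universe; bulls without records get estimate 0 and a flag.

    Returns a DataFrame indexed by bull id with columns ``estimate``,
    ``n_records`` and ``no_records``. Estimates are centered at 0 by
    construction (they sum to ~0 whenever every bull has records).
    """
    spec = spec or MixedModelSpec()
    if "bull_id" not in records.columns or "score" not in records.columns:
        raise ValueError("records need bull_id and score columns")
    y = records["score"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("scores must be 0/1")
    observed_bulls = pd.unique(records["bull_id"])
    if len(observed_bulls) < 2:
        raise ValueError("need records from at least 2 bulls")

    if fixed_effects is None:
        fixed_effects = [c for c in DEFAULT_FIXED_EFFECT_COLUMNS
                         if c in records.columns]
    n = len(records)
    blocks = [sparse.csr_matrix(np.ones((n, 1)))]
    labels = ["(intercept)"]
    for col in fixed_effects:
        if col not in records.columns:
            raise ValueError(f"fixed-effect column {col!r} absent from records")
        mat, lvls = _one_hot(records[col], drop_first=True)
        blocks.append(mat)
        labels.extend(f"{col}={lv}" for lv in lvls)
    X = sparse.hstack(blocks, format="csr")

    # reject a singular fixed-effect design, naming the confounded columns
    XtX = (X.T @ X).toarray()
    rank = np.linalg.matrix_rank(XtX)
    if rank < X.shape[1]:
        from scipy.linalg import qr
        _, r, piv = qr(X.toarray(), pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [labels[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
        bad += [labels[p] for p in piv[len(diag):]]
        raise ValueError(f"singular fixed-effect design; confounded columns: {bad}")

    Z, bull_labels = _one_hot(records["bull_id"], drop_first=False)
    q = Z.shape[1]
    lam = spec.lambda_bull
    if spec.include_cow:
        if "cow_id" not in records.columns:
            raise ValueError("include_cow requires a cow_id column")
        Zc, _ = _one_hot(records["cow_id"], drop_first=False)
        W = sparse.hstack([X, Z, Zc], format="csr")
        ridge = sparse.block_diag([
            sparse.csr_matrix((X.shape[1], X.shape[1])),
            lam * sparse.identity(q),
            spec.lambda_cow * sparse.identity(Zc.shape[1]),
        ])
    else:
        W = sparse.hstack([X, Z], format="csr")
        ridge = sparse.block_diag([
            sparse.csr_matrix((X.shape[1], X.shape[1])),
            lam * sparse.identity(q),
        ])
    lhs = (W.T @ W + ridge).tocsc()
    rhs = W.T @ y
    sol = spsolve(lhs, rhs)
    u = sol[X.shape[1]:X.shape[1] + q]

    est = pd.Series(u, index=bull_labels, name="estimate")
    counts = records["bull_id"].value_counts()
    universe = list(bulls) if bulls is not None else list(bull_labels)
    out = pd.DataFrame(index=pd.Index(universe, name="bull_id"))
    out["estimate"] = est.reindex(universe).fillna(0.0)
    out["n_records"] = counts.reindex(universe).fillna(0).astype(int)
    out["no_records"] = out["n_records"] == 0
    return out


def classify_fertility(estimates: pd.Series, rule=("quantile", 0.43)) -> pd.Series:
    """Assign fertile/subfertile classes from bull-effect estimates.

    ``rule`` is ``("quantile", q)`` — exactly ceil(q*n) lowest estimates are
    subfertile, ties broken by bull id order — or ``("threshold", t)`` —
    subfertile iff estimate < t. The numeric cut separating the classes is a
    user decision; no published value exists for it.
    """
    if not np.isfinite(estimates.to_numpy(dtype=float)).all():
        raise ValueError("estimates must be finite")
    kind, value = rule
    if kind == "quantile":
        n = len(estimates)
        k = ceil(value * n)
        order = sorted(estimates.index, key=lambda b: (estimates[b], str(b)))
        sub = set(order[:k])
        labels = ["subfertile" if b in sub else "fertile" for b in estimates.index]
    elif kind == "threshold":
        labels = ["subfertile" if v < value else "fertile" for v in estimates]
    else:
        raise ValueError(f"unknown rule kind {kind!r}")
    return pd.Series(labels, index=estimates.index, name="fertility_class")
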