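"""Pearson correlation matrices and cognate-pair selection.

The first statistical stage of sponge inference correlates every gene of
one RNA class against every gene of another (e.g. all mRNAs against all
lncRNAs) over the shared samples, then selects the "cognate" pairs whose
correlation exceeds a high percentile of the full distribution. The
conditioned miRNA/mRNA correlation distributions used to motivate the
method (restricting mRNAs to those with at least one cognate lncRNA)
are exposed as multiset restrictions of a correlation matrix.

Correlations are pairwise-complete: each cell uses the samples where
both profiles are observed, and is flagged undefined (NaN) when too few
complete pairs remain or a profile has zero variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic.

    ``percentile <= 0`` returns the minimum, ``percentile >= 100`` the
    maximum.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("percentile of an empty/undefined distribution")
    if percentile <= 0:
        return float(values.min())
    rank = min(math.ceil(percentile / 100.0 * values.size), values.size)
    return float(np.partition(values, rank - 1)[rank - 1])


@dataclass
class CorrelationMatrix:
    """Dense correlation grid between two gene sets.

    ``r`` holds Pearson coefficients (NaN = undefined), ``p`` two-sided
    p-values from the t test on r, and ``n_used`` the per-cell count of
    pairwise-complete samples.
    """

    row_ids: list[str]
    col_ids: list[str]
    r: np.ndarray
    p: np.ndarray | None
    n_used: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.row_ids), len(self.col_ids))
        if self.r.shape != shape:
            raise ValidationError(f"r shape {self.r.shape} != id shape {shape}")
        defined = np.isfinite(self.r)
        if np.any(np.abs(self.r[defined]) > 1 + 1e-9):
            raise ValidationError("|r| exceeds 1")
        if self.p is not None and np.any(
            (self.p[np.isfinite(self.p)] < 0) | (self.p[np.isfinite(self.p)] > 1)
        ):
            raise ValidationError("p-values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.row_ids, columns=self.col_ids)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form export: row_id, col_id, r, p, n_used."""
        rows, cols = np.meshgrid(
            np.arange(len(self.row_ids)), np.arange(len(self.col_ids)), indexing="ij"
        )
        out = pd.DataFrame(
            {
                "row_id": np.asarray(self.row_ids, dtype=object)[rows.ravel()],
                "col_id": np.asarray(self.col_ids, dtype=object)[cols.ravel()],
                "r": self.r.ravel(),
                "n_used": self.n_used.ravel().astype(int),
            }
        )
        if self.p is not None:
            out["p"] = self.p.ravel()
        return out

    def defined_values(self) -> np.ndarray:
        return self.r[np.isfinite(self.r)]


def pearson_matrix(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    min_pairs: int = 30,
    compute_p: bool = True,
) -> CorrelationMatrix:
    """Pearson correlation of every gene of *a* against every gene of *b*.

    Uses pairwise-complete samples. A cell is undefined (NaN) when fewer
    than ``min(min_pairs, n_samples)`` (and never fewer than 3) complete
    pairs are available, or when either profile is constant over the
    complete pairs. The residual-missingness guard ``min_pairs``
    defaults to 30 complete pairs.
    """
    if a.sample_ids != b.sample_ids:
        raise ValidationError("matrices must share identically ordered sample ids")
    n_samples = a.n_samples
    eff_min = max(3, min(min_pairs, n_samples))

    A = a.values()
    B = b.values()
    Ma = np.isfinite(A)
    Mb = np.isfinite(B)
    A0 = np.where(Ma, A, 0.0)
    B0 = np.where(Mb, B, 0.0)
    Maf = Ma.astype(float)
    Mbf = Mb.astype(float)

    n = Maf @ Mbf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = A0 @ Mbf.T
        sy = Maf @ B0.T
        sxy = A0 @ B0.T
        sxx = (A0 * A0) @ Mbf.T
        syy = Maf @ (B0 * B0).T
        cov = sxy - sx * sy / n
        var_x = sxx - sx * sx / n
        var_y = syy - sy * sy / n
        r = cov / np.sqrt(var_x * var_y)

    tiny = 1e-12
    undefined = (n < eff_min) | (var_x <= tiny) | (var_y <= tiny)
    n_undef = int(undefined.sum())
    if n_undef:
        logger.info("pearson_matrix: %d undefined cells", n_undef)
    r = np.clip(r, -1.0, 1.0)
    r[undefined] = np.nan
    if a.data is b.data or (a.gene_ids == b.gene_ids and a.data.equals(b.data)):
        # self-correlation of a complete, non-constant profile is exactly 1
        diag = np.arange(min(r.shape))
        keep = ~undefined[diag, diag]
        r[diag[keep], diag[keep]] = 1.0

    p = None
    if compute_p:
        with np.errstate(invalid="ignore", divide="ignore"):
            df = n - 2
            t = r * np.sqrt(df / (1.0 - r * r))
            p = 2.0 * stats.t.sf(np.abs(t), df)
            p = np.where(np.abs(r) >= 1.0, 0.0, p)
        p[~np.isfinite(r)] = np.nan
    return CorrelationMatrix(list(a.gene_ids), list(b.gene_ids), r, p, n.astype(int))


@dataclass
class PairSet:
    """Cognate mRNA/lncRNA pairs selected by correlation percentile."""

    frame: pd.DataFrame  # columns mrna, lncrna, r
    threshold_r: float
    percentile: float
    tail: str = "positive"

    def __post_init__(self) -> None:
        if self.frame.duplicated(["mrna", "lncrna"]).any():
            raise ValidationError("duplicate (mrna, lncrna) pairs")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.frame["mrna"])

    @property
    def lncrna_ids(self) -> list[str]:
        return list(self.frame["lncrna"])

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["mrna"], self.frame["lncrna"]))


def select_top_pairs(
    corr: CorrelationMatrix,
    percentile: float = 99.0,
    tail: str = "positive",
) -> PairSet:
    """Select pairs in the extreme tail of the correlation distribution.

    The cutoff is the nearest-rank *percentile* of all defined r values.
    With ``tail="positive"`` (the default, matching the cognate-pair
    definition) pairs with r >= cutoff are returned; ties at the cutoff
    are included. ``tail="negative"`` selects r <= -cutoff instead
    (anti-correlated partners).
    """
    if tail not in ("positive", "negative"):
        raise ValidationError(f"unknown tail {tail!r}")
    values = corr.defined_values()
    if values.size == 0:
        raise ValidationError("correlation matrix has no defined values")
    cutoff = nearest_rank_percentile(values, percentile)
    with np.errstate(invalid="ignore"):
        mask = corr.r >= cutoff if tail == "positive" else corr.r <= -cutoff
    mask &= np.isfinite(corr.r)
    rows, cols = np.nonzero(mask)
    frame = pd.DataFrame(
        {
            "mrna": np.asarray(corr.row_ids, dtype=object)[rows],
            "lncrna": np.asarray(corr.col_ids, dtype=object)[cols],
            "r": corr.r[rows, cols],
        }
    )
    ascending = tail == "negative"
    frame = frame.sort_values(
        ["r", "mrna", "lncrna"], ascending=[ascending, True, True]
    ).reset_index(drop=True)
    logger.info(
        "select_top_pairs: %d pairs at realized cutoff %.4f (%s tail, pct %.4g)",
        len(frame),
        cutoff,
        tail,
        percentile,
    )
    return PairSet(frame, float(cutoff), float(percentile), tail)


def conditioned_distribution(
    corr: CorrelationMatrix,
    row_subset=None,
    col_subset=None,
) -> np.ndarray:
    """Defined r values restricted to optional row/column id subsets.

    With no subsets this is the full correlation distribution; passing
    the mRNAs that have at least one cognate lncRNA reproduces the
    selection-conditioned miRNA/mRNA distribution, and additionally
    passing the mediator miRNAs the doubly conditioned one.
    """
    r = corr.r
    if row_subset is not None:
        wanted = set(row_subset)
        idx = [i for i, g in enumerate(corr.row_ids) if g in wanted]
        r = r[idx, :]
    if col_subset is not None:
        wanted = set(col_subset)
        idx = [j for j, g in enumerate(corr.col_ids) if g in wanted]
        r = r[:, idx]
    return r[np.isfinite(r)]
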