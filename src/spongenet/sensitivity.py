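"""Sensitivity-correlation scoring of (mRNA, lncRNA, miRNA) triplets.

For a cognate mRNA/lncRNA pair (expression profiles X, Y) and a
candidate mediating miRNA (profile Z), the first-order partial
correlation

    rho_XY|Z = (rho_XY - rho_XZ * rho_ZY) / sqrt((1 - rho_XZ^2)(1 - rho_ZY^2))

measures how much of the X-Y association survives the computational
removal of Z. The sensitivity correlation

    S = rho_XY - rho_XY|Z

is near zero for direct X-Y interactions and approaches rho_XY when the
association is entirely routed through the miRNA — the signature of a
sponge (ceRNA) relationship. Triplets are scored for every selected
pair against every miRNA, purely from the three class-level correlation
matrices, so the full scan is a few dense array operations rather than
per-triplet passes over the data.

A triplet's module class follows the sign of the mRNA-miRNA
correlation: negative is the *pure sponge* configuration (the miRNA
represses both competitors), positive the *mixed TF-sponge*
configuration (consistent with an intervening miRNA-targeted
transcriptional repressor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix, PairSet, nearest_rank_percentile, pearson_matrix
from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

MODULE_CLASSES = ("pure", "mixed", "ambiguous", "undefined")


def partial_correlation(r_xy, r_xz, r_zy, eps: float = 1e-12):
    """First-order partial correlation rho_XY|Z from the three pairwise r.

    Accepts scalars or arrays. Undefined (NaN) wherever |r_xz| or
    |r_zy| >= 1 - eps (degenerate denominator) or an input is NaN;
    never raises on degenerate values.
    """
    r_xy = np.asarray(r_xy, dtype=float)
    r_xz = np.asarray(r_xz, dtype=float)
    r_zy = np.asarray(r_zy, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((1.0 - r_xz * r_xz) * (1.0 - r_zy * r_zy))
        out = (r_xy - r_xz * r_zy) / denom
        degenerate = (np.abs(r_xz) >= 1.0 - eps) | (np.abs(r_zy) >= 1.0 - eps)
    out = np.where(degenerate, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def sensitivity_correlation(r_xy, partial):
    """S = rho_XY - rho_XY|Z; NaN (undefined) propagates from partial."""
    r_xy = np.asarray(r_xy, dtype=float)
    partial = np.asarray(partial, dtype=float)
    out = r_xy - partial
    if out.ndim == 0:
        return float(out)
    return out


def classify_module(r_xz, partial=None):
    """Module class from the sign of the mRNA-miRNA correlation.

    pure if r_xz < 0, mixed if r_xz > 0, ambiguous if exactly 0;
    undefined when r_xz (or, if given, the partial correlation) is NaN.
    """
    r_xz = np.asarray(r_xz, dtype=float)
    undefined = ~np.isfinite(r_xz)
    if partial is not None:
        undefined = undefined | ~np.isfinite(np.asarray(partial, dtype=float))
    out = np.select(
        [undefined, r_xz < 0, r_xz > 0],
        ["undefined", "pure", "mixed"],
        default="ambiguous",
    )
    if out.ndim == 0:
        return str(out)
    return out


@dataclass
class TripletScan:
    """Sensitivity scores for all (pair x miRNA) triplets.

    Component correlations and scores are stored as pairs x miRNAs
    arrays; ``to_frame`` materializes the long triplet table and
    ``to_heatmap`` the pairs x miRNAs S matrix (rows keyed
    ``"mrna|lncrna"``).
    """

    pair_frame: pd.DataFrame  # columns mrna, lncrna, r_xy
    mirna_ids: list[str]
    r_xz: np.ndarray  # (n_pairs, n_mirna) mRNA-miRNA
    r_zy: np.ndarray  # (n_pairs, n_mirna) miRNA-lncRNA
    partial: np.ndarray
    s: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pair_frame)

    @property
    def n_triplets(self) -> int:
        return self.n_pairs * len(self.mirna_ids)

    def _frame_for_mask(self, mask: np.ndarray) -> pd.DataFrame:
        rows, cols = np.nonzero(mask)
        r_xy = self.pair_frame["r_xy"].to_numpy()
        frame = pd.DataFrame(
            {
                "mrna": self.pair_frame["mrna"].to_numpy(dtype=object)[rows],
                "lncrna": self.pair_frame["lncrna"].to_numpy(dtype=object)[rows],
                "mirna": np.asarray(self.mirna_ids, dtype=object)[cols],
                "r_xy": r_xy[rows],
                "r_xz": self.r_xz[rows, cols],
                "r_zy": self.r_zy[rows, cols],
                "partial": self.partial[rows, cols],
                "s": self.s[rows, cols],
            }
        )
        frame["module_class"] = classify_module(
            frame["r_xz"].to_numpy(), frame["partial"].to_numpy()
        )
        return frame

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per triplet with all score components."""
        return self._frame_for_mask(np.ones(self.s.shape, dtype=bool))

    def to_heatmap(self) -> pd.DataFrame:
        keys = self.pair_frame["mrna"] + "|" + self.pair_frame["lncrna"]
        return pd.DataFrame(self.s, index=list(keys), columns=self.mirna_ids)

    def defined_s(self) -> np.ndarray:
        return self.s[np.isfinite(self.s)]


def scan_triplets_from_correlations(
    pairs: PairSet,
    mrna_mirna: CorrelationMatrix,
    mirna_lncrna: CorrelationMatrix,
) -> TripletScan:
    """Score every (pair x miRNA) triplet from precomputed matrices.

    *mrna_mirna* is the mRNA x miRNA correlation matrix, *mirna_lncrna*
    the miRNA x lncRNA one; pair r values come from the pair set.
    Undefined component correlations propagate to undefined scores.
    """
    if mrna_mirna.col_ids != mirna_lncrna.row_ids:
        raise ValidationError("miRNA ids disagree between correlation matrices")
    mrna_index = {g: i for i, g in enumerate(mrna_mirna.row_ids)}
    lnc_index = {g: i for i, g in enumerate(mirna_lncrna.col_ids)}
    try:
        rows = np.array([mrna_index[m] for m in pairs.frame["mrna"]], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"pair mRNA {exc.args[0]!r} absent from matrix") from None
    try:
        cols = np.array([lnc_index[l] for l in pairs.frame["lncrna"]], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"pair lncRNA {exc.args[0]!r} absent from matrix") from None

    r_xz = mrna_mirna.r[rows, :]
    r_zy = mirna_lncrna.r[:, cols].T
    r_xy = pairs.frame["r"].to_numpy(dtype=float)
    partial = partial_correlation(r_xy[:, None], r_xz, r_zy)
    s = r_xy[:, None] - partial
    pair_frame = pd.DataFrame(
        {
            "mrna": pairs.frame["mrna"].to_numpy(dtype=object),
            "lncrna": pairs.frame["lncrna"].to_numpy(dtype=object),
            "r_xy": r_xy,
        }
    )
    return TripletScan(
        pair_frame, list(mrna_mirna.col_ids), r_xz, r_zy, partial, s
    )


def scan_triplets(
    pairs: PairSet,
    mrna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    min_pairs: int = 30,
) -> TripletScan:
    """Score triplets from expression matrices (correlations computed here)."""
    pair_mrnas = sorted(set(pairs.frame["mrna"]))
    pair_lncs = sorted(set(pairs.frame["lncrna"]))
    xz = pearson_matrix(
        mrna.subset_genes(pair_mrnas), mirna, min_pairs=min_pairs, compute_p=False
    )
    zy = pearson_matrix(
        mirna, lncrna.subset_genes(pair_lncs), min_pairs=min_pairs, compute_p=False
    )
    return scan_triplets_from_correlations(pairs, xz, zy)


@dataclass
class TripletSelection:
    """High-S triplets with the realized selection cutoff."""

    frame: pd.DataFrame
    cutoff: float
    mode: str

    def __len__(self) -> int:
        return len(self.frame)

    def selected_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["mrna"], self.frame["lncrna"]))


def select_triplets(
    scan: TripletScan,
    mode: str = "fixed",
    s_threshold: float = 0.3,
    percentile: float = 99.0,
) -> TripletSelection:
    """Select high-sensitivity triplets.

    ``mode="fixed"`` keeps triplets with S strictly above *s_threshold*
    (default 0.3); ``mode="percentile"`` keeps S at or above the
    nearest-rank *percentile* of the defined S distribution. Undefined
    scores are never selected. The realized cutoff is reported.
    """
    if scan.n_triplets == 0:
        raise ValidationError("empty triplet scan")
    if mode == "fixed":
        cutoff = float(s_threshold)
        with np.errstate(invalid="ignore"):
            mask = scan.s > cutoff
    elif mode == "percentile":
        cutoff = nearest_rank_percentile(scan.defined_s(), percentile)
        with np.errstate(invalid="ignore"):
            mask = scan.s >= cutoff
    else:
        raise ValidationError(f"unknown selection mode {mode!r}")
    mask &= np.isfinite(scan.s)
    frame = scan._frame_for_mask(mask)
    frame = frame.sort_values(
        ["s", "mrna", "lncrna", "mirna"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    logger.info(
        "select_triplets: kept %d/%d triplets (mode=%s, cutoff=%.4f)",
        len(frame),
        scan.n_triplets,
        mode,
        cutoff,
    )
    return TripletSelection(frame, cutoff, mode)
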